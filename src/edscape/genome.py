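"""Reference-genome bundle: sequence, gene models, and repeat annotation.

Sequences are held as numpy ``uint8`` arrays of ASCII codes so that read
simulation, pileup construction, and alignment can operate without string
copies.  All internal coordinates are 0-based half-open; emitted GTF/BED/TSV
follow the conventions of those formats (GTF 1-based closed, BED 0-based
half-open).
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from pyfaidx import Fasta

# ASCII codes for the four bases
A, C, G, T = 65, 67, 71, 84
_COMPLEMENT = np.arange(256, dtype=np.uint8)
_COMPLEMENT[A], _COMPLEMENT[C], _COMPLEMENT[G], _COMPLEMENT[T] = T, G, C, A
_COMPLEMENT[ord("N")] = ord("N")

# base -> 2-bit code (A=0, C=1, G=2, T=3); anything else maps to 0
TWOBIT = np.zeros(256, dtype=np.int64)
TWOBIT[C], TWOBIT[G], TWOBIT[T] = 1, 2, 3


def seq_to_array(seq: str) -> np.ndarray:
    return np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8).copy()


def array_to_seq(arr: np.ndarray) -> str:
    return arr.tobytes().decode("ascii")


def revcomp_array(arr: np.ndarray) -> np.ndarray:
    return _COMPLEMENT[arr[::-1]]


def revcomp(seq: str) -> str:
    return array_to_seq(revcomp_array(seq_to_array(seq)))


@dataclass
class GeneModel:
    """A single-transcript protein-coding (or noncoding) gene model.

    ``exons``/``cds`` are sorted lists of 0-based half-open genomic
    intervals.  ``utr5``/``utr3`` are derived exonic intervals outside the
    CDS, named by transcript orientation.
    """

    gene_id: str
    transcript_id: str
    chrom: str
    strand: str  # '+' or '-'
    exons: list[tuple[int, int]]
    cds: list[tuple[int, int]] = field(default_factory=list)
    utr5: list[tuple[int, int]] = field(default_factory=list)
    utr3: list[tuple[int, int]] = field(default_factory=list)

    @property
    def start(self) -> int:
        return self.exons[0][0]

    @property
    def end(self) -> int:
        return self.exons[-1][1]

    @property
    def is_coding(self) -> bool:
        return bool(self.cds)

    @property
    def cds_length(self) -> int:
        return sum(e - s for s, e in self.cds)

    def introns(self) -> list[tuple[int, int]]:
        return [
            (self.exons[i][1], self.exons[i + 1][0])
            for i in range(len(self.exons) - 1)
        ]

    def contains(self, pos: int) -> bool:
        return self.start <= pos < self.end

    def spliced_cds_positions(self) -> np.ndarray:
        """Genomic positions of CDS bases in coding-strand (5'->3') order."""
        pos = np.concatenate([np.arange(s, e) for s, e in self.cds])
        return pos if self.strand == "+" else pos[::-1]

    def cds_offset_of(self, pos: int) -> int | None:
        """0-based offset of ``pos`` within the spliced CDS, coding strand."""
        offset = 0
        intervals = self.cds if self.strand == "+" else self.cds[::-1]
        for s, e in intervals:
            if s <= pos < e:
                return offset + (pos - s if self.strand == "+" else e - 1 - pos)
            offset += e - s
        return None


@dataclass
class RepeatInterval:
    chrom: str
    start: int
    end: int
    name: str  # e.g. "SINE/tRNA:Pre0_SS"
    strand: str = "+"

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class GenomeBundle:
    """Reference sequence plus gene models and repeat intervals."""

    seqs: dict[str, np.ndarray]
    genes: list[GeneModel] = field(default_factory=list)
    repeats: list[RepeatInterval] = field(default_factory=list)

    @property
    def chrom_lengths(self) -> dict[str, int]:
        return {c: len(s) for c, s in self.seqs.items()}

    def sequence(self, chrom: str, start: int, end: int, strand: str = "+") -> str:
        arr = self.seqs[chrom][start:end]
        return array_to_seq(arr if strand == "+" else revcomp_array(arr))

    def base(self, chrom: str, pos: int, strand: str = "+") -> str:
        b = chr(self.seqs[chrom][pos])
        return b if strand == "+" else chr(_COMPLEMENT[ord(b)])

    # ---------------------------------------------------------------- IO
    def write_fasta(self, path: str | Path, width: int = 70) -> None:
        with open(path, "w") as fh:
            for chrom in self.seqs:
                fh.write(f">{chrom}\n")
                seq = array_to_seq(self.seqs[chrom])
                for i in range(0, len(seq), width):
                    fh.write(seq[i : i + width] + "\n")

    def write_gtf(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for g in self.genes:
                attrs = f'gene_id "{g.gene_id}"; transcript_id "{g.transcript_id}";'

                def row(feature: str, s: int, e: int) -> str:
                    return (
                        f"{g.chrom}\tedscape\t{feature}\t{s + 1}\t{e}\t.\t"
                        f"{g.strand}\t.\t{attrs}\n"
                    )

                fh.write(row("gene", g.start, g.end))
                fh.write(row("transcript", g.start, g.end))
                for s, e in g.exons:
                    fh.write(row("exon", s, e))
                for s, e in g.cds:
                    fh.write(row("CDS", s, e))
                for s, e in g.utr5:
                    fh.write(row("five_prime_utr", s, e))
                for s, e in g.utr3:
                    fh.write(row("three_prime_utr", s, e))

    def write_repeat_bed(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for r in self.repeats:
                fh.write(
                    f"{r.chrom}\t{r.start}\t{r.end}\t{r.name}\t0\t{r.strand}\n"
                )


def _parse_gtf_attrs(attrs: str) -> dict[str, str]:
    out = {}
    for part in attrs.strip().split(";"):
        part = part.strip()
        if not part:
            continue
        key, _, val = part.partition(" ")
        out[key] = val.strip().strip('"')
    return out


def read_gtf(path: str | Path) -> list[GeneModel]:
    """Parse a GTF with gene_id/transcript_id attributes into gene models."""
    per_tx: dict[str, dict] = {}
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            chrom, _, feature, start, end, _, strand, _, attrs = line.rstrip(
                "\n"
            ).split("\t")
            info = _parse_gtf_attrs(attrs)
            tx = info.get("transcript_id")
            if tx is None:
                continue
            rec = per_tx.setdefault(
                tx,
                {
                    "gene_id": info.get("gene_id", tx),
                    "chrom": chrom,
                    "strand": strand,
                    "exon": [],
                    "CDS": [],
                    "five_prime_utr": [],
                    "three_prime_utr": [],
                },
            )
            if feature in rec:
                rec[feature].append((int(start) - 1, int(end)))
    genes = []
    for tx, rec in per_tx.items():
        genes.append(
            GeneModel(
                gene_id=rec["gene_id"],
                transcript_id=tx,
                chrom=rec["chrom"],
                strand=rec["strand"],
                exons=sorted(rec["exon"]),
                cds=sorted(rec["CDS"]),
                utr5=sorted(rec["five_prime_utr"]),
                utr3=sorted(rec["three_prime_utr"]),
            )
        )
    genes.sort(key=lambda g: (g.chrom, g.start))
    return genes


def read_repeat_bed(path: str | Path) -> list[RepeatInterval]:
    repeats = []
    with open(path) as fh:
        for line in fh:
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            chrom, start, end, name = fields[:4]
            strand = fields[5] if len(fields) > 5 else "+"
            repeats.append(RepeatInterval(chrom, int(start), int(end), name, strand))
    return repeats


def read_fasta(path: str | Path) -> dict[str, np.ndarray]:
    fa = Fasta(str(path), rebuild=True)
    return {name: seq_to_array(str(fa[name][:])) for name in fa.keys()}


def load_bundle(
    fasta: str | Path, gtf: str | Path | None = None, bed: str | Path | None = None
) -> GenomeBundle:
    return GenomeBundle(
        seqs=read_fasta(fasta),
        genes=read_gtf(gtf) if gtf else [],
        repeats=read_repeat_bed(bed) if bed else [],
    )
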