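"""Alignment ingestion, duplicate removal, filtered pileups, and a
desk-scale seed-and-extend aligner.

Two read representations coexist with identical semantics:

* :class:`ReadAlignment` — one dataclass per read, the unit the public
  contracts are written against.
* :class:`ReadBlock` — a numpy-backed column store of reads sharing a
  chromosome and read length, used on the hot paths (simulation, pileup,
  dedup) where millions of per-object operations would dominate runtime.

Internal coordinates are 0-based half-open.  RNA pileups clip read ends and
drop low-quality bases; DNA pileups apply the quality filter only.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pysam

from .genome import A, C, G, T, TWOBIT, array_to_seq, revcomp_array, seq_to_array

BASE_CODES = {A: 0, C: 1, G: 2, T: 3}
CODE_TO_ASCII = np.array([A, C, G, T], dtype=np.uint8)
ASCII_TO_CODE = np.full(256, 255, dtype=np.uint8)
for _b, _c in BASE_CODES.items():
    ASCII_TO_CODE[_b] = _c


class SamFormatError(ValueError):
    """Raised for malformed SAM records, carrying the record number."""


@dataclass
class ReadAlignment:
    """A single ungapped aligned read (the evidence unit for calling)."""

    read_id: str
    sample_id: str
    chrom: str
    start: int  # 0-based leftmost reference position
    strand: str  # '+' or '-'
    sequence: str
    qualities: np.ndarray  # per-base Phred scores, uint8
    mapq: int = 60

    def __post_init__(self) -> None:
        self.qualities = np.asarray(self.qualities, dtype=np.uint8)
        if len(self.sequence) != len(self.qualities):
            raise SamFormatError(
                f"read {self.read_id}: sequence length {len(self.sequence)} != "
                f"quality length {len(self.qualities)}"
            )
        if self.start < 0:
            raise SamFormatError(f"read {self.read_id}: negative start")

    @property
    def end(self) -> int:
        return self.start + len(self.sequence)


@dataclass
class FastqRead:
    read_id: str
    sequence: str
    qualities: np.ndarray

    def __post_init__(self) -> None:
        self.qualities = np.asarray(self.qualities, dtype=np.uint8)


@dataclass
class ReadBlock:
    """Column-store of same-length reads on one chromosome, sorted by start."""

    sample_id: str
    chrom: str
    starts: np.ndarray  # int64, sorted ascending
    strands: np.ndarray  # uint8: 0='+', 1='-'
    seqs: np.ndarray  # (n, L) uint8 ASCII
    quals: np.ndarray  # (n, L) uint8 Phred
    ids: np.ndarray  # unicode array
    mapq: int = 60

    @property
    def n(self) -> int:
        return len(self.starts)

    @property
    def read_length(self) -> int:
        return self.seqs.shape[1]

    def sort(self) -> "ReadBlock":
        order = np.argsort(self.starts, kind="stable")
        return self.take(order)

    def take(self, idx: np.ndarray) -> "ReadBlock":
        return ReadBlock(
            self.sample_id,
            self.chrom,
            self.starts[idx],
            self.strands[idx],
            self.seqs[idx],
            self.quals[idx],
            self.ids[idx],
            self.mapq,
        )

    def to_alignments(self) -> list[ReadAlignment]:
        return [
            ReadAlignment(
                read_id=str(self.ids[i]),
                sample_id=self.sample_id,
                chrom=self.chrom,
                start=int(self.starts[i]),
                strand="-" if self.strands[i] else "+",
                sequence=array_to_seq(self.seqs[i]),
                qualities=self.quals[i].copy(),
                mapq=self.mapq,
            )
            for i in range(self.n)
        ]

    def overlapping(self, pos: int) -> np.ndarray:
        """Indices of reads covering ``pos`` (starts sorted)."""
        L = self.read_length
        lo = np.searchsorted(self.starts, pos - L + 1, side="left")
        hi = np.searchsorted(self.starts, pos, side="right")
        return np.arange(lo, hi)


def blocks_from_alignments(
    alignments: list[ReadAlignment], sample_id: str | None = None
) -> list[ReadBlock]:
    """Group alignments into per-(chrom, length) blocks."""
    groups: dict[tuple[str, int], list[ReadAlignment]] = {}
    for aln in alignments:
        groups.setdefault((aln.chrom, len(aln.sequence)), []).append(aln)
    blocks = []
    for (chrom, L), alns in sorted(groups.items()):
        blocks.append(
            ReadBlock(
                sample_id=sample_id or alns[0].sample_id,
                chrom=chrom,
                starts=np.array([a.start for a in alns], dtype=np.int64),
                strands=np.array(
                    [1 if a.strand == "-" else 0 for a in alns], dtype=np.uint8
                ),
                seqs=np.vstack([seq_to_array(a.sequence) for a in alns]),
                quals=np.vstack([a.qualities for a in alns]),
                ids=np.array([a.read_id for a in alns]),
                mapq=alns[0].mapq,
            ).sort()
        )
    return blocks


# ------------------------------------------------------------------ SAM IO
def read_sam(
    path: str | Path, sample_id: str | None = None, min_mapq: int = 0
) -> list[ReadAlignment]:
    """Read a SAM file (with @SQ headers) into alignments.

    Unmapped records are skipped; records below ``min_mapq`` are skipped
    ("uniquely mapped" ingest gate).  Malformed records raise
    :class:`SamFormatError` with the record number.
    """
    sample = sample_id if sample_id is not None else Path(path).stem
    out: list[ReadAlignment] = []
    with pysam.AlignmentFile(str(path), "r", check_sq=True) as sam:
        iterator = sam.fetch(until_eof=True)
        i = 0
        while True:
            i += 1
            try:
                try:
                    rec = next(iterator)
                except StopIteration:
                    break
                if rec.is_unmapped:
                    continue
                if rec.mapping_quality < min_mapq:
                    continue
                seq = rec.query_sequence
                quals = rec.query_qualities
                if seq is None or quals is None or len(seq) != len(quals):
                    raise ValueError("sequence/quality mismatch")
                out.append(
                    ReadAlignment(
                        read_id=rec.query_name,
                        sample_id=sample,
                        chrom=rec.reference_name,
                        start=rec.reference_start,
                        strand="-" if rec.is_reverse else "+",
                        sequence=seq,
                        qualities=np.array(quals, dtype=np.uint8),
                        mapq=rec.mapping_quality,
                    )
                )
            except (ValueError, OSError, SamFormatError) as exc:
                raise SamFormatError(f"malformed SAM record {i}: {exc}") from exc
    return out


def _sam_header_lines(chrom_lengths: dict[str, int]) -> list[str]:
    lines = ["@HD\tVN:1.6\tSO:coordinate"]
    for chrom, length in chrom_lengths.items():
        lines.append(f"@SQ\tSN:{chrom}\tLN:{length}")
    lines.append("@PG\tID:edscape\tPN:edscape")
    return lines


def _qual_string(quals: np.ndarray) -> str:
    return (np.asarray(quals, dtype=np.uint8) + 33).tobytes().decode("ascii")


def write_sam(
    alignments: list[ReadAlignment] | list[ReadBlock],
    path: str | Path,
    chrom_lengths: dict[str, int],
    tags: dict[str, str] | None = None,
) -> None:
    """Write alignments (or blocks) as plain SAM with @SQ headers."""
    with open(path, "w") as fh:
        for line in _sam_header_lines(chrom_lengths):
            fh.write(line + "\n")
        for item in alignments:
            if isinstance(item, ReadBlock):
                fh.writelines(_block_sam_lines(item, tags))
            else:
                fh.write(_alignment_sam_line(item, tags))


def _alignment_sam_line(a: ReadAlignment, tags: dict[str, str] | None = None) -> str:
    flag = 16 if a.strand == "-" else 0
    L = len(a.sequence)
    extra = ""
    if tags:
        extra = "\t" + "\t".join(f"{k}:Z:{v}" for k, v in tags.items())
    return (
        f"{a.read_id}\t{flag}\t{a.chrom}\t{a.start + 1}\t{a.mapq}\t{L}M\t*\t0\t0\t"
        f"{a.sequence}\t{_qual_string(a.qualities)}{extra}\n"
    )


def _block_sam_lines(b: ReadBlock, tags: dict[str, str] | None = None) -> list[str]:
    L = b.read_length
    cigar = f"{L}M"
    quals = (b.quals + 33).astype(np.uint8)
    extra = ""
    if tags:
        extra = "\t" + "\t".join(f"{k}:Z:{v}" for k, v in tags.items())
    lines = []
    for i in range(b.n):
        flag = 16 if b.strands[i] else 0
        lines.append(
            f"{b.ids[i]}\t{flag}\t{b.chrom}\t{b.starts[i] + 1}\t{b.mapq}\t{cigar}"
            f"\t*\t0\t0\t{b.seqs[i].tobytes().decode('ascii')}"
            f"\t{quals[i].tobytes().decode('ascii')}{extra}\n"
        )
    return lines


def read_fastq(path: str | Path) -> list[FastqRead]:
    reads = []
    with open(path) as fh:
        while True:
            header = fh.readline().strip()
            if not header:
                break
            seq = fh.readline().strip()
            fh.readline()
            qual = fh.readline().strip()
            reads.append(
                FastqRead(
                    read_id=header[1:].split()[0],
                    sequence=seq,
                    qualities=np.frombuffer(qual.encode(), dtype=np.uint8) - 33,
                )
            )
    return reads


def write_fastq(reads: list[FastqRead], path: str | Path) -> None:
    with open(path, "w") as fh:
        for r in reads:
            fh.write(f"@{r.read_id}\n{r.sequence}\n+\n{_qual_string(r.qualities)}\n")


# --------------------------------------------------------- duplicate removal
def remove_duplicates(alignments: list[ReadAlignment]) -> list[ReadAlignment]:
    """Keep one read per (chrom, start, strand): highest quality sum, ties
    broken by lexicographically smallest read id.  Idempotent."""
    best: dict[tuple[str, int, str], ReadAlignment] = {}
    for a in alignments:
        key = (a.chrom, a.start, a.strand)
        cur = best.get(key)
        if cur is None:
            best[key] = a
            continue
        qa, qc = int(a.qualities.sum()), int(cur.qualities.sum())
        if qa > qc or (qa == qc and a.read_id < cur.read_id):
            best[key] = a
    # preserve input order of the retained reads
    kept = {id(v) for v in best.values()}
    return [a for a in alignments if id(a) in kept]


def remove_duplicates_block(block: ReadBlock) -> ReadBlock:
    """Vectorised duplicate removal with the same retention rule."""
    if block.n == 0:
        return block
    qsum = block.quals.sum(axis=1).astype(np.int64)
    # sort by (start, strand, -qsum, id); first entry of each group wins
    order = np.lexsort((block.ids, -qsum, block.strands, block.starts))
    starts = block.starts[order]
    strands = block.strands[order]
    new_group = np.ones(block.n, dtype=bool)
    new_group[1:] = (np.diff(starts) != 0) | (np.diff(strands.astype(np.int16)) != 0)
    keep = np.sort(order[new_group])
    return block.take(keep)


# ------------------------------------------------------------------ pileup
RNA, DNA = "RNA", "DNA"


class Pileup:
    """Per-position base counts per sample, in DNA and RNA layers.

    Counts are stored as (4, chrom_length) uint32 arrays indexed by the
    2-bit base code; a base contributes only if it passes the Phred filter
    and (for RNA) the end-clip window.
    """

    def __init__(self, chrom_lengths: dict[str, int]):
        self.chrom_lengths = dict(chrom_lengths)
        self._counts: dict[tuple[str, str, str], np.ndarray] = {}

    def _array(self, sample: str, layer: str, chrom: str) -> np.ndarray:
        key = (sample, layer, chrom)
        if key not in self._counts:
            self._counts[key] = np.zeros(
                (4, self.chrom_lengths[chrom]), dtype=np.uint32
            )
        return self._counts[key]

    @property
    def samples(self) -> list[str]:
        return sorted({s for s, _, _ in self._counts})

    def add_block(
        self,
        block: ReadBlock,
        layer: str,
        quality_min: int = 30,
        end_clip: int = 6,
        sample: str | None = None,
    ) -> None:
        if block.n == 0:
            return
        counts = self._array(sample or block.sample_id, layer, block.chrom)
        L = block.read_length
        clip = end_clip if layer == RNA else 0
        mask = block.quals >= quality_min
        if clip:
            mask[:, :clip] = False
            mask[:, L - clip :] = False
        codes = ASCII_TO_CODE[block.seqs]
        mask &= codes != 255
        positions = block.starts[:, None] + np.arange(L)[None, :]
        flat = codes.astype(np.int64) * self.chrom_lengths[block.chrom] + positions
        add = np.bincount(flat[mask], minlength=4 * self.chrom_lengths[block.chrom])
        counts += add.reshape(4, -1).astype(np.uint32)

    def add_alignments(
        self,
        alignments: list[ReadAlignment],
        layer: str,
        quality_min: int = 30,
        end_clip: int = 6,
        sample: str | None = None,
    ) -> None:
        for block in blocks_from_alignments(alignments, sample):
            self.add_block(block, layer, quality_min, end_clip, sample)

    def counts(self, sample: str, layer: str, chrom: str) -> np.ndarray:
        return self._array(sample, layer, chrom)

    def counts_at(self, sample: str, layer: str, chrom: str, pos: int) -> dict:
        arr = self._array(sample, layer, chrom)[:, pos]
        return {"A": int(arr[0]), "C": int(arr[1]), "G": int(arr[2]), "T": int(arr[3])}

    def to_tsv(self, path: str | Path) -> None:
        """Dump nonzero positions: chrom, pos1, sample, A, C, G, T, layer."""
        with open(path, "w") as fh:
            fh.write("chrom\tpos\tsample\tA\tC\tG\tT\tlayer\n")
            for (sample, layer, chrom), arr in sorted(self._counts.items()):
                nz = np.flatnonzero(arr.sum(axis=0))
                for pos in nz:
                    a, c, g, t = (int(arr[k, pos]) for k in range(4))
                    fh.write(
                        f"{chrom}\t{pos + 1}\t{sample}\t{a}\t{c}\t{g}\t{t}\t{layer}\n"
                    )


def build_pileup(
    alignments: list[ReadAlignment] | list[ReadBlock],
    chrom_lengths: dict[str, int],
    layer: str = RNA,
    quality_min: int = 30,
    end_clip: int = 6,
) -> Pileup:
    """Build a filtered pileup from deduplicated alignments of one sample."""
    pileup = Pileup(chrom_lengths)
    if alignments and isinstance(alignments[0], ReadBlock):
        for block in alignments:
            pileup.add_block(block, layer, quality_min, end_clip)
    else:
        pileup.add_alignments(alignments, layer, quality_min, end_clip)
    return pileup


# ------------------------------------------------- seed-and-extend aligner
@dataclass
class AlignmentHit:
    chrom: str
    start: int
    strand: str
    mismatch_count: int
    is_unique: bool = False


class GenomeIndex:
    """Sorted k-mer index over a set of sequences (one strand).

    Lookup is by binary search on the sorted 2-bit k-mer codes, which keeps
    construction vectorised and memory proportional to the genome.
    """

    def __init__(self, seqs: dict[str, np.ndarray], k: int = 16):
        if k > 31:
            raise ValueError("k must be <= 31 for 2-bit packing")
        self.k = k
        self.seqs = seqs
        self.chroms = list(seqs)
        self._codes: dict[str, np.ndarray] = {}
        self._order: dict[str, np.ndarray] = {}
        for chrom, arr in seqs.items():
            codes = kmer_codes(arr, k)
            order = np.argsort(codes, kind="stable")
            self._codes[chrom] = codes[order]
            self._order[chrom] = order

    def seed_positions(self, code: int, chrom: str) -> np.ndarray:
        codes = self._codes[chrom]
        lo = np.searchsorted(codes, code, side="left")
        hi = np.searchsorted(codes, code, side="right")
        return self._order[chrom][lo:hi]


def kmer_codes(arr: np.ndarray, k: int) -> np.ndarray:
    """2-bit packed codes of all k-mers of an ASCII sequence array."""
    codes2 = TWOBIT[arr]
    n = len(arr) - k + 1
    if n <= 0:
        return np.zeros(0, dtype=np.int64)
    out = np.zeros(n, dtype=np.int64)
    for i in range(k):
        out = (out << 2) | codes2[i : i + n]
    return out


def _extend_candidates(
    query: np.ndarray, genome: np.ndarray, cand_starts: np.ndarray, max_mm: int
) -> list[tuple[int, int]]:
    """Count mismatches of full-length ungapped placements; keep <= max_mm."""
    L = len(query)
    hits = []
    for s in np.unique(cand_starts):
        if s < 0 or s + L > len(genome):
            continue
        mm = int(np.count_nonzero(genome[s : s + L] != query))
        if mm <= max_mm:
            hits.append((int(s), mm))
    return hits


def seed_extend_align(
    read_sequence: str,
    genome: dict[str, np.ndarray],
    k: int = 16,
    max_mismatch_frac: float = 0.1,
    index: GenomeIndex | None = None,
    strands: str = "+-",
    seed_stride: int = 1,
) -> list[AlignmentHit]:
    """Find all full-length ungapped placements of a read on the genome.

    Every k-mer of the read (at ``seed_stride`` spacing, plus the final
    k-mer) is looked up in the index; each seed proposes a diagonal which is
    extended to a full-length comparison.  Hits with mismatch fraction at
    most ``max_mismatch_frac`` are returned for the requested strands,
    sorted by mismatch count then coordinate; ``is_unique`` marks a hit that
    is the sole best-scoring placement.
    """
    L = len(read_sequence)
    if L < k:
        raise ValueError(f"read length {L} shorter than seed length {k}")
    if index is None:
        index = GenomeIndex(genome, k)
    max_mm = int(np.floor(max_mismatch_frac * L))
    queries = []
    if "+" in strands:
        queries.append(("+", seq_to_array(read_sequence)))
    if "-" in strands:
        queries.append(("-", revcomp_array(seq_to_array(read_sequence))))
    hits: list[AlignmentHit] = []
    for strand, query in queries:
        qcodes = kmer_codes(query, k)
        offsets = list(range(0, L - k + 1, seed_stride))
        if offsets[-1] != L - k:
            offsets.append(L - k)
        for chrom in index.chroms:
            cand = []
            for off in offsets:
                pos = index.seed_positions(int(qcodes[off]), chrom)
                if len(pos):
                    cand.append(pos - off)
            if not cand:
                continue
            for s, mm in _extend_candidates(
                query, index.seqs[chrom], np.concatenate(cand), max_mm
            ):
                hits.append(AlignmentHit(chrom, s, strand, mm))
    hits.sort(key=lambda h: (h.mismatch_count, h.chrom, h.start, h.strand))
    if hits:
        best = hits[0].mismatch_count
        n_best = sum(1 for h in hits if h.mismatch_count == best)
        hits[0].is_unique = n_best == 1
    return hits
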