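"""Site annotation: genic region, repeat class, recoding consequence, and
flanking sequence context.

Genic assignment is a total function with the fixed precedence
CDS > 3'-UTR > 5'-UTR > intron > noncoding-gene > intergenic across all
overlapping transcripts, so every site receives exactly one label.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from Bio.Seq import Seq
from intervaltree import IntervalTree

from .genome import GeneModel, GenomeBundle, RepeatInterval, revcomp

GENIC_LABELS = ("CDS", "UTR3", "UTR5", "intron", "noncoding-gene", "intergenic")
_PRECEDENCE = {label: i for i, label in enumerate(GENIC_LABELS)}


class AnnotationError(ValueError):
    pass


@dataclass
class RecodingEffect:
    gene: str
    transcript: str
    codon_index: int  # 1-based amino-acid position
    ref_aa: str
    alt_aa: str
    is_synonymous: bool
    notation: str  # e.g. "Q607R"; "Q608Q" style for synonymous


class GeneAnnotator:
    """Interval-tree lookup over gene models for fast genic assignment."""

    def __init__(self, genes: list[GeneModel]):
        self.genes = genes
        self._trees: dict[str, IntervalTree] = {}
        for g in genes:
            tree = self._trees.setdefault(g.chrom, IntervalTree())
            features = [("CDS", g.cds), ("UTR3", g.utr3), ("UTR5", g.utr5)]
            covered = []
            for label, ivs in features:
                for s, e in ivs:
                    tree.addi(s, e, (label, g))
                    covered.append((s, e))
            if not g.is_coding:
                for s, e in g.exons:
                    tree.addi(s, e, ("noncoding-gene", g))
            for s, e in g.introns():
                tree.addi(s, e, ("intron", g))

    def assign(self, chrom: str, pos: int) -> tuple[str, GeneModel | None]:
        tree = self._trees.get(chrom)
        if tree is None:
            return "intergenic", None
        hits = sorted(
            ((_PRECEDENCE[label], label, g) for _, _, (label, g) in tree[pos]),
            key=lambda t: (t[0], t[2].gene_id),
        )
        if not hits:
            return "intergenic", None
        _, label, gene = hits[0]
        return label, gene

    def genes_containing(self, chrom: str, pos: int) -> list[GeneModel]:
        return [g for g in self.genes if g.chrom == chrom and g.contains(pos)]


def assign_genic_region(
    chrom: str, pos: int, annotator: GeneAnnotator
) -> str:
    """Label a site by genic context under the fixed precedence order."""
    return annotator.assign(chrom, pos)[0]


class RepeatAnnotator:
    def __init__(self, repeats: list[RepeatInterval]):
        self._trees: dict[str, IntervalTree] = {}
        for r in repeats:
            self._trees.setdefault(r.chrom, IntervalTree()).addi(r.start, r.end, r)

    def assign(self, chrom: str, pos: int) -> str | None:
        tree = self._trees.get(chrom)
        if tree is None:
            return None
        hits = [iv.data for iv in tree[pos]]  # half-open containment
        if not hits:
            return None
        # overlap ties: smallest interval, then alphabetical name
        hits.sort(key=lambda r: (r.length, r.name))
        return hits[0].name


def assign_repeat(chrom: str, pos: int, annotator: RepeatAnnotator) -> str | None:
    return annotator.assign(chrom, pos)


def recoding_effect(
    bundle: GenomeBundle, gene: GeneModel, pos: int
) -> RecodingEffect:
    """Amino-acid consequence of A->G editing (inosine decoded as G) at a
    CDS position of ``gene``'s transcript.

    The codon is rebuilt from the spliced CDS on the coding strand; the
    edited base becomes G in coding-strand space regardless of genomic
    strand.  codon_index is the 1-based amino-acid position.
    """
    if gene.cds_length % 3 != 0:
        raise AnnotationError(
            f"{gene.transcript_id}: CDS length {gene.cds_length} not divisible by 3"
        )
    offset = gene.cds_offset_of(pos)
    if offset is None:
        raise AnnotationError(f"position {pos} not in CDS of {gene.transcript_id}")
    codon_index = offset // 3 + 1
    cds_positions = gene.spliced_cds_positions()
    codon_genomic = cds_positions[3 * (codon_index - 1) : 3 * codon_index]
    codon = "".join(
        bundle.base(gene.chrom, int(p), gene.strand) for p in codon_genomic
    )
    within = offset % 3
    alt_codon = codon[:within] + "G" + codon[within + 1 :]
    ref_aa = str(Seq(codon).translate())
    alt_aa = str(Seq(alt_codon).translate())
    synonymous = ref_aa == alt_aa
    notation = f"{ref_aa}{codon_index}{alt_aa}"
    return RecodingEffect(
        gene=gene.gene_id,
        transcript=gene.transcript_id,
        codon_index=codon_index,
        ref_aa=ref_aa,
        alt_aa=alt_aa,
        is_synonymous=synonymous,
        notation=notation,
    )


# ----------------------------------------------------- sequence context
def context_frequencies(
    sites: list[tuple[str, int, str]],
    bundle: GenomeBundle,
    flank: int = 5,
) -> tuple[np.ndarray, dict]:
    """Base frequencies at offsets -flank..-1, +1..+flank around sites.

    Flanks are read on the edited strand (reverse complement for '-').
    Returns a (2*flank, 4) row-stochastic matrix over A/C/G/T (rows ordered
    -flank..-1, +1..+flank; N excluded from denominators) and a summary with
    the number of edge-excluded sites.
    """
    offsets = [o for o in range(-flank, flank + 1) if o != 0]
    counts = np.zeros((len(offsets), 4), dtype=np.int64)
    base_index = {"A": 0, "C": 1, "G": 2, "T": 3}
    excluded = 0
    for chrom, pos, strand in sites:
        length = len(bundle.seqs[chrom])
        if pos - flank < 0 or pos + flank >= length:
            excluded += 1
            continue
        window = bundle.sequence(chrom, pos - flank, pos + flank + 1, strand)
        # on '-' the window is already reverse-complemented: index from 5' end
        for row, off in enumerate(offsets):
            b = window[flank + off]
            if b in base_index:
                counts[row, base_index[b]] += 1
    totals = counts.sum(axis=1, keepdims=True)
    freqs = np.divide(counts, totals, out=np.zeros_like(counts, float), where=totals > 0)
    return freqs, {"offsets": offsets, "n_excluded_edge": excluded}


def random_A_background(
    bundle: GenomeBundle, n: int, seed: int
) -> list[tuple[str, int, str]]:
    """Randomly selected genomic A sites (either strand) as a context null."""
    rng = np.random.default_rng(seed)
    chroms = list(bundle.seqs)
    lengths = np.array([len(bundle.seqs[c]) for c in chroms], dtype=float)
    out: list[tuple[str, int, str]] = []
    while len(out) < n:
        ci = int(rng.choice(len(chroms), p=lengths / lengths.sum()))
        chrom = chroms[ci]
        pos = int(rng.integers(0, lengths[ci]))
        strand = "+" if rng.random() < 0.5 else "-"
        if bundle.base(chrom, pos, strand) == "A":
            out.append((chrom, pos, strand))
    return out


def context_table_tsv(freqs: np.ndarray, info: dict, path) -> None:
    with open(path, "w") as fh:
        fh.write("offset\tA\tC\tG\tT\n")
        for row, off in enumerate(info["offsets"]):
            vals = "\t".join(f"{v:.6f}" for v in freqs[row])
            fh.write(f"{off:+d}\t{vals}\n")
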