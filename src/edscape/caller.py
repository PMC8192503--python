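"""Two-round A-to-I editing-site identification.

Round 1 ("de novo") applies, per sample and per candidate position:

I.   DNA homozygosity for the reference base at >= 10 quality-filtered DNA
     reads (strict major-allele fraction 1.0 by default);
II.  RNA evidence from the quality-filtered, end-clipped pileup: at least 3
     variant reads with editing level >= 5%;
III. a paralog guard: variant-supporting reads are realigned with the
     seed-and-extend aligner and the site is discarded when fewer than 50%
     of them realign uniquely to the original locus;
IV.  support in at least 2 samples (counted over samples passing I-III).

Round 2 re-quantifies every master-list site in every sample with at least
10 edited+unedited reads, flagging a sample as edited from a single variant
read; covered-but-unedited records are emitted so pooled denominators stay
correct.  A 4-read floor ("known" mode) serves external low-depth data.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .annot import GeneAnnotator
from .genome import GenomeBundle
from .samio import (
    ASCII_TO_CODE,
    GenomeIndex,
    Pileup,
    ReadBlock,
    seed_extend_align,
)

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}
BASES = "ACGT"


@dataclass
class CallConfig:
    dna_min_depth: int = 10
    dna_major_allele_min_frac: float = 1.0
    rna_quality_min: int = 30
    end_clip: int = 6
    min_edited_reads_r1: int = 3
    min_level_r1: float = 0.05
    blat_qualifying_min_frac: float = 0.5
    min_samples: int = 2
    r2_min_total: int = 10
    r2_min_edited: int = 1
    known_min_total: int = 4
    aligner_k: int = 16
    aligner_max_mismatch_frac: float = 0.1
    max_variant_reads_realigned: int = 50  # cap on per-site realignments

    def __post_init__(self) -> None:
        for frac in ("dna_major_allele_min_frac", "min_level_r1", "blat_qualifying_min_frac"):
            v = getattr(self, frac)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{frac} must be in [0, 1]")


@dataclass
class SiteEvidence:
    chrom: str
    pos: int  # 0-based
    ref_base: str
    var_base: str
    dna_counts: dict[str, np.ndarray]  # sample -> len-4 counts
    rna_counts: dict[str, np.ndarray]
    variant_read_ids: dict[str, list[str]] = field(default_factory=dict)


@dataclass
class EditingSite:
    chrom: str
    pos: int  # 0-based
    edited_strand: str
    mismatch_type: str  # e.g. "A-to-G", expressed on the edited strand
    ref_base: str  # genomic (+) reference base
    var_base: str  # genomic (+) variant base
    n_supporting_samples: int = 0
    genic_region: str | None = None
    repeat_class: str | None = None
    recoding: str | None = None  # notation, e.g. "Q607R"

    @property
    def key(self) -> tuple[str, int, str]:
        return (self.chrom, self.pos, self.edited_strand)


# ------------------------------------------------------------- criteria
def is_dna_homozygous(
    dna_counts: np.ndarray | dict, cfg: CallConfig
) -> tuple[bool, str | None]:
    """Criterion I: depth >= dna_min_depth and the major allele carries at
    least ``dna_major_allele_min_frac`` of quality-filtered DNA bases."""
    counts = _as_counts(dna_counts)
    depth = int(counts.sum())
    if depth < cfg.dna_min_depth:
        return False, None
    major = int(counts.argmax())
    if counts[major] / depth < cfg.dna_major_allele_min_frac:
        return False, None
    return True, BASES[major]


def _as_counts(counts) -> np.ndarray:
    if isinstance(counts, dict):
        return np.array([counts.get(b, 0) for b in BASES], dtype=np.int64)
    return np.asarray(counts, dtype=np.int64)


class MultiAllelicSite(ValueError):
    pass


def classify_mismatch(
    chrom: str,
    pos: int,
    ref_base: str,
    var_base: str,
    annotator: GeneAnnotator | None,
) -> tuple[str, str]:
    """Assign the edited strand and the mismatch type on that strand.

    The strand is the annotated gene strand when the site lies in exactly
    one gene's span; otherwise the strand under which the mismatch reads
    A-to-G if one exists, else '+'.
    """
    genes = annotator.genes_containing(chrom, pos) if annotator else []
    if len(genes) == 1:
        strand = genes[0].strand
    elif (ref_base, var_base) == ("A", "G"):
        strand = "+"
    elif (ref_base, var_base) == ("T", "C"):
        strand = "-"
    else:
        strand = "+"
    if strand == "+":
        mismatch = f"{ref_base}-to-{var_base}"
    else:
        mismatch = f"{_COMP[ref_base]}-to-{_COMP[var_base]}"
    return strand, mismatch


def paralog_filter(
    variant_reads: list,
    chrom: str,
    pos: int,
    genome: dict[str, np.ndarray],
    cfg: CallConfig,
    index: GenomeIndex | None = None,
    cache: dict | None = None,
) -> tuple[bool, float]:
    """Criterion III: realign variant-supporting reads; a read qualifies if
    its unique best placement overlaps the site.  Pass iff the qualifying
    fraction reaches ``blat_qualifying_min_frac``."""
    if not variant_reads:
        return False, 0.0
    reads = variant_reads[: cfg.max_variant_reads_realigned]
    qualifying = 0
    for read in reads:
        key = read.read_id
        result = cache.get(key) if cache is not None else None
        if result is None:
            hits = seed_extend_align(
                read.sequence,
                genome,
                k=cfg.aligner_k,
                max_mismatch_frac=cfg.aligner_max_mismatch_frac,
                index=index,
            )
            best = hits[0] if hits and hits[0].is_unique else None
            result = (best.chrom, best.start, len(read.sequence)) if best else None
            if cache is not None:
                cache[key] = result
        if result is not None:
            hchrom, hstart, hlen = result
            if hchrom == chrom and hstart <= pos < hstart + hlen:
                qualifying += 1
    frac = qualifying / len(reads)
    return frac >= cfg.blat_qualifying_min_frac, frac


# -------------------------------------------------------------- round 1
def call_round1(
    pileup: Pileup,
    rna_blocks: dict[str, list[ReadBlock]],
    bundle: GenomeBundle,
    cfg: CallConfig,
    sample_animal: dict[str, str],
    annotator: GeneAnnotator | None = None,
) -> tuple[list[EditingSite], pd.DataFrame]:
    """De novo identification across samples.

    ``pileup`` must hold RNA layers per sample (deduplicated, quality- and
    clip-filtered, including recovered hyper-edited reads) and DNA layers
    per animal; ``sample_animal`` maps each RNA sample to its DNA donor.
    Returns the master site list (union over samples, deduplicated by
    (chrom, position, strand)) and a per-sample detail table.
    """
    if annotator is None:
        annotator = GeneAnnotator(bundle.genes)
    index = GenomeIndex(bundle.seqs, cfg.aligner_k)
    align_cache: dict[str, tuple | None] = {}
    samples = sorted(rna_blocks)
    support: dict[tuple[str, int], list[str]] = {}
    detail_rows = []

    for sample in samples:
        animal = sample_animal[sample]
        for chrom, length in bundle.chrom_lengths.items():
            rna = pileup.counts(sample, "RNA", chrom).astype(np.int64)
            dna = pileup.counts(animal, "DNA", chrom).astype(np.int64)
            cand = _candidate_positions(rna, dna, bundle.seqs[chrom], cfg)
            blocks = [b for b in rna_blocks[sample] if b.chrom == chrom]
            for pos, ref_b, var_b, var_n, level in cand:
                reads = _variant_reads(blocks, pos, var_b, cfg)
                ok, frac = paralog_filter(
                    reads, chrom, pos, bundle.seqs, cfg, index, align_cache
                )
                detail_rows.append(
                    {
                        "sample": sample,
                        "chrom": chrom,
                        "pos": pos,
                        "ref": ref_b,
                        "var": var_b,
                        "edited_reads": var_n,
                        "level": level,
                        "blat_fraction": frac,
                        "pass": ok,
                    }
                )
                if ok:
                    support.setdefault((chrom, pos), []).append(sample)

    master: list[EditingSite] = []
    for (chrom, pos), supporting in sorted(support.items()):
        if len(supporting) < cfg.min_samples:
            continue
        ref_b = chr(bundle.seqs[chrom][pos])
        var_b = _pooled_variant_base(pileup, supporting, chrom, pos, ref_b)
        strand, mismatch = classify_mismatch(chrom, pos, ref_b, var_b, annotator)
        master.append(
            EditingSite(
                chrom=chrom,
                pos=pos,
                edited_strand=strand,
                mismatch_type=mismatch,
                ref_base=ref_b,
                var_base=var_b,
                n_supporting_samples=len(supporting),
            )
        )
    detail = pd.DataFrame(
        detail_rows,
        columns=[
            "sample", "chrom", "pos", "ref", "var",
            "edited_reads", "level", "blat_fraction", "pass",
        ],
    )
    return master, detail


def _candidate_positions(rna, dna, ref_arr, cfg: CallConfig):
    """Vectorised screen for criteria I + II; returns per-position records
    (pos, ref_base, var_base, var_count, level), multi-allelic sites dropped."""
    ref_codes = ASCII_TO_CODE[ref_arr].astype(np.int64)
    valid_ref = ref_codes != 255
    positions = np.arange(len(ref_arr))

    dna_depth = dna.sum(axis=0)
    dna_major = dna.max(axis=0)
    ref_dna = np.where(valid_ref, dna[np.clip(ref_codes, 0, 3), positions], 0)
    homozygous = (
        (dna_depth >= cfg.dna_min_depth)
        & (dna_major == ref_dna)
        & (ref_dna >= np.ceil(cfg.dna_major_allele_min_frac * dna_depth))
        & valid_ref
    )

    non_ref = rna.copy()
    non_ref[np.clip(ref_codes, 0, 3), positions] = 0
    order = np.argsort(non_ref, axis=0)
    var_code = order[-1]
    var_count = np.take_along_axis(non_ref, var_code[None, :], axis=0)[0]
    second_count = np.take_along_axis(non_ref, order[-2][None, :], axis=0)[0]
    ref_count = np.where(valid_ref, rna[np.clip(ref_codes, 0, 3), positions], 0)
    pair_total = ref_count + var_count
    with np.errstate(divide="ignore", invalid="ignore"):
        level = np.where(pair_total > 0, var_count / np.maximum(pair_total, 1), 0.0)

    cand = (
        homozygous
        & (var_count >= cfg.min_edited_reads_r1)
        & (level >= cfg.min_level_r1)
        & (second_count < cfg.min_edited_reads_r1)  # multi-allelic dropped
        & (second_count < var_count)  # tie between variants -> ambiguous
    )
    out = []
    for pos in np.flatnonzero(cand):
        out.append(
            (
                int(pos),
                BASES[ref_codes[pos]],
                BASES[var_code[pos]],
                int(var_count[pos]),
                float(level[pos]),
            )
        )
    return out


def _variant_reads(blocks: list[ReadBlock], pos: int, var_base: str, cfg: CallConfig):
    """Reads whose filtered base at ``pos`` is the variant."""
    from .samio import ReadAlignment
    from .genome import array_to_seq

    want = ord(var_base)
    out = []
    for b in blocks:
        idx = b.overlapping(pos)
        if len(idx) == 0:
            continue
        cols = pos - b.starts[idx]
        keep = (
            (b.seqs[idx, cols] == want)
            & (b.quals[idx, cols] >= cfg.rna_quality_min)
            & (cols >= cfg.end_clip)
            & (cols < b.read_length - cfg.end_clip)
        )
        for i in idx[keep]:
            out.append(
                ReadAlignment(
                    read_id=str(b.ids[i]),
                    sample_id=b.sample_id,
                    chrom=b.chrom,
                    start=int(b.starts[i]),
                    strand="-" if b.strands[i] else "+",
                    sequence=array_to_seq(b.seqs[i]),
                    qualities=b.quals[i],
                    mapq=b.mapq,
                )
            )
    return out


def _pooled_variant_base(
    pileup: Pileup, samples: list[str], chrom: str, pos: int, ref_base: str
) -> str:
    pooled = np.zeros(4, dtype=np.int64)
    for s in samples:
        pooled += pileup.counts(s, "RNA", chrom)[:, pos].astype(np.int64)
    pooled[BASES.index(ref_base)] = 0
    return BASES[int(pooled.argmax())]


# -------------------------------------------------------------- round 2
def call_round2(
    master: list[EditingSite],
    pileup: Pileup,
    samples: list[str],
    cfg: CallConfig,
    mode: str = "denovo",
) -> pd.DataFrame:
    """Per-sample quantification of master-list sites.

    A (site, sample) record is emitted when edited + unedited reads reach
    the coverage floor (``r2_min_total``, or ``known_min_total`` in
    ``mode='known'``); the ``edited`` flag requires ``r2_min_edited``
    variant reads.  Covered-but-unedited records are retained.
    """
    min_total = cfg.known_min_total if mode == "known" else cfg.r2_min_total
    rows = []
    for site in master:
        ref_i = BASES.index(site.ref_base)
        var_i = BASES.index(site.var_base)
        for sample in samples:
            counts = pileup.counts(sample, "RNA", site.chrom)[:, site.pos]
            ref_n, var_n = int(counts[ref_i]), int(counts[var_i])
            total = ref_n + var_n
            if total < min_total:
                continue
            rows.append(
                {
                    "chrom": site.chrom,
                    "pos": site.pos,
                    "strand": site.edited_strand,
                    "mismatch": site.mismatch_type,
                    "sample": sample,
                    "unedited": ref_n,
                    "edited": var_n,
                    "total": total,
                    "level": var_n / total,
                    "is_edited": var_n >= cfg.r2_min_edited,
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "chrom", "pos", "strand", "mismatch", "sample",
            "unedited", "edited", "total", "level", "is_edited",
        ],
    )


# ------------------------------------------------------------------- IO
def master_to_tsv(master: list[EditingSite], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("chrom\tpos\tstrand\tmismatch\tref\tvar\tn_supporting_samples\t"
                 "genic_region\trepeat_class\trecoding\n")
        for s in master:
            fh.write(
                f"{s.chrom}\t{s.pos + 1}\t{s.edited_strand}\t{s.mismatch_type}\t"
                f"{s.ref_base}\t{s.var_base}\t{s.n_supporting_samples}\t"
                f"{s.genic_region or '.'}\t{s.repeat_class or '.'}\t"
                f"{s.recoding or '.'}\n"
            )


def master_from_tsv(path: str | Path) -> list[EditingSite]:
    df = pd.read_csv(path, sep="\t", na_values=".", keep_default_na=False)
    out = []
    for _, r in df.iterrows():
        out.append(
            EditingSite(
                chrom=str(r["chrom"]),
                pos=int(r["pos"]) - 1,
                edited_strand=str(r["strand"]),
                mismatch_type=str(r["mismatch"]),
                ref_base=str(r["ref"]),
                var_base=str(r["var"]),
                n_supporting_samples=int(r["n_supporting_samples"]),
                genic_region=r["genic_region"] if r["genic_region"] else None,
                repeat_class=r["repeat_class"] if r["repeat_class"] else None,
                recoding=r["recoding"] if r["recoding"] else None,
            )
        )
    return out


def write_bedgraph(
    quant: pd.DataFrame, region_samples: list[str], path: str | Path
) -> None:
    """Per-region browser track: chrom, start0, end, pooled level x 100."""
    sub = quant[quant["sample"].isin(region_samples)]
    pooled = (
        sub.groupby(["chrom", "pos"])[["edited", "total"]].sum().reset_index()
    )
    with open(path, "w") as fh:
        fh.write('track type=bedGraph name="editing_level"\n')
        for _, r in pooled.sort_values(["chrom", "pos"]).iterrows():
            level = 100.0 * r["edited"] / r["total"] if r["total"] else 0.0
            fh.write(f"{r['chrom']}\t{int(r['pos'])}\t{int(r['pos']) + 1}\t{level:.2f}\n")
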