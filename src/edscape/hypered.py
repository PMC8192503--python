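"""Hyper-edited read recovery by base-transformed realignment.

Reads so densely A-to-G edited that direct alignment fails are recovered by
collapsing the editing channel: every A in the read and in the genome is
replaced by G, the transformed read is realigned, and the original sequence
is restored at the recovered locus.  Antisense transcripts are covered by
aligning the reverse complement of the transformed read against the T->C
transformed forward genome, which is the algebraic mirror of the A->G
scheme on the other strand.

A recovered placement is accepted when, in original sequence space, the
A->G channel dominates the mismatches: at least ``min_edits_per_read`` A->G
mismatches, an A->G share of at least ``min_ag_fraction_of_mismatches``,
and a non-A->G mismatch fraction of at most ``max_other_mismatch_frac``.  A
read that realigns with no mismatches at all passes through unchanged (it
is simply alignable, not hyper-edited).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .genome import A, C, G, T, array_to_seq, revcomp_array, seq_to_array
from .samio import (
    AlignmentHit,
    FastqRead,
    GenomeIndex,
    ReadAlignment,
    seed_extend_align,
)


@dataclass
class HyperConfig:
    min_ag_fraction_of_mismatches: float = 0.6
    min_edits_per_read: int = 5
    max_other_mismatch_frac: float = 0.05
    aligner_k: int = 16
    # generous mismatch budget in transformed space: residual mismatches
    # there are sequencing errors, not edits
    aligner_max_mismatch_frac: float = 0.1

    def __post_init__(self) -> None:
        for name in ("min_ag_fraction_of_mismatches", "max_other_mismatch_frac"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")


def transform(seq: str, from_base: str, to_base: str) -> str:
    """Replace every ``from_base`` by ``to_base``; length-preserving and
    idempotent."""
    return seq.replace(from_base, to_base)


def transform_array(arr: np.ndarray, from_base: int, to_base: int) -> np.ndarray:
    out = arr.copy()
    out[out == from_base] = to_base
    return out


@dataclass
class RecoveryReport:
    read_id: str
    status: str  # recovered | clean | no_hit | not_unique | too_few_edits |
    #              low_ag_fraction | too_many_other_mismatches
    chrom: str | None = None
    start: int | None = None
    strand: str | None = None
    n_ag: int = 0
    n_other: int = 0


class HyperAligner:
    """Seed indexes over the A->G and T->C transformed genomes."""

    def __init__(self, seqs: dict[str, np.ndarray], k: int = 16):
        self.seqs = seqs
        self.ag = {c: transform_array(s, A, G) for c, s in seqs.items()}
        self.tc = {c: transform_array(s, T, C) for c, s in seqs.items()}
        self.index_ag = GenomeIndex(self.ag, k)
        self.index_tc = GenomeIndex(self.tc, k)
        self.k = k


def recover_hyper_edited(
    unmapped_reads: list[FastqRead],
    seqs: dict[str, np.ndarray],
    cfg: HyperConfig | None = None,
    sample_id: str = "sample",
    aligner: HyperAligner | None = None,
) -> tuple[list[ReadAlignment], list[RecoveryReport]]:
    """Recover hyper-edited reads from an unmapped pool.

    Returns alignments carrying the ORIGINAL sequences (genomic-forward
    orientation) and a per-read report with a reason code for every input
    read.
    """
    cfg = cfg or HyperConfig()
    if aligner is None:
        aligner = HyperAligner(seqs, cfg.aligner_k)
    recovered: list[ReadAlignment] = []
    reports: list[RecoveryReport] = []
    for read in unmapped_reads:
        report = _recover_one(read, aligner, cfg, sample_id, recovered)
        reports.append(report)
    return recovered, reports


def _recover_one(
    read: FastqRead,
    aligner: HyperAligner,
    cfg: HyperConfig,
    sample_id: str,
    recovered: list[ReadAlignment],
) -> RecoveryReport:
    arr = seq_to_array(read.sequence)
    r_ag = transform_array(arr, A, G)
    hits: list[tuple[AlignmentHit, str]] = []
    for hit in seed_extend_align(
        array_to_seq(r_ag),
        aligner.ag,
        k=aligner.k,
        max_mismatch_frac=cfg.aligner_max_mismatch_frac,
        index=aligner.index_ag,
        strands="+",
    ):
        hits.append((hit, "+"))
    for hit in seed_extend_align(
        array_to_seq(revcomp_array(r_ag)),
        aligner.tc,
        k=aligner.k,
        max_mismatch_frac=cfg.aligner_max_mismatch_frac,
        index=aligner.index_tc,
        strands="+",
    ):
        hits.append((hit, "-"))
    if not hits:
        return RecoveryReport(read.read_id, "no_hit")
    hits.sort(key=lambda hs: (hs[0].mismatch_count, hs[0].chrom, hs[0].start, hs[1]))
    best_mm = hits[0][0].mismatch_count
    if sum(1 for h, _ in hits if h.mismatch_count == best_mm) > 1:
        return RecoveryReport(read.read_id, "not_unique")
    hit, strand = hits[0]

    # restore the original read in genomic-forward orientation
    if strand == "+":
        fwd_seq, fwd_quals = arr, read.qualities
    else:
        fwd_seq, fwd_quals = revcomp_array(arr), read.qualities[::-1]
    ref = aligner.seqs[hit.chrom][hit.start : hit.start + len(fwd_seq)]
    mismatch = ref != fwd_seq
    if strand == "+":
        ag = mismatch & (ref == A) & (fwd_seq == G)
    else:
        ag = mismatch & (ref == T) & (fwd_seq == C)
    n_ag = int(ag.sum())
    n_other = int(mismatch.sum()) - n_ag
    n_mm = n_ag + n_other

    status = "recovered"
    if n_mm == 0:
        status = "clean"  # alignable as-is; pass through
    elif n_ag < cfg.min_edits_per_read:
        return RecoveryReport(read.read_id, "too_few_edits", n_ag=n_ag, n_other=n_other)
    elif n_ag / n_mm < cfg.min_ag_fraction_of_mismatches:
        return RecoveryReport(read.read_id, "low_ag_fraction", n_ag=n_ag, n_other=n_other)
    elif n_other / len(fwd_seq) > cfg.max_other_mismatch_frac:
        return RecoveryReport(
            read.read_id, "too_many_other_mismatches", n_ag=n_ag, n_other=n_other
        )
    recovered.append(
        ReadAlignment(
            read_id=read.read_id,
            sample_id=sample_id,
            chrom=hit.chrom,
            start=hit.start,
            strand=strand,
            sequence=array_to_seq(fwd_seq),
            qualities=np.asarray(fwd_quals, dtype=np.uint8),
            mapq=60,
        )
    )
    return RecoveryReport(
        read.read_id, status, hit.chrom, hit.start, strand, n_ag, n_other
    )


def report_to_tsv(reports: list[RecoveryReport], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("read_id\tstatus\tchrom\tpos\tstrand\tn_ag\tn_other\n")
        for r in reports:
            pos = "" if r.start is None else str(r.start + 1)
            fh.write(
                f"{r.read_id}\t{r.status}\t{r.chrom or ''}\t{pos}\t"
                f"{r.strand or ''}\t{r.n_ag}\t{r.n_other}\n"
            )
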