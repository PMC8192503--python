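"""In-memory orchestration of the editing-landscape stages.

The CLI, the test fixtures, and the acceptance script all drive the same
stage functions defined here: simulate -> deduplicate -> hyper-recover ->
pileup -> round-1 call -> round-2 quantify -> annotate -> landscape stats.
Each function is a thin composition of the per-module operations; no stage
re-implements another module's logic.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import annot, caller, hypered, simdata, stats
from .genome import GenomeBundle
from .samio import (
    Pileup,
    ReadBlock,
    blocks_from_alignments,
    remove_duplicates_block,
)


@dataclass
class PipelineResult:
    config: simdata.SimConfig
    call_config: caller.CallConfig
    bundle: GenomeBundle
    truth: simdata.TruthSet
    reads: simdata.SimReads
    rna_blocks: dict[str, list[ReadBlock]]
    pileup: Pileup
    recovered: dict[str, list] = field(default_factory=dict)
    recovery_reports: dict[str, list] = field(default_factory=dict)
    master: list[caller.EditingSite] = field(default_factory=list)
    round1_detail: pd.DataFrame | None = None
    quant: pd.DataFrame | None = None
    matrix: stats.EditingMatrix | None = None
    region_matrix: stats.EditingMatrix | None = None


def simulate(config: simdata.SimConfig):
    bundle = simdata.generate_reference(config)
    truth = simdata.plant_truth(bundle, config)
    reads = simdata.simulate_reads(bundle, truth, config)
    return bundle, truth, reads


def recover_hyper(
    bundle: GenomeBundle,
    reads: simdata.SimReads,
    hyper_cfg: hypered.HyperConfig | None = None,
):
    """Recover each sample's unmapped pool against shared transformed indexes."""
    hyper_cfg = hyper_cfg or hypered.HyperConfig()
    aligner = hypered.HyperAligner(bundle.seqs, hyper_cfg.aligner_k)
    recovered, reports = {}, {}
    for sample, pool in reads.unmapped.items():
        recovered[sample], reports[sample] = hypered.recover_hyper_edited(
            pool, bundle.seqs, hyper_cfg, sample_id=sample, aligner=aligner
        )
    return recovered, reports


def dedup_and_pileup(
    bundle: GenomeBundle,
    reads: simdata.SimReads,
    recovered: dict[str, list] | None,
    call_cfg: caller.CallConfig,
):
    """Deduplicate per sample (direct + recovered reads jointly) and build
    quality-filtered RNA and DNA pileup layers."""
    chrom_lengths = bundle.chrom_lengths
    pileup = Pileup(chrom_lengths)
    rna_blocks: dict[str, list[ReadBlock]] = {}
    for sample, blocks in reads.rna.items():
        merged: dict[str, list[ReadBlock]] = {}
        for b in blocks:
            merged.setdefault(b.chrom, []).append(b)
        if recovered and recovered.get(sample):
            for rb in blocks_from_alignments(recovered[sample], sample):
                merged.setdefault(rb.chrom, []).append(rb)
        deduped = []
        for chrom, parts in merged.items():
            block = parts[0] if len(parts) == 1 else _concat_blocks(parts)
            block = remove_duplicates_block(block.sort())
            deduped.append(block)
            pileup.add_block(
                block, "RNA",
                quality_min=call_cfg.rna_quality_min,
                end_clip=call_cfg.end_clip,
            )
        rna_blocks[sample] = deduped
    for animal, blocks in reads.dna.items():
        for b in blocks:
            block = remove_duplicates_block(b)
            pileup.add_block(block, "DNA", quality_min=call_cfg.rna_quality_min, end_clip=0)
    return pileup, rna_blocks


def _concat_blocks(parts: list[ReadBlock]) -> ReadBlock:
    assert len({p.read_length for p in parts}) == 1, "mixed read lengths"
    return ReadBlock(
        sample_id=parts[0].sample_id,
        chrom=parts[0].chrom,
        starts=np.concatenate([p.starts for p in parts]),
        strands=np.concatenate([p.strands for p in parts]),
        seqs=np.vstack([p.seqs for p in parts]),
        quals=np.vstack([p.quals for p in parts]),
        ids=np.concatenate([p.ids.astype(str) for p in parts]),
        mapq=parts[0].mapq,
    )


def annotate_master(
    master: list[caller.EditingSite], bundle: GenomeBundle
) -> list[caller.EditingSite]:
    """Fill genic-region, repeat-class and recoding slots in place."""
    gene_annot = annot.GeneAnnotator(bundle.genes)
    repeat_annot = annot.RepeatAnnotator(bundle.repeats)
    for site in master:
        label, gene = gene_annot.assign(site.chrom, site.pos)
        site.genic_region = label
        site.repeat_class = repeat_annot.assign(site.chrom, site.pos)
        if label == "CDS" and gene is not None and gene.is_coding:
            try:
                site.recoding = annot.recoding_effect(bundle, gene, site.pos).notation
            except annot.AnnotationError:
                site.recoding = None
    return master


def run_pipeline(
    sim_cfg: simdata.SimConfig | None = None,
    call_cfg: caller.CallConfig | None = None,
    hyper_cfg: hypered.HyperConfig | None = None,
    with_hyper_recovery: bool = True,
) -> PipelineResult:
    """Simulate and run the full calling/quantification pipeline in memory."""
    sim_cfg = sim_cfg or simdata.SimConfig()
    call_cfg = call_cfg or caller.CallConfig()
    bundle, truth, reads = simulate(sim_cfg)
    recovered, reports = (
        recover_hyper(bundle, reads, hyper_cfg) if with_hyper_recovery else ({}, {})
    )
    pileup, rna_blocks = dedup_and_pileup(bundle, reads, recovered, call_cfg)
    sample_animal = {s: sim_cfg.sample_animal(s) for s in sim_cfg.samples}
    master, detail = caller.call_round1(
        pileup, rna_blocks, bundle, call_cfg, sample_animal
    )
    annotate_master(master, bundle)
    quant = caller.call_round2(master, pileup, sim_cfg.samples, call_cfg)
    matrix = stats.EditingMatrix.from_quant(quant) if not quant.empty else None
    region_matrix = None
    if matrix is not None:
        grouping = {s: sim_cfg.sample_region(s) for s in matrix.edited.columns}
        region_matrix = stats.pool_counts(matrix, grouping)
    return PipelineResult(
        config=sim_cfg,
        call_config=call_cfg,
        bundle=bundle,
        truth=truth,
        reads=reads,
        rna_blocks=rna_blocks,
        pileup=pileup,
        recovered=recovered,
        recovery_reports=reports,
        master=master,
        round1_detail=detail,
        quant=quant,
        matrix=matrix,
        region_matrix=region_matrix,
    )


# ------------------------------------------------ evaluation against truth
def evaluate_round1(
    result: PipelineResult,
    min_level: float = 0.10,
    min_expected_edited: float = 3.0,
    min_samples: int = 2,
) -> dict:
    """Recall/precision of the master list against planted truth.

    Recall is measured on sites whose expected edited-read count and true
    level clear the thresholds in at least ``min_samples`` samples (the
    recoverable stratum); precision over all calls; het-SNP positions with
    adequate DNA depth must attract zero calls.
    """
    cfg = result.config
    truth = result.truth
    called = {(s.chrom, s.pos) for s in result.master}
    region_index = {r: i for i, r in enumerate(cfg.regions)}
    # effective per-sample depth after duplicate collapse
    eligible = []
    for site in truth.sites:
        n_ok = 0
        for sample in cfg.samples:
            level = site.levels[region_index[cfg.sample_region(sample)]]
            depth = _expected_depth(result, sample, site.chrom, site.pos)
            if level >= min_level and depth * level >= min_expected_edited:
                n_ok += 1
        if n_ok >= min_samples:
            eligible.append(site)
    truth_pos = truth.site_positions()
    tp_eligible = sum(1 for s in eligible if (s.chrom, s.pos) in called)
    recall = tp_eligible / len(eligible) if eligible else float("nan")
    tp_all = sum(1 for key in called if key in truth_pos)
    precision = tp_all / len(called) if called else float("nan")
    het_hits = _het_snp_calls(result, called)
    return {
        "n_called": len(called),
        "n_eligible": len(eligible),
        "recall": recall,
        "precision": precision,
        "het_snp_calls": het_hits,
    }


def _expected_depth(result: PipelineResult, sample: str, chrom: str, pos: int) -> int:
    counts = result.pileup.counts(sample, "RNA", chrom)[:, pos]
    return int(counts.sum())


def _het_snp_calls(result: PipelineResult, called: set) -> int:
    hits = 0
    for chrom, pos, _ref, _alt in result.truth.het_snps:
        dna_depth = 0
        for animal in result.config.animals:
            dna_depth = max(
                dna_depth, int(result.pileup.counts(animal, "DNA", chrom)[:, pos].sum())
            )
        if dna_depth >= result.call_config.dna_min_depth and (chrom, pos) in called:
            hits += 1
    return hits


def evaluate_hyper_recovery(result: PipelineResult) -> dict:
    """Fraction of planted hyper-edited reads recovered at their emitting
    locus (read ids encode sample:chrom:pos1:strand:serial) and the number
    recovered anywhere else."""
    planted = result.truth.hyper_read_ids
    at_locus = wrong = 0
    for sample, alns in result.recovered.items():
        for aln in alns:
            if aln.read_id not in planted:
                continue
            _, chrom, pos1, strand, _ = aln.read_id.split(":")
            if aln.chrom == chrom and aln.start == int(pos1) - 1 and aln.strand == strand:
                at_locus += 1
            else:
                wrong += 1
    return {
        "n_planted": len(planted),
        "recovered_at_locus": at_locus,
        "recovered_elsewhere": wrong,
        "recovery_rate": at_locus / len(planted) if planted else float("nan"),
    }
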