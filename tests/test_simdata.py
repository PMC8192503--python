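import filecmp

import numpy as np
import pytest
from scipy import stats as sps

from edscape import pipeline, simdata
from edscape.genome import revcomp
from edscape.samio import Pileup

TINY = dict(
    rng_seed=3, n_chroms=1, chrom_length=15_000, n_genes=2, n_sites=20,
    n_het_snps=5, rna_depth=10, dna_depth=10, n_regions=2, samples_per_region=1,
    n_region_enriched=0,
)


def test_generate_reference_counts_and_structure():
    cfg = simdata.SimConfig(**TINY, exons_per_gene=3)
    bundle = simdata.generate_reference(cfg)
    assert len(bundle.genes) == 2
    assert sum(len(g.exons) for g in bundle.genes) == 6
    for g in bundle.genes:
        assert g.cds_length % 3 == 0
        # exons non-overlapping and sorted
        for (s1, e1), (s2, e2) in zip(g.exons, g.exons[1:]):
            assert e1 <= s2
        # coding strand starts with ATG
        first = g.spliced_cds_positions()[:3]
        codon = "".join(bundle.base(g.chrom, int(p), g.strand) for p in first)
        assert codon == "ATG"


def test_repeat_fraction_zero_gives_no_repeats():
    cfg = simdata.SimConfig(**{**TINY, "repeat_fraction": 0.0})
    assert simdata.generate_reference(cfg).repeats == []


def test_infeasible_gene_layout_raises_sizing_error():
    with pytest.raises(simdata.SizingError):
        simdata.generate_reference(
            simdata.SimConfig(rng_seed=0, n_chroms=1, chrom_length=1_000,
                              n_genes=5, read_length=100)
        )


def test_outputs_byte_identical_for_fixed_seed(tmp_path):
    cfg = simdata.SimConfig(**TINY)
    for d in ("a", "b"):
        bundle, truth, reads = pipeline.simulate(cfg)
        simdata.write_outputs(bundle, truth, reads, tmp_path / d)
    names = [p.name for p in (tmp_path / "a").iterdir()]
    match, mismatch, errors = filecmp.cmpfiles(
        tmp_path / "a", tmp_path / "b", names, shallow=False
    )
    assert not mismatch and not errors


def test_truth_sites_sit_on_reference_A_of_edited_strand(small_world):
    bundle, truth, _ = small_world
    for site in truth.sites:
        assert bundle.base(site.chrom, site.pos, site.strand) == "A"


def test_het_snps_disjoint_from_sites_and_count(small_world):
    _, truth, _ = small_world
    snp_pos = {(c, p) for c, p, _, _ in truth.het_snps}
    assert len(snp_pos) == 10
    assert not snp_pos & truth.site_positions()


def test_no_het_snps_when_disabled():
    cfg = simdata.SimConfig(**{**TINY, "n_het_snps": 0})
    bundle = simdata.generate_reference(cfg)
    truth = simdata.plant_truth(bundle, cfg)
    assert truth.het_snps == []


def test_repeat_sites_cluster_spatially(small_world):
    _, truth, _ = small_world
    repeat_pos = sorted(
        s.pos for s in truth.sites if s.site_class == "repeat"
    )
    clustered = 0
    for i, p in enumerate(repeat_pos):
        near = [q for q in repeat_pos if abs(q - p) <= 100]
        if len(near) >= 3:
            clustered += 1
    assert clustered / len(repeat_pos) >= 0.5


def test_beta_level_model_mean_matches_analytic():
    # Beta(1, 9) has mean 1/10; 500 planted draws should agree within 3 SE
    cfg = simdata.SimConfig(
        rng_seed=11, n_chroms=2, chrom_length=120_000, n_genes=8, n_sites=500,
        n_het_snps=0, n_region_enriched=0, cds_high_fraction=0.0,
        level_model={k: (1.0, 9.0) for k in simdata.SITE_CLASSES},
        n_regions=2, samples_per_region=1,
    )
    bundle = simdata.generate_reference(cfg)
    truth = simdata.plant_truth(bundle, cfg)
    levels = np.array([s.levels[0] for s in truth.sites])
    se = np.sqrt(9.0 / (100 * 11)) / np.sqrt(len(levels))
    assert len(levels) == 500
    assert abs(levels.mean() - 0.1) < 3 * se


def test_full_editing_at_level_one_without_errors():
    cfg = simdata.SimConfig(
        **{**TINY, "base_error_rate": 0.0, "duplicate_rate": 0.0,
           "hyper_read_fraction": 0.0, "rna_depth": 100.0},
    )
    bundle = simdata.generate_reference(cfg)
    chrom, pos, strand = _intergenic_A(bundle)
    truth = simdata.TruthSet(
        sites=[simdata.TruthSite(chrom, pos, strand, "repeat",
                                 np.full(cfg.n_regions, 1.0))],
        het_snps=[], regions=cfg.regions,
    )
    reads = simdata.simulate_reads(bundle, truth, cfg)
    for sample, blocks in reads.rna.items():
        for b in blocks:
            idx = b.overlapping(pos)
            covering = b.seqs[idx, pos - b.starts[idx]]
            assert (covering == ord("G")).all()


def test_observed_fraction_within_binomial_interval_at_half_level():
    cfg = simdata.SimConfig(
        **{**TINY, "base_error_rate": 0.0, "duplicate_rate": 0.0,
           "hyper_read_fraction": 0.0, "rna_depth": 200.0, "n_regions": 1},
    )
    bundle = simdata.generate_reference(cfg)
    chrom, pos, strand = _intergenic_A(bundle)
    truth = simdata.TruthSet(
        sites=[simdata.TruthSite(chrom, pos, strand, "repeat", np.array([0.5]))],
        het_snps=[], regions=cfg.regions,
    )
    reads = simdata.simulate_reads(bundle, truth, cfg)
    block = reads.rna[cfg.samples[0]][0]
    idx = block.overlapping(pos)
    bases = block.seqs[idx, pos - block.starts[idx]]
    n = len(bases)
    g = int((bases == ord("G")).sum())
    lo, hi = sps.binom.interval(0.99, n, 0.5)
    assert lo <= g <= hi


def _intergenic_A(bundle):
    chrom = next(iter(bundle.seqs))
    spans = [(g.start, g.end) for g in bundle.genes if g.chrom == chrom]
    for pos in range(200, len(bundle.seqs[chrom]) - 200):
        if bundle.base(chrom, pos) == "A" and not any(
            s - 150 <= pos < e + 150 for s, e in spans
        ):
            return chrom, pos, "+"
    raise AssertionError("no intergenic A found")


def test_no_duplicate_reads_when_rate_zero():
    # sparse library so coincidental same-start fragments are absent
    cfg = simdata.SimConfig(
        **{**TINY, "duplicate_rate": 0.0, "rna_depth": 0.4, "dna_depth": 0.4,
           "hyper_read_fraction": 0.0},
    )
    bundle, truth, reads = pipeline.simulate(cfg)
    for blocks in reads.rna.values():
        for b in blocks:
            keys = {
                (int(b.starts[i]), int(b.strands[i]), b.seqs[i].tobytes())
                for i in range(b.n)
            }
            assert len(keys) == b.n


def test_dna_reads_show_both_het_alleles(small_world):
    # each het SNP should show both alleles in every animal's DNA at depth >= 20
    bundle, truth, reads = small_world
    for chrom, pos, ref, alt in truth.het_snps:
        for animal, blocks in reads.dna.items():
            for b in blocks:
                if b.chrom != chrom:
                    continue
                idx = b.overlapping(pos)
                bases = b.seqs[idx, pos - b.starts[idx]]
                if len(bases) >= 20:
                    assert (bases == ord(ref)).any() and (bases == ord(alt)).any()


def test_hyper_reads_diverted_to_unmapped_and_heavily_edited(small_world):
    bundle, truth, reads = small_world
    assert truth.hyper_read_ids
    kept_ids = {
        str(i) for blocks in reads.rna.values() for b in blocks for i in b.ids
    }
    assert not truth.hyper_read_ids & kept_ids
    # each hyper read has at least 5 edits relative to its emitting locus
    for sample, pool in reads.unmapped.items():
        for read in pool[:20]:
            _, chrom, pos1, strand, _ = read.read_id.split(":")
            start = int(pos1) - 1
            ref = bundle.sequence(chrom, start, start + len(read.sequence), "+")
            seq = read.sequence if strand == "+" else revcomp(read.sequence)
            edits = sum(
                1 for r, q in zip(ref, seq)
                if (strand == "+" and r == "A" and q == "G")
                or (strand == "-" and r == "T" and q == "C")
            )
            assert edits >= 5
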