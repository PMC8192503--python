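import numpy as np
import pytest

from edscape import pipeline, simdata

# Modest-scale study: one 30-kb chromosome, 2 regions x 2 animals, depth 30.
SMALL_CONFIG = dict(
    rng_seed=7,
    n_chroms=1,
    chrom_length=30_000,
    n_genes=4,
    n_sites=60,
    n_het_snps=10,
    rna_depth=30,
    dna_depth=30,
    n_regions=2,
    samples_per_region=2,
    n_region_enriched=5,
)


@pytest.fixture(scope="session")
def small_cfg():
    return simdata.SimConfig(**SMALL_CONFIG)


@pytest.fixture(scope="session")
def small_world(small_cfg):
    """(bundle, truth, reads) for the small study."""
    return pipeline.simulate(small_cfg)


@pytest.fixture(scope="session")
def small_result(small_cfg):
    """Full pipeline result on the small study.

    With only two samples per region, a single surviving DNA sequencing
    error would veto a site under the strict homozygosity default, so the
    documented relaxation (major-allele fraction 0.95) is exercised here.
    """
    from edscape.caller import CallConfig

    return pipeline.run_pipeline(
        small_cfg, call_cfg=CallConfig(dna_major_allele_min_frac=0.95)
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
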