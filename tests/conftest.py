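import numpy as np
import pytest

from namqg import simnam


@pytest.fixture(scope="session")
def small_cfg():
    return simnam.SimConfig(
        n_families=4, n_ril_per_family=40, n_chrom=2, markers_per_chrom=30,
        n_environments=2, h2_additive_target=0.3, h2_epistatic_target=0.1,
        n_qtl_additive=6, n_qtl_epistatic_pairs=2, missing_rate=0.03, seed=11,
    )


@pytest.fixture(scope="session")
def small_pop(small_cfg):
    """Complete small NAM population: (panel, plots, truth, founders)."""
    return simnam.simulate(small_cfg)


@pytest.fixture(scope="session")
def additive_pop():
    """Purely additive, single-environment population for genomic tests."""
    cfg = simnam.SimConfig(
        n_families=4, n_ril_per_family=50, n_chrom=2, markers_per_chrom=40,
        n_environments=1, h2_additive_target=0.4, h2_epistatic_target=0.0,
        gxe_sd=0.0, spatial_gradient_sd=0.0, n_qtl_additive=10, seed=21,
    )
    panel, plots, truth, founders = simnam.simulate(cfg)
    rng = np.random.default_rng(99)
    y = truth.true_genetic_values + rng.normal(0, np.sqrt(0.6), panel.n_individuals)
    return panel, y, truth
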