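import numpy as np
import pandas as pd
import pytest

from diacidseq import BarSeqFitness, diacid_world, simulate_scenario
from diacidseq import fba as fba_mod

RECOVERY_SEED = 11
RECOVERY_DEPTH = 1_000_000


@pytest.fixture(scope="session")
def recovery_world():
    """The stochastic recovery scenario: 200 genes, ~15 strains/gene,
    depth 1e6, duplicate experiments."""
    return diacid_world(n_genes=200, seed=RECOVERY_SEED)


@pytest.fixture(scope="session")
def recovery_sim(recovery_world):
    return simulate_scenario(recovery_world, depth=RECOVERY_DEPTH, mode="multinomial", seed=RECOVERY_SEED)


@pytest.fixture(scope="session")
def recovery_results(recovery_sim):
    return BarSeqFitness.from_simulation(recovery_sim).fit()


@pytest.fixture(scope="session")
def expectation_results():
    """Noise-free (expectation-mode) run for exactness checks.

    The repressor gene is excluded: its 2^13.55-fold enrichment collapses
    every other strain's expected counts toward the rounding floor in that
    condition, which is sampling-depth physics, not estimator error.
    """
    world = diacid_world(n_genes=120, include_repressor=False, seed=3)
    sim = simulate_scenario(world, depth=5_000_000, mode="expectation", seed=3)
    return world, sim, BarSeqFitness.from_simulation(sim).fit()


@pytest.fixture(scope="session")
def production_model():
    """Core template with all diacid pathways and the indigoidine module."""
    return fba_mod.build_production_model(chains=(4, 5, 6, 7, 8, 9, 10, 11, 12))


@pytest.fixture()
def masked_matrix():
    """Small locus x condition matrix with masked cells for imputation and
    correlation tests."""
    return pd.DataFrame(
        {
            "c1": [0.0, 0.0, 0.0, 1.0],
            "c2": [0.0, 0.0, 0.0, 2.0],
            "c3": [np.nan, 5.0, 7.0, 3.0],
        },
        index=["g1", "g2", "g3", "g4"],
    )
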