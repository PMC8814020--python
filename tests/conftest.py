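import warnings

import numpy as np
import pytest

from amherit.experiments import simulate_unrelated_cohort
from amherit.simulator import SimConfig, generate_founders


@pytest.fixture(autouse=True)
def _quiet_heritability_warnings():
    with warnings.catch_warnings():
        warnings.filterwarnings(
            "ignore", message=".*lies outside \\[0, 1\\].*", category=UserWarning
        )
        yield


@pytest.fixture(scope="session")
def small_panel():
    """Dense small founder panel (many SNPs per block) for LD-sensitive tests."""
    return generate_founders(
        p=400,
        n_founders=150,
        chromosomes=2,
        blocks_per_chromosome=5,
        seed=7,
    )


@pytest.fixture(scope="session")
def am_cohort():
    """A small unrelated cohort at assortative-mating equilibrium (r=0.5)."""
    cfg = SimConfig(
        seed=5,
        N=1200,
        p=600,
        m=300,
        r=0.5,
        n_founders=400,
        chromosomes=10,
        blocks_per_chromosome=20,
    )
    return simulate_unrelated_cohort(cfg, n=600)


@pytest.fixture(scope="session")
def null_cohort():
    """Matched random-mating cohort (r=0)."""
    cfg = SimConfig(
        seed=6,
        N=1200,
        p=600,
        m=300,
        r=0.0,
        n_founders=400,
        chromosomes=10,
        blocks_per_chromosome=20,
    )
    return simulate_unrelated_cohort(cfg, n=600)


@pytest.fixture
def rng():
    return np.random.default_rng(20260927)
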