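import numpy as np
import pytest

from swbtwin import SimulationParams, simulate_cohort


@pytest.fixture(scope="session")
def default_cohort():
    """Five-study cohort at the design's sample sizes (seed 0)."""
    return simulate_cohort(SimulationParams(seed=0))


@pytest.fixture(scope="session")
def default_cohort_with_latents():
    return simulate_cohort(SimulationParams(seed=0), return_latents=True)


@pytest.fixture(scope="session")
def small_cohort():
    """Small random-layout cohort for cheap structural tests."""
    params = SimulationParams(layout="random",
                              n_families_per_study=(8, 8, 8, 8, 8),
                              selection_spec={}, seed=3)
    return simulate_cohort(params)


@pytest.fixture
def rng():
    return np.random.default_rng(20260922)
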