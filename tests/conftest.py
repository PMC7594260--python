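import numpy as np
import pytest

from wmengage.simulate import SimulationConfig, generate_cohort


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(2026)


@pytest.fixture(scope="session")
def toy_cohort():
    """Default 10-subject 8x8x8 null cohort (no mediators)."""
    return generate_cohort(SimulationConfig(seed=11))


@pytest.fixture(scope="session")
def tiny_cohort():
    """Two-subject cohort small enough for brute-force oracles."""
    return generate_cohort(SimulationConfig(grid_shape=(7, 7, 7), n_timepoints=120,
                                            n_subjects=2, seed=5))
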