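import numpy as np
import pytest

from florsel.synthetic_data import SimulationConfig, simulate_study


@pytest.fixture(scope="session")
def small_study():
    """A compact simulated study reused by read-only tests."""
    cfg = SimulationConfig(n_populations=3, pairs_per_population=40, seed=11)
    return simulate_study(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
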