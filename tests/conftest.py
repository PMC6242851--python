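import numpy as np
import pytest

from pinnitrack.synthetic import SimConfig, simulate_environment, simulate_population


@pytest.fixture(scope="session")
def small_config():
    return SimConfig(n_seals=2, duration_days=20, seed=11)


@pytest.fixture(scope="session")
def small_env(small_config):
    return simulate_environment(small_config)


@pytest.fixture(scope="session")
def small_population(small_config):
    """A 2-seal, 20-day labelled dataset shared across test modules."""
    ds, truth = simulate_population(small_config)
    return ds, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
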