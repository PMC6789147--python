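import numpy as np
import pytest

from allopoly.simulate import SimulationConfig, simulate_dataset


@pytest.fixture(scope="session")
def default_config() -> SimulationConfig:
    return SimulationConfig(seed=7)


@pytest.fixture(scope="session")
def default_dataset(default_config):
    """One shared default synthetic dataset (generation is deterministic)."""
    return simulate_dataset(default_config)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(123)
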