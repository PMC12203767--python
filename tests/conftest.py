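import numpy as np
import pytest

from ivweights import ScenarioConfig, simulate_dataset


@pytest.fixture(scope="session")
def small_dataset():
    """One moderate draw from the default scenario (n=500, J=20)."""
    return simulate_dataset(ScenarioConfig(n=500, J=20, rho=0.0, theta=1.0, seed=42))


@pytest.fixture(scope="session")
def big_dataset():
    """One large draw for consistency checks (n=100000, J=20)."""
    return simulate_dataset(ScenarioConfig(n=100_000, J=20, rho=0.0, theta=1.0, seed=7))


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240917)
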