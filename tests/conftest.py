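import numpy as np
import pytest

from regprior.synthetic_data import SimulationConfig, simulate_study


@pytest.fixture(scope="session")
def default_study():
    """One fully simulated study at the default conditions."""
    return simulate_study(SimulationConfig(seed=7))


@pytest.fixture(scope="session")
def noiseless_study():
    """Noise-free tracks make CRE recovery deterministic."""
    return simulate_study(SimulationConfig(seed=11, track_noise_sd=0.0))


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
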