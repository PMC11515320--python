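import warnings

import numpy as np
import pytest

from chemopde.simulate import SimulationConfig, simulate_ks

warnings.filterwarnings("ignore", message="only .* of rollout inputs")


@pytest.fixture(scope="session")
def fast_sim():
    """One fast-tier ground-truth run shared by the whole suite."""
    config = SimulationConfig()
    b, c = simulate_ks(config)
    return b, c, config


@pytest.fixture(scope="session")
def diffusion_sim():
    """Pure-diffusion run (χ0 = κ = 0) for closed-form oracles."""
    config = SimulationConfig(chi0=0.0, kappa=0.0, t_end=100.0)
    b, c = simulate_ks(config)
    return b, c, config


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
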