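import numpy as np
import pytest

from molsynapse import pnp
from molsynapse.signals import CurrentTrace
from molsynapse.synapse import SynapseParams


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def quiet_params():
    """Noise-free surrogate parameters (deterministic device)."""
    return SynapseParams(noise_sigma=0.0, seed=0)


@pytest.fixture
def noisy_params():
    return SynapseParams(noise_sigma=0.01, seed=7)


@pytest.fixture
def coarse_pnp_config():
    """Small, fast PNP configuration for unit tests."""
    return pnp.PNPConfig(n_grid=48, dt=2e-3)


@pytest.fixture
def double_exp_trace():
    """Canonical noiseless double-exponential relaxation trace."""
    # dense early sampling resolves the fast component, coarse later the slow
    t = np.concatenate([np.arange(0.0, 2.0, 0.002), np.arange(2.0, 300.0, 0.05)])
    params = dict(a=1e-9, tau1=0.15, b=0.5e-9, tau2=80.0, c=0.1e-9)
    y = (
        params["a"] * np.exp(-t / params["tau1"])
        + params["b"] * np.exp(-t / params["tau2"])
        + params["c"]
    )
    return CurrentTrace(t, y), params
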