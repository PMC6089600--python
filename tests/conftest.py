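import numpy as np
import pytest

from ktflim.flim import IRF, DecayModel
from ktflim.simulate import SimConfig
from ktflim.tension import AuroraActivationParams, PhosBindingParams


@pytest.fixture
def sim_config():
    return SimConfig()


@pytest.fixture
def delta_irf_config():
    """Config whose window is long enough that folding is negligible."""
    cfg = SimConfig(n_bins=256)
    return cfg, IRF.delta(cfg.n_fine, cfg.bin_width)


@pytest.fixture
def donor_model():
    return DecayModel("single", tau_d=3.75)


@pytest.fixture
def mixture_model():
    """Two-exponential decay at the lifetimes and amplitude fitted for
    FlAsH-labeled metaphase cells."""
    return DecayModel("double", tau_d=3.71, tau_fret=0.75, f_fret=0.13)


@pytest.fixture
def aurora_params():
    return AuroraActivationParams(K=3.5, A_star=4.6)


@pytest.fixture
def phos_binding_params():
    return PhosBindingParams(Kphos=19.0, K0=1.43, K0_prime=18.0)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
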