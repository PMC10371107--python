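import numpy as np
import pytest

from errorfields import (
    ControllerConfig,
    ErrorSample,
    ErrorStatModel,
    LearnerState,
    default_reach_specs,
)
from errorfields.error_model import COMPONENTS


@pytest.fixture
def spec():
    """Default first reach: 15 cm along +x, td = 1.5 s."""
    return default_reach_specs()[0]


@pytest.fixture
def specs():
    return default_reach_specs()


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_constant_model(mu=0.0, sigma=1.0, td=1.5, sigma_floor=0.05,
                        directions=(0, 1, 2)):
    """Hand-built model with time-constant mu and sigma on every channel."""
    model = ErrorStatModel(td=td, sigma_floor=sigma_floor)
    for d in directions:
        for comp in COMPONENTS:
            mu_c = np.zeros(8)
            mu_c[0] = mu
            sd_c = np.zeros(8)
            sd_c[0] = sigma
            model.mu_coeffs[(d, comp)] = mu_c
            model.sigma_coeffs[(d, comp)] = sd_c
    return model


@pytest.fixture
def unit_model():
    """Model with mu = 0, sigma = 1 everywhere (density mode 1/sqrt(2 pi))."""
    return make_constant_model(mu=0.0, sigma=1.0)


def constant_error_trials(value_ext, value_perp, n_trials=4, direction=0,
                          td=1.5, n_samples=30):
    """Trials whose error is constant in time and identical across trials."""
    ts = np.linspace(0.0, td, n_samples)
    return [
        [ErrorSample(float(t), value_ext, value_perp, direction) for t in ts]
        for _ in range(n_trials)
    ]


@pytest.fixture
def noiseless_learner():
    return LearnerState(motor_noise_sd=0.0)


@pytest.fixture
def null_cfg():
    return ControllerConfig(mode="NULL")
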