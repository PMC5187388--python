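import numpy as np
import pytest
from hypothesis import settings

from adaptivesr import EnvironmentConfig, SensorParams, generate_ou_series

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def std_env() -> EnvironmentConfig:
    """Standard acoustic environment at full simulation length."""
    return EnvironmentConfig(mu_I=40.0, sigma_I=25.0, dt=0.1, n_samples=200_000, seed=123)


@pytest.fixture(scope="session")
def long_ou(std_env):
    return generate_ou_series(std_env)


@pytest.fixture(scope="session")
def default_params() -> SensorParams:
    return SensorParams(I_theta=0.0, f_sp=50.0, f_max=250.0, mu_I=40.0, sigma_I=25.0)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(987)
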