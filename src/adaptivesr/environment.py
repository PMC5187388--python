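"""Standard acoustic environment: autocorrelated sound-intensity trajectories.

The model's acoustic input is a time series of sound-intensity levels
``I(t)`` in dB SPL whose marginal distribution is Gaussian with mean
``mu_I`` (default 40 dB SPL) and standard deviation ``sigma_I``
(default 25 dB).  Temporal structure is introduced through an
Ornstein-Uhlenbeck (OU) process with unit relaxation rate,

    dI_t = (mu_I - I_t) dt + sqrt(2 sigma_I^2) dW_t,

so the stationary law is exactly N(mu_I, sigma_I^2) and the
autocorrelation decays as exp(-tau) in model time units.  An i.i.d.
Gaussian series with the same marginal serves as the uncorrelated
control.  On the dB scale intensities are unbounded below, so negative
values are legitimate.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import lfilter
from scipy.stats import norm

__all__ = [
    "EnvironmentConfig",
    "IntensityTimeSeries",
    "gaussian_intensity_pdf",
    "generate_ou_series",
    "generate_iid_series",
]


@dataclass(frozen=True)
class EnvironmentConfig:
    """Parameters of the standard acoustic environment.

    Attributes
    ----------
    mu_I : float
        Mean intensity in dB SPL.
    sigma_I : float
        Intensity standard deviation in dB.
    dt : float
        Sampling step in model time units (the OU correlation time is 1).
    n_samples : int
        Series length.
    seed : int or None
        Seed for the generator used when no explicit rng is passed.
    I0 : float or None
        Initial intensity in dB SPL.  ``None`` (default) draws the
        initial value from the stationary distribution so the whole
        series is stationary and no burn-in is needed.
    """

    mu_I: float = 40.0
    sigma_I: float = 25.0
    dt: float = 0.1
    n_samples: int = 200_000
    seed: int | None = None
    I0: float | None = None

    def __post_init__(self) -> None:
        if not self.sigma_I > 0:
            raise ValueError(f"sigma_I must be positive, got {self.sigma_I}")
        if not self.dt > 0:
            raise ValueError(f"dt must be positive, got {self.dt}")
        if self.n_samples < 2:
            raise ValueError(f"n_samples must be >= 2, got {self.n_samples}")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


@dataclass(frozen=True)
class IntensityTimeSeries:
    """Sampled sound-intensity levels in dB SPL with a fixed time step."""

    values: np.ndarray = field(repr=False)
    dt: float

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        if values.ndim != 1 or values.size < 2:
            raise ValueError("values must be a 1-D sequence of length >= 2")
        if not np.all(np.isfinite(values)):
            raise ValueError("intensity values must be finite")
        if not self.dt > 0:
            raise ValueError(f"dt must be positive, got {self.dt}")

    def __len__(self) -> int:
        return self.values.size

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.values.size) * self.dt


def gaussian_intensity_pdf(I, mu_I: float = 40.0, sigma_I: float = 25.0):
    """Probability density of the sound-intensity levels (per dB).

    Evaluates the Gaussian density ``N(mu_I, sigma_I^2)`` at intensity
    ``I`` (scalar or array), the marginal law of the standard acoustic
    environment.
    """
    if not sigma_I > 0:
        raise ValueError(f"sigma_I must be positive, got {sigma_I}")
    return norm.pdf(I, loc=mu_I, scale=sigma_I)


def _resolve_rng(config: EnvironmentConfig, rng: np.random.Generator | None) -> np.random.Generator:
    return rng if rng is not None else config.rng()


def generate_ou_series(
    config: EnvironmentConfig, rng: np.random.Generator | None = None
) -> IntensityTimeSeries:
    """Generate an OU intensity trajectory with stationary law N(mu_I, sigma_I^2).

    Uses the exact transition density of the OU process,

        I_{t+dt} = mu_I + (I_t - mu_I) e^{-dt} + sigma_I sqrt(1 - e^{-2 dt}) xi,

    with ``xi ~ N(0, 1)``, which is unconditionally stable and exact for
    any step size (Euler-Maruyama is neither).  Implemented as an AR(1)
    recursion through a linear filter, so generation is O(n) vectorised.
    """
    rng = _resolve_rng(config, rng)
    phi = np.exp(-config.dt)
    innovation_sd = config.sigma_I * np.sqrt(1.0 - phi * phi)

    if config.I0 is not None:
        x0 = config.I0 - config.mu_I
    else:
        x0 = config.sigma_I * rng.standard_normal()

    xi = rng.standard_normal(config.n_samples)
    xi[0] = 0.0  # slot 0 holds the initial condition
    deviations, _ = lfilter([1.0], [1.0, -phi], innovation_sd * xi, zi=[phi * x0])
    deviations[0] = x0
    return IntensityTimeSeries(values=config.mu_I + deviations, dt=config.dt)


def generate_iid_series(
    config: EnvironmentConfig, rng: np.random.Generator | None = None
) -> IntensityTimeSeries:
    """Generate the uncorrelated control: i.i.d. draws from N(mu_I, sigma_I^2).

    Marginally indistinguishable from the OU series but with a delta
    autocorrelation (unit peak at lag zero only).
    """
    rng = _resolve_rng(config, rng)
    values = rng.normal(config.mu_I, config.sigma_I, size=config.n_samples)
    return IntensityTimeSeries(values=values, dt=config.dt)
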