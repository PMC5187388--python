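"""Auditory-nerve sensor: infomax rate-intensity function with injected noise.

The inner-hair-cell synapse / auditory-nerve stage is modelled as a
threshold sensor whose rate-intensity function follows the infomax
principle: above the hearing threshold ``I_theta`` the firing rate is
proportional to the cumulative distribution function of the intensity
environment the sensor is adapted to, so equal firing-rate intervals
carry equal probability mass.  Below threshold the output is the
spontaneous rate ``f_sp``; the response saturates at ``f_max``:

    f(I) = f_sp                                               I < I_theta
    f(I) = f_sp + (f_max - f_sp) * (Phi_I(I) - P_sp) / (1 - P_sp)   else

with ``Phi_I`` the Gaussian CDF of the adapted environment and
``P_sp = Phi_I(I_theta)`` the sub-threshold probability mass.

Hearing loss is represented purely as an elevation of ``I_theta`` with
``f_sp``, ``f_max`` and the adapted distribution unchanged.  Internal
(SR) noise is zero-mean white Gaussian added to the intensity before
the threshold comparison: the noisy response is ``f(I + n)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import ndtr

__all__ = [
    "SensorParams",
    "NoiseModel",
    "FiringRateSeries",
    "spontaneous_probability",
    "rate_intensity",
    "respond",
]

from .environment import IntensityTimeSeries


@dataclass(frozen=True)
class SensorParams:
    """Sensor parameters.

    ``I_theta``: hearing threshold, dB SPL.  ``f_sp``/``f_max``:
    spontaneous and maximum firing rates, Hz.  ``mu_I``/``sigma_I``:
    mean and standard deviation (dB) of the intensity distribution the
    rate function is adapted to.  The adapted distribution stays fixed
    at the standard environment even when the threshold is raised;
    re-adaptation after hearing loss is deliberately not modelled.
    """

    I_theta: float = 0.0
    f_sp: float = 50.0
    f_max: float = 250.0
    mu_I: float = 40.0
    sigma_I: float = 25.0

    def __post_init__(self) -> None:
        if not self.f_sp >= 0:
            raise ValueError(f"f_sp must be >= 0, got {self.f_sp}")
        if not self.f_max > self.f_sp:
            raise ValueError(f"f_max must exceed f_sp, got f_max={self.f_max}, f_sp={self.f_sp}")
        if not self.sigma_I > 0:
            raise ValueError(f"sigma_I must be positive, got {self.sigma_I}")

    def with_threshold(self, I_theta: float) -> "SensorParams":
        """Copy with an elevated (or lowered) hearing threshold."""
        return SensorParams(I_theta, self.f_sp, self.f_max, self.mu_I, self.sigma_I)


@dataclass(frozen=True)
class NoiseModel:
    """Internal white noise: zero mean, tunable variance ``sigma_n_sq`` (dB^2)."""

    sigma_n_sq: float = 0.0

    def __post_init__(self) -> None:
        if not self.sigma_n_sq >= 0:
            raise ValueError(f"sigma_n_sq must be >= 0, got {self.sigma_n_sq}")

    @property
    def sigma_n(self) -> float:
        return float(np.sqrt(self.sigma_n_sq))


@dataclass(frozen=True)
class FiringRateSeries:
    """Auditory-nerve firing rates (Hz) on the same time grid as the input."""

    values: np.ndarray = field(repr=False)
    dt: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "values", np.asarray(self.values, dtype=float))

    def __len__(self) -> int:
        return self.values.size

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.values.size) * self.dt


def spontaneous_probability(params: SensorParams) -> float:
    """Probability mass of the adapted intensity distribution below threshold.

    This is ``P_sp = Phi((I_theta - mu_I) / sigma_I)``, the fraction of
    time a sensor adapted to the standard environment emits only
    spontaneous activity.
    """
    return float(ndtr((params.I_theta - params.mu_I) / params.sigma_I))


def rate_intensity(I, params: SensorParams):
    """Infomax rate-intensity function: firing rate (Hz) at intensity ``I`` (dB).

    Continuous at the threshold, non-decreasing, bounded in
    ``[f_sp, f_max]`` and saturating at ``f_max`` as ``I -> inf``.
    Accepts scalars or arrays.
    """
    I = np.asarray(I, dtype=float)
    p_sp = spontaneous_probability(params)
    if p_sp >= 1.0:
        # threshold so far above the adapted distribution that the CDF
        # normalisation degenerates: the sensor only ever fires spontaneously
        out = np.full_like(I, params.f_sp)
        return float(out) if out.ndim == 0 else out
    cdf = ndtr((I - params.mu_I) / params.sigma_I)
    driven = params.f_sp + (params.f_max - params.f_sp) * (cdf - p_sp) / (1.0 - p_sp)
    out = np.where(I < params.I_theta, params.f_sp, driven)
    if out.ndim == 0:
        return float(out)
    return out


def respond(
    series: IntensityTimeSeries,
    params: SensorParams,
    noise: NoiseModel = NoiseModel(0.0),
    rng: np.random.Generator | int | None = None,
    noise_draws_per_sample: int = 1,
) -> FiringRateSeries:
    """Noisy sensor response to an intensity trajectory.

    For every sample an independent noise value ``n ~ N(0, sigma_n^2)``
    is added to the intensity before the threshold comparison and the
    CDF evaluation, i.e. the output is ``f(I(t) + n(t))``.  With
    ``sigma_n_sq = 0`` this reduces exactly to mapping the noiseless
    rate-intensity function over the series.

    ``noise_draws_per_sample`` models the bandwidth of the internal
    noise relative to the intensity sampling: with ``m > 1`` the noise
    takes ``m`` independent values while the intensity holds one sample,
    and the reported rate is the average of the ``m`` thresholded
    responses.  The default ``m = 1`` treats rates as instantaneous
    analogue quantities driven by a single noise value per sample.
    """
    if noise_draws_per_sample < 1:
        raise ValueError("noise_draws_per_sample must be >= 1")
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)

    I = series.values
    if noise.sigma_n_sq == 0.0:
        return FiringRateSeries(values=rate_intensity(I, params), dt=series.dt)

    sigma_n = noise.sigma_n
    m = noise_draws_per_sample
    if m == 1:
        rates = rate_intensity(I + sigma_n * rng.standard_normal(I.size), params)
    else:
        rates = np.zeros_like(I)
        for _ in range(m):  # average of m thresholded sub-responses
            rates += rate_intensity(I + sigma_n * rng.standard_normal(I.size), params)
        rates /= m
    return FiringRateSeries(values=rates, dt=series.dt)
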