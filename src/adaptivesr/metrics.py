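"""Information objectives: autocorrelation and mutual information.

The adaptive-SR controller needs a proxy for transmitted information
that can be computed from the sensor output alone.  That proxy is the
mean autocorrelation: the normalised autocorrelation function

    AC(tau) = (1/T) sum_t (x_t - mu_X)(x_{t+tau} - mu_X) / sigma_X^2

averaged over lags tau = 1..N.  Mean and variance are single-pass
statistics of the full series.  A histogram-based plug-in estimator of
the mutual information between sensor input and output (in bits) is
provided as the information-theoretic reference objective.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ACFunction",
    "MIEstimate",
    "autocorrelation_function",
    "mean_autocorrelation",
    "mutual_information",
]


def _as_values(series) -> np.ndarray:
    values = getattr(series, "values", series)
    return np.asarray(values, dtype=float)


@dataclass(frozen=True)
class ACFunction:
    """Normalised autocorrelation at integer lags 0..N.

    ``lags`` are in samples; ``lag_times`` converts to model time units
    when the originating series' time step is known.  ``degenerate``
    flags a constant input series, for which the normalisation is
    undefined and AC is defined as 0 at every lag.
    """

    lags: np.ndarray = field(repr=False)
    values: np.ndarray = field(repr=False)
    dt: float | None = None
    degenerate: bool = False

    @property
    def lag_times(self) -> np.ndarray:
        if self.dt is None:
            raise ValueError("no time step attached to this ACFunction")
        return self.lags * self.dt


@dataclass(frozen=True)
class MIEstimate:
    """Plug-in mutual-information estimate in bits."""

    value: float
    n_bins_x: int
    n_bins_y: int


def autocorrelation_function(series, max_lag: int) -> ACFunction:
    """Normalised autocorrelation function for lags 0..max_lag.

    Accepts an ``IntensityTimeSeries``, ``FiringRateSeries`` or plain
    array.  A constant series (e.g. a fully sub-threshold response at
    zero noise) has no well-defined normalisation; it is returned with
    ``degenerate=True`` and AC identically zero, the convention under
    which an information detector reads "nothing transmitted".
    """
    x = _as_values(series)
    dt = getattr(series, "dt", None)
    if max_lag < 0:
        raise ValueError("max_lag must be >= 0")
    if x.size <= max_lag:
        raise ValueError(f"series length {x.size} must exceed max_lag {max_lag}")

    lags = np.arange(max_lag + 1)
    mu = x.mean()
    centered = x - mu
    var = float(centered.dot(centered)) / x.size
    if var == 0.0:
        return ACFunction(lags=lags, values=np.zeros(max_lag + 1), dt=dt, degenerate=True)

    T = x.size
    values = np.empty(max_lag + 1)
    values[0] = 1.0
    for tau in range(1, max_lag + 1):
        values[tau] = centered[:-tau].dot(centered[tau:]) / (T * var)
    return ACFunction(lags=lags, values=values, dt=dt, degenerate=False)


def mean_autocorrelation(acf: ACFunction) -> float:
    """Average of AC(tau) over the positive lags 1..N (lag 0 excluded)."""
    if acf.values.size < 2:
        raise ValueError("mean autocorrelation needs at least one positive lag")
    return float(np.mean(acf.values[1:]))


def mutual_information(
    x_series,
    y_series,
    n_bins: int = 64,
    clip_sd: float = 5.0,
    value_range: tuple[tuple[float, float], tuple[float, float]] | None = None,
) -> MIEstimate:
    """Histogram plug-in estimate of MI(X; Y) in bits.

    Uses an equal-width 2-D histogram with ``n_bins`` bins per axis,
    each axis clipped to mean +/- ``clip_sd`` standard deviations (or to
    the explicit ``value_range`` when given).  The estimate is
    non-negative.  A degenerate (constant) axis carries no information
    and yields exactly 0 bits.
    """
    x = _as_values(x_series)
    y = _as_values(y_series)
    if x.size != y.size:
        raise ValueError(f"length mismatch: {x.size} vs {y.size}")
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")

    if x.std() == 0.0 or y.std() == 0.0:
        return MIEstimate(value=0.0, n_bins_x=n_bins, n_bins_y=n_bins)

    def _range(v: np.ndarray) -> tuple[float, float]:
        m, s = v.mean(), v.std()
        return (m - clip_sd * s, m + clip_sd * s)

    ranges = [_range(x), _range(y)] if value_range is None else list(value_range)
    joint, _, _ = np.histogram2d(x, y, bins=n_bins, range=ranges)
    joint /= joint.sum()
    px = joint.sum(axis=1, keepdims=True)
    py = joint.sum(axis=0, keepdims=True)
    mask = joint > 0
    mi = float(np.sum(joint[mask] * np.log2(joint[mask] / (px @ py)[mask])))
    return MIEstimate(value=max(mi, 0.0), n_bins_x=n_bins, n_bins_y=n_bins)
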