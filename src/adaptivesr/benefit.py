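"""Hearing-threshold benefit of optimally tuned SR noise.

Two independent estimators quantify how much injected noise lowers the
behavioural hearing threshold after a simulated hearing loss (threshold
elevation ``I_theta = loss``):

* Detection estimator: a psychometric function (detection probability
  versus probe intensity) is simulated with and without the AC-optimal
  noise; the benefit is the shift of its 50 %-detection point in dB.
* Iso-AC estimator: mean output autocorrelation is mapped as a function
  of the threshold with and without SR noise; the benefit is the
  horizontal distance between the two curves at equal autocorrelation,
  i.e. the threshold a healthy-noise sensor would need to transmit as
  much as the SR-assisted lossy one.

Detection model.  One trial presents a constant probe intensity ``I``
for a window of ``window_m`` internal-noise samples and counts as a
detection if any sample satisfies ``I + n >= I_theta`` (the response
exceeds the spontaneous rate at least once).  With a single noise draw
a zero-mean noise cannot move the 50 % point (the closed form is
``Phi((I - I_theta)/sigma_n)``, centred on the threshold); a
multi-sample window is the minimal detection mechanism through which
zero-mean noise lowers the measured threshold.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .environment import EnvironmentConfig
from .resonance import (
    DEFAULT_N_LAGS,
    ResonanceCurve,
    _argmax_smoothed,
    _grid_objectives,
    default_noise_grid,
    resonance_curve,
)
from .sensor import SensorParams

__all__ = [
    "PsychometricCurve",
    "ACThresholdCurve",
    "BenefitResult",
    "psychometric_curve",
    "benefit_by_detection",
    "ac_threshold_curve",
    "benefit_by_ac",
    "sr_benefit",
]

DEFAULT_WINDOW_M = 10
DEFAULT_THRESHOLD_GRID = np.arange(0.0, 60.0 + 1e-9, 2.0)


@dataclass(frozen=True)
class PsychometricCurve:
    """Detection probability versus probe intensity with its 50 % point."""

    probe_intensities: np.ndarray = field(repr=False)
    detection_prob: np.ndarray = field(repr=False)
    threshold_50: float


@dataclass(frozen=True)
class ACThresholdCurve:
    """Mean output AC as a function of the hearing threshold.

    ``mean_ac_no_sr`` uses zero injected noise, ``mean_ac_with_sr`` the
    AC-optimal noise found per threshold (``sigma_n_opt``).
    """

    thresholds: np.ndarray = field(repr=False)
    mean_ac_no_sr: np.ndarray = field(repr=False)
    mean_ac_with_sr: np.ndarray = field(repr=False)
    sigma_n_opt: np.ndarray = field(repr=False)


@dataclass(frozen=True)
class BenefitResult:
    """SR threshold benefit (dB) at one hearing loss, by both estimators."""

    hearing_loss: float
    benefit_ac: float
    benefit_detection: float
    sigma_n_opt: float
    degenerate: bool = False


def _interp_threshold_50(intensities: np.ndarray, probs: np.ndarray) -> float:
    """50 %-point of a (noisily) non-decreasing psychometric function.

    Linear interpolation across the 0.5 crossing; a deterministic step
    (0 straight to 1 between adjacent probes) returns the probe at which
    detection occurs, the median of a degenerate detection law.
    """
    above = np.nonzero(probs >= 0.5)[0]
    if above.size == 0 or above[0] == 0:
        raise ValueError(
            "probe grid does not span the 50% crossing "
            f"(range {intensities[0]:g}..{intensities[-1]:g} dB, "
            f"detection {probs[0]:.3f}..{probs[-1]:.3f})"
        )
    j = int(above[0])
    p_lo, p_hi = probs[j - 1], probs[j]
    if p_lo == 0.0 and p_hi == 1.0:
        return float(intensities[j])
    return float(intensities[j - 1] + (0.5 - p_lo) * (intensities[j] - intensities[j - 1]) / (p_hi - p_lo))


def psychometric_curve(
    params: SensorParams,
    sigma_n_sq: float,
    probe_grid: np.ndarray | None = None,
    window_m: int = DEFAULT_WINDOW_M,
    n_trials: int = 2000,
    seed: int | None = None,
) -> PsychometricCurve:
    """Simulate the psychometric function at one injected-noise level.

    Each of ``n_trials`` trials presents the probe for ``window_m``
    independent noise samples; the trial detects if any sample crosses
    threshold.  With ``sigma_n_sq = 0`` the curve is the deterministic
    step at ``I_theta``.
    """
    if n_trials < 100:
        raise ValueError("n_trials must be >= 100 for a usable curve")
    if window_m < 1:
        raise ValueError("window_m must be >= 1")
    sigma_n = float(np.sqrt(sigma_n_sq))

    if probe_grid is None:
        span = max(5.0, 6.0 * sigma_n)
        probe_grid = np.arange(params.I_theta - span, params.I_theta + span + 1e-9, 0.25)
    probe_grid = np.asarray(probe_grid, dtype=float)

    if sigma_n == 0.0:
        probs = (probe_grid >= params.I_theta).astype(float)
    else:
        rng = np.random.default_rng(seed)
        probs = np.empty(probe_grid.size)
        for i, probe in enumerate(probe_grid):
            noise = rng.standard_normal((n_trials, window_m)) * sigma_n
            detected = np.any(probe + noise >= params.I_theta, axis=1)
            probs[i] = detected.mean()

    return PsychometricCurve(
        probe_intensities=probe_grid,
        detection_prob=probs,
        threshold_50=_interp_threshold_50(probe_grid, probs),
    )


def _optimal_noise_for(
    env: EnvironmentConfig,
    params: SensorParams,
    noise_grid: np.ndarray | None,
    seed,
    n_lags: int,
    noise_draws_per_sample: int,
) -> ResonanceCurve:
    return resonance_curve(
        env,
        params,
        noise_grid=noise_grid,
        metric="ac",
        seed=seed,
        n_lags=n_lags,
        noise_draws_per_sample=noise_draws_per_sample,
    )


def benefit_by_detection(
    hearing_loss: float,
    env: EnvironmentConfig,
    base_params: SensorParams = SensorParams(),
    window_m: int = DEFAULT_WINDOW_M,
    seed: int | None = None,
    noise_grid: np.ndarray | None = None,
    n_trials: int = 4000,
    n_lags: int = DEFAULT_N_LAGS,
    noise_draws_per_sample: int = 1,
) -> float:
    """Detection-threshold benefit (dB) of AC-optimal noise at one hearing loss.

    Elevates the threshold by ``hearing_loss`` dB, finds the AC-optimal
    noise on the standard environment, and returns the difference of the
    50 %-detection points without and with that noise.
    """
    params = base_params.with_threshold(base_params.I_theta + hearing_loss)
    curve = _optimal_noise_for(env, params, noise_grid, seed, n_lags, noise_draws_per_sample)
    sigma_opt_sq = curve.optimum_sigma_n_sq

    t50_quiet = psychometric_curve(params, 0.0, window_m=window_m).threshold_50
    t50_sr = psychometric_curve(
        params, sigma_opt_sq, window_m=window_m, n_trials=n_trials, seed=seed
    ).threshold_50
    return float(t50_quiet - t50_sr)


def detection_threshold_closed_form(
    params: SensorParams, sigma_n_sq: float, window_m: int
) -> float:
    """Analytic 50 %-detection point for the windowed any-crossing rule.

    ``P(detect | I) = 1 - Phi((I_theta - I)/sigma_n)^m`` for independent
    window samples, so the 50 % point is
    ``I_theta - sigma_n * Phi^{-1}(0.5^{1/m})``.
    """
    from scipy.special import ndtri

    sigma_n = float(np.sqrt(sigma_n_sq))
    if sigma_n == 0.0:
        return params.I_theta
    return float(params.I_theta - sigma_n * ndtri(0.5 ** (1.0 / window_m)))


def ac_threshold_curve(
    env: EnvironmentConfig,
    thresholds: np.ndarray | None = None,
    base_params: SensorParams = SensorParams(),
    seed: int | None = None,
    noise_grid: np.ndarray | None = None,
    n_lags: int = DEFAULT_N_LAGS,
    noise_draws_per_sample: int = 1,
    smooth: bool = True,
) -> ACThresholdCurve:
    """Mean output AC versus hearing threshold, without and with optimal SR noise.

    One environment realisation and one unit-noise array (derived from
    ``seed``) are shared across all thresholds and grid levels, so the
    monotone structure of the curves is estimated without independent
    Monte-Carlo jitter between neighbouring thresholds.
    """
    if thresholds is None:
        thresholds = DEFAULT_THRESHOLD_GRID
    thresholds = np.asarray(thresholds, dtype=float)
    if thresholds.size < 2 or np.any(np.diff(thresholds) <= 0):
        raise ValueError("thresholds must be strictly increasing with >= 2 entries")
    if noise_grid is None:
        noise_grid = default_noise_grid(env.sigma_I)
    noise_grid = np.asarray(noise_grid, dtype=float)

    no_sr = np.empty(thresholds.size)
    with_sr = np.empty(thresholds.size)
    sigma_opt = np.empty(thresholds.size)
    for i, theta in enumerate(thresholds):
        params = base_params.with_threshold(theta)
        mean_ac, _ = _grid_objectives(
            env,
            params,
            np.sqrt(noise_grid),
            want_mi=False,
            seed=seed,  # same seed => same realisation across thresholds
            n_lags=n_lags,
            noise_draws_per_sample=noise_draws_per_sample,
            independent_realizations=False,
            mi_bins=64,
        )
        no_sr[i] = mean_ac[0]
        if np.all(mean_ac == 0.0):
            k = mean_ac.size - 1
        else:
            k = _argmax_smoothed(mean_ac, smooth)
        with_sr[i] = mean_ac[k]
        sigma_opt[i] = noise_grid[k]

    return ACThresholdCurve(
        thresholds=thresholds,
        mean_ac_no_sr=no_sr,
        mean_ac_with_sr=with_sr,
        sigma_n_opt=sigma_opt,
    )


def benefit_by_ac(hearing_loss: float, curve: ACThresholdCurve) -> float:
    """Iso-AC threshold benefit (dB) read off an AC-versus-threshold curve.

    Finds the threshold ``I_theta'`` at which the no-SR curve equals the
    with-SR autocorrelation at ``hearing_loss`` and returns
    ``hearing_loss - I_theta'``.  Both lookups use monotone linear
    interpolation on the (decreasing) curves.
    """
    thr = curve.thresholds
    if not (thr[0] <= hearing_loss <= thr[-1]):
        raise ValueError(
            f"hearing loss {hearing_loss:g} dB outside the curve range "
            f"{thr[0]:g}..{thr[-1]:g} dB"
        )
    target_ac = float(np.interp(hearing_loss, thr, curve.mean_ac_with_sr))

    no_sr = curve.mean_ac_no_sr
    lo, hi = float(np.min(no_sr)), float(np.max(no_sr))
    if not (lo <= target_ac <= hi):
        raise ValueError(
            f"target autocorrelation {target_ac:.4f} outside the no-SR curve range "
            f"[{lo:.4f}, {hi:.4f}]; extend the threshold grid"
        )
    # no-SR curve decreases with threshold: invert by reversing.
    matched_threshold = float(np.interp(target_ac, no_sr[::-1], thr[::-1]))
    return float(hearing_loss - matched_threshold)


def sr_benefit(
    hearing_loss: float,
    env: EnvironmentConfig,
    base_params: SensorParams = SensorParams(),
    window_m: int = DEFAULT_WINDOW_M,
    seed: int | None = None,
    ac_curve: ACThresholdCurve | None = None,
    noise_grid: np.ndarray | None = None,
    n_lags: int = DEFAULT_N_LAGS,
    noise_draws_per_sample: int = 1,
) -> BenefitResult:
    """Both benefit estimators plus the optimal noise at one hearing loss."""
    if ac_curve is None:
        ac_curve = ac_threshold_curve(
            env,
            base_params=base_params,
            seed=seed,
            noise_grid=noise_grid,
            n_lags=n_lags,
            noise_draws_per_sample=noise_draws_per_sample,
        )
    b_ac = benefit_by_ac(hearing_loss, ac_curve)
    b_det = benefit_by_detection(
        hearing_loss,
        env,
        base_params=base_params,
        window_m=window_m,
        seed=seed,
        noise_grid=noise_grid,
        n_lags=n_lags,
        noise_draws_per_sample=noise_draws_per_sample,
    )
    sigma_opt = float(np.interp(hearing_loss, ac_curve.thresholds, ac_curve.sigma_n_opt))
    return BenefitResult(
        hearing_loss=float(hearing_loss),
        benefit_ac=b_ac,
        benefit_detection=b_det,
        sigma_n_opt=sigma_opt,
    )
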