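"""Resonance curves, optimal-noise search and the closed-loop noise controller.

A resonance curve evaluates an information objective (mean output
autocorrelation, optionally mutual information) of the sensor response
on a grid of injected-noise variances; its argmax defines the optimal
SR noise level ``sigma_n_opt^2``.  The feedback controller realises the
same optimisation online: it hill-climbs the mean autocorrelation by
finite differences, emulating a noise generator steered by an
information detector.

Numerics.  By default every grid point reuses one environment
realisation and one unit-variance noise array scaled to the grid level
(common random numbers).  Differences along the grid are then estimated
with far lower variance than with independent realisations, which keeps
the located argmax stable where the curve is flat near its maximum.
``independent_realizations=True`` restores per-point fresh simulations.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .environment import EnvironmentConfig, generate_ou_series
from .metrics import autocorrelation_function, mean_autocorrelation, mutual_information
from .sensor import SensorParams, rate_intensity

__all__ = [
    "ResonanceCurve",
    "FeedbackController",
    "FeedbackTrajectory",
    "default_noise_grid",
    "resonance_curve",
    "find_optimal_noise",
    "run_feedback_loop",
]

DEFAULT_N_LAGS = 50


def default_noise_grid(
    sigma_I: float = 25.0, n_levels: int = 60, max_factor: float = 3.0
) -> np.ndarray:
    """Noise-variance grid: ``n_levels`` values of sigma_n^2 with sigma_n
    equally spaced from 0 to ``max_factor * sigma_I``.

    Equal spacing in sigma_n (not sigma_n^2) resolves optima both close
    to zero (low thresholds) and far out (high thresholds).
    """
    sigma_n = np.linspace(0.0, max_factor * sigma_I, n_levels)
    return sigma_n**2


@dataclass(frozen=True)
class ResonanceCurve:
    """Information objective versus injected-noise variance.

    ``optimum_sigma_n_sq`` is a member of the grid; with the default
    3-point smoothing the argmax is taken on the smoothed curve while
    ``optimum_value`` reports the raw objective at that grid point.
    ``degenerate`` flags a curve that is zero everywhere (the signal
    never reaches threshold even at the largest grid noise); the largest
    grid value is then returned as the optimum.
    """

    sigma_n_sq_grid: np.ndarray = field(repr=False)
    mean_ac: np.ndarray = field(repr=False)
    optimum_sigma_n_sq: float
    optimum_value: float
    mi_bits: np.ndarray | None = field(default=None, repr=False)
    degenerate: bool = False

    @property
    def sigma_n_grid(self) -> np.ndarray:
        return np.sqrt(self.sigma_n_sq_grid)

    @property
    def optimum_index(self) -> int:
        return int(np.argmin(np.abs(self.sigma_n_sq_grid - self.optimum_sigma_n_sq)))

    def argmax_mi(self) -> int:
        if self.mi_bits is None:
            raise ValueError("curve was computed without mutual information")
        return _argmax_smoothed(self.mi_bits, smooth=True)


def _smooth3(values: np.ndarray) -> np.ndarray:
    """3-point moving average with reflected ends."""
    padded = np.concatenate([values[:1], values, values[-1:]])
    return (padded[:-2] + padded[1:-1] + padded[2:]) / 3.0


def _argmax_smoothed(values: np.ndarray, smooth: bool) -> int:
    v = _smooth3(values) if smooth else values
    return int(np.argmax(v))  # np.argmax takes the first (smallest-noise) tie


def _mean_ac_of_rates(rates: np.ndarray, n_lags: int) -> float:
    acf = autocorrelation_function(rates, max_lag=n_lags)
    if acf.degenerate:
        return 0.0
    return mean_autocorrelation(acf)


def _grid_objectives(
    env: EnvironmentConfig,
    params: SensorParams,
    sigma_n_grid: np.ndarray,
    want_mi: bool,
    seed,
    n_lags: int,
    noise_draws_per_sample: int,
    independent_realizations: bool,
    mi_bins: int,
):
    """Evaluate mean AC (and MI) at each sigma_n of the grid."""
    m = noise_draws_per_sample
    seed_seq = np.random.SeedSequence(seed)
    mean_ac = np.empty(sigma_n_grid.size)
    mi = np.empty(sigma_n_grid.size) if want_mi else None

    def _one(sigma_n, I, Z):
        if sigma_n == 0.0:
            rates = rate_intensity(I, params)
        elif m == 1:
            rates = rate_intensity(I + sigma_n * Z, params)
        else:
            rates = np.mean([rate_intensity(I + sigma_n * Zk, params) for Zk in Z], axis=0)
        return rates

    if independent_realizations:
        for k, (sigma_n, child) in enumerate(zip(sigma_n_grid, seed_seq.spawn(sigma_n_grid.size))):
            rng = np.random.default_rng(child)
            I = generate_ou_series(env, rng=rng).values
            Z = rng.standard_normal((m, I.size)) if m > 1 else rng.standard_normal(I.size)
            rates = _one(sigma_n, I, Z)
            mean_ac[k] = _mean_ac_of_rates(rates, n_lags)
            if want_mi:
                mi[k] = mutual_information(I, rates, n_bins=mi_bins).value
    else:
        rng = np.random.default_rng(seed_seq)
        I = generate_ou_series(env, rng=rng).values
        Z = rng.standard_normal((m, I.size)) if m > 1 else rng.standard_normal(I.size)
        for k, sigma_n in enumerate(sigma_n_grid):
            rates = _one(sigma_n, I, Z)
            mean_ac[k] = _mean_ac_of_rates(rates, n_lags)
            if want_mi:
                mi[k] = mutual_information(I, rates, n_bins=mi_bins).value
    return mean_ac, mi


def resonance_curve(
    env: EnvironmentConfig,
    params: SensorParams,
    noise_grid: np.ndarray | None = None,
    metric: str = "ac",
    seed: int | None = None,
    n_lags: int = DEFAULT_N_LAGS,
    noise_draws_per_sample: int = 1,
    independent_realizations: bool = False,
    smooth: bool = True,
    mi_bins: int = 64,
) -> ResonanceCurve:
    """Compute the resonance curve of the sensor on a noise-variance grid.

    ``metric`` is ``"ac"``, ``"mi"`` or ``"both"``; the located optimum
    always refers to the mean-autocorrelation objective (the quantity an
    input-agnostic information detector can evaluate), with MI attached
    for cross-checking when requested.
    """
    if metric not in ("ac", "mi", "both"):
        raise ValueError(f"metric must be 'ac', 'mi' or 'both', got {metric!r}")
    if noise_grid is None:
        noise_grid = default_noise_grid(env.sigma_I)
    noise_grid = np.asarray(noise_grid, dtype=float)
    if noise_grid.size == 0 or np.any(np.diff(noise_grid) <= 0):
        raise ValueError("noise grid must be non-empty and strictly increasing")
    if noise_grid[0] != 0.0:
        raise ValueError("noise grid must include sigma_n_sq = 0")

    want_mi = metric in ("mi", "both")
    mean_ac, mi = _grid_objectives(
        env,
        params,
        np.sqrt(noise_grid),
        want_mi,
        seed,
        n_lags,
        noise_draws_per_sample,
        independent_realizations,
        mi_bins,
    )

    if np.all(mean_ac == 0.0):
        opt_idx = noise_grid.size - 1
        degenerate = True
    else:
        opt_idx = _argmax_smoothed(mean_ac, smooth)
        degenerate = False
    return ResonanceCurve(
        sigma_n_sq_grid=noise_grid,
        mean_ac=mean_ac,
        optimum_sigma_n_sq=float(noise_grid[opt_idx]),
        optimum_value=float(mean_ac[opt_idx]),
        mi_bits=mi,
        degenerate=degenerate,
    )


def find_optimal_noise(curve: ResonanceCurve, smooth: bool = True) -> float:
    """Optimal noise variance: argmax of mean AC over the grid.

    Exact ties break toward the smaller noise level.  An all-zero curve
    (signal never crossing threshold) returns the largest grid value;
    inspect ``curve.degenerate`` for the warning flag.
    """
    if np.all(curve.mean_ac == 0.0):
        return float(curve.sigma_n_sq_grid[-1])
    return float(curve.sigma_n_sq_grid[_argmax_smoothed(curve.mean_ac, smooth)])


@dataclass(frozen=True)
class FeedbackController:
    """Configuration of the finite-difference noise controller.

    ``step_size``: initial update of sigma_n per iteration, dB.
    ``probe_step``: finite-difference half-width in sigma_n, dB.
    ``n_probe_samples``: environment samples per objective probe.
    ``tol``: relative spread of sigma_n^2 over the last 10 iterations
    below which the loop is declared converged.
    """

    step_size: float = 2.0
    probe_step: float = 1.0
    n_probe_samples: int = 50_000
    max_iter: int = 60
    tol: float = 0.01
    decay_iters: float = 8.0
    sigma_n_max: float | None = None  # default: 3 * sigma_I


@dataclass(frozen=True)
class FeedbackTrajectory:
    """Iterates of the closed-loop noise controller."""

    sigma_n_sq: np.ndarray = field(repr=False)
    mean_ac: np.ndarray = field(repr=False)
    converged: bool

    @property
    def n_iter(self) -> int:
        return self.sigma_n_sq.size - 1

    @property
    def terminal_sigma_n_sq(self) -> float:
        """Noise level the loop settles at: mean sigma_n of the last 10 iterates."""
        tail = np.sqrt(self.sigma_n_sq[-10:])
        return float(np.mean(tail) ** 2)


def run_feedback_loop(
    env: EnvironmentConfig,
    params: SensorParams,
    controller: FeedbackController = FeedbackController(),
    seed: int | None = None,
    start_sigma_n_sq: float = 0.0,
    n_lags: int = DEFAULT_N_LAGS,
    noise_draws_per_sample: int = 1,
) -> FeedbackTrajectory:
    """Close the loop: adapt sigma_n^2 by hill climbing on mean output AC.

    Each iteration draws a fresh probe realisation of the environment,
    evaluates the objective at ``sigma_n +/- probe_step`` on that same
    realisation (paired probes cancel most Monte-Carlo error in the
    difference), and moves ``sigma_n`` by a decaying step in the uphill
    direction, clipped to ``[0, sigma_n_max]``.
    """
    sigma_max = controller.sigma_n_max if controller.sigma_n_max is not None else 3.0 * env.sigma_I
    seed_seq = np.random.SeedSequence(seed)
    probe_env = EnvironmentConfig(
        mu_I=env.mu_I,
        sigma_I=env.sigma_I,
        dt=env.dt,
        n_samples=controller.n_probe_samples,
        I0=env.I0,
    )

    m = noise_draws_per_sample
    sigma = float(np.sqrt(start_sigma_n_sq))
    sigmas_sq = [sigma**2]
    objectives = []
    converged = False

    def _objective(sigma_n, I, Z):
        if sigma_n == 0.0:
            rates = rate_intensity(I, params)
        elif m == 1:
            rates = rate_intensity(I + sigma_n * Z, params)
        else:
            rates = np.mean([rate_intensity(I + sigma_n * Zk, params) for Zk in Z], axis=0)
        return _mean_ac_of_rates(rates, n_lags)

    for k, child in enumerate(seed_seq.spawn(controller.max_iter)):
        rng = np.random.default_rng(child)
        I = generate_ou_series(probe_env, rng=rng).values
        Z = rng.standard_normal((m, I.size)) if m > 1 else rng.standard_normal(I.size)

        step = controller.step_size / (1.0 + k / controller.decay_iters)
        c = controller.probe_step
        hi = min(sigma + c, sigma_max)
        lo = max(sigma - c, 0.0)
        j_hi = _objective(hi, I, Z)
        j_lo = _objective(lo, I, Z)
        objectives.append(0.5 * (j_hi + j_lo))

        if j_hi > j_lo:
            sigma = min(sigma + step, sigma_max)
        elif j_lo > j_hi:
            sigma = max(sigma - step, 0.0)
        sigmas_sq.append(sigma**2)

        if k >= 10:
            tail = np.asarray(sigmas_sq[-10:])
            scale = max(float(np.median(tail)), 1e-9)
            if (tail.max() - tail.min()) / scale < controller.tol:
                converged = True
                break

    objectives.append(objectives[-1] if objectives else 0.0)
    return FeedbackTrajectory(
        sigma_n_sq=np.asarray(sigmas_sq),
        mean_ac=np.asarray(objectives),
        converged=converged,
    )
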