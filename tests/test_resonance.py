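"""Resonance curves, optimal-noise search, and the feedback controller."""

import numpy as np
import pytest

from adaptivesr import (
    EnvironmentConfig,
    FeedbackController,
    ResonanceCurve,
    SensorParams,
    default_noise_grid,
    find_optimal_noise,
    resonance_curve,
    run_feedback_loop,
)


def _make_curve(mean_ac):
    mean_ac = np.asarray(mean_ac, dtype=float)
    grid = np.linspace(0.0, 100.0, mean_ac.size)
    k = int(np.argmax(mean_ac))
    return ResonanceCurve(
        sigma_n_sq_grid=grid,
        mean_ac=mean_ac,
        optimum_sigma_n_sq=float(grid[k]),
        optimum_value=float(mean_ac[k]),
    )


class TestNoiseGrid:
    def test_default_grid_shape_and_range(self):
        grid = default_noise_grid(25.0)
        assert grid.size == 60
        assert grid[0] == 0.0
        assert grid[-1] == pytest.approx((3 * 25.0) ** 2)
        assert np.all(np.diff(grid) > 0)


class TestFindOptimalNoise:
    def test_monotone_decreasing_curve_prefers_zero(self):
        curve = _make_curve(np.linspace(0.5, 0.1, 20))
        assert find_optimal_noise(curve, smooth=False) == 0.0

    def test_interior_peak_located(self):
        values = np.concatenate([np.linspace(0.0, 0.4, 10), np.linspace(0.38, 0.05, 10)])
        curve = _make_curve(values)
        expected = curve.sigma_n_sq_grid[9]
        assert find_optimal_noise(curve, smooth=False) == pytest.approx(expected)

    def test_ties_break_toward_smaller_noise(self):
        values = np.array([0.1, 0.3, 0.2, 0.3, 0.1])
        curve = _make_curve(values)
        assert find_optimal_noise(curve, smooth=False) == pytest.approx(curve.sigma_n_sq_grid[1])

    def test_all_zero_curve_returns_largest_grid_value(self):
        curve = ResonanceCurve(
            sigma_n_sq_grid=np.linspace(0.0, 100.0, 5),
            mean_ac=np.zeros(5),
            optimum_sigma_n_sq=100.0,
            optimum_value=0.0,
            degenerate=True,
        )
        assert find_optimal_noise(curve) == 100.0


class TestResonanceCurve:
    def test_supra_threshold_signal_needs_no_noise(self):
        # threshold 6 sigma below every input: noise can only degrade
        env = EnvironmentConfig(n_samples=50_000, seed=31)
        params = SensorParams(I_theta=40.0 - 6 * 25.0)
        curve = resonance_curve(env, params, seed=31)
        assert curve.optimum_sigma_n_sq == 0.0
        assert not curve.degenerate

    def test_unreachable_threshold_flags_degenerate(self):
        env = EnvironmentConfig(n_samples=2_000, seed=32)
        params = SensorParams(I_theta=2000.0)
        curve = resonance_curve(env, params, seed=32, n_lags=20)
        assert curve.degenerate
        assert curve.optimum_sigma_n_sq == pytest.approx(curve.sigma_n_sq_grid[-1])

    def test_interior_peak_with_band_limited_noise(self):
        # with noise fluctuating faster than the intensity (10 draws per
        # sample) the classic stochastic-resonance peak appears at a
        # half-sub-threshold operating point
        env = EnvironmentConfig(n_samples=100_000, seed=33)
        params = SensorParams(I_theta=40.0)
        curve = resonance_curve(env, params, seed=33, noise_draws_per_sample=10)
        sigma_opt = np.sqrt(curve.optimum_sigma_n_sq)
        assert 5.0 < sigma_opt < 25.0
        assert curve.optimum_value > curve.mean_ac[0] + 0.002

    def test_optimum_is_grid_member_and_consistent(self):
        env = EnvironmentConfig(n_samples=20_000, seed=34)
        curve = resonance_curve(env, SensorParams(I_theta=30.0), seed=34, n_lags=20)
        assert curve.optimum_sigma_n_sq in curve.sigma_n_sq_grid
        assert curve.optimum_sigma_n_sq == find_optimal_noise(curve)

    def test_grid_validation(self):
        env = EnvironmentConfig(n_samples=1_000, seed=0)
        params = SensorParams()
        with pytest.raises(ValueError):
            resonance_curve(env, params, noise_grid=np.array([1.0, 4.0]))  # missing zero
        with pytest.raises(ValueError):
            resonance_curve(env, params, noise_grid=np.array([0.0, 4.0, 4.0]))
        with pytest.raises(ValueError):
            resonance_curve(env, params, metric="entropy")

    def test_mi_requires_request(self):
        env = EnvironmentConfig(n_samples=5_000, seed=35)
        curve = resonance_curve(env, SensorParams(I_theta=20.0), seed=35, n_lags=10)
        assert curve.mi_bits is None
        with pytest.raises(ValueError):
            curve.argmax_mi()


class TestFeedbackLoop:
    def test_settles_at_zero_for_supra_threshold_signal(self):
        env = EnvironmentConfig(n_samples=200_000, seed=41)
        params = SensorParams(I_theta=-60.0)
        traj = run_feedback_loop(
            env, params, controller=FeedbackController(max_iter=30), seed=41
        )
        assert traj.terminal_sigma_n_sq < 1.0

    def test_starting_at_optimum_stays_near_it(self):
        # averaged-noise regime with a genuine interior optimum
        env = EnvironmentConfig(n_samples=200_000, seed=42)
        params = SensorParams(I_theta=40.0)
        grid_curve = resonance_curve(env, params, seed=42, noise_draws_per_sample=10)
        opt = grid_curve.optimum_sigma_n_sq
        traj = run_feedback_loop(
            env,
            params,
            controller=FeedbackController(max_iter=30),
            seed=42,
            start_sigma_n_sq=opt,
            noise_draws_per_sample=10,
        )
        assert abs(np.sqrt(traj.terminal_sigma_n_sq) - np.sqrt(opt)) < 4.0

    def test_climbs_to_interior_optimum_from_zero(self):
        env = EnvironmentConfig(n_samples=200_000, seed=43)
        params = SensorParams(I_theta=40.0)
        grid_curve = resonance_curve(env, params, seed=43, noise_draws_per_sample=10)
        traj = run_feedback_loop(env, params, seed=43, noise_draws_per_sample=10)
        assert abs(np.sqrt(traj.terminal_sigma_n_sq) - np.sqrt(grid_curve.optimum_sigma_n_sq)) < 4.0

    def test_trajectory_bookkeeping(self):
        env = EnvironmentConfig(n_samples=20_000, seed=44)
        traj = run_feedback_loop(
            env,
            SensorParams(I_theta=10.0),
            controller=FeedbackController(max_iter=15, n_probe_samples=10_000),
            seed=44,
        )
        assert traj.sigma_n_sq.size == traj.mean_ac.size
        assert traj.n_iter <= 15
        assert np.all(np.isfinite(traj.sigma_n_sq))
        assert np.all(traj.sigma_n_sq >= 0.0)
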