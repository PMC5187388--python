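"""Psychometric functions, AC-vs-threshold curves, and SR benefit estimators."""

import math

import numpy as np
import pytest

from adaptivesr import (
    ACThresholdCurve,
    EnvironmentConfig,
    SensorParams,
    ac_threshold_curve,
    benefit_by_ac,
    psychometric_curve,
    sr_benefit,
)
from adaptivesr.benefit import detection_threshold_closed_form


def _phi(z):
    return 0.5 * (1.0 + math.erf(z / math.sqrt(2.0)))


class TestPsychometricCurve:
    def test_zero_noise_is_a_step_at_threshold(self):
        params = SensorParams(I_theta=20.0)
        curve = psychometric_curve(params, 0.0)
        assert curve.threshold_50 == pytest.approx(20.0)
        below = curve.probe_intensities < 20.0
        assert np.all(curve.detection_prob[below] == 0.0)
        assert np.all(curve.detection_prob[~below] == 1.0)

    def test_single_sample_window_matches_gaussian_exceedance(self):
        # window of one: P(detect) = Phi((I - theta)/sigma_n), so the 50%
        # point sits exactly at the threshold despite the noise
        params = SensorParams(I_theta=30.0)
        sigma_n = 6.0
        curve = psychometric_curve(params, sigma_n**2, window_m=1, n_trials=4000, seed=1)
        expected = np.array(
            [_phi((I - 30.0) / sigma_n) for I in curve.probe_intensities]
        )
        assert np.max(np.abs(curve.detection_prob - expected)) < 0.03
        assert curve.threshold_50 == pytest.approx(30.0, abs=0.3)

    def test_windowed_detection_shifts_threshold_left(self):
        # m independent looks: P(detect) = 1 - Phi((theta - I)/sigma_n)^m
        params = SensorParams(I_theta=30.0)
        sigma_n, m = 6.0, 10
        curve = psychometric_curve(params, sigma_n**2, window_m=m, n_trials=4000, seed=2)
        closed_form = detection_threshold_closed_form(params, sigma_n**2, m)
        assert closed_form < 30.0
        assert curve.threshold_50 == pytest.approx(closed_form, abs=0.3)
        expected = np.array(
            [1.0 - _phi((30.0 - I) / sigma_n) ** m for I in curve.probe_intensities]
        )
        assert np.max(np.abs(curve.detection_prob - expected)) < 0.03

    def test_detection_probability_rises_with_intensity(self):
        params = SensorParams(I_theta=10.0)
        curve = psychometric_curve(params, 16.0, n_trials=4000, seed=3)
        # non-decreasing within Monte-Carlo error
        assert np.all(np.diff(curve.detection_prob) > -0.05)

    def test_probe_grid_must_span_crossing(self):
        params = SensorParams(I_theta=0.0)
        with pytest.raises(ValueError, match="50%"):
            psychometric_curve(params, 4.0, probe_grid=np.array([20.0, 25.0, 30.0]), seed=0)

    def test_trial_count_floor(self):
        with pytest.raises(ValueError):
            psychometric_curve(SensorParams(), 1.0, n_trials=10)


class TestBenefitByAc:
    def _linear_curve(self, shift):
        thresholds = np.arange(0.0, 61.0, 2.0)
        no_sr = 1.0 - thresholds / 100.0
        with_sr = 1.0 - np.clip(thresholds - shift, 0.0, None) / 100.0
        return ACThresholdCurve(
            thresholds=thresholds,
            mean_ac_no_sr=no_sr,
            mean_ac_with_sr=with_sr,
            sigma_n_opt=np.full_like(thresholds, 25.0),
        )

    def test_identical_curves_give_zero_benefit(self):
        curve = self._linear_curve(0.0)
        assert benefit_by_ac(30.0, curve) == pytest.approx(0.0, abs=1e-9)

    def test_known_horizontal_shift_is_recovered(self):
        curve = self._linear_curve(5.0)
        assert benefit_by_ac(30.0, curve) == pytest.approx(5.0, abs=1e-9)

    def test_loss_outside_curve_range_rejected(self):
        curve = self._linear_curve(0.0)
        with pytest.raises(ValueError, match="outside"):
            benefit_by_ac(80.0, curve)

    def test_unreachable_target_ac_rejected(self):
        thresholds = np.arange(0.0, 21.0, 2.0)
        curve = ACThresholdCurve(
            thresholds=thresholds,
            mean_ac_no_sr=1.0 - thresholds / 100.0,
            mean_ac_with_sr=np.full_like(thresholds, 2.0),  # above the no-SR range
            sigma_n_opt=np.zeros_like(thresholds),
        )
        with pytest.raises(ValueError, match="extend the threshold grid"):
            benefit_by_ac(10.0, curve)


@pytest.fixture(scope="module")
def small_curve():
    env = EnvironmentConfig(n_samples=40_000, seed=51)
    thresholds = np.arange(0.0, 61.0, 10.0)
    grid = np.linspace(0.0, 60.0, 16) ** 2
    return ac_threshold_curve(env, thresholds=thresholds, seed=51, noise_grid=grid)


class TestAcThresholdCurve:

    def test_no_sr_autocorrelation_decreases_with_threshold(self, small_curve):
        assert np.all(np.diff(small_curve.mean_ac_no_sr) < 0)

    def test_sr_never_hurts(self, small_curve):
        assert np.all(small_curve.mean_ac_with_sr >= small_curve.mean_ac_no_sr - 1e-12)

    def test_threshold_grid_validation(self):
        env = EnvironmentConfig(n_samples=1_000, seed=0)
        with pytest.raises(ValueError):
            ac_threshold_curve(env, thresholds=np.array([10.0]))
        with pytest.raises(ValueError):
            ac_threshold_curve(env, thresholds=np.array([10.0, 5.0]))


class TestLagCountRobustness:
    def test_iso_ac_benefit_insensitive_to_lag_count(self):
        # the number of evaluated lag-times is a free analysis parameter;
        # the benefit read-out must not depend on it materially
        env = EnvironmentConfig(n_samples=40_000, seed=61)
        thresholds = np.arange(0.0, 61.0, 10.0)
        grid = np.linspace(0.0, 60.0, 16) ** 2
        benefits = []
        for n_lags in (20, 50, 100):
            curve = ac_threshold_curve(
                env, thresholds=thresholds, seed=61, noise_grid=grid, n_lags=n_lags
            )
            benefits.append(benefit_by_ac(30.0, curve))
        assert max(benefits) - min(benefits) < 1.0


class TestSrBenefit:
    def test_no_loss_means_no_benefit(self):
        env = EnvironmentConfig(n_samples=60_000, seed=52)
        thresholds = np.arange(0.0, 31.0, 5.0)
        curve = ac_threshold_curve(env, thresholds=thresholds, seed=52)
        result = sr_benefit(0.0, env, seed=52, ac_curve=curve)
        assert result.benefit_ac == pytest.approx(0.0, abs=0.5)
        assert result.benefit_detection == pytest.approx(0.0, abs=0.5)
        assert result.hearing_loss == 0.0

    def test_result_fields_are_consistent(self):
        env = EnvironmentConfig(n_samples=60_000, seed=53)
        thresholds = np.arange(0.0, 41.0, 5.0)
        curve = ac_threshold_curve(env, thresholds=thresholds, seed=53)
        result = sr_benefit(20.0, env, seed=53, ac_curve=curve)
        assert result.sigma_n_opt >= 0.0
        assert np.isfinite(result.benefit_ac)
        assert np.isfinite(result.benefit_detection)
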