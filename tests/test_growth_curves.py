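"""Calibration, smoothing, QC and doubling-time estimation."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from colonyscreen import (
    GrowthCurve,
    InvalidCalibrationError,
    InvalidParameterError,
    NoGrowthError,
    QCRules,
    calibrate_intensity,
    estimate_doubling_time,
    qc_curve,
    smooth_curve,
)
from colonyscreen.growth_curves import (
    FLAG_LOW_DYNAMIC_RANGE,
    FLAG_NON_MONOTONE,
    FLAG_TOO_FEW_POINTS,
)


def exponential_curve(D=1.5, dt=1 / 3, n=60, N0=1e5, plate="p"):
    t = np.arange(n) * dt
    return GrowthCurve(plate, 0, 0, t, N0 * 2 ** (t / D))


class TestCalibration:
    def test_identity(self):
        v = np.array([1.0, 5.0, 9.0])
        assert np.array_equal(calibrate_intensity(v), v)

    def test_negative_clamps_to_zero(self):
        assert calibrate_intensity(np.array([-5.0]))[0] == 0.0

    def test_monotone_cubic_round_trip(self):
        cal = lambda x: x ** 3 + 2 * x  # strictly increasing
        v = np.linspace(0.0, 10.0, 25)
        out = calibrate_intensity(v, cal)
        # invert numerically and recover the original series
        from scipy.optimize import brentq

        back = np.array([brentq(lambda x, yy=y: cal(x) - yy, 0, 20) for y in out])
        assert np.allclose(back, v, atol=1e-8)

    def test_non_monotone_rejected(self):
        with pytest.raises(InvalidCalibrationError):
            calibrate_intensity(np.array([0.0, 4.0]), lambda x: -x)


class TestSmoothing:
    def test_constant_unchanged(self):
        c = GrowthCurve("p", 0, 0, np.arange(20.0), np.full(20, 7.0))
        assert np.allclose(smooth_curve(c).values, 7.0)

    def test_spike_removed_by_median(self):
        v = np.full(21, 5.0)
        v[10] += 100.0
        c = GrowthCurve("p", 0, 0, np.arange(21.0), v)
        out = smooth_curve(c, median_window=3, mean_window=1)
        assert np.allclose(out.values, 5.0)

    def test_noisy_exponential_rmse_decreases(self, rng):
        """Log-scale RMSE to the noise-free truth drops after smoothing
        (log scale weights all phases of an exponential curve equally)."""
        truth = exponential_curve(n=120)
        noisy_values = truth.values * np.exp(rng.normal(0, 0.1, truth.values.size))
        noisy = GrowthCurve("p", 0, 0, truth.times, noisy_values)
        sm = smooth_curve(noisy)
        log_truth = np.log(truth.values)
        rmse_before = np.sqrt(np.mean((np.log(noisy.values) - log_truth) ** 2))
        rmse_after = np.sqrt(np.mean((np.log(sm.values) - log_truth) ** 2))
        assert rmse_after < rmse_before

    def test_even_window_rejected(self):
        c = exponential_curve()
        with pytest.raises(InvalidParameterError):
            smooth_curve(c, median_window=4)
        with pytest.raises(InvalidParameterError):
            smooth_curve(c, mean_window=2)

    def test_length_preserved(self):
        c = exponential_curve(n=31)
        assert smooth_curve(c).values.size == 31


class TestQC:
    def test_doubling_series_passes(self):
        c = exponential_curve(D=2.5, n=217)
        assert qc_curve(c) == set()

    def test_constant_series_fails_dynamic_range(self):
        c = GrowthCurve("p", 0, 0, np.arange(20.0), np.full(20, 3.0))
        assert FLAG_LOW_DYNAMIC_RANGE in qc_curve(c)

    def test_too_few_points(self):
        c = GrowthCurve("p", 0, 0, np.arange(5.0), np.linspace(1, 10, 5))
        assert FLAG_TOO_FEW_POINTS in qc_curve(c)

    def test_alternating_noise_fails_monotonicity(self):
        v = np.where(np.arange(30) % 2 == 0, 1e5, 3e5).astype(float)
        c = GrowthCurve("p", 0, 0, np.arange(30.0), v)
        assert FLAG_NON_MONOTONE in qc_curve(c)

    def test_simulator_corruption_rejected_at_configured_rate(self):
        """QC rejection on simulator output tracks the 0.3% corruption rate."""
        from colonyscreen import SimulationConfig, simulate_screen
        from colonyscreen.growth_curves import process_plate

        cfg = SimulationConfig(noise_sd=0.0, bias_amplitude=0.1, seed=5)
        curves, _, truth = simulate_screen(cfg, [f"s{i}" for i in range(1152)])
        n_total, n_rejected, n_corrupt_caught = 0, 0, 0
        corrupted = set(truth.corrupted)
        for pid, plate_curves in curves.items():
            table = process_plate(plate_curves)
            rejected = table[~table.qc_pass]
            n_total += len(table)
            n_rejected += len(rejected)
            n_corrupt_caught += sum(
                (pid, int(r.row), int(r.col)) in corrupted for r in rejected.itertuples()
            )
        assert n_corrupt_caught == len(corrupted)  # every corrupted curve rejected
        # rejection fraction ~ corruption rate (few, if any, false rejections)
        assert n_rejected / n_total == pytest.approx(0.003, abs=0.002)


class TestDoublingTime:
    def test_exact_doubling_series(self):
        t = np.arange(12.0)
        c = GrowthCurve("p", 0, 0, t, 2.0 ** t)
        est = estimate_doubling_time(c)
        assert est.D == pytest.approx(1.0, abs=1e-12)
        assert est.log2D == pytest.approx(0.0, abs=1e-12)
        assert est.fit_r2 == pytest.approx(1.0, abs=1e-9)

    def test_exponential_rate_recovered(self):
        c = exponential_curve(D=1.5)
        est = estimate_doubling_time(c)
        assert est.D == pytest.approx(1.5, rel=0.05)

    def test_constant_series_no_growth(self):
        c = GrowthCurve("p", 0, 0, np.arange(20.0), np.full(20, 1e5))
        with pytest.raises(NoGrowthError):
            estimate_doubling_time(c)

    @pytest.mark.parametrize("window", [3, 5, 7, 11, 21])
    def test_exact_on_exponential_any_window(self, window):
        """Noise-free exponential: D correct to >= 6 significant digits."""
        c = exponential_curve(D=2.345, n=80)
        est = estimate_doubling_time(c, window=window)
        assert est.D == pytest.approx(2.345, rel=1e-6)

    @given(scale=st.floats(min_value=1e-3, max_value=1e6))
    def test_scale_invariance(self, scale):
        """Multiplying the series by a constant leaves D unchanged."""
        c = exponential_curve(D=2.0, n=40)
        scaled = GrowthCurve("p", 0, 0, c.times, c.values * scale)
        assert estimate_doubling_time(scaled).D == pytest.approx(
            estimate_doubling_time(c).D, rel=1e-9
        )

    def test_smoothing_changes_noise_free_estimate_under_1pct(self):
        c = exponential_curve(D=2.5, n=217)
        d_raw = estimate_doubling_time(c).D
        d_smooth = estimate_doubling_time(smooth_curve(c)).D
        assert abs(d_smooth - d_raw) / d_raw < 0.01

    def test_logistic_far_from_capacity(self):
        """Early logistic phase behaves exponentially: D = ln2/r within 5%."""
        from colonyscreen import logistic_curve

        r = math.log(2) / 1.5
        t = np.arange(0, 30, 1 / 3)
        c = GrowthCurve("p", 0, 0, t, logistic_curve(1e5, 1e9, r, t))
        assert estimate_doubling_time(c).D == pytest.approx(1.5, rel=0.05)

    def test_strictly_increasing_times_required(self):
        with pytest.raises(InvalidParameterError):
            GrowthCurve("p", 0, 0, np.array([0.0, 0.0, 1.0]), np.ones(3))
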