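"""Piecewise fitting, F-ratio selection and variance calibration."""

import itertools
import math

import numpy as np
import pytest

from ventasync import (
    VarianceCalibration,
    calibrate_variance,
    f_ratio,
    fit_piecewise,
    segment_cost,
    select_model,
)
from ventasync.regression import UnfittableError, critical_value
from ventasync.waveform import HalfCycle

from conftest import make_polyline_half, random_half


def brute_force_fit(half, r, min_segment_points):
    """Independent oracle: enumerate all breakpoint combinations, OLS per
    segment via lstsq, track the minimum (first winner on ties)."""
    v, p = half.volume, half.pressure
    n = len(v)
    m = min_segment_points

    def seg_sse(a, b):
        x = np.column_stack([v[a:b], np.ones(b - a)])
        coef, res, rank, _ = np.linalg.lstsq(x, p[a:b], rcond=None)
        fitted = x @ coef
        return float(np.sum((p[a:b] - fitted) ** 2))

    best = (math.inf, None)
    for combo in itertools.combinations(range(m, n - m + 1), r - 1):
        bounds = (0,) + combo + (n,)
        if any(b - a < m for a, b in zip(bounds[:-1], bounds[1:])):
            continue
        total = 0.0
        for a, b in zip(bounds[:-1], bounds[1:]):
            total += seg_sse(a, b)
        if total < best[0]:
            best = (total, combo)
    return best


class TestSegmentCost:
    def test_exact_line_recovered(self):
        v = np.linspace(0, 1, 30)
        slope, intercept, sse = segment_cost(v, 10 * v + 5)
        assert slope == pytest.approx(10, abs=1e-10)
        assert intercept == pytest.approx(5, abs=1e-10)
        assert sse == pytest.approx(0, abs=1e-18)

    def test_two_points_interpolate_exactly(self):
        _, _, sse = segment_cost(np.array([0.1, 0.4]), np.array([3.0, 9.0]))
        assert sse == pytest.approx(0, abs=1e-20)

    def test_matches_normal_equation_oracle(self, rng):
        v = rng.uniform(0, 1, 20)
        p = 12 * v + 3 + rng.normal(0, 0.5, 20)
        slope, intercept, sse = segment_cost(v, p)
        x = np.column_stack([v, np.ones(20)])
        beta = np.linalg.solve(x.T @ x, x.T @ p)
        sse_oracle = float(np.sum((p - x @ beta) ** 2))
        assert slope == pytest.approx(beta[0], rel=1e-9)
        assert intercept == pytest.approx(beta[1], rel=1e-9)
        assert sse == pytest.approx(sse_oracle, rel=1e-9)

    def test_vertical_segment_flagged_degenerate(self):
        v = np.full(10, 0.3)
        p = np.arange(10.0)
        slope, intercept, sse = segment_cost(v, p)
        assert math.isnan(slope)
        assert intercept == pytest.approx(4.5)
        assert sse == pytest.approx(float(np.sum((p - 4.5) ** 2)))


class TestFitPiecewise:
    def test_noise_free_two_segment_recovery(self):
        half = make_polyline_half([8, 25], [0.5], n=100, v_max=0.5)
        fit = fit_piecewise(half, 2)
        assert fit.rsse <= 1e-12
        assert fit.breakpoints[0] == pytest.approx(0.25, abs=0.01)
        assert fit.slopes == pytest.approx([8, 25], abs=1e-6)

    def test_r1_reduces_to_segment_cost(self, rng):
        half = random_half(rng, n=80, r=2)
        fit = fit_piecewise(half, 1)
        slope, intercept, sse = segment_cost(half.volume, half.pressure)
        assert fit.slopes[0] == pytest.approx(slope)
        assert fit.rsse == pytest.approx(sse)

    def test_small_n_matches_bruteforce_enumeration(self, rng):
        half = random_half(rng, n=25, r=3, noise_sd=0.8)
        fit = fit_piecewise(half, 3, min_segment_points=5)
        oracle_rsse, oracle_combo = brute_force_fit(half, 3, 5)
        assert tuple(fit.breakpoint_indices) == oracle_combo
        assert fit.rsse == pytest.approx(oracle_rsse, rel=1e-9)

    def test_insufficient_points_rejected(self):
        half = make_polyline_half([10, 20], [0.5], n=12)
        with pytest.raises(UnfittableError):
            fit_piecewise(half, 3, min_segment_points=5)

    def test_breakpoints_strictly_inside_and_ordered(self, rng):
        for _ in range(10):
            half = random_half(rng, n=120, r=4)
            fit = fit_piecewise(half, 4)
            idx = fit.breakpoint_indices
            assert np.all(np.diff(idx) > 0)
            assert idx[0] >= 5 and idx[-1] <= half.n_points - 5
            assert len(fit.breakpoints) == 3

    def test_rsse_monotone_in_r(self, rng):
        for _ in range(10):
            half = random_half(rng, n=150, r=3)
            rsse = [fit_piecewise(half, r).rsse for r in (1, 2, 3, 4, 5)]
            for lo, hi in zip(rsse[1:], rsse[:-1]):
                assert lo <= hi * (1 + 1e-9) + 1e-12

    def test_affine_equivariance(self, rng):
        half = random_half(rng, n=90, r=3)
        c, d = 2.5, -7.0
        scaled = HalfCycle(half.phase, half.volume, c * half.pressure + d)
        base = fit_piecewise(half, 3)
        other = fit_piecewise(scaled, 3)
        np.testing.assert_allclose(other.slopes, c * base.slopes, rtol=1e-8)
        np.testing.assert_allclose(other.intercepts, c * base.intercepts + d,
                                   rtol=1e-8, atol=1e-8)
        assert other.rsse == pytest.approx(c * c * base.rsse, rel=1e-8)


class TestFRatioAndSelection:
    def test_no_improvement_gives_zero(self, rng):
        half = random_half(rng, n=100, r=1, noise_sd=0.0)
        f2 = fit_piecewise(half, 2)
        f3 = fit_piecewise(half, 3)
        calib = VarianceCalibration(0.5, 10, "per-breath")
        assert f_ratio(f2, f3, calib) == pytest.approx(0.0, abs=1e-6)

    def test_arithmetic_from_definition(self):
        a = fit_piecewise(make_polyline_half([5, 30], [0.4], n=60), 2)
        b = fit_piecewise(make_polyline_half([5, 30], [0.4], n=60), 3)
        a.rsse, b.rsse = 5.0, 2.0
        calib = VarianceCalibration(0.5, 10, "per-breath")
        assert f_ratio(a, b, calib) == pytest.approx(6.0)

    def test_noise_free_three_segments_exceed_any_critical_value(self):
        half = make_polyline_half([10, -20, 40], [0.33, 0.66], n=120)
        f2 = fit_piecewise(half, 2)
        f3 = fit_piecewise(half, 3)
        calib = VarianceCalibration(1e-6, 1, "per-breath")
        f = f_ratio(f2, f3, calib)
        assert f > critical_value(0.01, 120, 2, f3.n_combinations)

    def test_select_accepts_two_segments_immediately(self, floor_calib):
        half = make_polyline_half([8, 25], [0.5], n=100)
        assert select_model(half, floor_calib).r == 2

    def test_select_recovers_four_segment_archetype(self, floor_calib):
        half = make_polyline_half([25, -15, 78, 25], [0.10, 0.30, 0.45], n=134)
        fit = select_model(half, floor_calib)
        assert fit.r == 4
        assert np.sign(fit.slopes).tolist() == [1, -1, 1, 1]

    def test_selection_trace_recorded(self, floor_calib):
        half = make_polyline_half([8, 25], [0.5], n=100)
        fit = select_model(half, floor_calib)
        assert fit.selection is not None
        assert fit.selection["tests"][0]["r"] == 2

    def test_recovery_rate_increases_with_slope_contrast(self, rng):
        # 3-segment truth with growing middle-slope contrast: the selected
        # model should recover r=3 more often as the contrast grows
        rates = []
        for contrast in (5.0, 30.0, 90.0):
            hits = 0
            for _ in range(15):
                half = make_polyline_half([20, 20 - contrast, 20], [0.33, 0.66],
                                          n=90, noise_sd=0.4, rng=rng)
                calib = VarianceCalibration(0.16, 10, "per-breath")
                hits += select_model(half, calib, r_max=4).r >= 3
            rates.append(hits / 15)
        assert rates[0] <= rates[1] + 1e-9 <= rates[2] + 2e-9
        assert rates[2] == 1.0


class TestCalibrateVariance:
    def test_noise_free_hits_floor(self):
        halves = [make_polyline_half([8, 25], [0.5], n=100) for _ in range(5)]
        calib = calibrate_variance(halves)
        assert calib.sigma2 == pytest.approx(1e-6)

    def test_single_half_equals_rsse_over_dof(self, rng):
        half = random_half(rng, n=100, r=2, noise_sd=0.5)
        calib = calibrate_variance([half])
        fit = fit_piecewise(half, 2)
        assert calib.sigma2 == pytest.approx(fit.rsse / (100 - 4))
        assert calib.n_halves_used == 1

    def test_known_noise_level_recovered(self, rng):
        halves = [
            make_polyline_half([10, 30], [0.5], n=100, noise_sd=0.5, rng=rng)
            for _ in range(60)
        ]
        calib = calibrate_variance(halves)
        assert calib.sigma2 == pytest.approx(0.25, rel=0.10)

    def test_all_unfittable_raises(self):
        tiny = HalfCycle("inspiration", np.array([0.0, 0.1]), np.array([5.0, 6.0]))
        with pytest.raises(Exception):
            calibrate_variance([tiny])
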