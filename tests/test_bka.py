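"""Growth-curve scoring: window selection, threshold inversion, classes."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from nabassay.bka import (
    AssayConfig,
    CurveRole,
    GrowthCurve,
    average_replicates,
    classify_killing,
    control_baseline,
    detect_growth,
    fit_linear_phase,
    score_bka,
    select_linear_range,
    time_to_threshold,
    with_class,
    KillingClass,
    LinearFit,
)
from nabassay.config import DEFAULT_TIME_GRID
from nabassay.synth import GrowthModelParams, simulate_growth_curve

CFG = AssayConfig()


def _brute_force_window(curve: GrowthCurve, cfg: AssayConfig) -> tuple[int, int]:
    """Independent window oracle: rank all windows with numpy polyfit."""
    t, y = curve.times_arr, curve.od_arr
    thr = cfg.od_threshold
    reaches = (y >= thr).any()
    first_above = int(np.flatnonzero(y >= thr)[0]) if reaches else None
    candidates = []
    n = len(t)
    for a in range(n):
        for b in range(a + cfg.min_window, n + 1):
            tw, yw = t[a:b], y[a:b]
            slope, intercept = np.polyfit(tw, yw, 1)
            if slope <= 0:
                continue
            if reaches:
                brackets = (yw <= thr).any() and (yw >= thr).any()
                if not brackets and not (a <= first_above < b):
                    continue
            elif yw.max() < thr - cfg.growth_min_rise:
                continue
            resid = yw - (slope * tw + intercept)
            ss_tot = ((yw - yw.mean()) ** 2).sum()
            r2 = 1.0 - (resid**2).sum() / ss_tot if ss_tot > 0 else 0.0
            candidates.append((round(r2, 9), b - a, -a, (a, b)))
    return max(candidates)[-1]


class TestDetectGrowth:
    def test_flat_curve_is_no_growth(self, flat_curve):
        assert detect_growth(flat_curve, CFG) is False

    def test_noiseless_rise_detected(self, noiseless_curve):
        assert detect_growth(noiseless_curve, CFG) is True

    def test_rise_that_never_nears_threshold_is_no_growth(self):
        # climbs 0.1 OD but stays far below the 0.3 threshold
        curve = GrowthCurve("slow", CurveRole.PLASMA, (0, 5, 10, 14), (0.05, 0.08, 0.12, 0.15))
        assert detect_growth(curve, CFG) is False

    def test_heat_inactivated_growth_restored(self):
        params = GrowthModelParams(lag_h=2.7, noise_sd=0.01)
        curve = simulate_growth_curve(params, DEFAULT_TIME_GRID, seed=3, role=CurveRole.HEAT_INACTIVATED)
        assert detect_growth(curve, CFG) is True


class TestSelectLinearRange:
    def test_rise_phase_selected_on_noiseless_curve(self, noiseless_curve):
        window = select_linear_range(noiseless_curve, CFG)
        # grid is (0, 5..14); the exact-linear stretch runs t=5..13 (plateau
        # reached at 13.5 makes t=14 off-line); index 1..9 inclusive
        assert window == (1, 10)
        assert window == _brute_force_window(noiseless_curve, CFG)

    def test_globally_linear_curve_uses_all_points(self):
        t = tuple(range(11))
        od = tuple(0.02 + 0.05 * x for x in t)
        curve = GrowthCurve("lin", CurveRole.PLASMA, t, od)
        assert select_linear_range(curve, CFG) == (0, 11)

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_exhaustive_enumeration_on_noisy_curves(self, seed):
        params = GrowthModelParams(lag_h=3 + seed % 4, noise_sd=0.015)
        curve = simulate_growth_curve(params, DEFAULT_TIME_GRID, seed=seed)
        assert detect_growth(curve, CFG)
        assert select_linear_range(curve, CFG) == _brute_force_window(curve, CFG)

    def test_window_always_at_least_three_points(self, noiseless_curve):
        a, b = select_linear_range(noiseless_curve, CFG)
        assert b - a >= 3


class TestFitAndInvert:
    def test_exact_line(self):
        curve = GrowthCurve("x", CurveRole.PLASMA, (5, 6, 7), (0.05, 0.15, 0.25))
        fit = fit_linear_phase(curve, (0, 3))
        assert fit.slope == pytest.approx(0.1)
        assert fit.intercept == pytest.approx(-0.45)
        assert fit.r2 == pytest.approx(1.0)

    def test_matches_normal_equations(self):
        rng = np.random.default_rng(11)
        t = np.sort(rng.uniform(0, 14, size=6))
        y = np.abs(rng.normal(0.3, 0.2, size=6))
        curve = GrowthCurve("r", CurveRole.PLASMA, tuple(t), tuple(y))
        fit = fit_linear_phase(curve, (0, 6))
        X = np.column_stack([np.ones(6), t])
        beta = np.linalg.solve(X.T @ X, X.T @ y)
        assert fit.intercept == pytest.approx(beta[0], abs=1e-10)
        assert fit.slope == pytest.approx(beta[1], abs=1e-10)

    def test_degenerate_flat_window_cannot_invert(self):
        fit = LinearFit(intercept=0.2, slope=0.0, r2=0.0, window=(0, 3))
        with pytest.raises(ValueError):
            time_to_threshold(fit, CFG)

    @pytest.mark.parametrize(
        "intercept,slope,expected",
        [(0.06, 0.03, 8.0), (-0.45, 0.1, 7.5)],
    )
    def test_inversion(self, intercept, slope, expected):
        fit = LinearFit(intercept=intercept, slope=slope, r2=1.0, window=(0, 3))
        assert time_to_threshold(fit, CFG) == pytest.approx(expected)

    def test_boundary_crossing_at_zero_rejected(self):
        fit = LinearFit(intercept=0.3, slope=0.1, r2=1.0, window=(0, 3))
        with pytest.raises(ValueError):
            time_to_threshold(fit, CFG)

    @given(
        slope1=st.floats(0.01, 0.5),
        slope2=st.floats(0.01, 0.5),
        intercept=st.floats(-0.5, 0.29),
    )
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_crossing_time_decreases_with_slope(self, slope1, slope2, intercept):
        lo, hi = sorted((slope1, slope2))
        if hi - lo < 1e-6:
            return
        f = lambda s: time_to_threshold(
            LinearFit(intercept=intercept, slope=s, r2=1.0, window=(0, 3)), CFG
        )
        assert f(hi) < f(lo)


class TestScoreBka:
    def test_flat_curve_censored_at_15h(self, flat_curve):
        res = score_bka(flat_curve, CFG)
        assert res.censored and not res.grew
        assert res.t_threshold == 15.0
        assert res.ln_t == pytest.approx(math.log(15.0))
        assert res.killing_class is KillingClass.ABSOLUTE_KILLING

    def test_noiseless_curve_recovers_true_crossing(self, noiseless_curve):
        res = score_bka(noiseless_curve, CFG)
        assert res.t_threshold == pytest.approx(7.5, abs=1e-6)
        assert res.ln_t == pytest.approx(math.log(7.5), abs=1e-6)

    def test_ln_transform_preserves_ranking(self):
        rng = np.random.default_rng(5)
        curves = [
            simulate_growth_curve(
                GrowthModelParams(lag_h=lag, noise_sd=0.01), DEFAULT_TIME_GRID, seed=i
            )
            for i, lag in enumerate(rng.uniform(1, 8, size=10))
        ]
        results = [score_bka(c, CFG) for c in curves]
        by_t = sorted(results, key=lambda r: r.t_threshold)
        by_ln = sorted(results, key=lambda r: r.ln_t)
        assert [r.sample_id for r in by_t] == [r.sample_id for r in by_ln]

    def test_replicates_averaged_on_hours_scale(self, noiseless_curve):
        r1 = score_bka(noiseless_curve, CFG)
        slower = simulate_growth_curve(
            GrowthModelParams(lag_h=7.0), DEFAULT_TIME_GRID, seed=0
        )
        r2 = score_bka(slower, CFG)
        merged = average_replicates([r1, r2], CFG)
        assert merged.t_threshold == pytest.approx((r1.t_threshold + r2.t_threshold) / 2)
        assert merged.ln_t == pytest.approx(math.log(merged.t_threshold))


class TestControlsAndClasses:
    @staticmethod
    def _control(lag, seed):
        # noiseless, rate 0.1 from baseline 0.05: crossing = lag + 2.5 h
        return simulate_growth_curve(
            GrowthModelParams(lag_h=lag), DEFAULT_TIME_GRID, seed=seed, role=CurveRole.CONTROL
        )

    def test_baseline_is_mean_of_crossings(self):
        # noiseless controls with lags 2.5, 3.5, 3.5, 4.5 cross at 5, 6, 6, 7 h
        controls = [self._control(lag, i) for i, lag in enumerate((2.5, 3.5, 3.5, 4.5))]
        assert control_baseline(controls, CFG) == pytest.approx(6.0, abs=1e-9)

    def test_identical_controls(self):
        controls = [self._control(3.5, i) for i in range(4)]
        assert control_baseline(controls, CFG) == pytest.approx(6.0, abs=1e-9)

    def test_censored_control_rejected(self, flat_curve):
        with pytest.raises(ValueError, match="failed to grow"):
            control_baseline([flat_curve] * 4, CFG)

    def test_unexpected_control_count_warns_but_works(self, caplog):
        controls = [self._control(3.5, i) for i in range(3)]
        with caplog.at_level("WARNING"):
            baseline = control_baseline(controls, CFG)
        assert baseline == pytest.approx(6.0, abs=1e-9)
        assert any("expected 4" in r.message for r in caplog.records)

    def test_class_boundaries(self, flat_curve, noiseless_curve):
        censored = score_bka(flat_curve, CFG)
        assert classify_killing(censored, 6.0) is KillingClass.ABSOLUTE_KILLING
        grew = score_bka(noiseless_curve, CFG)  # crosses at 7.5
        assert classify_killing(grew, 7.5) is KillingClass.NO_KILLING  # tie -> no killing
        assert classify_killing(grew, 4.5) is KillingClass.INTERMEDIATE_KILLING

    def test_classes_partition_cohort(self, small_cohort):
        from nabassay.pipeline import score_growth_stage

        table, _ = score_growth_stage(small_cohort.curves, CFG)
        plasma = table[table["role"] == "plasma"]
        counts = plasma["killing_class"].value_counts()
        assert counts.sum() == len(plasma)
        assert set(counts.index) <= {k.value for k in KillingClass}
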