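"""ELISA aggregation, background rank tests, competition, standard curve."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from nabassay.elisa import (
    ElisaPlate,
    WellInfo,
    WellRole,
    aggregate_replicates,
    compare_to_background,
    competition_reduction,
    fit_standard_curve,
    interpolate,
    mann_whitney_exact,
    _four_pl,
)


def _plate(assignments):
    """Build a plate from {well: (role, sample_id, value, ...)} tuples."""
    wells = np.zeros((8, 12))
    layout = {}
    rows = "ABCDEFGH"
    for well, (role, sid, value) in assignments.items():
        r, c = rows.index(well[0]), int(well[1:]) - 1
        wells[r, c] = value
        layout[well] = WellInfo(role=role, sample_id=sid, replicate=c)
    return ElisaPlate(wells=wells, layout=layout)


class TestAggregate:
    def test_identical_replicates(self):
        plate = _plate({f"A{i}": (WellRole.SAMPLE, "s1", 0.4) for i in (1, 2, 3)})
        res = aggregate_replicates(plate, "s1")
        assert res.mean_a450 == pytest.approx(0.4)
        assert res.sd_a450 == pytest.approx(0.0, abs=1e-12)
        assert res.n_replicates == 3

    def test_duplicate_se_hand_computed(self):
        plate = _plate({"A1": (WellRole.SAMPLE, "s1", 0.3), "A2": (WellRole.SAMPLE, "s1", 0.5)})
        res = aggregate_replicates(plate, "s1")
        assert res.mean_a450 == pytest.approx(0.4)
        # sd of (0.3, 0.5) is 0.1*sqrt(2); se = sd/sqrt(2) = 0.1
        assert res.se_a450 == pytest.approx(0.1)

    def test_well_order_invariance(self):
        vals = [0.31, 0.52, 0.44]
        a = _plate({f"A{i+1}": (WellRole.SAMPLE, "s", v) for i, v in enumerate(vals)})
        b = _plate({f"A{i+1}": (WellRole.SAMPLE, "s", v) for i, v in enumerate(reversed(vals))})
        ra, rb = aggregate_replicates(a, "s"), aggregate_replicates(b, "s")
        assert (ra.mean_a450, ra.sd_a450) == (rb.mean_a450, rb.sd_a450)

    def test_missing_sample_and_single_replicate_rejected(self):
        plate = _plate({"A1": (WellRole.SAMPLE, "s1", 0.4), "A2": (WellRole.SAMPLE, "s1", 0.4)})
        with pytest.raises(KeyError):
            aggregate_replicates(plate, "nope")
        with pytest.raises(ValueError, match="replicate"):
            _plate({"A1": (WellRole.SAMPLE, "solo", 0.4)})


def _permutation_oracle(x, y):
    """Label-permutation p-value from rank sums (independent recount)."""
    pooled = np.concatenate([x, y])
    n = len(x)
    ranks = sps.rankdata(pooled)
    mu = n * (len(pooled) + 1) / 2.0
    obs = abs(ranks[:n].sum() - mu)
    hits = total = 0
    for comb in itertools.combinations(range(len(pooled)), n):
        total += 1
        if abs(ranks[list(comb)].sum() - mu) >= obs - 1e-12:
            hits += 1
    return hits / total


class TestRankTest:
    def test_identical_groups_p_is_one(self):
        p, sig = compare_to_background([0.1, 0.1, 0.1], [0.1, 0.1, 0.1])
        assert p == 1.0 and not sig

    @pytest.mark.parametrize(
        "x,y",
        [
            ((0.9, 0.8, 0.85), (0.1, 0.12, 0.11)),
            ((0.4, 0.5, 0.4, 0.6), (0.45, 0.3, 0.35)),
            ((0.2, 0.2, 0.3, 0.5, 0.4), (0.2, 0.25, 0.3)),  # with ties
            ((1.0, 0.9), (0.1, 0.2, 0.3, 0.15, 0.25, 0.12, 0.18, 0.22)),
        ],
    )
    def test_exact_p_matches_permutation_enumeration(self, x, y):
        p, _ = compare_to_background(x, y)
        assert p == pytest.approx(_permutation_oracle(np.array(x), np.array(y)), abs=1e-12)

    @pytest.mark.parametrize("n,m", [(3, 3), (4, 5), (6, 4), (8, 8)])
    def test_tie_free_exact_matches_scipy(self, n, m):
        rng = np.random.default_rng(n * 10 + m)
        x, y = rng.normal(0.5, 0.2, n), rng.normal(0.3, 0.2, m)
        p = mann_whitney_exact(x, y)
        ref = sps.mannwhitneyu(x, y, alternative="two-sided", method="exact").pvalue
        assert p == pytest.approx(float(ref), abs=1e-12)

    def test_strong_separation_significant_at_bonferroni_level(self):
        # triplicate sample vs nine background wells: the exact two-sided
        # floor is 2/C(12,3) ~ 0.009, below the corrected level
        backgrounds = (0.1, 0.12, 0.11, 0.09, 0.13, 0.1, 0.08, 0.11, 0.12)
        p, sig = compare_to_background((0.9, 0.8, 0.85), backgrounds, alpha=0.05 / 3)
        assert sig and p < 0.017

    def test_large_groups_use_normal_approximation(self):
        rng = np.random.default_rng(0)
        x, y = rng.normal(0.6, 0.1, 12), rng.normal(0.4, 0.1, 12)
        p, _ = compare_to_background(x, y)
        ref = sps.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic").pvalue
        assert p == pytest.approx(float(ref))


class TestCompetition:
    def test_point_values(self):
        assert competition_reduction(0.5, 0.5) == 0.0
        assert competition_reduction(0.8, 0.4) == pytest.approx(0.5)
        with pytest.raises(ValueError):
            competition_reduction(0.0, 0.1)

    @given(
        u=st.floats(0.05, 3.0),
        c=st.floats(0.0, 3.0),
        scale=st.floats(0.1, 10.0),
    )
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_scale_invariance(self, u, c, scale):
        assert competition_reduction(u * scale, c * scale) == pytest.approx(
            competition_reduction(u, c), abs=1e-9
        )

    def test_generator_reduction_recovered(self, small_cohort):
        from nabassay.pipeline import elisa_stage
        from nabassay.bka import AssayConfig

        out = elisa_stage(small_cohort.plates, AssayConfig())
        comp = out["competition"].set_index("sample_id")["reduction"]
        for sid, true_r in small_cohort.truth["competition_reductions"].items():
            assert comp[sid] == pytest.approx(true_r, abs=0.15)


class TestStandardCurve:
    TRUE = (0.05, 1.2, 300.0, 2.8)

    def _standards(self, noise=0.0, seed=0):
        rng = np.random.default_rng(seed)
        concs = [20.0 * 2**i for i in range(8)]
        return [(c, float(_four_pl(np.array([c]), *self.TRUE)[0] + rng.normal(0, noise))) for c in concs]

    def test_noiseless_parameter_recovery(self):
        curve = fit_standard_curve(self._standards())
        for fitted, true in zip(curve.params, self.TRUE):
            assert fitted == pytest.approx(true, rel=1e-6)

    def test_round_trip_through_interpolation(self):
        standards = self._standards()
        curve = fit_standard_curve(standards)
        for conc, od in standards:
            res = interpolate(curve, od)
            assert res.in_range
            assert res.concentration == pytest.approx(conc, rel=1e-6)

    def test_query_outside_standard_range_flagged(self):
        curve = fit_standard_curve(self._standards())
        assert not interpolate(curve, 2.95).in_range
        assert not interpolate(curve, 0.01).in_range

    def test_too_few_or_non_monotone_standards_rejected(self):
        with pytest.raises(ValueError, match=">=4"):
            fit_standard_curve([(10, 0.1), (20, 0.2), (40, 0.4)])
        bad = [(10, 0.1), (20, 0.5), (40, 0.3), (80, 0.9)]
        with pytest.raises(ValueError, match="monotone"):
            fit_standard_curve(bad)
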