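"""Scoring rules, learning curves, paired statistics, psychoacoustics."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from cifit.outcomes import (
    FLAG_ASSIGNED,
    FLAG_INVALID,
    FLAG_MEASURED,
    FLAG_MISSING,
    FLAG_TOO_DIFFICULT,
    LoudnessSurface,
    VisitSeries,
    acalos_auc,
    apply_score_rules,
    curve_params,
    effort_levels,
    holm_bonferroni,
    learning_curve,
    paired_compare,
    preference_proportion,
    series_from_frame,
    smrt_staircase,
)


def _visit(measure, week, value, flag=FLAG_MEASURED, fitting="test", **extra):
    row = dict(subject_id="S01", fitting=fitting, measure=measure,
               visit_week=week, value=value, flag=flag)
    row.update(extra)
    return row


class TestScoreRules:
    def test_low_quiet_score_gates_srt_to_assignment(self):
        df = pd.DataFrame([
            _visit("quiet", 4, 45.0),
            _visit("srt", 4, np.nan, FLAG_MISSING, level_min=-20.0, level_max=20.0),
        ])
        out = apply_score_rules(df)
        srt = out[out["measure"] == "srt"].iloc[0]
        assert (srt["value"], srt["flag"]) == (15.0, FLAG_ASSIGNED)

    def test_too_difficult_quiet_scores_guessing_floor(self):
        df = pd.DataFrame([_visit("quiet", 1, np.nan, FLAG_TOO_DIFFICULT)])
        out = apply_score_rules(df)
        assert out.iloc[0]["value"] == 20.0

    def test_measured_srt_above_ceiling_excluded(self):
        df = pd.DataFrame([
            _visit("quiet", 6, 72.0),
            _visit("srt", 6, 16.2, level_min=-20.0, level_max=20.0),
        ])
        out = apply_score_rules(df)
        assert out[out["measure"] == "srt"].iloc[0]["flag"] == FLAG_INVALID

    def test_srt_outside_presented_range_excluded(self):
        df = pd.DataFrame([
            _visit("quiet", 6, 72.0),
            _visit("srt", 6, 10.0, level_min=-5.0, level_max=5.0),
        ])
        out = apply_score_rules(df)
        assert out[out["measure"] == "srt"].iloc[0]["flag"] == FLAG_INVALID

    def test_valid_srt_passes_through(self):
        df = pd.DataFrame([
            _visit("quiet", 6, 72.0),
            _visit("srt", 6, 4.5, level_min=-20.0, level_max=20.0),
        ])
        out = apply_score_rules(df)
        srt = out[out["measure"] == "srt"].iloc[0]
        assert (srt["value"], srt["flag"]) == (4.5, FLAG_MEASURED)

    def test_cnc_visit_is_mean_of_test_and_retest(self):
        df = pd.DataFrame([_visit("cnc", 2, 40.0), _visit("cnc", 2, 50.0)])
        out = apply_score_rules(df)
        assert len(out) == 1
        assert out.iloc[0]["value"] == 45.0

    def test_idempotent(self):
        rng = np.random.default_rng(0)
        rows = []
        for week in (0, 2, 4, 6):
            rows.append(_visit("cnc", week, rng.uniform(0, 60)))
            rows.append(_visit("cnc", week, rng.uniform(0, 60)))
            q = rng.uniform(10, 90)
            rows.append(
                _visit("quiet", week, np.nan, FLAG_TOO_DIFFICULT)
                if q < 25 else _visit("quiet", week, q)
            )
            rows.append(
                _visit("srt", week, rng.uniform(0, 18),
                       level_min=-20.0, level_max=20.0)
            )
        once = apply_score_rules(pd.DataFrame(rows))
        twice = apply_score_rules(once)
        pd.testing.assert_frame_equal(
            once.reset_index(drop=True), twice.reset_index(drop=True),
            check_dtype=False,
        )

    def test_unknown_measure_rejected(self):
        with pytest.raises(ValueError, match="unknown measure"):
            apply_score_rules(pd.DataFrame([_visit("telepathy", 0, 1.0)]))


class TestLearningCurve:
    def _series(self, pairs):
        days, values = zip(*pairs)
        return VisitSeries("S01", "test", "cnc", days, values)

    def test_linear_midpoint(self):
        curve = learning_curve(self._series([(0, 10.0), (84, 94.0)]))
        assert curve[42] == pytest.approx(52.0)

    def test_constant_curve(self):
        curve = learning_curve(self._series([(0, 30.0), (28, 30.0), (84, 30.0)]))
        assert np.all(curve == 30.0)

    def test_interior_missing_bridged_linearly(self):
        curve = learning_curve(
            self._series([(0, 0.0), (28, 28.0), (42, np.nan), (56, 56.0)])
        )
        assert curve[42] == pytest.approx(42.0)

    def test_boundary_missing_carried_flat(self):
        curve = learning_curve(
            self._series([(0, np.nan), (14, 20.0), (70, 60.0), (84, np.nan)])
        )
        assert curve[0] == 20.0 and curve[84] == 60.0

    def test_exact_at_knots(self):
        pairs = [(0, 5.0), (7, 12.0), (28, 44.0), (84, 71.0)]
        curve = learning_curve(self._series(pairs))
        for d, v in pairs:
            assert curve[d] == pytest.approx(v)

    def test_fewer_than_two_visits_rejected(self):
        with pytest.raises(ValueError, match="2 non-missing"):
            learning_curve(self._series([(0, 10.0), (84, np.nan)]))


class TestCurveParams:
    def test_constant_curve(self):
        p = curve_params(np.full(85, 50.0))
        assert (p.begin, p.end, p.auc, p.learning_rate) == (50.0, 50.0, 4200.0, 0.0)

    def test_linear_ramp(self):
        p = curve_params(np.linspace(0, 84, 85))
        assert p.auc == pytest.approx(3528.0)
        assert p.learning_rate == pytest.approx(1.0)

    def test_auc_equals_trapezoid_on_knots(self):
        days = np.array([0, 7, 21, 56, 84], float)
        vals = np.array([4.0, 18.0, 30.0, 55.0, 60.0])
        curve = learning_curve(VisitSeries("s", "test", "cnc", tuple(days), tuple(vals)))
        assert curve_params(curve).auc == pytest.approx(np.trapezoid(vals, days))


def exact_signed_rank_p(diffs):
    """Oracle: two-sided p by enumerating all 2^n sign assignments."""
    d = np.asarray(diffs, float)
    d = d[d != 0]
    ranks = stats.rankdata(np.abs(d))
    w_obs = ranks[d > 0].sum()
    n = len(d)
    stat = min(w_obs, n * (n + 1) / 2 - w_obs)
    count = 0
    for signs in itertools.product([0, 1], repeat=n):
        w = ranks[np.array(signs, bool)].sum()
        if min(w, n * (n + 1) / 2 - w) <= stat + 1e-12:
            count += 1
    return count / 2**n


class TestPairedCompare:
    def test_identical_arms_give_p_one(self):
        with pytest.warns(UserWarning, match="zero"):
            res = paired_compare([1, 2, 3, 4, 5], [1, 2, 3, 4, 5], n_boot=100, seed=0)
        assert res.p_value == 1.0

    def test_all_positive_differences_exact_p(self):
        res = paired_compare([2, 4, 6, 8, 10], [1, 2, 3, 4, 5], n_boot=100, seed=0)
        assert res.p_value == pytest.approx(0.0625)

    def test_sign_symmetry(self):
        rng = np.random.default_rng(1)
        a, b = rng.normal(0, 1, 10), rng.normal(0, 1, 10)
        r1 = paired_compare(a, b, n_boot=200, seed=0)
        r2 = paired_compare(b, a, n_boot=200, seed=0)
        assert r1.p_value == pytest.approx(r2.p_value)
        assert r1.median_difference == pytest.approx(-r2.median_difference)

    @pytest.mark.parametrize("n", [6, 9, 12])
    def test_matches_sign_flip_enumeration(self, n):
        rng = np.random.default_rng(n)
        for _ in range(5):
            d = rng.normal(0.4, 1.0, n)
            res = paired_compare(d + 1.0, np.ones(n), n_boot=50, seed=0)
            assert res.p_value == pytest.approx(exact_signed_rank_p(d), abs=1e-12)

    def test_bootstrap_ci_brackets_median_difference(self):
        rng = np.random.default_rng(5)
        a = rng.normal(10, 2, 20)
        b = rng.normal(8, 2, 20)
        res = paired_compare(a, b, n_boot=4000, seed=7)
        assert res.ci95_low <= res.median_difference <= res.ci95_high

    def test_bootstrap_reproducible(self):
        a, b = [1, 3, 2, 5, 4, 7], [0, 1, 1, 2, 2, 3]
        r1 = paired_compare(a, b, n_boot=500, seed=11)
        r2 = paired_compare(a, b, n_boot=500, seed=11)
        assert (r1.ci95_low, r1.ci95_high) == (r2.ci95_low, r2.ci95_high)


class TestHolmBonferroni:
    def test_single_p_unchanged(self):
        adj, rej = holm_bonferroni([0.03])
        assert adj[0] == pytest.approx(0.03) and rej[0]

    def test_step_down_worked_example(self):
        adj, rej = holm_bonferroni([0.01, 0.04])
        assert adj == pytest.approx([0.02, 0.04])
        assert rej.all()

    def test_stopping_rule_retains_both(self):
        adj, rej = holm_bonferroni([0.03, 0.04])
        assert not rej.any()
        assert adj == pytest.approx([0.06, 0.06])

    def test_bounded_between_raw_and_bonferroni(self):
        rng = np.random.default_rng(2)
        for _ in range(20):
            p = rng.uniform(0, 1, rng.integers(2, 8))
            adj, _ = holm_bonferroni(p)
            assert np.all(adj >= p - 1e-15)
            assert np.all(adj <= np.minimum(p * len(p), 1.0) + 1e-15)
            order = np.argsort(p)
            assert np.all(np.diff(adj[order]) >= -1e-15)  # monotone in rank

    def test_invalid_p_rejected(self):
        with pytest.raises(ValueError):
            holm_bonferroni([0.5, 1.2])


class TestPsychoacoustics:
    def test_effort_levels_centered_on_srt(self):
        assert effort_levels(0.0) == pytest.approx([-6, -3, 0, 3, 6, 9])
        levels = effort_levels(1.9)
        assert levels[0] == pytest.approx(-4.1)
        assert levels[-1] == pytest.approx(10.9)
        assert np.diff(levels) == pytest.approx([3.0] * 5)

    def _flat_surface(self, loudness):
        levels = np.array([0.0, 50.0, 105.0])
        return LoudnessSurface(
            {f: (levels, np.full(3, loudness)) for f in (250, 500, 1000, 2000, 4000)}
        )

    def test_constant_loudness_rectangle_auc(self):
        overall, per = acalos_auc(self._flat_surface(25.0))
        assert per[1000] == pytest.approx(2625.0)
        assert overall == pytest.approx(17 * 2625.0)  # 17-point frequency grid

    def test_zero_loudness_zero_auc(self):
        overall, per = acalos_auc(self._flat_surface(0.0))
        assert overall == 0.0 and all(v == 0.0 for v in per.values())

    def test_auc_linear_in_loudness(self):
        o1, p1 = acalos_auc(self._flat_surface(10.0))
        o2, p2 = acalos_auc(self._flat_surface(20.0))
        assert o2 == pytest.approx(2 * o1)
        assert all(p2[f] == pytest.approx(2 * p1[f]) for f in p1)

    def test_non_monotone_levels_rejected(self):
        surface = LoudnessSurface(
            {250: (np.array([0.0, 50.0, 40.0]), np.array([0.0, 20.0, 30.0]))}
        )
        with pytest.raises(ValueError, match="strictly increase"):
            acalos_auc(surface)

    def test_staircase_converges_to_oracle_threshold(self):
        thr = smrt_staircase(lambda v, rng: v < 3.0, seed=0)
        assert thr == pytest.approx(3.0, abs=0.2)

    def test_staircase_pinned_at_floor(self):
        assert smrt_staircase(lambda v, rng: False, seed=0) == 0.5

    def test_staircase_deterministic_with_seed(self):
        def lapse(v, rng):
            return rng.random() < (0.95 if v < 2.5 else 0.05)

        assert smrt_staircase(lapse, seed=4) == smrt_staircase(lapse, seed=4)


class TestPreference:
    def test_two_of_fourteen(self):
        pct, lo, hi = preference_proportion(2, 14)
        assert pct == pytest.approx(14.3, abs=0.05)
        assert lo == pytest.approx(0.018, abs=0.005)
        assert hi == pytest.approx(0.43, abs=0.02)

    def test_bounds(self):
        with pytest.raises(ValueError):
            preference_proportion(5, 4)


class TestSeriesExtraction:
    def test_invalid_flagged_visits_become_missing(self):
        df = pd.DataFrame([
            _visit("srt", 0, 15.0, FLAG_ASSIGNED),
            _visit("srt", 4, 16.2, FLAG_INVALID),
            _visit("srt", 8, 5.0),
        ])
        s = series_from_frame(df, "S01", "test", "srt")
        assert s.days == (0, 28, 56)
        assert np.isnan(s.values[1])
        assert s.values[0] == 15.0 and s.values[2] == 5.0
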