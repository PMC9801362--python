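import numpy as np
import pytest

from lipedex.roc import (
    DegenerateCurveError,
    RocSummary,
    auc,
    auc_ci_delong,
    binormal_auc,
    empirical_roc,
    roc_battery,
    summarize_index,
    youden_j,
    youden_optimal,
)


def brute_force_points(case, ctrl, thresholds, higher_is_case=True):
    """Confusion-matrix enumeration at every threshold."""
    points = []
    for t in thresholds:
        if higher_is_case:
            tp = np.sum(case >= t)
            tn = np.sum(ctrl < t)
        else:
            tp = np.sum(case <= t)
            tn = np.sum(ctrl > t)
        points.append((tp / len(case), tn / len(ctrl)))
    return points


def brute_force_u(case, ctrl):
    """Pairwise-comparison U with ties half-counted."""
    wins = sum((c > k) + 0.5 * (c == k) for c in case for k in ctrl)
    return wins / (len(case) * len(ctrl))


class TestEmpiricalRoc:
    def test_perfect_separation(self):
        curve = empirical_roc([0.5, 0.6, 0.7], [0.3, 0.4, 0.45])
        assert auc(curve) == pytest.approx(1.0)

    def test_identical_multisets(self):
        scores = [0.1, 0.2, 0.3, 0.3, 0.5]
        curve = empirical_roc(scores, scores)
        assert auc(curve) == pytest.approx(0.5)

    def test_degenerate_scores(self):
        with pytest.raises(DegenerateCurveError):
            empirical_roc([1.0, 1.0], [1.0, 1.0, 1.0])

    def test_curve_hits_both_corners(self):
        rng = np.random.default_rng(0)
        curve = empirical_roc(rng.normal(1, 1, 30), rng.normal(0, 1, 30))
        x = 1 - curve.specificity
        assert (x[0], curve.sensitivity[0]) == (1.0, 1.0)
        assert (x[-1], curve.sensitivity[-1]) == (0.0, 0.0)

    def test_matches_brute_force_enumeration(self):
        rng = np.random.default_rng(1)
        case = rng.normal(1, 1, 12)
        ctrl = rng.normal(0, 1, 15)
        curve = empirical_roc(case, ctrl)
        assert curve.orientation == "higher-is-case"
        finite = np.isfinite(curve.thresholds)
        expected = brute_force_points(case, ctrl, curve.thresholds[finite])
        for (sens, spec), i in zip(expected, np.flatnonzero(finite)):
            assert curve.sensitivity[i] == pytest.approx(sens, abs=1e-12)
            assert curve.specificity[i] == pytest.approx(spec, abs=1e-12)

    def test_orientation_flip_for_lower_scores_in_cases(self):
        rng = np.random.default_rng(2)
        case = rng.normal(0, 1, 40)
        ctrl = rng.normal(1, 1, 40)
        curve = empirical_roc(case, ctrl)
        assert curve.orientation == "lower-is-case"
        assert auc(curve) > 0.5


class TestAuc:
    def test_equals_normalized_u(self):
        rng = np.random.default_rng(3)
        for _ in range(25):
            case = np.round(rng.normal(1, 1, 30), 1)  # rounding forces ties
            ctrl = np.round(rng.normal(0, 1, 30), 1)
            a = auc(empirical_roc(case, ctrl))
            u = brute_force_u(case, ctrl)
            assert a == pytest.approx(max(u, 1 - u), abs=1e-12)

    def test_flip_symmetry(self):
        rng = np.random.default_rng(4)
        case = rng.normal(1, 1, 25)
        ctrl = rng.normal(0, 1, 25)
        a = auc(empirical_roc(case, ctrl))
        flipped = auc(empirical_roc(-case, -ctrl))
        assert a == pytest.approx(flipped, abs=1e-12)

    def test_shift_monotonicity(self):
        rng = np.random.default_rng(5)
        case = rng.normal(0.5, 1, 40)
        ctrl = rng.normal(0.0, 1, 40)
        base = auc(empirical_roc(case, ctrl))
        shifted = auc(empirical_roc(case + 0.5, ctrl))
        assert shifted >= base - 1e-12


class TestDelongCi:
    def test_perfect_separation_upper_bound_one(self):
        lo, hi = auc_ci_delong(np.arange(10, 20.0), np.arange(0, 10.0))
        assert hi == 1.0
        assert lo == pytest.approx(1.0)

    def test_width_at_study_scale(self):
        rng = np.random.default_rng(6)
        case = rng.normal(0.451, 0.050, 74)
        ctrl = rng.normal(0.354, 0.055, 148)
        lo, hi = auc_ci_delong(case, ctrl)
        assert 0.04 < hi - lo < 0.13  # published interval spans 0.86-0.94

    def test_interval_contains_point_estimate(self):
        rng = np.random.default_rng(7)
        case = rng.normal(1, 1, 30)
        ctrl = rng.normal(0, 1, 60)
        lo, hi = auc_ci_delong(case, ctrl)
        a = auc(empirical_roc(case, ctrl))
        assert lo <= a <= hi

    def test_needs_two_per_group(self):
        with pytest.raises(ValueError):
            auc_ci_delong([1.0], [0.0, 0.5])


class TestYouden:
    def test_j_identity(self):
        assert round(youden_j(0.95, 0.73), 2) == 0.68

    def test_perfect_separation_toy(self):
        curve = empirical_roc([0.5, 0.6, 0.7], [0.3, 0.4, 0.45])
        cutoff, sens, spec, j = youden_optimal(curve)
        assert j == pytest.approx(1.0)
        assert cutoff == pytest.approx(0.475)
        assert sens == 1.0 and spec == 1.0

    def test_matches_exhaustive_scan(self):
        rng = np.random.default_rng(8)
        for _ in range(30):
            case = np.round(rng.normal(0.6, 0.2, 20), 2)
            ctrl = np.round(rng.normal(0.4, 0.2, 20), 2)
            curve = empirical_roc(case, ctrl)
            cutoff, sens, spec, j = youden_optimal(curve)
            best_j = max(curve.sensitivity + curve.specificity - 1.0)
            assert j == pytest.approx(best_j, abs=1e-12)

    def test_tie_break_prefers_sensitivity(self):
        # two thresholds reach the same J; pick the more sensitive one
        curve = empirical_roc([1.0, 3.0], [2.0, 4.0])
        cutoff, sens, spec, j = youden_optimal(curve)
        best_j = max(curve.sensitivity + curve.specificity - 1.0)
        candidates = [
            (s, c) for c, s, p in zip(curve.thresholds, curve.sensitivity, curve.specificity)
            if s + p - 1.0 == pytest.approx(best_j, abs=1e-12)
        ]
        assert sens == max(s for s, _ in candidates)


class TestBinormal:
    def test_leg_share_parameters(self):
        assert binormal_auc(0.451, 0.050, 0.354, 0.055) == pytest.approx(0.9041, abs=5e-4)

    def test_equal_means(self):
        assert binormal_auc(1.0, 0.5, 1.0, 0.7) == 0.5

    def test_legs_arms_parameters(self):
        assert binormal_auc(0.556, 0.047, 0.462, 0.054) == pytest.approx(0.9054, abs=5e-4)

    def test_orientation_symmetry(self):
        assert binormal_auc(0.3, 0.1, 0.5, 0.1) == binormal_auc(0.5, 0.1, 0.3, 0.1)

    def test_nonpositive_sd_rejected(self):
        with pytest.raises(ValueError):
            binormal_auc(1.0, 0.0, 0.0, 1.0)

    def test_empirical_converges_to_binormal(self):
        rng = np.random.default_rng(9)
        case = rng.normal(0.451, 0.050, 100_000)
        ctrl = rng.normal(0.354, 0.055, 100_000)
        a = auc(empirical_roc(case, ctrl))
        assert a == pytest.approx(binormal_auc(0.451, 0.050, 0.354, 0.055), abs=0.005)


class TestRocBattery:
    def test_top_indices(self, matched, battery):
        summaries = roc_battery(matched, battery)
        top3 = {s.index for s in summaries[:3]}
        assert top3 == {"fm_share_legs", "fm_share_legs_arms", "trunk_legs_fm_ratio"}

    def test_arm_indices_absent(self, matched, battery):
        summaries = roc_battery(matched, battery)
        names = {s.index for s in summaries}
        assert "fm_share_arms" not in names
        assert "fm_fmi_arms" not in names

    def test_only_fm_indices_and_ranked(self, matched, battery):
        summaries = roc_battery(matched, battery)
        aucs = [s.auc for s in summaries]
        assert aucs == sorted(aucs, reverse=True)
        assert all(s.auc >= 0.5 for s in summaries)
        assert all(not s.index.startswith("lm_") and s.index != "almi" for s in summaries)

    def test_trunk_indices_flip_orientation(self, matched, battery):
        summaries = roc_battery(matched, battery)
        by_name = {s.index: s for s in summaries}
        assert by_name["trunk_legs_fm_ratio"].orientation == "lower-is-case"
        assert by_name["fm_share_legs"].orientation == "higher-is-case"

    def test_empty_results_give_empty_battery(self, matched):
        assert roc_battery(matched, []) == []

    def test_summary_invariants(self, matched, battery):
        for s in roc_battery(matched, battery):
            assert s.ci_low <= s.auc <= s.ci_high
            assert s.youden_j == pytest.approx(s.sensitivity + s.specificity - 1)


def test_summarize_index_smoke():
    rng = np.random.default_rng(10)
    s = summarize_index(rng.normal(1, 1, 50), rng.normal(0, 1, 50), index="toy")
    assert isinstance(s, RocSummary)
    assert 0.5 <= s.auc <= 1.0
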