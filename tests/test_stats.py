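import numpy as np
import pytest

from lipedex.composition import PANEL_INDEX_NAMES
from lipedex.matching import MatchedCohort
from lipedex.stats import (
    ComparisonResult,
    CorrelationResult,
    InsufficientDataError,
    assess_normality,
    bonferroni_threshold,
    compare_multi_groups,
    compare_two_groups,
    correlate_index_with_stage,
    run_comparison_battery,
)


class TestAssessNormality:
    def test_gaussian_accepted_most_seeds(self):
        # Shapiro-Wilk type-I error ~5% at alpha 0.05
        normal = sum(
            assess_normality(np.random.default_rng(seed).normal(size=500)).normal
            for seed in range(100)
        )
        assert normal >= 90

    def test_lognormal_rejected(self):
        x = np.exp(np.random.default_rng(0).normal(0, 1.5, size=500))
        assert not assess_normality(x).normal

    def test_constant_sample_degenerate(self):
        decision = assess_normality(np.ones(20))
        assert decision.degenerate
        assert not decision.normal

    def test_small_sample_rejected(self):
        with pytest.raises(InsufficientDataError):
            assess_normality([1.0, 2.0])

    def test_any_group_failing_flips_decision(self):
        rng = np.random.default_rng(1)
        gaussian = rng.normal(size=300)
        skewed = np.exp(rng.normal(0, 1.5, size=300))
        assert assess_normality(gaussian, gaussian).normal
        assert not assess_normality(gaussian, skewed).normal


class TestCompareTwoGroups:
    def test_identical_samples(self):
        x = np.random.default_rng(0).normal(size=50)
        result = compare_two_groups(x, x.copy())
        assert result.statistic == pytest.approx(0.0, abs=1e-12)
        assert result.p_value == pytest.approx(1.0)
        assert not result.significant

    def test_leg_share_strongly_significant(self, matched):
        results = run_comparison_battery(matched)
        leg = next(r for r in results if r.index == "fm_share_legs")
        assert leg.p_value < 0.05 / 27
        assert leg.significant

    def test_arm_share_not_significant(self, matched):
        results = run_comparison_battery(matched)
        arm = next(r for r in results if r.index == "fm_share_arms")
        assert arm.p_value > 0.05 / 27
        assert not arm.significant

    def test_routing_recorded(self):
        rng = np.random.default_rng(3)
        gaussian = compare_two_groups(rng.normal(size=100), rng.normal(size=100))
        assert gaussian.test == "t"
        skewed = compare_two_groups(
            np.exp(rng.normal(0, 1.5, size=100)), np.exp(rng.normal(0, 1.5, size=100))
        )
        assert skewed.test == "mann-whitney"

    def test_small_samples_rejected(self):
        with pytest.raises(InsufficientDataError):
            compare_two_groups([1.0, 2.0], [3.0, 4.0, 5.0])

    def test_flag_threshold_consistency_enforced(self):
        with pytest.raises(ValueError):
            ComparisonResult(
                index="x", group_means={}, group_sds={}, group_ns={},
                test="t", statistic=1.0, p_value=0.5, threshold=0.05, significant=True,
            )


class TestCompareMultiGroups:
    def test_identical_groups(self):
        x = np.random.default_rng(0).normal(size=30)
        result = compare_multi_groups({"a": x, "b": x.copy(), "c": x.copy()})
        assert result.statistic == pytest.approx(0.0, abs=1e-12)
        assert result.p_value == pytest.approx(1.0)

    def test_one_shifted_group_flagged_by_tukey(self):
        rng = np.random.default_rng(0)
        groups = {
            "a": rng.normal(0, 1, 30),
            "b": rng.normal(0, 1, 30),
            "c": rng.normal(5, 1, 30),
        }
        result = compare_multi_groups(groups)
        assert result.test == "anova"
        assert result.p_value < 0.001
        assert result.posthoc is not None
        flagged = {(p.group_a, p.group_b) for p in result.posthoc if p.significant}
        assert flagged == {("a", "c"), ("b", "c")}

    def test_small_group_excluded(self):
        rng = np.random.default_rng(2)
        groups = {
            "a": rng.normal(0, 1, 30),
            "b": rng.normal(0, 1, 30),
            "c": rng.normal(0, 1, 30),
            "tiny": rng.normal(0, 1, 2),
        }
        result = compare_multi_groups(groups, min_group_size=5)
        assert "tiny" not in result.group_ns

    def test_too_few_groups_after_exclusion(self):
        rng = np.random.default_rng(3)
        groups = {"a": rng.normal(size=30), "b": rng.normal(size=30), "c": rng.normal(size=3)}
        with pytest.raises(InsufficientDataError):
            compare_multi_groups(groups, min_group_size=5)


class TestBonferroni:
    def test_study_threshold(self):
        threshold = bonferroni_threshold(0.05, 27)
        assert threshold == 0.05 / 27
        assert f"{threshold:.5f}" == "0.00185"

    def test_identity(self):
        assert bonferroni_threshold(0.05, 1) == 0.05

    def test_quarter(self):
        assert bonferroni_threshold(0.01, 4) == pytest.approx(0.0025)

    def test_product_recovers_alpha(self):
        for n in (1, 3, 27, 100):
            assert bonferroni_threshold(0.05, n) * n == pytest.approx(0.05, rel=1e-12)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            bonferroni_threshold(0.0, 10)
        with pytest.raises(ValueError):
            bonferroni_threshold(0.05, 0)


class TestCorrelation:
    def test_r_squared_consistency(self):
        result = CorrelationResult(index="x", method="spearman", r=0.329,
                                   r_squared=0.329**2, p_value=0.005)
        assert round(result.r_squared, 3) == 0.108

    def test_perfect_correlation(self):
        stages = np.array([1, 2, 3, 4] * 6, dtype=float)
        result = correlate_index_with_stage(stages, stages)
        assert result.r == pytest.approx(1.0)
        assert result.r_squared == pytest.approx(1.0)

    def test_null_correlation_mostly_small(self):
        hits = 0
        for seed in range(100):
            rng = np.random.default_rng(seed)
            values = rng.normal(size=72)
            stages = rng.choice([1, 2, 3, 4], size=72, p=[14 / 74, 39 / 74, 19 / 74, 2 / 74])
            result = correlate_index_with_stage(values, stages)
            hits += abs(result.r) < 0.3
        assert hits >= 95

    def test_zero_stage_variance_rejected(self):
        with pytest.raises(InsufficientDataError):
            correlate_index_with_stage([1.0, 2.0, 3.0], [2, 2, 2])

    def test_routing(self):
        rng = np.random.default_rng(5)
        stages = rng.choice([1, 2, 3], size=100).astype(float)
        gaussian = correlate_index_with_stage(rng.normal(size=100), stages)
        assert gaussian.method == "pearson"
        skewed = correlate_index_with_stage(np.exp(rng.normal(0, 2, size=100)), stages)
        assert skewed.method == "spearman"


class TestBattery:
    def test_27_rows(self, battery):
        assert len(battery) == 27
        assert [r.index for r in battery] == list(PANEL_INDEX_NAMES)

    def test_thresholds_are_bonferroni(self, battery):
        assert all(r.threshold == 0.05 / 27 for r in battery)

    def test_direction_of_effects(self, battery):
        by_name = {r.index: r for r in battery}
        # leg and gynoid fat indices higher in cases, trunk/android lower
        for name in ("fm_share_legs", "fm_share_legs_arms", "fm_share_gynoid", "fm_fmi_legs"):
            r = by_name[name]
            assert r.group_means["case"] > r.group_means["control"]
        for name in ("fm_share_trunk", "fm_share_android", "trunk_legs_fm_ratio",
                     "android_gynoid_ratio"):
            r = by_name[name]
            assert r.group_means["case"] < r.group_means["control"]

    def test_stage_stratification_with_exclusion(self, matched):
        results = run_comparison_battery(matched, stratify="stage")
        assert len(results) == 27
        tested = [r for r in results if r.test in ("anova", "kruskal-wallis")]
        assert tested, "expected at least some stage comparisons to run"
        for r in tested:
            assert all(n >= 5 for n in r.group_ns.values())

    def test_bmi_class_stratification(self, matched):
        results = run_comparison_battery(matched, stratify="bmi_class")
        strata = {r.stratum for r in results}
        assert len(results) == 27 * len(strata)

    def test_empty_cohort_rejected(self):
        with pytest.raises(ValueError):
            run_comparison_battery(MatchedCohort.from_groups([], []))
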