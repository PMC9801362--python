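"""Normality-routed comparison battery over the 27-index panel.

Test routing mirrors the study design: Shapiro-Wilk at alpha = 0.05 per
group, Student's t / one-way ANOVA when every group looks Gaussian,
Mann-Whitney / Kruskal-Wallis otherwise, Tukey HSD post hoc only after a
significant ANOVA, Pearson/Spearman for stage correlations, and a
Bonferroni threshold over the 27 panel indices.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import TYPE_CHECKING, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .composition import PANEL_INDEX_NAMES, PANEL_SIZE, compute_index_panel

if TYPE_CHECKING:  # pragma: no cover
    from .matching import MatchedCohort

__all__ = [
    "NormalityDecision",
    "ComparisonResult",
    "CorrelationResult",
    "PairwiseResult",
    "InsufficientDataError",
    "assess_normality",
    "compare_two_groups",
    "compare_multi_groups",
    "bonferroni_threshold",
    "correlate_index_with_stage",
    "run_comparison_battery",
    "panel_frame",
]

DEFAULT_ALPHA = 0.05
MIN_GROUP_SIZE = 5


class InsufficientDataError(ValueError):
    """Raised when a sample is too small (or too degenerate) to test."""


@dataclass(frozen=True)
class NormalityDecision:
    normal: bool
    p_values: tuple[float, ...]
    degenerate: bool = False


@dataclass(frozen=True)
class PairwiseResult:
    group_a: str
    group_b: str
    p_value: float
    significant: bool


@dataclass(frozen=True)
class ComparisonResult:
    index: str
    group_means: dict[str, float]
    group_sds: dict[str, float]
    group_ns: dict[str, int]
    test: str  # "t" | "mann-whitney" | "anova" | "kruskal-wallis"
    statistic: float
    p_value: float
    threshold: float
    significant: bool
    posthoc: tuple[PairwiseResult, ...] | None = None
    stratum: str | None = None

    def __post_init__(self) -> None:
        if not (np.isnan(self.p_value) or 0 <= self.p_value <= 1):
            raise ValueError(f"p value out of [0,1]: {self.p_value}")
        if not np.isnan(self.p_value) and self.significant != (self.p_value < self.threshold):
            raise ValueError("significance flag inconsistent with threshold")


@dataclass(frozen=True)
class CorrelationResult:
    index: str
    method: str  # "pearson" | "spearman"
    r: float
    r_squared: float
    p_value: float

    def __post_init__(self) -> None:
        if not -1 - 1e-12 <= self.r <= 1 + 1e-12:
            raise ValueError(f"r out of [-1,1]: {self.r}")


def assess_normality(*samples: Sequence[float], alpha: float = DEFAULT_ALPHA) -> NormalityDecision:
    """Shapiro-Wilk per sample; non-normal if any sample fails at ``alpha``.

    Constant (zero-variance) samples are reported as degenerate and
    non-normal rather than tested.
    """
    if not samples:
        raise ValueError("at least one sample required")
    p_values: list[float] = []
    degenerate = False
    for x in samples:
        x = np.asarray(x, dtype=float)
        if len(x) < 3:
            raise InsufficientDataError(f"normality assessment needs n >= 3, got {len(x)}")
        if np.ptp(x) == 0:
            degenerate = True
            p_values.append(0.0)
            continue
        p_values.append(float(sps.shapiro(x).pvalue))
    normal = (not degenerate) and all(p >= alpha for p in p_values)
    return NormalityDecision(normal=normal, p_values=tuple(p_values), degenerate=degenerate)


def _moments(x: np.ndarray) -> tuple[float, float]:
    return float(np.mean(x)), float(np.std(x, ddof=1)) if len(x) > 1 else float("nan")


def compare_two_groups(
    x: Sequence[float],
    y: Sequence[float],
    index: str = "",
    labels: tuple[str, str] = ("case", "control"),
    threshold: float = DEFAULT_ALPHA,
    stratum: str | None = None,
) -> ComparisonResult:
    """Two-group comparison routed by normality (Student's t vs Mann-Whitney)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 3 or len(y) < 3:
        raise InsufficientDataError("both samples need n >= 3")
    decision = assess_normality(x, y)
    if decision.normal:
        test = "t"
        res = sps.ttest_ind(x, y, equal_var=True)
        statistic, p = float(res.statistic), float(res.pvalue)
    else:
        test = "mann-whitney"
        # exact for small tie-free samples, normal approximation with tie
        # correction otherwise
        ties = len(np.unique(np.concatenate([x, y]))) < len(x) + len(y)
        method = "exact" if (max(len(x), len(y)) <= 20 and not ties) else "asymptotic"
        res = sps.mannwhitneyu(x, y, alternative="two-sided", method=method)
        statistic, p = float(res.statistic), float(res.pvalue)
    mx, sx = _moments(x)
    my, sy = _moments(y)
    return ComparisonResult(
        index=index,
        group_means={labels[0]: mx, labels[1]: my},
        group_sds={labels[0]: sx, labels[1]: sy},
        group_ns={labels[0]: len(x), labels[1]: len(y)},
        test=test,
        statistic=statistic,
        p_value=min(p, 1.0),
        threshold=threshold,
        significant=p < threshold,
        stratum=stratum,
    )


def compare_multi_groups(
    groups: dict[str, Sequence[float]],
    index: str = "",
    min_group_size: int = MIN_GROUP_SIZE,
    threshold: float = DEFAULT_ALPHA,
    posthoc_alpha: float = DEFAULT_ALPHA,
    stratum: str | None = None,
) -> ComparisonResult:
    """Multi-group comparison (ANOVA + Tukey HSD, or Kruskal-Wallis).

    Groups smaller than ``min_group_size`` are excluded before testing
    (small-group exclusion); at least 3 eligible groups must remain.
    Tukey HSD runs only after a significant ANOVA.
    """
    eligible = {k: np.asarray(v, dtype=float) for k, v in groups.items() if len(v) >= min_group_size}
    if len(eligible) < 3:
        raise InsufficientDataError(
            f"need >= 3 groups of size >= {min_group_size}, have {len(eligible)}"
        )
    decision = assess_normality(*eligible.values())
    arrays = list(eligible.values())
    names = list(eligible.keys())
    posthoc: tuple[PairwiseResult, ...] | None = None
    if decision.normal:
        test = "anova"
        res = sps.f_oneway(*arrays)
        statistic, p = float(res.statistic), float(res.pvalue)
        if p < posthoc_alpha:
            tk = sps.tukey_hsd(*arrays)
            pairs = []
            for i in range(len(arrays)):
                for j in range(i + 1, len(arrays)):
                    pv = float(tk.pvalue[i, j])
                    pairs.append(PairwiseResult(names[i], names[j], pv, pv < posthoc_alpha))
            posthoc = tuple(pairs)
    else:
        test = "kruskal-wallis"
        res = sps.kruskal(*arrays)
        statistic, p = float(res.statistic), float(res.pvalue)
    if np.isnan(p):  # identical constant-free groups give F=0 / undefined
        statistic, p = 0.0, 1.0
    return ComparisonResult(
        index=index,
        group_means={k: float(np.mean(v)) for k, v in eligible.items()},
        group_sds={k: float(np.std(v, ddof=1)) for k, v in eligible.items()},
        group_ns={k: len(v) for k, v in eligible.items()},
        test=test,
        statistic=statistic,
        p_value=min(p, 1.0),
        threshold=threshold,
        significant=p < threshold,
        posthoc=posthoc,
        stratum=stratum,
    )


def bonferroni_threshold(alpha: float, n_tests: int) -> float:
    """Bonferroni-adjusted per-test threshold: alpha / n_tests."""
    if not 0 < alpha < 1:
        raise ValueError(f"alpha must be in (0,1), got {alpha}")
    if n_tests < 1:
        raise ValueError(f"n_tests must be >= 1, got {n_tests}")
    return alpha / n_tests


def correlate_index_with_stage(
    values: Sequence[float],
    stages: Sequence[float],
    index: str = "",
) -> CorrelationResult:
    """Correlation of an index with ordinal stage, routed by normality.

    Pearson when the index values look Gaussian (Shapiro-Wilk on the index
    sample), Spearman otherwise.
    """
    values = np.asarray(values, dtype=float)
    stages = np.asarray(stages, dtype=float)
    if len(values) != len(stages):
        raise ValueError("values and stages must be paired")
    if len(values) < 3:
        raise InsufficientDataError("correlation needs n >= 3")
    if np.ptp(stages) == 0:
        raise InsufficientDataError("stage variance is zero")
    if np.ptp(values) == 0:
        raise InsufficientDataError("index variance is zero")
    if assess_normality(values).normal:
        method = "pearson"
        r, p = sps.pearsonr(values, stages)
    else:
        method = "spearman"
        r, p = sps.spearmanr(values, stages)
    r = float(r)
    return CorrelationResult(index=index, method=method, r=r, r_squared=r * r, p_value=float(p))


def panel_frame(records) -> pd.DataFrame:
    """Index panel for a list of records as a DataFrame (one row each)."""
    rows = []
    for r in records:
        panel = compute_index_panel(r)
        row = {"id": r.id, "group": r.group, "bmi_class": r.bmi_class.value,
               "lipedema_type": r.lipedema_type, "lipedema_stage": r.lipedema_stage}
        row.update(panel.values)
        row.update({"bmi": panel.bmi, "fmi": panel.fmi, "lmi": panel.lmi,
                    "total_bmd": panel.total_bmd})
        rows.append(row)
    return pd.DataFrame(rows)


def run_comparison_battery(
    matched: "MatchedCohort",
    alpha: float = DEFAULT_ALPHA,
    stratify: str | None = None,
    min_group_size: int = MIN_GROUP_SIZE,
) -> list[ComparisonResult]:
    """One comparison per panel index, Bonferroni threshold over all 27.

    ``stratify=None`` compares cases vs controls on the full cohort;
    ``stratify="bmi_class"`` reruns the two-group battery per WHO class;
    ``stratify="type"`` / ``"stage"`` compare case subgroups with
    small-group exclusion.  Per-index failures (e.g. strata too small) are
    recorded with a NaN p value and the battery continues.
    """
    if not matched.cases or (stratify != "type" and stratify != "stage" and not matched.controls):
        raise ValueError("battery needs a non-empty matched cohort")
    threshold = bonferroni_threshold(alpha, PANEL_SIZE)
    frame = panel_frame(matched.records)
    results: list[ComparisonResult] = []

    def _two_group(sub: pd.DataFrame, stratum: str | None) -> None:
        for name in PANEL_INDEX_NAMES:
            x = sub.loc[sub["group"] == "case", name].to_numpy()
            y = sub.loc[sub["group"] == "control", name].to_numpy()
            try:
                results.append(
                    compare_two_groups(x, y, index=name, threshold=threshold, stratum=stratum)
                )
            except InsufficientDataError:
                results.append(_failed(name, threshold, stratum))

    def _failed(name: str, threshold: float, stratum: str | None) -> ComparisonResult:
        return ComparisonResult(
            index=name, group_means={}, group_sds={}, group_ns={},
            test="insufficient-data", statistic=float("nan"), p_value=float("nan"),
            threshold=threshold, significant=False, stratum=stratum,
        )

    if stratify is None:
        _two_group(frame, None)
    elif stratify == "bmi_class":
        for cls, sub in frame.groupby("bmi_class", sort=True):
            _two_group(sub, str(cls))
    elif stratify in ("type", "stage"):
        col = f"lipedema_{stratify}"
        cases = frame[frame["group"] == "case"]
        for name in PANEL_INDEX_NAMES:
            groups = {
                f"{stratify}_{int(level)}": sub[name].to_numpy()
                for level, sub in cases.groupby(col, sort=True)
            }
            try:
                results.append(
                    compare_multi_groups(
                        groups, index=name, min_group_size=min_group_size,
                        threshold=threshold, stratum=stratify,
                    )
                )
            except InsufficientDataError:
                results.append(_failed(name, threshold, stratify))
    else:
        raise ValueError(f"unknown stratification {stratify!r}")
    return results


def comparison_table(results: list[ComparisonResult]) -> pd.DataFrame:
    """Flatten battery results into a report table."""
    rows = []
    for r in results:
        row = {"index": r.index, "stratum": r.stratum, "test": r.test,
               "statistic": r.statistic, "p_value": r.p_value,
               "threshold": r.threshold, "significant": r.significant}
        for g, m in r.group_means.items():
            row[f"mean_{g}"] = m
        for g, s in r.group_sds.items():
            row[f"sd_{g}"] = s
        for g, n in r.group_ns.items():
            row[f"n_{g}"] = n
        rows.append(row)
    return pd.DataFrame(rows)
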