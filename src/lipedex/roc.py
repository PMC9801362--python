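"""Empirical ROC curves, AUC with DeLong confidence intervals, Youden-optimal
cutoffs, and a closed-form binormal oracle.

Candidate thresholds are the midpoints between consecutive distinct pooled
score values plus -inf/+inf sentinels, so reported cutoffs always fall
between observed values.  Orientation (whether higher or lower scores
indicate a case) is auto-selected by comparing group means so that AUC >=
0.5, and is recorded on the curve.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import TYPE_CHECKING, Sequence

import numpy as np
from scipy import stats as sps

from .composition import FM_PANEL_NAMES

if TYPE_CHECKING:  # pragma: no cover
    from .matching import MatchedCohort
    from .stats import ComparisonResult

__all__ = [
    "RocCurve",
    "RocSummary",
    "DegenerateCurveError",
    "empirical_roc",
    "auc",
    "auc_ci_delong",
    "youden_optimal",
    "youden_j",
    "binormal_auc",
    "summarize_index",
    "roc_battery",
]

HIGHER = "higher-is-case"
LOWER = "lower-is-case"


class DegenerateCurveError(ValueError):
    """Raised when all pooled scores are identical."""


@dataclass(frozen=True)
class RocCurve:
    """Empirical ROC: per-threshold sensitivity/specificity.

    Thresholds are on the original score scale, ordered so that sensitivity
    is non-increasing along the array (i.e. by increasing case-positivity
    strictness).  A score counts as case-positive when it is >= threshold
    (orientation ``higher-is-case``) or <= threshold (``lower-is-case``).
    """

    orientation: str
    thresholds: np.ndarray
    sensitivity: np.ndarray
    specificity: np.ndarray
    n_cases: int
    n_controls: int

    def __post_init__(self) -> None:
        if self.orientation not in (HIGHER, LOWER):
            raise ValueError(f"unknown orientation {self.orientation!r}")
        sens, spec = self.sensitivity, self.specificity
        if np.any(sens < -1e-12) or np.any(sens > 1 + 1e-12):
            raise ValueError("sensitivity out of [0,1]")
        if np.any(spec < -1e-12) or np.any(spec > 1 + 1e-12):
            raise ValueError("specificity out of [0,1]")
        if np.any(np.diff(sens) > 1e-12):
            raise ValueError("sensitivity must be non-increasing with strictness")


@dataclass(frozen=True)
class RocSummary:
    index: str
    auc: float
    ci_low: float
    ci_high: float
    cutoff: float
    sensitivity: float
    specificity: float
    youden_j: float
    orientation: str

    def __post_init__(self) -> None:
        if not self.ci_low - 1e-12 <= self.auc <= self.ci_high + 1e-12:
            raise ValueError("AUC outside its confidence interval")
        if abs(self.youden_j - (self.sensitivity + self.specificity - 1)) > 1e-9:
            raise ValueError("J must equal sensitivity + specificity - 1")


def _orient(case_scores: np.ndarray, control_scores: np.ndarray) -> str:
    """Choose the orientation giving AUC >= 0.5.

    The rank-sum (Mann-Whitney) statistic decides; group means break the
    exact tie at U = 0.5.
    """
    m, n = len(case_scores), len(control_scores)
    ranks = sps.rankdata(np.concatenate([case_scores, control_scores]))
    u = (ranks[:m].sum() - m * (m + 1) / 2.0) / (m * n)
    if u != 0.5:
        return HIGHER if u > 0.5 else LOWER
    return HIGHER if case_scores.mean() >= control_scores.mean() else LOWER


def empirical_roc(
    case_scores: Sequence[float],
    control_scores: Sequence[float],
) -> RocCurve:
    """Build the empirical ROC curve over all midpoint thresholds."""
    case = np.asarray(case_scores, dtype=float)
    ctrl = np.asarray(control_scores, dtype=float)
    if len(case) < 1 or len(ctrl) < 1:
        raise ValueError("both groups need at least one score")
    pooled = np.unique(np.concatenate([case, ctrl]))
    if len(pooled) < 2:
        raise DegenerateCurveError("all scores identical; ROC curve is degenerate")

    orientation = _orient(case, ctrl)
    sign = 1.0 if orientation == HIGHER else -1.0
    sc = np.sort(sign * case)
    st = np.sort(sign * ctrl)
    grid = np.unique(sign * pooled)
    thresholds = np.concatenate([[-np.inf], (grid[:-1] + grid[1:]) / 2.0, [np.inf]])

    # case-positive when oriented score >= threshold
    sens = 1.0 - np.searchsorted(sc, thresholds, side="left") / len(sc)
    spec = np.searchsorted(st, thresholds, side="left") / len(st)
    return RocCurve(
        orientation=orientation,
        thresholds=sign * thresholds,
        sensitivity=sens,
        specificity=spec,
        n_cases=len(case),
        n_controls=len(ctrl),
    )


def auc(curve: RocCurve) -> float:
    """Trapezoidal area under the curve in (1 - specificity, sensitivity) space.

    Equals the Mann-Whitney U statistic / (n1 * n0) with ties counted 0.5.
    """
    x = 1.0 - curve.specificity
    y = curve.sensitivity
    order = np.lexsort((y, x))  # staircase: x ascending, y ascending within x
    return float(np.trapezoid(y[order], x[order]))


def _delong_auc_variance(case: np.ndarray, ctrl: np.ndarray) -> tuple[float, float]:
    """DeLong (1988) AUC and variance estimate via midranks."""
    m, n = len(case), len(ctrl)
    pooled = np.concatenate([case, ctrl])
    r = sps.rankdata(pooled)
    r_case = sps.rankdata(case)
    r_ctrl = sps.rankdata(ctrl)
    auc_hat = (r[:m].sum() - m * (m + 1) / 2.0) / (m * n)
    v10 = (r[:m] - r_case) / n  # structural components over cases
    v01 = 1.0 - (r[m:] - r_ctrl) / m  # over controls
    s10 = np.var(v10, ddof=1) if m > 1 else 0.0
    s01 = np.var(v01, ddof=1) if n > 1 else 0.0
    return float(auc_hat), float(s10 / m + s01 / n)


def auc_ci_delong(
    case_scores: Sequence[float],
    control_scores: Sequence[float],
    level: float = 0.95,
) -> tuple[float, float]:
    """DeLong Wald confidence interval for the (orientation-corrected) AUC."""
    if not 0 < level < 1:
        raise ValueError("level must be in (0,1)")
    case = np.asarray(case_scores, dtype=float)
    ctrl = np.asarray(control_scores, dtype=float)
    if len(case) < 2 or len(ctrl) < 2:
        raise ValueError("DeLong CI needs n >= 2 per group")
    sign = 1.0 if _orient(case, ctrl) == HIGHER else -1.0
    auc_hat, var = _delong_auc_variance(sign * case, sign * ctrl)
    z = sps.norm.ppf(0.5 + level / 2.0)
    half = z * np.sqrt(max(var, 0.0))
    return (float(max(0.0, auc_hat - half)), float(min(1.0, auc_hat + half)))


def youden_optimal(curve: RocCurve) -> tuple[float, float, float, float]:
    """Maximize J = sensitivity + specificity - 1 over all thresholds.

    Ties are broken toward higher sensitivity (the rule-out use case), then
    toward the lower cutoff.  Returns (cutoff, sensitivity, specificity, J).
    """
    j = curve.sensitivity + curve.specificity - 1.0
    best = None
    for i in range(len(j)):
        key = (round(float(j[i]), 12), float(curve.sensitivity[i]), -float(curve.thresholds[i]))
        if best is None or key > best[0]:
            best = (key, i)
    i = best[1]
    return (
        float(curve.thresholds[i]),
        float(curve.sensitivity[i]),
        float(curve.specificity[i]),
        float(j[i]),
    )


def youden_j(sensitivity: float, specificity: float) -> float:
    """Youden's index J = sensitivity + specificity - 1."""
    if not 0 <= sensitivity <= 1 or not 0 <= specificity <= 1:
        raise ValueError("sensitivity and specificity must be in [0,1]")
    return sensitivity + specificity - 1.0


def binormal_auc(case_mean: float, case_sd: float, control_mean: float, control_sd: float) -> float:
    """Closed-form AUC for two Gaussian score distributions.

    Phi(|mean difference| / sqrt(case_sd^2 + control_sd^2)); the absolute
    value applies the same orientation correction as the empirical curve.
    """
    if case_sd <= 0 or control_sd <= 0:
        raise ValueError("standard deviations must be > 0")
    z = abs(case_mean - control_mean) / float(np.hypot(case_sd, control_sd))
    return float(sps.norm.cdf(z))


def summarize_index(
    case_scores: Sequence[float],
    control_scores: Sequence[float],
    index: str = "",
    level: float = 0.95,
) -> RocSummary:
    """Full ROC summary (AUC, CI, Youden operating point) for one index."""
    curve = empirical_roc(case_scores, control_scores)
    cutoff, sens, spec, j = youden_optimal(curve)
    lo, hi = auc_ci_delong(case_scores, control_scores, level=level)
    a = auc(curve)
    return RocSummary(
        index=index,
        auc=a,
        ci_low=min(lo, a),
        ci_high=max(hi, a),
        cutoff=cutoff,
        sensitivity=sens,
        specificity=spec,
        youden_j=j,
        orientation=curve.orientation,
    )


def roc_battery(
    matched: "MatchedCohort",
    battery_results: Sequence["ComparisonResult"],
    level: float = 0.95,
) -> list[RocSummary]:
    """ROC summaries for every FM index flagged significant, ranked by AUC."""
    from .stats import panel_frame

    significant = [
        r.index for r in battery_results
        if r.significant and r.stratum is None and r.index in FM_PANEL_NAMES
    ]
    if not significant:
        return []
    frame = panel_frame(matched.records)
    case = frame[frame["group"] == "case"]
    ctrl = frame[frame["group"] == "control"]
    summaries = [
        summarize_index(case[name].to_numpy(), ctrl[name].to_numpy(), index=name, level=level)
        for name in significant
    ]
    summaries.sort(key=lambda s: s.auc, reverse=True)
    return summaries
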