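"""Tolerance-based 1:ratio case-control matching.

Greedy nearest-neighbour without replacement: cases are processed in
ascending id order; eligible controls (|d age| <= age_tol and |d BMI| <=
bmi_tol, tolerances inclusive) are ranked by the normalised L1 distance
|d age|/age_tol + |d BMI|/bmi_tol with ties broken by control id.  Greedy
is deterministic and transparent; it is not guaranteed optimal, which is
acceptable at the default 4x pool.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .composition import BmiClass, ParticipantRecord, classify_bmi, compute_fmi

__all__ = ["MatchedCohort", "MatchingInfeasibleError", "match_controls", "summarize_cohort"]


class MatchingInfeasibleError(ValueError):
    """Raised when some case cannot be given ``ratio`` eligible controls."""


@dataclass
class MatchedCohort:
    """Cases plus their tolerance-matched controls with provenance.

    ``assignment`` may be ``None`` for cohorts reloaded from disk where only
    the group composition (not the per-pair bookkeeping) is known; pairwise
    invariants are then not checkable and group-level analyses still apply.
    """

    cases: list[ParticipantRecord]
    controls: list[ParticipantRecord]
    assignment: dict[str, list[str]] | None
    age_tol: float
    bmi_tol: float
    ratio: int

    @classmethod
    def from_groups(cls, cases, controls) -> "MatchedCohort":
        """Group-level cohort without per-pair provenance."""
        ratio = len(controls) // max(1, len(cases))
        return cls(
            cases=sorted(cases, key=lambda r: r.id),
            controls=list(controls),
            assignment=None,
            age_tol=float("nan"),
            bmi_tol=float("nan"),
            ratio=ratio,
        )

    def __post_init__(self) -> None:
        if self.assignment is None:
            return
        by_id = {r.id: r for r in self.cases + self.controls}
        seen: set[str] = set()
        for case in self.cases:
            matched = self.assignment.get(case.id)
            if matched is None or len(matched) != self.ratio:
                raise ValueError(f"case {case.id} must map to exactly {self.ratio} controls")
            for cid in matched:
                if cid in seen:
                    raise ValueError(f"control {cid} assigned twice")
                seen.add(cid)
                ctrl = by_id[cid]
                if abs(ctrl.age - case.age) > self.age_tol + 1e-12:
                    raise ValueError(f"pair ({case.id}, {cid}) violates age tolerance")
                if abs(ctrl.bmi - case.bmi) > self.bmi_tol + 1e-12:
                    raise ValueError(f"pair ({case.id}, {cid}) violates BMI tolerance")

    @property
    def records(self) -> list[ParticipantRecord]:
        return self.cases + self.controls


def match_controls(
    cases: list[ParticipantRecord],
    pool: list[ParticipantRecord],
    ratio: int = 2,
    age_tol: float = 3.0,
    bmi_tol: float = 3.0,
) -> MatchedCohort:
    """Select ``ratio`` controls per case within the age/BMI tolerances."""
    if ratio < 1:
        raise ValueError("ratio must be >= 1")
    if age_tol <= 0 or bmi_tol <= 0:
        raise ValueError("tolerances must be > 0")
    if len(pool) < ratio * len(cases):
        raise MatchingInfeasibleError(
            f"pool of {len(pool)} cannot supply {ratio} controls for {len(cases)} cases"
        )

    used: set[str] = set()
    assignment: dict[str, list[str]] = {}
    selected: list[ParticipantRecord] = []
    for case in sorted(cases, key=lambda r: r.id):
        candidates = []
        for ctrl in pool:
            if ctrl.id in used:
                continue
            da, db = abs(ctrl.age - case.age), abs(ctrl.bmi - case.bmi)
            if da <= age_tol and db <= bmi_tol:
                candidates.append((da / age_tol + db / bmi_tol, ctrl.id, ctrl))
        if len(candidates) < ratio:
            raise MatchingInfeasibleError(
                f"case {case.id} has only {len(candidates)} eligible controls "
                f"remaining (needs {ratio})"
            )
        candidates.sort(key=lambda t: (t[0], t[1]))
        chosen = [c[2] for c in candidates[:ratio]]
        assignment[case.id] = [c.id for c in chosen]
        used.update(c.id for c in chosen)
        selected.extend(chosen)

    return MatchedCohort(
        cases=sorted(cases, key=lambda r: r.id),
        controls=selected,
        assignment=assignment,
        age_tol=age_tol,
        bmi_tol=bmi_tol,
        ratio=ratio,
    )


def summarize_cohort(matched: MatchedCohort) -> pd.DataFrame:
    """Per-BMI-class cohort summary (counts, age/BMI/FMI by group).

    One row per WHO class plus an overall row; empty class cells are
    reported with n = 0 rather than dropped.  Group-difference p values
    (two-group comparison with normality routing) are appended where both
    groups have at least 3 members.
    """
    from .stats import compare_two_groups  # late import: stats depends on this module's type

    if not matched.cases and not matched.controls:
        raise ValueError("cannot summarize an empty cohort")

    def _stratum(label: str, cases, controls) -> dict:
        n = len(cases) + len(controls)
        row: dict = {
            "stratum": label,
            "n": n,
            "n_cases": len(cases),
            "n_controls": len(controls),
            "pct": 100.0 * n / (len(matched.cases) + len(matched.controls)),
        }
        for name, fn in (
            ("age", lambda r: r.age),
            ("bmi", lambda r: r.bmi),
            ("fmi", compute_fmi),
        ):
            xs = np.array([fn(r) for r in cases], dtype=float)
            ys = np.array([fn(r) for r in controls], dtype=float)
            row[f"{name}_case_mean"] = xs.mean() if len(xs) else np.nan
            row[f"{name}_case_sd"] = xs.std(ddof=1) if len(xs) > 1 else np.nan
            row[f"{name}_control_mean"] = ys.mean() if len(ys) else np.nan
            row[f"{name}_control_sd"] = ys.std(ddof=1) if len(ys) > 1 else np.nan
            if len(xs) >= 3 and len(ys) >= 3:
                row[f"{name}_p"] = compare_two_groups(xs, ys, index=name).p_value
            else:
                row[f"{name}_p"] = np.nan
        return row

    rows = [_stratum("overall", matched.cases, matched.controls)]
    for cls in BmiClass:
        cases = [r for r in matched.cases if r.bmi_class is cls]
        controls = [r for r in matched.controls if r.bmi_class is cls]
        rows.append(_stratum(cls.value, cases, controls))
    return pd.DataFrame(rows)
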