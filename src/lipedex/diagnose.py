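"""Clinical criteria, type/stage taxonomy, and the DXA-assisted decision rule.

The leg FM/total FM index is strictly a rule-out aid: it never overrides
fully met clinical criteria, and only a value below the cutoff can rule the
disease out in doubtful cases (the rule-in side is inclusive, so a share
exactly at the cutoff stays indeterminate).
"""

from __future__ import annotations

from dataclasses import dataclass, fields
from enum import Enum

__all__ = [
    "ClinicalCriteria",
    "Verdict",
    "DiagnosisOutcome",
    "FatPattern",
    "SkinMorphology",
    "DEFAULT_CUTOFF",
    "ALTERNATE_CUTOFF",
    "criteria_met",
    "apply_diagnostic_algorithm",
    "classify_type",
    "classify_stage",
]

#: Default rule-out cutoff for the leg FM/total FM index.
DEFAULT_CUTOFF = 0.383
#: Published variant of the same cutoff; selectable, never silently chosen.
ALTERNATE_CUTOFF = 0.384


@dataclass(frozen=True)
class ClinicalCriteria:
    """The six clinical criteria; all must be explicitly set (booleans)."""

    disproportionate_symmetric_limb_fat: bool  # sparing hands and feet
    weight_loss_resistance: bool
    pain_tenderness_easy_bruising: bool
    touch_sensitivity_or_limb_fatigue: bool
    minimal_or_no_pitting_edema: bool
    no_relief_with_elevation: bool

    def __post_init__(self) -> None:
        for f in fields(self):
            value = getattr(self, f.name)
            if not isinstance(value, bool):
                raise ValueError(f"criterion {f.name} must be an explicit bool, got {value!r}")


class Verdict(str, Enum):
    CONFIRMED = "confirmed"
    RULED_OUT_UNLIKELY = "ruled-out-unlikely"
    INDETERMINATE_REVIEW = "indeterminate-review"


@dataclass(frozen=True)
class DiagnosisOutcome:
    verdict: Verdict
    leg_share: float
    cutoff: float
    criteria_met: bool
    lipedema_type: int | None = None
    lipedema_stage: int | None = None

    def __post_init__(self) -> None:
        if self.verdict is Verdict.RULED_OUT_UNLIKELY and not self.leg_share < self.cutoff:
            raise ValueError("rule-out verdict requires leg share < cutoff")


def criteria_met(criteria: ClinicalCriteria) -> bool:
    """True iff all six clinical criteria are met (strict conjunction)."""
    return all(getattr(criteria, f.name) for f in fields(ClinicalCriteria))


def apply_diagnostic_algorithm(
    criteria: ClinicalCriteria,
    leg_share: float,
    cutoff: float = DEFAULT_CUTOFF,
    lipedema_type: int | None = None,
    lipedema_stage: int | None = None,
) -> DiagnosisOutcome:
    """Decision rule for suspected lipedema.

    All criteria met -> confirmed (the index never overrides the clinic).
    Criteria doubtful/incomplete and leg share < cutoff -> ruled-out-unlikely.
    Criteria doubtful/incomplete and leg share >= cutoff -> indeterminate,
    refer for multidisciplinary review.
    """
    if not 0 < leg_share < 1:
        raise ValueError(f"leg FM/total FM share must be in (0,1), got {leg_share}")
    if not 0 < cutoff < 1:
        raise ValueError(f"cutoff must be in (0,1), got {cutoff}")
    met = criteria_met(criteria)
    if met:
        verdict = Verdict.CONFIRMED
    elif leg_share < cutoff:
        verdict = Verdict.RULED_OUT_UNLIKELY
    else:
        verdict = Verdict.INDETERMINATE_REVIEW
    return DiagnosisOutcome(
        verdict=verdict,
        leg_share=leg_share,
        cutoff=cutoff,
        criteria_met=met,
        lipedema_type=lipedema_type if verdict is Verdict.CONFIRMED else None,
        lipedema_stage=lipedema_stage if verdict is Verdict.CONFIRMED else None,
    )


class FatPattern(str, Enum):
    """Lower-limb fat distribution descriptors."""

    HIPS_BUTTOCKS = "hips-buttocks"
    HIPS_TO_KNEES = "hips-to-knees"
    HIPS_TO_ANKLE_CUFF = "hips-to-ankle-with-cuff-sign"
    CALF_ONLY = "calf-only"


_TYPE_BY_PATTERN = {
    FatPattern.HIPS_BUTTOCKS: 1,
    FatPattern.HIPS_TO_KNEES: 2,
    FatPattern.HIPS_TO_ANKLE_CUFF: 3,
    FatPattern.CALF_ONLY: 5,
}


def classify_type(pattern: FatPattern, arm_involvement: bool) -> int:
    """Type I-V: arm involvement dominates (IV), else by distribution pattern."""
    if not isinstance(pattern, FatPattern):
        raise ValueError(f"missing or invalid fat distribution descriptor: {pattern!r}")
    if arm_involvement:
        return 4
    return _TYPE_BY_PATTERN[pattern]


class SkinMorphology(str, Enum):
    """Skin/subcutis morphology descriptors."""

    SMOOTH_THICKENED = "smooth-thickened"
    ORANGE_PEEL_NODULES = "orange-peel-nodules"
    FOLDS_DIVOTS = "folds-divots"


_STAGE_BY_SKIN = {
    SkinMorphology.SMOOTH_THICKENED: 1,
    SkinMorphology.ORANGE_PEEL_NODULES: 2,
    SkinMorphology.FOLDS_DIVOTS: 3,
}


def classify_stage(skin: SkinMorphology, lymphedema: bool) -> int:
    """Stage 1-4: concomitant lymphedema is stage 4 regardless of skin."""
    if not isinstance(skin, SkinMorphology):
        raise ValueError(f"missing or invalid skin descriptor: {skin!r}")
    if lymphedema:
        return 4
    return _STAGE_BY_SKIN[skin]
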