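"""Participant records and regional body-composition indices.

All masses are kept in kilograms internally; bone mineral density converts
kg to g at the boundary.  The index panel contains exactly 27 named entries
(the multiple-testing denominator of the comparison battery); BMI, FMI, LMI
and total-body BMD ride along as non-panel extras.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum
from typing import Mapping

__all__ = [
    "BmiClass",
    "BMI_CLASS_BOUNDS",
    "RegionMasses",
    "ParticipantRecord",
    "IndexPanel",
    "PANEL_INDEX_NAMES",
    "FM_PANEL_NAMES",
    "PANEL_SIZE",
    "REGIONS",
    "PANEL_REGIONS",
    "OutOfStudyRangeError",
    "RecordValidationError",
    "IndexComputationError",
    "compute_bmi",
    "classify_bmi",
    "compute_fmi",
    "compute_lmi",
    "compute_almi",
    "compute_total_bmd",
    "compute_index_panel",
]

#: Scanner regions carried on every record (``total`` is stored separately).
REGIONS = ("legs", "arms", "trunk", "android", "gynoid", "head")

#: Regions the index panel reports (legs_arms is the sum of legs and arms).
PANEL_REGIONS = ("legs", "arms", "legs_arms", "trunk", "android", "gynoid")


class OutOfStudyRangeError(ValueError):
    """Raised for BMI values below the studied range (< 18 kg/m^2)."""


class RecordValidationError(ValueError):
    """Raised when a participant record violates its invariants."""


class IndexComputationError(ValueError):
    """Raised when an index denominator is zero (named per index)."""


class BmiClass(str, Enum):
    """WHO adult BMI classes, half-open intervals on the studied range."""

    NORMAL_WEIGHT = "normal_weight"
    OVERWEIGHT = "overweight"
    OBESITY_I = "obesity_class_1"
    OBESITY_II = "obesity_class_2"
    OBESITY_III = "obesity_class_3"


#: Half-open [lower, upper) bounds for each class.
BMI_CLASS_BOUNDS: dict[BmiClass, tuple[float, float]] = {
    BmiClass.NORMAL_WEIGHT: (18.0, 25.0),
    BmiClass.OVERWEIGHT: (25.0, 30.0),
    BmiClass.OBESITY_I: (30.0, 35.0),
    BmiClass.OBESITY_II: (35.0, 40.0),
    BmiClass.OBESITY_III: (40.0, math.inf),
}


def compute_bmi(weight_kg: float, height_m: float) -> float:
    """Body mass index: weight divided by height squared (kg/m^2)."""
    if weight_kg <= 0:
        raise ValueError(f"weight must be > 0 kg, got {weight_kg}")
    if height_m <= 0:
        raise ValueError(f"height must be > 0 m, got {height_m}")
    return weight_kg / height_m**2


def classify_bmi(bmi: float) -> BmiClass:
    """Map a BMI to its WHO class; values below 18 are out of study range."""
    if bmi < 18.0:
        raise OutOfStudyRangeError(f"BMI {bmi} below studied range (>= 18)")
    for cls, (lo, hi) in BMI_CLASS_BOUNDS.items():
        if lo <= bmi < hi:
            return cls
    raise AssertionError("unreachable: class bounds cover [18, inf)")


@dataclass(frozen=True)
class RegionMasses:
    """Per-region masses (kg) for one tissue compartment.

    The android region is a sub-region of the trunk; the gynoid region
    overlaps both legs and trunk, so regions do not partition the total.
    """

    legs: float
    arms: float
    trunk: float
    android: float
    gynoid: float
    head: float
    total: float

    def __post_init__(self) -> None:
        if self.total <= 0:
            raise RecordValidationError(f"total mass must be > 0, got {self.total}")
        for region in REGIONS:
            value = getattr(self, region)
            if value < 0:
                raise RecordValidationError(f"{region} mass must be >= 0, got {value}")
            if value > self.total * (1 + 1e-9):
                raise RecordValidationError(
                    f"{region} mass {value} exceeds total {self.total}"
                )

    def region(self, name: str) -> float:
        if name == "legs_arms":
            return self.legs + self.arms
        return getattr(self, name)


@dataclass(frozen=True)
class ParticipantRecord:
    """One participant: demographics, regional masses, group and taxonomy.

    ``lipedema_type`` (1-5) and ``lipedema_stage`` (1-4) must be present
    if and only if the participant is a case.
    """

    id: str
    group: str  # "case" | "control"
    age: float
    height_m: float
    weight_kg: float
    fm: RegionMasses
    lm: RegionMasses
    bone_mass_total_kg: float
    bone_area_cm2: float
    lipedema_type: int | None = None
    lipedema_stage: int | None = None

    def __post_init__(self) -> None:
        if self.group not in ("case", "control"):
            raise RecordValidationError(f"group must be case|control, got {self.group!r}")
        if self.height_m <= 0:
            raise RecordValidationError(f"height must be > 0, got {self.height_m}")
        if self.weight_kg <= 0:
            raise RecordValidationError(f"weight must be > 0, got {self.weight_kg}")
        if self.age < 18:
            raise RecordValidationError(f"age must be >= 18 (adult cohort), got {self.age}")
        if self.bone_mass_total_kg < 0:
            raise RecordValidationError("bone mass must be >= 0")
        if self.bone_area_cm2 <= 0:
            raise RecordValidationError("bone area must be > 0")
        is_case = self.group == "case"
        has_taxonomy = self.lipedema_type is not None and self.lipedema_stage is not None
        if is_case and not has_taxonomy:
            raise RecordValidationError(f"case {self.id} must carry type and stage")
        if not is_case and (self.lipedema_type is not None or self.lipedema_stage is not None):
            raise RecordValidationError(f"control {self.id} must not carry type/stage")
        if self.lipedema_type is not None and self.lipedema_type not in (1, 2, 3, 4, 5):
            raise RecordValidationError(f"type must be 1-5, got {self.lipedema_type}")
        if self.lipedema_stage is not None and self.lipedema_stage not in (1, 2, 3, 4):
            raise RecordValidationError(f"stage must be 1-4, got {self.lipedema_stage}")

    @property
    def bmi(self) -> float:
        return compute_bmi(self.weight_kg, self.height_m)

    @property
    def bmi_class(self) -> BmiClass:
        return classify_bmi(self.bmi)


def compute_fmi(record: ParticipantRecord) -> float:
    """Fat mass index: total FM / height^2 (kg/m^2)."""
    return record.fm.total / record.height_m**2


def compute_lmi(record: ParticipantRecord) -> float:
    """Lean mass index: total LM / height^2 (kg/m^2)."""
    return record.lm.total / record.height_m**2


def compute_almi(leg_lm_kg: float, arm_lm_kg: float, height_m: float) -> float:
    """Appendicular lean mass index: (leg LM + arm LM) / height^2."""
    if leg_lm_kg < 0 or arm_lm_kg < 0:
        raise ValueError("lean masses must be >= 0")
    if height_m <= 0:
        raise ValueError(f"height must be > 0, got {height_m}")
    return (leg_lm_kg + arm_lm_kg) / height_m**2


def compute_total_bmd(bone_mass_total_kg: float, bone_area_cm2: float) -> float:
    """Total-body bone mineral density (g/cm^2), head excluded upstream."""
    if bone_area_cm2 <= 0:
        raise ValueError(f"bone area must be > 0 cm^2, got {bone_area_cm2}")
    if bone_mass_total_kg < 0:
        raise ValueError("bone mass must be >= 0")
    return bone_mass_total_kg * 1000.0 / bone_area_cm2


def _panel_names() -> tuple[str, ...]:
    names: list[str] = []
    names += [f"fm_fmi_{r}" for r in PANEL_REGIONS]
    names += [f"fm_share_{r}" for r in PANEL_REGIONS]
    names += ["trunk_legs_fm_ratio", "android_gynoid_ratio"]
    names += [f"lm_lmi_{r}" for r in PANEL_REGIONS]
    names += [f"lm_share_{r}" for r in PANEL_REGIONS]
    names += ["almi"]
    return tuple(names)


#: The 27 panel entry names, in reporting order.
PANEL_INDEX_NAMES: tuple[str, ...] = _panel_names()
PANEL_SIZE = 27
assert len(PANEL_INDEX_NAMES) == PANEL_SIZE

#: The 14 fat-mass distribution indices (candidates for ROC analysis).
FM_PANEL_NAMES: tuple[str, ...] = tuple(
    n for n in PANEL_INDEX_NAMES
    if n.startswith("fm_") or n in ("trunk_legs_fm_ratio", "android_gynoid_ratio")
)
assert len(FM_PANEL_NAMES) == 14


@dataclass(frozen=True)
class IndexPanel:
    """The 27-entry index panel for one participant, plus non-panel extras."""

    values: Mapping[str, float]
    bmi: float
    fmi: float
    lmi: float
    total_bmd: float

    def __post_init__(self) -> None:
        if tuple(self.values.keys()) != PANEL_INDEX_NAMES:
            raise ValueError("panel must contain exactly the 27 named indices, in order")

    def __len__(self) -> int:
        return len(self.values)

    def __getitem__(self, name: str) -> float:
        return self.values[name]


def _pct_fat(fm: float, lm: float, bone: float) -> float:
    tissue = fm + lm + bone
    if tissue <= 0:
        raise IndexComputationError("zero tissue mass in fat-percentage denominator")
    return fm / tissue


def compute_index_panel(
    record: ParticipantRecord,
    pct_fat_denominator: str = "fat_lean",
) -> IndexPanel:
    """Compute the 27 distribution indices for one participant.

    ``pct_fat_denominator`` selects the regional %fat convention used by the
    android/gynoid ratio: ``"fat_lean"`` uses fat/(fat+lean) (default, the
    record schema carries no regional bone masses); ``"fat_lean_bone"``
    additionally allocates total bone mass to regions proportionally to
    their fat+lean tissue mass, approximating the scanner's tissue-%fat.
    """
    if pct_fat_denominator not in ("fat_lean", "fat_lean_bone"):
        raise ValueError(f"unknown %fat dialect {pct_fat_denominator!r}")
    h2 = record.height_m**2
    fm, lm = record.fm, record.lm
    fmi = fm.total / h2
    lmi = lm.total / h2

    values: dict[str, float] = {}
    for region in ("legs", "arms", "trunk", "android", "gynoid"):
        values[f"fm_fmi_{region}"] = fm.region(region) / fmi
    values["fm_fmi_legs_arms"] = values["fm_fmi_legs"] + values["fm_fmi_arms"]
    for region in ("legs", "arms", "trunk", "android", "gynoid"):
        values[f"fm_share_{region}"] = fm.region(region) / fm.total
    values["fm_share_legs_arms"] = values["fm_share_legs"] + values["fm_share_arms"]

    if fm.legs <= 0:
        raise IndexComputationError("trunk_legs_fm_ratio: leg FM is zero")
    values["trunk_legs_fm_ratio"] = fm.trunk / fm.legs

    bone_android = bone_gynoid = 0.0
    if pct_fat_denominator == "fat_lean_bone":
        total_tissue = fm.total + lm.total
        bone_android = record.bone_mass_total_kg * (fm.android + lm.android) / total_tissue
        bone_gynoid = record.bone_mass_total_kg * (fm.gynoid + lm.gynoid) / total_tissue
    android_pct = _pct_fat(fm.android, lm.android, bone_android)
    gynoid_pct = _pct_fat(fm.gynoid, lm.gynoid, bone_gynoid)
    if gynoid_pct <= 0:
        raise IndexComputationError("android_gynoid_ratio: gynoid fat percentage is zero")
    values["android_gynoid_ratio"] = android_pct / gynoid_pct

    for region in ("legs", "arms", "trunk", "android", "gynoid"):
        values[f"lm_lmi_{region}"] = lm.region(region) / lmi
    values["lm_lmi_legs_arms"] = values["lm_lmi_legs"] + values["lm_lmi_arms"]
    for region in ("legs", "arms", "trunk", "android", "gynoid"):
        values[f"lm_share_{region}"] = lm.region(region) / lm.total
    values["lm_share_legs_arms"] = values["lm_share_legs"] + values["lm_share_arms"]

    values["almi"] = compute_almi(lm.legs, lm.arms, record.height_m)

    ordered = {name: values[name] for name in PANEL_INDEX_NAMES}
    return IndexPanel(
        values=ordered,
        bmi=record.bmi,
        fmi=fmi,
        lmi=lmi,
        total_bmd=compute_total_bmd(record.bone_mass_total_kg, record.bone_area_cm2),
    )
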