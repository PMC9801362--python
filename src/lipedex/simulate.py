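"""Synthetic cohort generator.

Distribution *indices*, not raw masses, are the calibration targets: regional
shares are drawn from truncated Gaussians (+/- 4 SD, floored at physical
limits, so moment distortion stays below printed precision) and masses are
reconstructed from them.  Trunk fat is the remainder after legs, arms and a
fixed head share; the android region is drawn as a fraction of trunk mass;
the gynoid region is drawn as its own share of the total (it overlaps legs
and trunk by scanner convention, so the overlap is deliberately not
mass-conserving).

Control-pool records are generated around the case age/BMI values (uniform
jitter well inside the matching tolerances), emulating a matched
case-control recruitment and guaranteeing the pool spans the case ranges.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .composition import (
    BMI_CLASS_BOUNDS,
    BmiClass,
    ParticipantRecord,
    RegionMasses,
    classify_bmi,
)

__all__ = [
    "ClassParams",
    "GroupParams",
    "GeneratorConfig",
    "ConfigValidationError",
    "MiscalibratedConfigError",
    "default_config",
    "generate_participant",
    "generate_cohort",
    "split_cohort",
    "CLASS_ORDER",
]

#: Reporting/sampling order of the WHO classes.
CLASS_ORDER: tuple[BmiClass, ...] = (
    BmiClass.NORMAL_WEIGHT,
    BmiClass.OVERWEIGHT,
    BmiClass.OBESITY_I,
    BmiClass.OBESITY_II,
    BmiClass.OBESITY_III,
)

_SHARE_EPS = 1e-6


class ConfigValidationError(ValueError):
    """Raised when generator parameters violate their invariants."""


class MiscalibratedConfigError(ValueError):
    """Raised when share draws would make trunk share <= 0 in > 1% of attempts."""


@dataclass(frozen=True)
class ClassParams:
    """Per BMI-class sampling parameters for one group."""

    age_mean: float
    age_sd: float
    bmi_mean: float
    bmi_sd: float
    bmi_lo: float
    bmi_hi: float
    fmi_mean: float
    fmi_sd: float

    def validate(self, label: str) -> None:
        for name in ("age_sd", "bmi_sd", "fmi_sd"):
            if getattr(self, name) < 0:
                raise ConfigValidationError(f"{label}: {name} must be >= 0")
        if not self.bmi_lo < self.bmi_hi:
            raise ConfigValidationError(f"{label}: empty BMI sampling range")
        if self.fmi_mean <= 0:
            raise ConfigValidationError(f"{label}: fmi_mean must be > 0")


@dataclass(frozen=True)
class GroupParams:
    """Per-group share distributions and physical scaling parameters."""

    height_mean: float
    height_sd: float
    leg_fm_share_mean: float
    leg_fm_share_sd: float
    arm_fm_share_mean: float
    arm_fm_share_sd: float
    head_fm_share: float
    gynoid_fm_share_mean: float
    gynoid_fm_share_sd: float
    android_fm_frac_mean: float  # fraction of trunk FM
    android_fm_frac_sd: float
    leg_lm_share_mean: float
    leg_lm_share_sd: float
    arm_lm_share_mean: float
    arm_lm_share_sd: float
    head_lm_share: float
    gynoid_lm_share_mean: float
    gynoid_lm_share_sd: float
    android_lm_frac_mean: float  # fraction of trunk LM
    android_lm_frac_sd: float
    bone_mass_fraction: float  # of total body mass
    bmd_mean: float
    bmd_sd: float
    by_class: dict[BmiClass, ClassParams] = field(default_factory=dict)

    def validate(self, label: str) -> None:
        if self.height_mean <= 0 or self.height_sd < 0:
            raise ConfigValidationError(f"{label}: invalid height parameters")
        share_means = {
            "leg_fm_share_mean": self.leg_fm_share_mean,
            "arm_fm_share_mean": self.arm_fm_share_mean,
            "head_fm_share": self.head_fm_share,
            "gynoid_fm_share_mean": self.gynoid_fm_share_mean,
            "android_fm_frac_mean": self.android_fm_frac_mean,
            "leg_lm_share_mean": self.leg_lm_share_mean,
            "arm_lm_share_mean": self.arm_lm_share_mean,
            "head_lm_share": self.head_lm_share,
            "gynoid_lm_share_mean": self.gynoid_lm_share_mean,
            "android_lm_frac_mean": self.android_lm_frac_mean,
        }
        for name, value in share_means.items():
            if not 0 < value < 1:
                raise ConfigValidationError(f"{label}: {name} must be in (0,1), got {value}")
        for name in (
            "leg_fm_share_sd", "arm_fm_share_sd", "gynoid_fm_share_sd",
            "android_fm_frac_sd", "leg_lm_share_sd", "arm_lm_share_sd",
            "gynoid_lm_share_sd", "android_lm_frac_sd", "bmd_sd",
        ):
            if getattr(self, name) < 0:
                raise ConfigValidationError(f"{label}: {name} must be >= 0")
        if self.leg_fm_share_mean + self.arm_fm_share_mean + self.head_fm_share >= 1:
            raise ConfigValidationError(f"{label}: FM head+leg+arm share means must be < 1")
        if self.leg_lm_share_mean + self.arm_lm_share_mean + self.head_lm_share >= 1:
            raise ConfigValidationError(f"{label}: LM head+leg+arm share means must be < 1")
        if not 0 < self.bone_mass_fraction < 0.2:
            raise ConfigValidationError(f"{label}: implausible bone_mass_fraction")
        if self.bmd_mean <= 0:
            raise ConfigValidationError(f"{label}: bmd_mean must be > 0")
        if set(self.by_class) != set(CLASS_ORDER):
            raise ConfigValidationError(f"{label}: by_class must cover all five WHO classes")
        for cls, cp in self.by_class.items():
            cp.validate(f"{label}.{cls.value}")


@dataclass(frozen=True)
class GeneratorConfig:
    """Full generator configuration (both groups, taxonomy, pool sizing)."""

    case: GroupParams
    control: GroupParams
    type_probabilities: tuple[float, float, float, float, float]
    stage_probabilities: tuple[float, float, float, float]
    case_class_weights: tuple[float, float, float, float, float]
    pool_multiplier: int = 4
    control_age_jitter: float = 2.0
    control_bmi_jitter: float = 2.0
    truncation_sds: float = 4.0
    seed: int | None = None

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        self.case.validate("case")
        self.control.validate("control")
        for name, probs, k in (
            ("type_probabilities", self.type_probabilities, 5),
            ("stage_probabilities", self.stage_probabilities, 4),
        ):
            if len(probs) != k:
                raise ConfigValidationError(f"{name} must have {k} entries")
            if any(p < 0 for p in probs):
                raise ConfigValidationError(f"{name} must be non-negative")
            if abs(sum(probs) - 1.0) > 1e-9:
                raise ConfigValidationError(f"{name} must sum to 1, got {sum(probs)}")
        if len(self.case_class_weights) != 5 or sum(self.case_class_weights) <= 0:
            raise ConfigValidationError("case_class_weights must be 5 positive weights")
        if self.pool_multiplier < 2:
            raise ConfigValidationError("pool_multiplier must be >= matching ratio (2)")
        if self.truncation_sds <= 0:
            raise ConfigValidationError("truncation_sds must be > 0")
        if not 0 <= self.control_age_jitter <= 3 or not 0 <= self.control_bmi_jitter <= 3:
            raise ConfigValidationError("control jitters must lie within the matching tolerances [0, 3]")

    # -- JSON round-trip -------------------------------------------------

    def to_dict(self) -> dict:
        d = asdict(self)
        for group in ("case", "control"):
            d[group]["by_class"] = {
                cls.value: asdict(cp) for cls, cp in getattr(self, group).by_class.items()
            }
        for key in ("type_probabilities", "stage_probabilities", "case_class_weights"):
            d[key] = list(d[key])
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "GeneratorConfig":
        def group(gd: dict) -> GroupParams:
            by_class = {
                BmiClass(k): ClassParams(**v) for k, v in gd["by_class"].items()
            }
            rest = {k: v for k, v in gd.items() if k != "by_class"}
            return GroupParams(by_class=by_class, **rest)

        return cls(
            case=group(d["case"]),
            control=group(d["control"]),
            type_probabilities=tuple(d["type_probabilities"]),
            stage_probabilities=tuple(d["stage_probabilities"]),
            case_class_weights=tuple(d["case_class_weights"]),
            pool_multiplier=d.get("pool_multiplier", 4),
            control_age_jitter=d.get("control_age_jitter", 2.0),
            control_bmi_jitter=d.get("control_bmi_jitter", 2.0),
            truncation_sds=d.get("truncation_sds", 4.0),
            seed=d.get("seed"),
        )

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "GeneratorConfig":
        return cls.from_dict(json.loads(Path(path).read_text()))


def default_config() -> GeneratorConfig:
    """Default parameters calibrated to the published group summaries.

    Case/control leg FM shares 0.451 (0.050) / 0.354 (0.055), arm shares
    0.106 (0.016) / 0.107 (0.013), gynoid shares 0.194 / 0.177; per-class
    age, BMI and FMI as published.  Head FM share is fixed at 0.02 (so
    legs+arms+trunk carries ~0.98 of total FM); bone mass fraction and the
    head LM shares are calibrated so that derived ALMI and trunk LM shares
    land on the published group values.
    """
    case_classes = {
        BmiClass.NORMAL_WEIGHT: ClassParams(31, 9, 23.2, 1.5, 18.0, 25.0, 8.06, 1.25),
        BmiClass.OVERWEIGHT: ClassParams(40, 9, 27.2, 1.5, 25.0, 30.0, 11.27, 1.63),
        BmiClass.OBESITY_I: ClassParams(42, 14, 32.0, 1.2, 30.0, 35.0, 14.86, 1.21),
        BmiClass.OBESITY_II: ClassParams(45, 14, 35.7, 0.7, 35.0, 40.0, 16.99, 1.24),
        BmiClass.OBESITY_III: ClassParams(45, 13, 49.1, 11.3, 40.0, 60.0, 23.63, 1.27),
    }
    control_classes = {
        BmiClass.NORMAL_WEIGHT: ClassParams(36, 10, 22.4, 1.4, 18.0, 25.0, 7.26, 1.33),
        BmiClass.OVERWEIGHT: ClassParams(41, 11, 27.4, 1.4, 25.0, 30.0, 10.95, 1.51),
        BmiClass.OBESITY_I: ClassParams(44, 14, 31.9, 1.4, 30.0, 35.0, 14.00, 1.18),
        BmiClass.OBESITY_II: ClassParams(42, 8, 36.4, 1.0, 35.0, 40.0, 17.37, 1.30),
        BmiClass.OBESITY_III: ClassParams(39, 6, 44.1, 4.8, 40.0, 60.0, 22.53, 1.30),
    }
    case = GroupParams(
        height_mean=1.66,
        height_sd=0.065,
        leg_fm_share_mean=0.451,
        leg_fm_share_sd=0.050,
        arm_fm_share_mean=0.106,
        arm_fm_share_sd=0.016,
        head_fm_share=0.02,
        gynoid_fm_share_mean=0.194,
        gynoid_fm_share_sd=0.018,
        android_fm_frac_mean=0.155,
        android_fm_frac_sd=0.03,
        leg_lm_share_mean=0.378,
        leg_lm_share_sd=0.052,
        arm_lm_share_mean=0.104,
        arm_lm_share_sd=0.017,
        head_lm_share=0.057,
        gynoid_lm_share_mean=0.155,
        gynoid_lm_share_sd=0.029,
        android_lm_frac_mean=0.150,
        android_lm_frac_sd=0.020,
        bone_mass_fraction=0.056,
        bmd_mean=1.12,
        bmd_sd=0.09,
        by_class=case_classes,
    )
    control = GroupParams(
        height_mean=1.66,
        height_sd=0.065,
        leg_fm_share_mean=0.354,
        leg_fm_share_sd=0.055,
        arm_fm_share_mean=0.107,
        arm_fm_share_sd=0.013,
        head_fm_share=0.02,
        gynoid_fm_share_mean=0.177,
        gynoid_fm_share_sd=0.023,
        android_fm_frac_mean=0.155,
        android_fm_frac_sd=0.03,
        leg_lm_share_mean=0.357,
        leg_lm_share_sd=0.018,
        arm_lm_share_mean=0.109,
        arm_lm_share_sd=0.009,
        head_lm_share=0.071,
        gynoid_lm_share_mean=0.154,
        gynoid_lm_share_sd=0.009,
        android_lm_frac_mean=0.151,
        android_lm_frac_sd=0.020,
        bone_mass_fraction=0.059,
        bmd_mean=1.12,
        bmd_sd=0.09,
        by_class=control_classes,
    )
    return GeneratorConfig(
        case=case,
        control=control,
        # observed frequencies 3/11/29/31/0 of 74 and 14/39/19/2 of 74
        type_probabilities=(3 / 74, 11 / 74, 29 / 74, 31 / 74, 0.0),
        stage_probabilities=(14 / 74, 39 / 74, 19 / 74, 2 / 74),
        case_class_weights=(13, 26, 20, 5, 10),
    )


def _trunc_normal(
    rng: np.random.Generator,
    mean: float,
    sd: float,
    lo: float = -np.inf,
    hi: float = np.inf,
    nsd: float = 4.0,
) -> float:
    """Draw from N(mean, sd) truncated to [mean - nsd*sd, mean + nsd*sd] ∩ [lo, hi]."""
    if sd == 0:
        if not lo <= mean <= hi:
            raise ValueError("degenerate draw outside bounds")
        return mean
    a = max(lo, mean - nsd * sd)
    b = min(hi, mean + nsd * sd)
    if a > b:
        raise ValueError(f"empty truncation interval [{a}, {b}]")
    for _ in range(100_000):
        x = rng.normal(mean, sd)
        if a <= x <= b:
            return x
    raise RuntimeError("truncated-normal rejection sampling failed to converge")


_rejection_rate_cache: dict[tuple, float] = {}


def _trunk_rejection_rate(leg_mean, leg_sd, arm_mean, arm_sd, head_share) -> float:
    """Estimated probability that a share draw leaves a non-positive trunk.

    Deterministic probe (fixed internal seed) so that the miscalibration
    check does not perturb, and is not perturbed by, the caller's stream.
    """
    key = (leg_mean, leg_sd, arm_mean, arm_sd, head_share)
    if key not in _rejection_rate_cache:
        probe = np.random.default_rng(987654321)
        legs = probe.normal(leg_mean, leg_sd, size=4000)
        arms = probe.normal(arm_mean, arm_sd, size=4000)
        trunk = 1.0 - legs - arms - head_share
        _rejection_rate_cache[key] = float(np.mean(trunk <= _SHARE_EPS))
    return _rejection_rate_cache[key]


def _draw_shares(
    rng: np.random.Generator,
    leg_mean: float,
    leg_sd: float,
    arm_mean: float,
    arm_sd: float,
    head_share: float,
    nsd: float,
    what: str,
) -> tuple[float, float, float]:
    """Draw (legs, arms, trunk) shares; trunk is the remainder after head."""
    rate = _trunk_rejection_rate(leg_mean, leg_sd, arm_mean, arm_sd, head_share)
    if rate > 0.01:
        raise MiscalibratedConfigError(
            f"{what} share parameters leave trunk <= 0 in {rate:.1%} of draws (> 1%)"
        )
    for _ in range(1000):
        legs = _trunc_normal(rng, leg_mean, leg_sd, lo=_SHARE_EPS, hi=1 - _SHARE_EPS, nsd=nsd)
        arms = _trunc_normal(rng, arm_mean, arm_sd, lo=_SHARE_EPS, hi=1 - _SHARE_EPS, nsd=nsd)
        trunk = 1.0 - legs - arms - head_share
        if trunk > _SHARE_EPS:
            return legs, arms, trunk
    raise MiscalibratedConfigError(f"{what} share draws never produced a positive trunk share")


def _generate(
    config: GeneratorConfig,
    group: str,
    bmi_class: BmiClass,
    rng: np.random.Generator,
    record_id: str,
    age: float | None = None,
    bmi: float | None = None,
) -> ParticipantRecord:
    g = config.case if group == "case" else config.control
    cp = g.by_class[bmi_class]
    nsd = config.truncation_sds

    if age is None:
        age = _trunc_normal(rng, cp.age_mean, cp.age_sd, lo=18.0, nsd=nsd)
    if bmi is None:
        # upper bound nudged below the class boundary (half-open intervals)
        bmi = _trunc_normal(rng, cp.bmi_mean, cp.bmi_sd, lo=cp.bmi_lo, hi=cp.bmi_hi - 1e-9, nsd=nsd)
    height = _trunc_normal(rng, g.height_mean, g.height_sd, lo=1.2, hi=2.2, nsd=nsd)
    h2 = height * height
    weight = bmi * h2

    fmi_cap = bmi * (1.0 - g.bone_mass_fraction) - 0.5  # keep lean mass positive
    fmi = _trunc_normal(rng, cp.fmi_mean, cp.fmi_sd, lo=0.5, hi=fmi_cap, nsd=nsd)
    fm_total = fmi * h2
    bone_total = g.bone_mass_fraction * weight
    lm_total = weight - fm_total - bone_total
    if lm_total <= 0:
        raise MiscalibratedConfigError(f"non-positive lean mass for {record_id}")

    leg_s, arm_s, trunk_s = _draw_shares(
        rng, g.leg_fm_share_mean, g.leg_fm_share_sd,
        g.arm_fm_share_mean, g.arm_fm_share_sd, g.head_fm_share, nsd, "FM",
    )
    android_frac = _trunc_normal(
        rng, g.android_fm_frac_mean, g.android_fm_frac_sd, lo=_SHARE_EPS, hi=1 - _SHARE_EPS, nsd=nsd
    )
    gynoid_s = _trunc_normal(
        rng, g.gynoid_fm_share_mean, g.gynoid_fm_share_sd, lo=_SHARE_EPS, hi=1 - _SHARE_EPS, nsd=nsd
    )
    fm = RegionMasses(
        legs=leg_s * fm_total,
        arms=arm_s * fm_total,
        trunk=trunk_s * fm_total,
        android=android_frac * trunk_s * fm_total,
        gynoid=gynoid_s * fm_total,
        head=g.head_fm_share * fm_total,
        total=fm_total,
    )

    leg_ls, arm_ls, trunk_ls = _draw_shares(
        rng, g.leg_lm_share_mean, g.leg_lm_share_sd,
        g.arm_lm_share_mean, g.arm_lm_share_sd, g.head_lm_share, nsd, "LM",
    )
    android_lfrac = _trunc_normal(
        rng, g.android_lm_frac_mean, g.android_lm_frac_sd, lo=_SHARE_EPS, hi=1 - _SHARE_EPS, nsd=nsd
    )
    gynoid_ls = _trunc_normal(
        rng, g.gynoid_lm_share_mean, g.gynoid_lm_share_sd, lo=_SHARE_EPS, hi=1 - _SHARE_EPS, nsd=nsd
    )
    lm = RegionMasses(
        legs=leg_ls * lm_total,
        arms=arm_ls * lm_total,
        trunk=trunk_ls * lm_total,
        android=android_lfrac * trunk_ls * lm_total,
        gynoid=gynoid_ls * lm_total,
        head=g.head_lm_share * lm_total,
        total=lm_total,
    )

    bmd = _trunc_normal(rng, g.bmd_mean, g.bmd_sd, lo=0.5, hi=2.0, nsd=nsd)
    bone_area = bone_total * 1000.0 / bmd  # cm^2

    lipedema_type = lipedema_stage = None
    if group == "case":
        lipedema_type = int(rng.choice(5, p=np.asarray(config.type_probabilities))) + 1
        lipedema_stage = int(rng.choice(4, p=np.asarray(config.stage_probabilities))) + 1

    return ParticipantRecord(
        id=record_id,
        group=group,
        age=float(age),
        height_m=float(height),
        weight_kg=float(weight),
        fm=fm,
        lm=lm,
        bone_mass_total_kg=float(bone_total),
        bone_area_cm2=float(bone_area),
        lipedema_type=lipedema_type,
        lipedema_stage=lipedema_stage,
    )


def generate_participant(
    config: GeneratorConfig,
    group: str,
    bmi_class: BmiClass,
    rng: np.random.Generator,
    record_id: str = "participant",
) -> ParticipantRecord:
    """Generate one participant record for the given group and WHO class."""
    if group not in ("case", "control"):
        raise ValueError(f"group must be case|control, got {group!r}")
    if bmi_class not in CLASS_ORDER:
        raise ValueError(f"unknown BMI class {bmi_class!r}")
    return _generate(config, group, bmi_class, rng, record_id)


def _apportion(weights, n: int) -> list[int]:
    """Largest-remainder apportionment of n among the weight vector."""
    total = float(sum(weights))
    quotas = [n * w / total for w in weights]
    counts = [int(np.floor(q)) for q in quotas]
    remainder = n - sum(counts)
    order = sorted(range(len(weights)), key=lambda i: quotas[i] - counts[i], reverse=True)
    for i in order[:remainder]:
        counts[i] += 1
    return counts


def generate_cohort(
    config: GeneratorConfig,
    n_cases: int,
    seed: int | None = None,
) -> list[ParticipantRecord]:
    """Generate ``n_cases`` cases plus ``pool_multiplier * n_cases`` controls.

    Deterministic for a fixed seed (``seed`` overrides ``config.seed``).
    Control ages and BMIs are jittered copies of case values, so the pool
    spans the case ranges and 1:2 matching at the default tolerances is
    feasible by construction.
    """
    if n_cases < 1:
        raise ValueError("n_cases must be >= 1")
    if seed is None:
        seed = config.seed
    rng = np.random.default_rng(seed)
    width = max(4, len(str(n_cases * config.pool_multiplier)))

    counts = _apportion(config.case_class_weights, n_cases)
    cases: list[ParticipantRecord] = []
    i = 0
    for cls, count in zip(CLASS_ORDER, counts):
        for _ in range(count):
            i += 1
            cases.append(_generate(config, "case", cls, rng, f"case-{i:0{width}d}"))

    controls: list[ParticipantRecord] = []
    j = 0
    aj, bj = config.control_age_jitter, config.control_bmi_jitter
    for case in cases:
        for _ in range(config.pool_multiplier):
            j += 1
            age = max(18.0, case.age + rng.uniform(-aj, aj))
            bmi = max(18.0, case.bmi + rng.uniform(-bj, bj))
            cls = classify_bmi(bmi)
            controls.append(
                _generate(config, "control", cls, rng, f"ctrl-{j:0{width}d}", age=age, bmi=bmi)
            )
    return cases + controls


def split_cohort(records) -> tuple[list[ParticipantRecord], list[ParticipantRecord]]:
    """Split a record list into (cases, controls)."""
    cases = [r for r in records if r.group == "case"]
    controls = [r for r in records if r.group == "control"]
    return cases, controls
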