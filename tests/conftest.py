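"""Shared fixtures: seeded synthetic cohorts and record builders."""

from __future__ import annotations

import numpy as np
import pytest

from lipedex.composition import ParticipantRecord, RegionMasses
from lipedex.matching import match_controls
from lipedex.simulate import (
    CLASS_ORDER,
    _apportion,
    _generate,
    default_config,
    generate_cohort,
    split_cohort,
)
from lipedex.stats import panel_frame, run_comparison_battery

SEED = 42


def make_record(
    record_id: str = "p1",
    group: str = "control",
    age: float = 40.0,
    bmi: float = 25.0,
    height: float = 1.60,
    leg_share: float = 0.40,
    **overrides,
):
    """Minimal valid participant record with controllable age/BMI/leg share."""
    h2 = height * height
    weight = bmi * h2
    fm_total = 0.40 * weight
    lm_total = 0.55 * weight
    bone = 0.05 * weight
    arm_share, head_share = 0.10, 0.02
    trunk_share = 1.0 - leg_share - arm_share - head_share
    fm = RegionMasses(
        legs=leg_share * fm_total, arms=arm_share * fm_total,
        trunk=trunk_share * fm_total, android=0.15 * trunk_share * fm_total,
        gynoid=0.18 * fm_total, head=head_share * fm_total, total=fm_total,
    )
    lm = RegionMasses(
        legs=0.36 * lm_total, arms=0.11 * lm_total, trunk=0.46 * lm_total,
        android=0.07 * lm_total, gynoid=0.15 * lm_total,
        head=0.07 * lm_total, total=lm_total,
    )
    kwargs = dict(
        id=record_id, group=group, age=age, height_m=height, weight_kg=weight,
        fm=fm, lm=lm, bone_mass_total_kg=bone, bone_area_cm2=bone * 1000 / 1.1,
    )
    if group == "case":
        kwargs.update(lipedema_type=3, lipedema_stage=2)
    kwargs.update(overrides)
    return ParticipantRecord(**kwargs)


def generate_group(config, group: str, n: int, seed: int):
    """n records for one group with the default case BMI-class mix."""
    rng = np.random.default_rng(seed)
    counts = _apportion(config.case_class_weights, n)
    records = []
    for cls, count in zip(CLASS_ORDER, counts):
        for _ in range(count):
            records.append(_generate(config, group, cls, rng, f"{group}-{len(records):05d}"))
    return records


@pytest.fixture(scope="session")
def default_cfg():
    return default_config()


@pytest.fixture(scope="session")
def cohort74(default_cfg):
    return generate_cohort(default_cfg, 74, seed=SEED)


@pytest.fixture(scope="session")
def matched(cohort74):
    cases, pool = split_cohort(cohort74)
    return match_controls(cases, pool, ratio=2, age_tol=3.0, bmi_tol=3.0)


@pytest.fixture(scope="session")
def battery(matched):
    return run_comparison_battery(matched)


@pytest.fixture(scope="session")
def cases_10k(default_cfg):
    return generate_group(default_cfg, "case", 10_000, seed=123)


@pytest.fixture(scope="session")
def controls_10k(default_cfg):
    return generate_group(default_cfg, "control", 10_000, seed=124)


@pytest.fixture(scope="session")
def cases_10k_panel(cases_10k):
    return panel_frame(cases_10k)


@pytest.fixture(scope="session")
def controls_10k_panel(controls_10k):
    return panel_frame(controls_10k)
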