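"""CSV participant tables (the package's sole table format).

One row per participant; header required; decimal point; UTF-8.  Reading
validates every row and reports malformed rows with their CSV line numbers;
write followed by read is the identity (floats round-trip exactly via
shortest-repr formatting).
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .composition import ParticipantRecord, RegionMasses

__all__ = ["PARTICIPANT_COLUMNS", "SchemaError", "TableValidationError",
           "read_participants", "write_participants", "participants_frame"]

PARTICIPANT_COLUMNS: tuple[str, ...] = (
    "id", "group", "age", "height_m", "weight_kg",
    "fm_legs", "fm_arms", "fm_trunk", "fm_android", "fm_gynoid", "fm_head", "fm_total",
    "lm_legs", "lm_arms", "lm_trunk", "lm_android", "lm_gynoid", "lm_head", "lm_total",
    "bone_mass_total_kg", "bone_area_cm2", "lipedema_type", "lipedema_stage",
)

_FLOAT_COLUMNS = PARTICIPANT_COLUMNS[2:21]


class SchemaError(ValueError):
    """Raised when required columns are missing."""


class TableValidationError(ValueError):
    """Raised when one or more rows fail validation (line numbers included)."""


def participants_frame(records: Iterable[ParticipantRecord]) -> pd.DataFrame:
    """Records as a DataFrame in the canonical column order."""
    rows = []
    for r in records:
        rows.append({
            "id": r.id, "group": r.group, "age": r.age,
            "height_m": r.height_m, "weight_kg": r.weight_kg,
            **{f"fm_{k}": getattr(r.fm, k) for k in
               ("legs", "arms", "trunk", "android", "gynoid", "head", "total")},
            **{f"lm_{k}": getattr(r.lm, k) for k in
               ("legs", "arms", "trunk", "android", "gynoid", "head", "total")},
            "bone_mass_total_kg": r.bone_mass_total_kg,
            "bone_area_cm2": r.bone_area_cm2,
            "lipedema_type": r.lipedema_type,
            "lipedema_stage": r.lipedema_stage,
        })
    return pd.DataFrame(rows, columns=list(PARTICIPANT_COLUMNS))


def write_participants(records: Sequence[ParticipantRecord], path: str | Path) -> None:
    """Write records to CSV (empty cells for absent type/stage)."""
    frame = participants_frame(records)
    frame["lipedema_type"] = frame["lipedema_type"].astype("Int64")
    frame["lipedema_stage"] = frame["lipedema_stage"].astype("Int64")
    frame.to_csv(path, index=False)


def read_participants(path: str | Path) -> list[ParticipantRecord]:
    """Read and validate a participant CSV; errors carry CSV line numbers."""
    frame = pd.read_csv(path, dtype={"id": str, "group": str}, float_precision="round_trip")
    missing = [c for c in PARTICIPANT_COLUMNS if c not in frame.columns]
    if missing:
        raise SchemaError(f"missing required columns: {', '.join(missing)}")

    records: list[ParticipantRecord] = []
    errors: list[str] = []
    for idx, row in frame.iterrows():
        line = idx + 2  # header is line 1
        try:
            values = {}
            for col in _FLOAT_COLUMNS:
                raw = row[col]
                values[col] = float(raw)
                if pd.isna(values[col]):
                    raise ValueError(f"column {col} is missing/NaN")
            def _opt_int(col: str) -> int | None:
                raw = row[col]
                return None if pd.isna(raw) else int(raw)
            fm = RegionMasses(
                legs=values["fm_legs"], arms=values["fm_arms"], trunk=values["fm_trunk"],
                android=values["fm_android"], gynoid=values["fm_gynoid"],
                head=values["fm_head"], total=values["fm_total"],
            )
            lm = RegionMasses(
                legs=values["lm_legs"], arms=values["lm_arms"], trunk=values["lm_trunk"],
                android=values["lm_android"], gynoid=values["lm_gynoid"],
                head=values["lm_head"], total=values["lm_total"],
            )
            records.append(ParticipantRecord(
                id=str(row["id"]),
                group=str(row["group"]),
                age=values["age"],
                height_m=values["height_m"],
                weight_kg=values["weight_kg"],
                fm=fm,
                lm=lm,
                bone_mass_total_kg=values["bone_mass_total_kg"],
                bone_area_cm2=values["bone_area_cm2"],
                lipedema_type=_opt_int("lipedema_type"),
                lipedema_stage=_opt_int("lipedema_stage"),
            ))
        except (ValueError, TypeError) as exc:
            errors.append(f"line {line} (id={row.get('id', '?')}): {exc}")
    if errors:
        raise TableValidationError(
            f"{len(errors)} malformed row(s):\n" + "\n".join(errors)
        )
    return records
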