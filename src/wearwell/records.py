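"""Wearable measurement data model and CSV I/O.

A :class:`DailyRecord` holds one person-day of device measurements
(steps, activity time by intensity, sleep phases, heart-rate summaries);
a :class:`PersonProfile` carries the socio-demographics (age, gender)
that the scoring rules stratify on.  Heart-rate zone classification and
the crude ``220 - age`` maximum-heart-rate estimate live here too, since
both operate on raw measurements rather than on period summaries.
"""

from __future__ import annotations

import dataclasses
import datetime as _dt
import logging
import math
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "Gender",
    "PersonProfile",
    "DailyRecord",
    "IntradayRecord",
    "HeartRateZone",
    "HR_ZONES",
    "DAILY_VARIABLES",
    "SchemaError",
    "read_daily_records",
    "write_daily_records",
    "read_profiles",
    "write_profiles",
    "records_to_frame",
    "classify_hr_zone",
    "estimate_hr_max",
]


class SchemaError(ValueError):
    """Raised when an input file violates the measurement schema."""


class Gender(str, Enum):
    MALE = "male"
    FEMALE = "female"
    UNSPECIFIED = "unspecified"


#: Measured variables emitted by the supported tracker devices, with the
#: value class used for validation: "time" (seconds, >= 0), "count"
#: (non-negative integer), "length" (metres), "rate" (bpm, in (0, 250)),
#: "energy" (calories) or "score" (dimensionless, >= 0).
DAILY_VARIABLES: dict[str, str] = {
    "still_calories": "energy",
    "total_calories": "energy",
    "walk_steps": "count",
    "walk_distance": "length",
    "stairs_floor_changes_up": "count",
    "elevation": "length",
    "still_time": "time",
    "physicalactivity_soft_time": "time",
    "physicalactivity_moderate_time": "time",
    "physicalactivity_intense_time": "time",
    "physicalactivity_calories": "energy",
    "heartrate_cardio_time": "time",
    "heartrate_peak_time": "time",
    "heartrate_resting": "rate",
    "heartrate_avg": "rate",
    "heartrate_max": "rate",
    "sleep_time": "time",
    "sleep_efficiency": "score",
    "sleep_deep_count": "count",
    "sleep_deep_time": "time",
    "sleep_light_count": "count",
    "sleep_light_time": "time",
    "sleep_rem_count": "count",
    "sleep_rem_time": "time",
    "sleep_wake_count": "count",
    "sleep_wake_time": "time",
    "sleep_awake_time": "time",
    "sleep_awake_count": "count",
    "sleep_restless_time": "time",
    "sleep_restless_count": "count",
    "sleep_asleep_time": "time",
    "sleep_asleep_count": "count",
}

_SLEEP_PHASE_TIMES = (
    "sleep_deep_time",
    "sleep_light_time",
    "sleep_rem_time",
    "sleep_wake_time",
    "sleep_awake_time",
    "sleep_restless_time",
    "sleep_asleep_time",
)


@dataclass(frozen=True)
class PersonProfile:
    """Static per-person attributes used for norm stratification."""

    person_id: str
    age: int
    gender: Gender = Gender.UNSPECIFIED

    def __post_init__(self) -> None:
        if not self.person_id:
            raise ValueError("person_id must be non-empty")
        if not 0 <= self.age <= 130:
            raise ValueError(f"age {self.age} outside [0, 130]")
        if not isinstance(self.gender, Gender):
            object.__setattr__(self, "gender", Gender(self.gender))


def _make_daily_record_fields():
    flds = [
        ("person_id", str, dataclasses.MISSING),
        ("date", _dt.date, dataclasses.MISSING),
    ]
    for name in DAILY_VARIABLES:
        flds.append((name, "float | None", field(default=None)))
    return flds


def _validate_daily(rec: "DailyRecord") -> None:
    for name, kind in DAILY_VARIABLES.items():
        v = getattr(rec, name)
        if v is None:
            continue
        if isinstance(v, float) and math.isnan(v):
            object.__setattr__(rec, name, None)
            continue
        if kind == "count":
            if v < 0 or float(v) != int(v):
                raise ValueError(f"{name}={v} must be a non-negative integer")
        elif kind == "rate":
            if not 0 < v < 250:
                raise ValueError(f"{name}={v} outside (0, 250) bpm")
        else:
            if v < 0:
                raise ValueError(f"{name}={v} must be >= 0")
    total = rec.sleep_time
    if total is not None:
        for phase in _SLEEP_PHASE_TIMES:
            v = getattr(rec, phase)
            if v is not None and v > total:
                raise ValueError(
                    f"{phase}={v} exceeds sleep_time={total}"
                )


DailyRecord = dataclasses.make_dataclass(
    "DailyRecord",
    _make_daily_record_fields(),
    frozen=True,
    namespace={"__post_init__": _validate_daily},
)
DailyRecord.__doc__ = (
    "One person-day of wearable measurements; every measured variable is "
    "optional and absent (None) when the device reported nothing."
)


@dataclass(frozen=True)
class IntradayRecord:
    """A single sub-daily sample of one measured variable."""

    person_id: str
    timestamp: _dt.datetime
    variable: str
    value: float

    def __post_init__(self) -> None:
        if self.variable not in DAILY_VARIABLES:
            raise ValueError(f"unknown variable {self.variable!r}")
        if self.value < 0:
            raise ValueError("value must be >= 0")
        if self.timestamp.second or self.timestamp.microsecond:
            raise ValueError("intra-daily resolution is one minute")


@dataclass(frozen=True)
class HeartRateZone:
    """A named fractional band of the maximum heart rate."""

    name: str
    lower_frac: float
    upper_frac: float


#: Default device zone definitions: peak 85-100 % of hr_max, cardio
#: 70-84 %, fat burn 50-69 %.  Bands are closed on the lower bound of the
#: higher zone so the three zones tile (0.5, 1.0] without gaps.
HR_ZONES: tuple[HeartRateZone, ...] = (
    HeartRateZone("peak", 0.85, 1.00),
    HeartRateZone("cardio", 0.70, 0.84),
    HeartRateZone("fat_burn", 0.50, 0.69),
)


def classify_hr_zone(hr: float, hr_max: float) -> str:
    """Name the target zone containing ``hr`` given a personal ``hr_max``.

    Returns ``"peak"``, ``"cardio"``, ``"fat_burn"`` or ``"below"`` (under
    50 % of ``hr_max``).  Fractions at a zone boundary belong to the
    higher zone.
    """
    if hr_max <= 0:
        raise ValueError("hr_max must be positive")
    if hr <= 0:
        raise ValueError("hr must be positive")
    frac = hr / hr_max
    if frac >= 0.85:
        return "peak"
    if frac >= 0.70:
        return "cardio"
    if frac >= 0.50:
        return "fat_burn"
    return "below"


def estimate_hr_max(profile: PersonProfile, observed_max: float | None = None) -> float:
    """Maximum heart rate: the device-observed maximum when available,
    otherwise the crude age formula ``220 - age``."""
    if observed_max is not None:
        if not 0 < observed_max < 250:
            raise ValueError(f"observed_max={observed_max} outside (0, 250)")
        return float(observed_max)
    if profile.age is None:  # pragma: no cover - dataclass forbids it
        raise ValueError("age required to estimate hr_max")
    return float(220 - profile.age)


# ---------------------------------------------------------------------------
# CSV I/O.  The interchange dialect is one row per person-day with columns
# person_id, date, <measured variable names>; empty cells mean "not measured".

def read_daily_records(
    path: str | Path, schema_strict: bool = True
) -> list[DailyRecord]:
    """Read person-day records from CSV.

    Unknown columns raise :class:`SchemaError` when ``schema_strict``,
    otherwise they are dropped with a warning.  Empty cells become absent
    fields (never zero).  Malformed dates, invariant violations and
    duplicate person-days raise :class:`SchemaError` naming the row.
    """
    df = pd.read_csv(path, dtype={"person_id": str})
    required = {"person_id", "date"}
    if not required.issubset(df.columns):
        raise SchemaError(f"missing required columns {required - set(df.columns)}")
    unknown = [c for c in df.columns if c not in DAILY_VARIABLES and c not in required]
    if unknown:
        if schema_strict:
            raise SchemaError(f"unknown columns {unknown}")
        logger.warning("ignoring unknown columns %s", unknown)
        df = df.drop(columns=unknown)

    records: list[DailyRecord] = []
    seen: set[tuple[str, _dt.date]] = set()
    var_cols = [c for c in df.columns if c in DAILY_VARIABLES]
    for i, row in enumerate(df.itertuples(index=False), start=2):
        row_d = row._asdict()
        try:
            day = _dt.date.fromisoformat(str(row_d["date"]))
        except ValueError as exc:
            raise SchemaError(f"row {i}: malformed date {row_d['date']!r}") from exc
        key = (row_d["person_id"], day)
        if key in seen:
            raise SchemaError(f"row {i}: duplicate person-day {key}")
        seen.add(key)
        values = {}
        for c in var_cols:
            v = row_d[c]
            if v is None or (isinstance(v, float) and math.isnan(v)):
                continue
            values[c] = float(v)
        try:
            records.append(DailyRecord(person_id=row_d["person_id"], date=day, **values))
        except ValueError as exc:
            raise SchemaError(f"row {i}: {exc}") from exc
    return records


def records_to_frame(records: Iterable[DailyRecord]) -> pd.DataFrame:
    """Tabulate records as a DataFrame (absent fields become NaN)."""
    rows = [dataclasses.asdict(r) for r in records]
    df = pd.DataFrame(rows, columns=["person_id", "date", *DAILY_VARIABLES])
    return df


def write_daily_records(records: Sequence[DailyRecord], path: str | Path) -> None:
    """Write records to the canonical CSV dialect, dropping all-empty columns."""
    df = records_to_frame(records)
    keep = ["person_id", "date"] + [
        c for c in DAILY_VARIABLES if df[c].notna().any()
    ]
    df[keep].to_csv(path, index=False)


def read_profiles(path: str | Path) -> list[PersonProfile]:
    """Read person profiles from CSV with columns person_id, age, gender."""
    df = pd.read_csv(path, dtype={"person_id": str})
    if not {"person_id", "age"}.issubset(df.columns):
        raise SchemaError("profiles CSV needs person_id and age columns")
    profiles = []
    for i, row in enumerate(df.itertuples(index=False), start=2):
        gender = getattr(row, "gender", "unspecified")
        if gender is None or (isinstance(gender, float) and math.isnan(gender)):
            gender = "unspecified"
        try:
            profiles.append(
                PersonProfile(person_id=row.person_id, age=int(row.age), gender=Gender(gender))
            )
        except ValueError as exc:
            raise SchemaError(f"row {i}: {exc}") from exc
    return profiles


def write_profiles(profiles: Sequence[PersonProfile], path: str | Path) -> None:
    pd.DataFrame(
        [
            {"person_id": p.person_id, "age": p.age, "gender": p.gender.value}
            for p in profiles
        ]
    ).to_csv(path, index=False)


def read_intraday(path: str | Path) -> list[IntradayRecord]:
    """Read intra-daily samples (person_id, timestamp, variable, value)."""
    df = pd.read_csv(path, dtype={"person_id": str})
    out = []
    for i, row in enumerate(df.itertuples(index=False), start=2):
        try:
            out.append(
                IntradayRecord(
                    person_id=row.person_id,
                    timestamp=_dt.datetime.fromisoformat(str(row.timestamp)),
                    variable=row.variable,
                    value=float(row.value),
                )
            )
        except ValueError as exc:
            raise SchemaError(f"row {i}: {exc}") from exc
    return out
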