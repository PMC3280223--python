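"""Victim records and registry file I/O.

A registry is a flat CSV, one row per fatality as recorded by one source
(hospital trauma registry or police accident reports). Fields may be missing;
an empty cell denotes a missing value. Timestamps are ISO-8601 at minute
resolution; a bare date (``YYYY-MM-DD``) records a known incident date with
an unknown time of day, which the linkage stage treats as time-missing.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import datetime
from pathlib import Path
from typing import Iterable, Optional

import pandas as pd

HOSPITAL = "hospital"
POLICE = "police"
SOURCES = (HOSPITAL, POLICE)

GENDERS = ("male", "female")
ROAD_USERS = ("pedestrian", "bicyclist", "motorcyclist", "driver", "passenger", "other")
ROAD_TRAFFIC_INJURY = "road_traffic_injury"

#: CSV schema, in column order, shared by both sources.
SCHEMA = (
    "record_id",
    "gender",
    "age",
    "road_user",
    "victims_in_incident",
    "vehicles_in_incident",
    "event_datetime",
    "location_code",
)

#: Fields reported by :func:`missingness_profile`. "date" and "time" split the
#: combined timestamp: a date-only record counts as time-missing but not
#: date-missing.
PROFILE_FIELDS = (
    "gender",
    "age",
    "road_user",
    "victims_in_incident",
    "vehicles_in_incident",
    "date",
    "time",
    "location_code",
)


class RegistryError(ValueError):
    """Raised when a registry file or record violates the schema."""


@dataclass(frozen=True)
class VictimRecord:
    """One fatality as recorded by one source; any field except the id may be missing."""

    record_id: str
    source: str
    gender: Optional[str] = None
    age: Optional[int] = None
    road_user: Optional[str] = None
    victims_in_incident: Optional[int] = None
    vehicles_in_incident: Optional[int] = None
    event_datetime: Optional[datetime] = None
    date_only: bool = False
    location_code: Optional[str] = None
    mechanism: str = ROAD_TRAFFIC_INJURY

    def __post_init__(self) -> None:
        if not self.record_id:
            raise RegistryError("record_id must be non-empty")
        if self.source not in SOURCES:
            raise RegistryError(f"unknown source {self.source!r}")
        if self.gender is not None and self.gender not in GENDERS:
            raise RegistryError(f"unknown gender {self.gender!r}")
        if self.road_user is not None and self.road_user not in ROAD_USERS:
            raise RegistryError(f"unknown road_user {self.road_user!r}")
        if self.age is not None and not 0 <= self.age <= 120:
            raise RegistryError(f"age {self.age} outside [0, 120]")
        if self.victims_in_incident is not None and self.victims_in_incident < 1:
            raise RegistryError("victims_in_incident must be >= 1 on a fatality record")
        if self.vehicles_in_incident is not None and self.vehicles_in_incident < 0:
            raise RegistryError("vehicles_in_incident must be >= 0")
        if self.date_only and self.event_datetime is None:
            raise RegistryError("date_only set without an event date")

    @property
    def time_known(self) -> bool:
        """True when the record carries a usable time of day."""
        return self.event_datetime is not None and not self.date_only


@dataclass
class RegistryFile:
    """An ordered, validated collection of records from one source."""

    source: str
    records: list[VictimRecord]
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.source not in SOURCES:
            raise RegistryError(f"unknown source {self.source!r}")
        seen: set[str] = set()
        for rec in self.records:
            if rec.source != self.source:
                raise RegistryError(
                    f"record {rec.record_id} tagged {rec.source!r} in a {self.source!r} registry"
                )
            if rec.record_id in seen:
                raise RegistryError(f"duplicate record_id {rec.record_id!r}")
            seen.add(rec.record_id)
        self.provenance.setdefault("n_records", len(self.records))
        self.provenance.setdefault("missingness", missingness_profile(self))

    def __len__(self) -> int:
        return len(self.records)

    def by_id(self) -> dict[str, VictimRecord]:
        return {rec.record_id: rec for rec in self.records}


def _parse_int(value: str, column: str, row: int) -> Optional[int]:
    if value == "":
        return None
    try:
        return int(value)
    except ValueError:
        raise RegistryError(f"row {row}: {column} {value!r} is not an integer") from None


def _parse_datetime(value: str, row: int) -> tuple[Optional[datetime], bool]:
    if value == "":
        return None, False
    try:
        stamp = datetime.fromisoformat(value)
    except ValueError:
        raise RegistryError(f"row {row}: bad event_datetime {value!r}") from None
    # A bare date means the time of day was not recorded.
    return stamp, len(value) == 10


def _parse_enum(value: str, allowed: tuple[str, ...], column: str, row: int) -> Optional[str]:
    if value == "" or value == "unreported":
        return None
    if value not in allowed:
        raise RegistryError(f"row {row}: {column} {value!r} not in {allowed}")
    return value


def read_registry(path: str | Path, source: str) -> RegistryFile:
    """Read and validate one registry CSV.

    Empty cells become missing values; the literal ``unreported`` in an enum
    column also maps to missing. Malformed enum or integer values raise
    :class:`RegistryError` rather than being coerced.
    """
    path = Path(path)
    frame = pd.read_csv(path, dtype=str, keep_default_na=False)
    unknown = set(frame.columns) - set(SCHEMA)
    if unknown:
        raise RegistryError(f"unknown columns {sorted(unknown)} in {path}")
    absent = set(SCHEMA) - set(frame.columns)
    if absent:
        raise RegistryError(f"missing columns {sorted(absent)} in {path}")

    records = []
    for i, row in enumerate(frame.itertuples(index=False)):
        stamp, date_only = _parse_datetime(row.event_datetime, i)
        records.append(
            VictimRecord(
                record_id=row.record_id,
                source=source,
                gender=_parse_enum(row.gender, GENDERS, "gender", i),
                age=_parse_int(row.age, "age", i),
                road_user=_parse_enum(row.road_user, ROAD_USERS, "road_user", i),
                victims_in_incident=_parse_int(row.victims_in_incident, "victims_in_incident", i),
                vehicles_in_incident=_parse_int(row.vehicles_in_incident, "vehicles_in_incident", i),
                event_datetime=stamp,
                date_only=date_only,
                location_code=row.location_code or None,
            )
        )
    return RegistryFile(source=source, records=records, provenance={"path": str(path)})


def _format_datetime(rec: VictimRecord) -> str:
    if rec.event_datetime is None:
        return ""
    if rec.date_only:
        return rec.event_datetime.strftime("%Y-%m-%d")
    return rec.event_datetime.strftime("%Y-%m-%dT%H:%M")


def write_registry(registry: RegistryFile, path: str | Path) -> None:
    """Write a registry back to CSV in the canonical schema (lossless round-trip)."""
    rows = []
    for rec in registry.records:
        rows.append(
            {
                "record_id": rec.record_id,
                "gender": rec.gender or "",
                "age": "" if rec.age is None else str(rec.age),
                "road_user": rec.road_user or "",
                "victims_in_incident": ""
                if rec.victims_in_incident is None
                else str(rec.victims_in_incident),
                "vehicles_in_incident": ""
                if rec.vehicles_in_incident is None
                else str(rec.vehicles_in_incident),
                "event_datetime": _format_datetime(rec),
                "location_code": rec.location_code or "",
            }
        )
    pd.DataFrame(rows, columns=list(SCHEMA)).to_csv(path, index=False)


def missingness_profile(registry: RegistryFile | Iterable[VictimRecord]) -> dict[str, int]:
    """Count missing values per field.

    The combined timestamp is reported as two entries: ``date`` (no timestamp
    at all) and ``time`` (no timestamp, or date-only).
    """
    records = registry.records if isinstance(registry, RegistryFile) else list(registry)
    counts = dict.fromkeys(PROFILE_FIELDS, 0)
    for rec in records:
        counts["gender"] += rec.gender is None
        counts["age"] += rec.age is None
        counts["road_user"] += rec.road_user is None
        counts["victims_in_incident"] += rec.victims_in_incident is None
        counts["vehicles_in_incident"] += rec.vehicles_in_incident is None
        counts["date"] += rec.event_datetime is None
        counts["time"] += not rec.time_known
        counts["location_code"] += rec.location_code is None
    return counts
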