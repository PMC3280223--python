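"""Deterministic registries emulating the motivating study's published counts.

The real hospital and police files were never deposited, but the study's
summary table fixes, for every stratification factor, how many records were
matched, police-only and hospital-only in each stratum. This module builds a
synthetic pair of registries whose records carry exactly those stratum
marginals, so that running the default linkage + stratified estimation on
them reproduces the published table cell-for-cell — an executable end-to-end
check of the whole pipeline.

Construction guarantees the linkage outcome analytically:

* every true pair shares a location code unique to it, and every unlinked
  record has its own location code, so a cross pair can only become a
  candidate if location is missing;
* event times are spaced 9 hours apart (three times the matching tolerance),
  so any location-missing cross pair still disagrees on time;
* hospital records with two or more missing fields are confined to the
  unmatched set (a pair with two unevaluable criteria is never a candidate
  under the one-missing-allowed rule).

The hospital side also carries the study's missingness profile: 46 missing
ages, 7 missing times, 4 missing locations, with 2 records missing age+time
and 1 missing age+time+location (53 records with any missing field), plus 3
unreported genders (2 on the police side), matching the published
missing-gender stratum.
"""

from __future__ import annotations

from datetime import datetime, timedelta
from pathlib import Path
from typing import Optional

from .records import HOSPITAL, POLICE, RegistryFile, VictimRecord
from .estimators import CaptureCounts

#: Published per-stratum (d1, d2, m) triples the fixture reproduces.
TABLE1_COUNTS: dict[str, dict[str, CaptureCounts]] = {
    "gender": {
        "male": CaptureCounts(73, 124, 31),
        "female": CaptureCounts(21, 17, 5),
        "missing": CaptureCounts(3, 2, 0),
    },
    "road_user": {
        "pedestrian": CaptureCounts(44, 77, 18),
        "bicyclist": CaptureCounts(13, 25, 8),
        "motorcyclist": CaptureCounts(2, 1, 1),
        "driver": CaptureCounts(7, 20, 4),
        "passenger": CaptureCounts(27, 18, 4),
        "other/missing": CaptureCounts(4, 2, 1),
    },
    "victims_per_incident": {
        "1-2": CaptureCounts(62, 115, 28),
        ">=3": CaptureCounts(35, 28, 8),
    },
    "vehicles_per_incident": {
        "0-1": CaptureCounts(80, 119, 33),
        ">=2": CaptureCounts(17, 24, 3),
    },
}

TABLE1_POOLED = CaptureCounts(d1=97, d2=143, m=36)

#: Published rounded estimates (point, ci_low, ci_high) for the pooled
#: analysis and rounded stratified totals, used by the test-suite.
TABLE1_POOLED_ESTIMATE = (380, 298, 463)
TABLE1_TOTALS = {
    "gender": 364,
    "road_user": 370,
    "victims_per_incident": 366,
    "vehicles_per_incident": 396,
}

_START = datetime(2008, 7, 1, 8, 0)
_SPACING_HOURS = 9


def _expand(pairs: list[tuple[object, int]]) -> list:
    out: list = []
    for value, count in pairs:
        out.extend([value] * count)
    return out


# Per-group attribute marginals (order of expansion is arbitrary; any joint
# satisfying the marginals reproduces the published per-factor strata).
_MATCHED = {
    "gender": _expand([("male", 31), ("female", 5)]),
    "road_user": _expand(
        [("pedestrian", 18), ("bicyclist", 8), ("motorcyclist", 1), ("driver", 4), ("passenger", 4), ("other", 1)]
    ),
    "victims": _expand([(1, 28), (3, 8)]),
    "vehicles": _expand([(1, 33), (2, 3)]),
}
_POLICE_ONLY = {
    "gender": _expand([("male", 93), ("female", 12), (None, 2)]),
    "road_user": _expand(
        [("pedestrian", 59), ("bicyclist", 17), ("driver", 16), ("passenger", 14), ("other", 1)]
    ),
    "victims": _expand([(1, 87), (3, 20)]),
    "vehicles": _expand([(1, 86), (2, 21)]),
}
_HOSPITAL_ONLY = {
    "gender": _expand([("male", 42), ("female", 16), (None, 3)]),
    "road_user": _expand(
        [("pedestrian", 26), ("bicyclist", 5), ("motorcyclist", 1), ("driver", 3), ("passenger", 23), ("other", 3)]
    ),
    "victims": _expand([(2, 34), (4, 27)]),
    "vehicles": _expand([(1, 47), (2, 14)]),
}

# Hospital-side missingness overlay, by position within each group. Matched
# records carry at most one missing field each; multi-missing records are
# hospital-only.
_MATCHED_AGE_MISSING = set(range(0, 17))
_MATCHED_TIME_MISSING = set(range(17, 20))
_MATCHED_LOC_MISSING = set(range(20, 22))
_HONLY_AGE_MISSING = set(range(0, 26)) | {28, 29, 30}
_HONLY_TIME_MISSING = {26, 28, 29, 30}
_HONLY_LOC_MISSING = {27, 30}


def _age(slot: int) -> int:
    return 18 + (slot * 7) % 50


def _slot_time(slot: int) -> datetime:
    return _START + timedelta(hours=_SPACING_HOURS * slot)


def _record(
    record_id: str,
    source: str,
    group: dict,
    i: int,
    slot: int,
    location: str,
    age_missing: bool = False,
    time_missing: bool = False,
    loc_missing: bool = False,
) -> VictimRecord:
    stamp = _slot_time(slot)
    if time_missing:
        stamp = stamp.replace(hour=0, minute=0)
    return VictimRecord(
        record_id=record_id,
        source=source,
        gender=group["gender"][i],
        age=None if age_missing else _age(slot),
        road_user=group["road_user"][i],
        victims_in_incident=group["victims"][i],
        vehicles_in_incident=group["vehicles"][i],
        event_datetime=stamp,
        date_only=time_missing,
        location_code=None if loc_missing else location,
    )


def table1_registries() -> tuple[RegistryFile, RegistryFile, list[tuple[str, str]]]:
    """Build the (hospital, police, true_links) triple emulating the study.

    Deterministic; 97 hospital and 143 police records whose default linkage
    yields exactly the 36 published matches and whose stratified counts equal
    the published table for all four factors.
    """
    hospital: list[VictimRecord] = []
    police: list[VictimRecord] = []
    links: list[tuple[str, str]] = []

    for i in range(36):
        slot = i
        loc = f"T1M{i:03d}"
        hid, pid = f"H{i:03d}", f"P{i:03d}"
        hospital.append(
            _record(
                hid, HOSPITAL, _MATCHED, i, slot, loc,
                age_missing=i in _MATCHED_AGE_MISSING,
                time_missing=i in _MATCHED_TIME_MISSING,
                loc_missing=i in _MATCHED_LOC_MISSING,
            )
        )
        police.append(_record(pid, POLICE, _MATCHED, i, slot, loc))
        links.append((hid, pid))

    for i in range(107):
        slot = 36 + i
        police.append(_record(f"P{36 + i:03d}", POLICE, _POLICE_ONLY, i, slot, f"T1P{i:03d}"))

    for i in range(61):
        slot = 143 + i
        hospital.append(
            _record(
                f"H{36 + i:03d}", HOSPITAL, _HOSPITAL_ONLY, i, slot, f"T1H{i:03d}",
                age_missing=i in _HONLY_AGE_MISSING,
                time_missing=i in _HONLY_TIME_MISSING,
                loc_missing=i in _HONLY_LOC_MISSING,
            )
        )

    h_registry = RegistryFile(source=HOSPITAL, records=hospital, provenance={"origin": "table1-fixture"})
    p_registry = RegistryFile(source=POLICE, records=police, provenance={"origin": "table1-fixture"})
    return h_registry, p_registry, links


def write_table1_fixture(out_dir: str | Path) -> tuple[Path, Path]:
    """Write the fixture registries as CSVs; returns the two paths."""
    from .records import write_registry

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    h, p, _ = table1_registries()
    h_path = out_dir / "hospital_table1.csv"
    p_path = out_dir / "police_table1.csv"
    write_registry(h, h_path)
    write_registry(p, p_path)
    return h_path, p_path
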