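"""Fuzzy cross-source record linkage.

A hospital record and a police record are compared on five criteria: gender,
age (within a tolerance, default 5 years), injury mechanism, location code
(exact equality), and event time (absolute difference within a tolerance,
default 3 hours). A criterion with a missing value on either side is
*unevaluable*. A pair is a candidate match when no criterion disagrees and at
most ``allow_missing`` criteria are unevaluable (default 1; the strict
sensitivity mode sets 0 and additionally requires age to agree).

Candidates are resolved to a one-to-one matching greedily in order of
increasing discrepancy (normalised age + time deviation, plus 1 per
unevaluable criterion), with record ids breaking ties, so the result is
deterministic and auditable.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import pandas as pd

from .records import RegistryFile, VictimRecord

AGREE = "agree"
DISAGREE = "disagree"
UNEVALUABLE = "unevaluable"

CRITERIA = ("gender", "age", "mechanism", "location", "time")


@dataclass(frozen=True)
class MatchCriteria:
    age_tolerance: float = 5.0
    time_tolerance_hours: float = 3.0
    allow_missing: int = 1
    require_age: bool = False

    def __post_init__(self) -> None:
        if self.age_tolerance < 0 or self.time_tolerance_hours < 0:
            raise ValueError("tolerances must be non-negative")
        if self.allow_missing not in (0, 1):
            raise ValueError("allow_missing must be 0 or 1")

    def strict(self) -> "MatchCriteria":
        """The age-required, no-missing-allowed variant used for sensitivity analysis."""
        return MatchCriteria(
            age_tolerance=self.age_tolerance,
            time_tolerance_hours=self.time_tolerance_hours,
            allow_missing=0,
            require_age=True,
        )


@dataclass(frozen=True)
class PairEvaluation:
    hospital_id: str
    police_id: str
    verdicts: dict[str, str]
    missing_used: int
    discrepancy: float

    def is_candidate(self, criteria: MatchCriteria) -> bool:
        if any(v == DISAGREE for v in self.verdicts.values()):
            return False
        if self.missing_used > criteria.allow_missing:
            return False
        if criteria.require_age and self.verdicts["age"] != AGREE:
            return False
        return True


@dataclass
class LinkageResult:
    """A one-to-one set of cross-source matched pairs."""

    pairs: list[PairEvaluation]
    n_hospital: int
    n_police: int

    def __post_init__(self) -> None:
        h_ids = [p.hospital_id for p in self.pairs]
        p_ids = [p.police_id for p in self.pairs]
        if len(set(h_ids)) != len(h_ids) or len(set(p_ids)) != len(p_ids):
            raise ValueError("matching is not one-to-one")

    @property
    def m(self) -> int:
        return len(self.pairs)

    @property
    def unmatched_hospital(self) -> int:
        return self.n_hospital - self.m

    @property
    def unmatched_police(self) -> int:
        return self.n_police - self.m

    def matched_hospital_ids(self) -> set[str]:
        return {p.hospital_id for p in self.pairs}

    def matched_police_ids(self) -> set[str]:
        return {p.police_id for p in self.pairs}


def _compare_equal(a, b) -> tuple[str, float]:
    if a is None or b is None:
        return UNEVALUABLE, 1.0
    return (AGREE, 0.0) if a == b else (DISAGREE, 0.0)


def _compare_within(a: Optional[float], b: Optional[float], tol: float) -> tuple[str, float]:
    if a is None or b is None:
        return UNEVALUABLE, 1.0
    delta = abs(a - b)
    if delta <= tol:  # inclusive: "within five years" admits exactly five
        return AGREE, delta / tol if tol > 0 else 0.0
    return DISAGREE, 0.0


def evaluate_pair(
    h: VictimRecord, p: VictimRecord, criteria: MatchCriteria = MatchCriteria()
) -> PairEvaluation:
    """Evaluate the five match criteria for one hospital/police record pair."""
    verdicts: dict[str, str] = {}
    discrepancy = 0.0

    verdicts["gender"], pen = _compare_equal(h.gender, p.gender)
    discrepancy += pen if verdicts["gender"] == UNEVALUABLE else 0.0

    v, dev = _compare_within(h.age, p.age, criteria.age_tolerance)
    verdicts["age"] = v
    discrepancy += dev if v == AGREE else (1.0 if v == UNEVALUABLE else 0.0)

    verdicts["mechanism"], pen = _compare_equal(h.mechanism, p.mechanism)
    discrepancy += pen if verdicts["mechanism"] == UNEVALUABLE else 0.0

    verdicts["location"], pen = _compare_equal(h.location_code, p.location_code)
    discrepancy += pen if verdicts["location"] == UNEVALUABLE else 0.0

    h_time = h.event_datetime.timestamp() / 3600.0 if h.time_known else None
    p_time = p.event_datetime.timestamp() / 3600.0 if p.time_known else None
    v, dev = _compare_within(h_time, p_time, criteria.time_tolerance_hours)
    verdicts["time"] = v
    discrepancy += dev if v == AGREE else (1.0 if v == UNEVALUABLE else 0.0)

    missing_used = sum(v == UNEVALUABLE for v in verdicts.values())
    return PairEvaluation(
        hospital_id=h.record_id,
        police_id=p.record_id,
        verdicts=verdicts,
        missing_used=missing_used,
        discrepancy=discrepancy,
    )


def link_records(
    hospital: RegistryFile,
    police: RegistryFile,
    criteria: MatchCriteria = MatchCriteria(),
) -> LinkageResult:
    """Build the one-to-one cross-source matching.

    All candidate pairs are sorted by (discrepancy, hospital_id, police_id)
    and accepted greedily while both records remain unmatched.
    """
    candidates = []
    for h in hospital.records:
        for p in police.records:
            ev = evaluate_pair(h, p, criteria)
            if ev.is_candidate(criteria):
                candidates.append(ev)
    candidates.sort(key=lambda ev: (ev.discrepancy, ev.hospital_id, ev.police_id))

    used_h: set[str] = set()
    used_p: set[str] = set()
    pairs = []
    for ev in candidates:
        if ev.hospital_id in used_h or ev.police_id in used_p:
            continue
        pairs.append(ev)
        used_h.add(ev.hospital_id)
        used_p.add(ev.police_id)
    return LinkageResult(pairs=pairs, n_hospital=len(hospital), n_police=len(police))


def capture_counts(link: LinkageResult):
    """The (d1, d2, m) triple a linkage implies."""
    from .estimators import CaptureCounts

    return CaptureCounts(d1=link.n_hospital, d2=link.n_police, m=link.m)


def write_links(link: LinkageResult, path: str | Path) -> None:
    pd.DataFrame(
        [
            {
                "hospital_id": p.hospital_id,
                "police_id": p.police_id,
                "missing_used": p.missing_used,
                "discrepancy": p.discrepancy,
            }
            for p in link.pairs
        ],
        columns=["hospital_id", "police_id", "missing_used", "discrepancy"],
    ).to_csv(path, index=False)
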