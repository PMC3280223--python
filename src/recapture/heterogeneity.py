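"""Stratification factors and tests of source dependence.

Two-source estimation assumes the sources capture independently. When capture
probabilities differ across subgroups (heterogeneity) and both sources share
that structure, the pooled estimate is biased. Chi-squared tests on the
stratum x source table of captured records flag factors along which the two
sources' samples differ; stratifying on such a factor and summing subgroup
estimates mitigates the bias.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .estimators import CaptureCounts
from .linkage import LinkageResult
from .records import RegistryFile, VictimRecord

logger = logging.getLogger(__name__)

MISSING = "missing"

#: Stratum labels per factor, in reporting order.
FACTOR_LABELS: dict[str, tuple[str, ...]] = {
    "gender": ("male", "female", MISSING),
    "road_user": (
        "pedestrian",
        "bicyclist",
        "motorcyclist",
        "driver",
        "passenger",
        "other/missing",
    ),
    "victims_per_incident": ("1-2", ">=3", MISSING),
    "vehicles_per_incident": ("0-1", ">=2", MISSING),
}

FACTORS = tuple(FACTOR_LABELS)


@dataclass(frozen=True)
class HeterogeneityTest:
    factor: str
    table: pd.DataFrame  # strata x (hospital, police) counts of captured records
    statistic: float
    dof: int
    p_value: float


def assign_stratum(record: VictimRecord, factor: str) -> str:
    """Map one record to its stratum label; the mapping is total."""
    if factor == "gender":
        return record.gender if record.gender is not None else MISSING
    if factor == "road_user":
        if record.road_user is None or record.road_user == "other":
            return "other/missing"
        return record.road_user
    if factor == "victims_per_incident":
        if record.victims_in_incident is None:
            return MISSING
        return "1-2" if record.victims_in_incident <= 2 else ">=3"
    if factor == "vehicles_per_incident":
        if record.vehicles_in_incident is None:
            return MISSING
        return "0-1" if record.vehicles_in_incident <= 1 else ">=2"
    raise ValueError(f"unknown stratification factor {factor!r}")


def assign_strata(registry: RegistryFile, factor: str) -> dict[str, str]:
    """Stratum label for every record in a registry, keyed by record id."""
    return {rec.record_id: assign_stratum(rec, factor) for rec in registry.records}


def stratified_capture_counts(
    link: LinkageResult,
    hospital: RegistryFile,
    police: RegistryFile,
    factor: str,
) -> list[tuple[str, CaptureCounts]]:
    """Split (d1, d2, m) by stratum; the splits sum back to the pooled triple.

    A matched pair is assigned the stratum of its *police-side* record (the
    police source had complete data in the motivating study); pairs whose two
    records disagree on the stratum are logged. Strata with no records in
    either source are dropped.
    """
    h_by_id = hospital.by_id()
    p_by_id = police.by_id()
    labels = FACTOR_LABELS[factor]

    m_s = dict.fromkeys(labels, 0)
    h_only = dict.fromkeys(labels, 0)
    p_only = dict.fromkeys(labels, 0)

    matched_h = link.matched_hospital_ids()
    matched_p = link.matched_police_ids()
    for pair in link.pairs:
        try:
            h_rec = h_by_id[pair.hospital_id]
            p_rec = p_by_id[pair.police_id]
        except KeyError as exc:
            raise ValueError(f"linkage references unknown record_id {exc.args[0]!r}") from None
        h_label = assign_stratum(h_rec, factor)
        p_label = assign_stratum(p_rec, factor)
        if h_label != p_label:
            logger.info(
                "stratum conflict for pair (%s, %s) on %s: hospital=%s police=%s; using police",
                pair.hospital_id, pair.police_id, factor, h_label, p_label,
            )
        m_s[p_label] += 1
    for rec in hospital.records:
        if rec.record_id not in matched_h:
            h_only[assign_stratum(rec, factor)] += 1
    for rec in police.records:
        if rec.record_id not in matched_p:
            p_only[assign_stratum(rec, factor)] += 1

    out = []
    for label in labels:
        d1 = m_s[label] + h_only[label]
        d2 = m_s[label] + p_only[label]
        if d1 == 0 and d2 == 0:
            continue
        out.append((label, CaptureCounts(d1=d1, d2=d2, m=m_s[label])))
    return out


def source_table(hospital: RegistryFile, police: RegistryFile, factor: str) -> pd.DataFrame:
    """Stratum x source contingency table of captured record counts."""
    labels = FACTOR_LABELS[factor]
    table = pd.DataFrame(0, index=list(labels), columns=["hospital", "police"])
    for rec in hospital.records:
        table.loc[assign_stratum(rec, factor), "hospital"] += 1
    for rec in police.records:
        table.loc[assign_stratum(rec, factor), "police"] += 1
    return table


def source_heterogeneity_test(
    hospital: RegistryFile, police: RegistryFile, factor: str
) -> HeterogeneityTest:
    """Pearson chi-squared test comparing the factor's distribution across sources.

    All-zero strata are dropped before testing; no continuity correction is
    applied. A warning is emitted when any expected cell falls below 5 (the
    test is still performed).
    """
    if len(hospital) == 0 or len(police) == 0:
        raise ValueError("both registries must be non-empty")
    table = source_table(hospital, police, factor)
    table = table.loc[(table.sum(axis=1) > 0)]
    if len(table) < 2:
        raise ValueError(f"factor {factor!r} has fewer than two non-empty strata")
    stat, p, dof, expected = stats.chi2_contingency(table.to_numpy(), correction=False)
    if np.any(expected < 5):
        warnings.warn(
            f"chi-squared for {factor!r}: some expected cell counts are below 5",
            stacklevel=2,
        )
    return HeterogeneityTest(
        factor=factor, table=table, statistic=float(stat), dof=int(dof), p_value=float(p)
    )
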