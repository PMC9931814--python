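"""Partial PHASES scoring (size + location + age) and risk grouping.

Only the size, location and age components of the clinical PHASES rupture
risk score are used; population, hypertension and prior hemorrhage are
deliberately left out. Fusiform and extracranial carotid aneurysms are
excluded from risk grouping altogether.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import pandas as pd

__all__ = ["AneurysmRecord", "RiskAssignment", "partial_phases", "risk_group",
           "LOCATIONS", "score_table", "read_record_table"]

LOCATIONS = ("ICA", "MCA", "ACA/Pcom/Posterior", "extracranial-ICA")

_LOCATION_POINTS = {"ICA": 0, "MCA": 2, "ACA/Pcom/Posterior": 4}


@dataclass(frozen=True)
class AneurysmRecord:
    location: str
    shape: str            # saccular | fusiform
    max_diameter: float   # mm
    patient_age: float    # years

    def __post_init__(self) -> None:
        if self.location not in LOCATIONS:
            raise ValueError(f"unknown location {self.location!r}")
        if self.shape not in ("saccular", "fusiform"):
            raise ValueError(f"unknown shape {self.shape!r}")
        if self.max_diameter <= 0:
            raise ValueError("max_diameter must be > 0")
        if self.patient_age < 0:
            raise ValueError("age must be >= 0")


@dataclass(frozen=True)
class RiskAssignment:
    partial_score: int | None
    group: str            # low | medium | excluded
    exclusion_reason: str  # fusiform | extracranial | none


def _size_points(d: float) -> int:
    # bin edges: [0,7), [7,10), [10,20), [20,inf) mm
    if d < 7.0:
        return 0
    if d < 10.0:
        return 3
    if d < 20.0:
        return 6
    return 10


def partial_phases(rec: AneurysmRecord) -> int:
    """Size + location + age points of the PHASES table."""
    if rec.shape == "fusiform" or rec.location == "extracranial-ICA":
        raise ValueError("record is excluded from risk scoring; use risk_group")
    points = _size_points(rec.max_diameter)
    points += _LOCATION_POINTS[rec.location]
    if rec.patient_age >= 70:
        points += 1
    return points


def risk_group(rec: AneurysmRecord) -> RiskAssignment:
    """Low (score <= 4) / medium (score > 4) grouping with exclusions."""
    if rec.shape == "fusiform":
        return RiskAssignment(None, "excluded", "fusiform")
    if rec.location == "extracranial-ICA":
        return RiskAssignment(None, "excluded", "extracranial")
    score = partial_phases(rec)
    return RiskAssignment(score, "low" if score <= 4 else "medium", "none")


def score_table(records: list[AneurysmRecord]) -> pd.DataFrame:
    """Per-aneurysm table of scores and groups (TSV-friendly)."""
    rows = []
    for i, rec in enumerate(records):
        ra = risk_group(rec)
        rows.append({
            "lesion": i,
            "shape": rec.shape,
            "size_mm": rec.max_diameter,
            "location": rec.location,
            "age": rec.patient_age,
            "partial_score": ra.partial_score,
            "risk_group": ra.group,
            "exclusion_reason": ra.exclusion_reason,
        })
    return pd.DataFrame(rows)


def read_record_table(path: str | Path) -> list[AneurysmRecord]:
    """Read a TSV with columns shape, size_mm, location, age."""
    df = pd.read_csv(path, sep="\t")
    return [AneurysmRecord(location=r["location"], shape=r["shape"],
                           max_diameter=float(r["size_mm"]),
                           patient_age=float(r["age"]))
            for _, r in df.iterrows()]
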