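"""Clinical records: relapse-free survival derivation and cohort selection.

RFS (relapse-free survival) is the number of days from initial treatment to
the earliest of a new tumor event or death; patients with neither are
censored at last follow-up.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Sequence

import pandas as pd

from .matrix import NA_STRINGS

#: conventional five-year follow-up window, in days (365 x 5)
FIVE_YEARS_DAYS = 1825

CLINICAL_COLUMNS = [
    "patient_id",
    "vital_status",
    "days_to_death",
    "days_to_last_followup",
    "days_to_new_tumor_event",
    "pathologic_stage",
]


class RecordRejected(ValueError):
    """A clinical record that cannot yield an RFS time."""


@dataclass
class ClinicalRecord:
    """One patient's survival fields plus derived RFS days and event flag.

    ``pathologic_stage`` is carried as metadata only; no computation uses it.
    """

    patient_id: str
    vital_status: str  # "alive" | "dead"
    days_to_death: float | None
    days_to_last_followup: float | None
    days_to_new_tumor: float | None
    rfs_days: float
    event: bool
    pathologic_stage: str | None = None

    def __post_init__(self) -> None:
        if self.rfs_days < 0:
            raise ValueError(f"{self.patient_id}: rfs_days must be nonnegative")


def _present(x: float | None) -> bool:
    return x is not None and not (isinstance(x, float) and math.isnan(x))


def derive_rfs(
    patient_id: str,
    vital_status: str = "alive",
    days_to_death: float | None = None,
    days_to_last_followup: float | None = None,
    days_to_new_tumor: float | None = None,
    pathologic_stage: str | None = None,
) -> ClinicalRecord:
    """Derive RFS days and the event indicator from raw clinical fields.

    ``rfs_days`` is the minimum over the present event fields
    (days to new tumor event, days to death); if neither is present the
    patient is censored at last follow-up.  ``event`` is True exactly when an
    event field contributed the minimum.

    Raises
    ------
    RecordRejected
        If all three day fields are missing.
    """
    event_days = [d for d in (days_to_new_tumor, days_to_death) if _present(d)]
    if event_days:
        rfs, event = min(event_days), True
    elif _present(days_to_last_followup):
        rfs, event = float(days_to_last_followup), False
    else:
        raise RecordRejected(f"{patient_id}: all day fields missing")
    if rfs < 0:
        raise RecordRejected(f"{patient_id}: negative day value {rfs}")
    return ClinicalRecord(
        patient_id=str(patient_id),
        vital_status=str(vital_status).strip().lower(),
        days_to_death=days_to_death if _present(days_to_death) else None,
        days_to_last_followup=days_to_last_followup if _present(days_to_last_followup) else None,
        days_to_new_tumor=days_to_new_tumor if _present(days_to_new_tumor) else None,
        rfs_days=float(rfs),
        event=event,
        pathologic_stage=pathologic_stage,
    )


def select_five_year_cohort(
    records: Sequence[ClinicalRecord], window_days: int = FIVE_YEARS_DAYS
) -> list[ClinicalRecord]:
    """Keep patients whose five-year outcome is fully ascertained.

    Retained are (a) patients with an event at or before ``window_days`` and
    (b) patients followed to at least ``window_days`` without an event inside
    the window; the latter are administratively censored at the window
    (``rfs_days`` truncated, ``event`` False).  Patients censored before the
    window have unknown five-year status and are dropped.
    """
    kept: list[ClinicalRecord] = []
    for r in records:
        if r.event and r.rfs_days <= window_days:
            kept.append(r)
        elif r.rfs_days >= window_days:
            kept.append(replace(r, rfs_days=float(window_days), event=False))
    return kept


def _parse_day(v: object) -> float | None:
    s = str(v).strip()
    if s in NA_STRINGS:
        return None
    return float(s)


def read_clinical_table(path: str | Path) -> tuple[list[ClinicalRecord], list[tuple[str, str]]]:
    """Read a clinical TSV and derive RFS for every parseable row.

    Expected headers: ``patient_id``, ``vital_status``, ``days_to_death``,
    ``days_to_last_followup``, ``days_to_new_tumor_event`` and optionally
    ``pathologic_stage``.  Returns the accepted records and a list of
    ``(patient_id, reason)`` for rejected rows.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = {"patient_id", "vital_status"} - set(df.columns)
    if missing:
        raise ValueError(f"clinical table {path} lacks required columns: {sorted(missing)}")
    records: list[ClinicalRecord] = []
    rejected: list[tuple[str, str]] = []
    for _, row in df.iterrows():
        pid = str(row["patient_id"])
        try:
            records.append(
                derive_rfs(
                    patient_id=pid,
                    vital_status=row.get("vital_status", "alive"),
                    days_to_death=_parse_day(row.get("days_to_death", "")),
                    days_to_last_followup=_parse_day(row.get("days_to_last_followup", "")),
                    days_to_new_tumor=_parse_day(row.get("days_to_new_tumor_event", "")),
                    pathologic_stage=(str(row["pathologic_stage"]) if "pathologic_stage" in df.columns else None),
                )
            )
        except (RecordRejected, ValueError) as exc:
            rejected.append((pid, str(exc)))
    return records, rejected


def write_clinical_table(records: Sequence[ClinicalRecord], path: str | Path) -> None:
    """Write raw clinical fields in the TSV dialect ``read_clinical_table`` consumes."""
    def fmt(x: float | None) -> str:
        return "" if x is None else ("%g" % x)

    rows = [
        {
            "patient_id": r.patient_id,
            "vital_status": r.vital_status,
            "days_to_death": fmt(r.days_to_death),
            "days_to_last_followup": fmt(r.days_to_last_followup),
            "days_to_new_tumor_event": fmt(r.days_to_new_tumor),
            "pathologic_stage": r.pathologic_stage or "",
        }
        for r in records
    ]
    pd.DataFrame(rows, columns=CLINICAL_COLUMNS).to_csv(path, sep="\t", index=False)
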