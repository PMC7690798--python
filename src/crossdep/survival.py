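"""Survival variant of the bidirectional scores, Kaplan-Meier and log-rank.

The patient-cohort analogue replaces the efficacy axis with relapse-free
survival (RFS) days: predictivity contrasts mean alive days between high- and
low-expression patients, descriptivity contrasts expression between
long- and short-surviving patients.  These scores use the raw (post-
truncation) RFS days and ignore the censoring indicator by construction; the
event-aware complement is the Kaplan-Meier / log-rank path on the same
median-split expression groups.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test as _ll_logrank

from . import association
from .association import (
    AssociationRecord,
    HitCall,
    PairScore,
    STATUS_OK,
    call_hits,
    median_split,
)
from .clinical import ClinicalRecord
from .matrix import OmicsMatrix


@dataclass
class SurvivalPanel:
    """Patient expression matrix aligned with clinical records."""

    expression: OmicsMatrix
    records: list[ClinicalRecord]

    def __post_init__(self) -> None:
        ids = [r.patient_id for r in self.records]
        if ids != self.expression.sample_ids:
            raise ValueError("clinical records must align 1:1 with expression samples")

    @property
    def rfs_days(self) -> np.ndarray:
        return np.array([r.rfs_days for r in self.records], dtype=float)

    @property
    def events(self) -> np.ndarray:
        return np.array([r.event for r in self.records], dtype=bool)

    def subset_patients(self, patient_ids: Sequence[str]) -> "SurvivalPanel":
        by_id = {r.patient_id: r for r in self.records}
        return SurvivalPanel(
            expression=self.expression.subset_samples(list(patient_ids)),
            records=[by_id[p] for p in patient_ids],
        )


def build_survival_panel(
    expression: OmicsMatrix, records: Sequence[ClinicalRecord]
) -> SurvivalPanel:
    """Intersect an expression matrix with clinical records on patient id."""
    by_id = {r.patient_id: r for r in records}
    shared = [s for s in expression.sample_ids if s in by_id]
    if not shared:
        raise ValueError("no patients shared between expression matrix and clinical records")
    return SurvivalPanel(
        expression=expression.subset_samples(shared),
        records=[by_id[s] for s in shared],
    )


def survival_predictivity(
    expr_g: Sequence[float] | np.ndarray,
    rfs: Sequence[float] | np.ndarray,
    variant: str = "student",
) -> PairScore:
    """Mean alive-days difference between high- and low-expression patients.

    Shares the cell-line predictivity code path with alive days standing in
    for phenotypic efficacy.
    """
    return association.predictivity(expr_g, rfs, variant=variant)


def survival_descriptivity(
    expr_g: Sequence[float] | np.ndarray,
    rfs: Sequence[float] | np.ndarray,
    variant: str = "student",
) -> PairScore:
    """Mean expression difference between long- and short-surviving patients."""
    return association.descriptivity(expr_g, rfs, variant=variant)


@dataclass
class KMCurve:
    """Product-limit survival estimate at the distinct event times."""

    event_times: np.ndarray
    survival: np.ndarray
    at_risk: np.ndarray
    n_events: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time": self.event_times,
                "survival": self.survival,
                "at_risk": self.at_risk,
                "events": self.n_events,
            }
        )


def km_estimate(rfs: Sequence[float] | np.ndarray, event: Sequence[bool] | np.ndarray) -> KMCurve:
    """Kaplan-Meier estimate S(t) = prod_{t_i <= t} (1 - d_i / n_i).

    Censored subjects leave the risk set after their censoring time.  The
    curve is reported at the distinct event times only.
    """
    rfs = np.asarray(rfs, dtype=float)
    event = np.asarray(event, dtype=bool)
    if rfs.size == 0:
        raise ValueError("at least one subject required")
    if (rfs < 0).any():
        raise ValueError("negative survival times")
    kmf = KaplanMeierFitter()
    kmf.fit(rfs, event_observed=event)
    table = kmf.event_table
    ev = table[table["observed"] > 0]
    times = ev.index.to_numpy(dtype=float)
    surv = kmf.survival_function_at_times(times).to_numpy(dtype=float)
    return KMCurve(
        event_times=times,
        survival=surv,
        at_risk=ev["at_risk"].to_numpy(dtype=int),
        n_events=ev["observed"].to_numpy(dtype=int),
    )


def logrank_test(
    rfs_a: Sequence[float] | np.ndarray,
    event_a: Sequence[bool] | np.ndarray,
    rfs_b: Sequence[float] | np.ndarray,
    event_b: Sequence[bool] | np.ndarray,
) -> tuple[float, float]:
    """Two-group log-rank test (chi-square with 1 df, hypergeometric variance).

    Ties are handled by the simultaneous-event convention.  Returns
    ``(nan, nan)`` when no events are observed, where the test is undefined.
    """
    rfs_a = np.asarray(rfs_a, dtype=float)
    rfs_b = np.asarray(rfs_b, dtype=float)
    event_a = np.asarray(event_a, dtype=bool)
    event_b = np.asarray(event_b, dtype=bool)
    if rfs_a.size == 0 or rfs_b.size == 0:
        raise ValueError("both groups must be non-empty")
    if int(event_a.sum()) + int(event_b.sum()) == 0:
        return math.nan, math.nan
    res = _ll_logrank(rfs_a, rfs_b, event_observed_A=event_a, event_observed_B=event_b)
    return float(res.test_statistic), float(res.p_value)


def survival_scan(
    panel: SurvivalPanel,
    alpha_pred: float = 0.01,
    alpha_desc: float = 0.05,
    variant: str = "student",
    require_sign_concordance: bool = True,
) -> tuple[list[AssociationRecord], list[HitCall]]:
    """Genome-wide bidirectional survival scores with per-gene log-rank tests.

    For every gene: predictivity and descriptivity against RFS days, plus a
    log-rank test comparing the high- vs low-expression patient groups
    (median split) using the event indicator.  Hits pass the asymmetric
    thresholds (predictivity p < ``alpha_pred``, descriptivity p <
    ``alpha_desc``) with sign concordance, as in the cell-line hit call.
    """
    expr_vals = panel.expression.values
    rfs = panel.rfs_days
    events = panel.events
    records: list[AssociationRecord] = []
    for i, gene in enumerate(panel.expression.gene_ids):
        pr = survival_predictivity(expr_vals[i], rfs, variant=variant)
        de = survival_descriptivity(expr_vals[i], rfs, variant=variant)
        status = pr.status if pr.status != STATUS_OK else de.status
        if status != STATUS_OK:
            pr = PairScore(math.nan, math.nan, pr.n_high, pr.n_low, pr.status)
            de = PairScore(math.nan, math.nan, de.n_high, de.n_low, de.status)
        chi2 = p_lr = math.nan
        split = median_split(expr_vals[i])
        if split.status == "ok" and split.high_idx.size and split.low_idx.size:
            chi2, p_lr = logrank_test(
                rfs[split.high_idx], events[split.high_idx],
                rfs[split.low_idx], events[split.low_idx],
            )
        records.append(
            AssociationRecord(
                gene_id=gene,
                predictivity=pr.score,
                predictivity_p=pr.p,
                descriptivity=de.score,
                descriptivity_p=de.p,
                n_high_exp=pr.n_high,
                n_low_exp=pr.n_low,
                n_high_phe=de.n_high,
                n_low_phe=de.n_low,
                status=status,
                logrank_chi2=chi2,
                logrank_p=p_lr,
            )
        )
    hits = call_hits(
        records,
        alpha_pred=alpha_pred,
        alpha_desc=alpha_desc,
        require_sign_concordance=require_sign_concordance,
    )
    return records, hits


def km_by_expression(
    panel: SurvivalPanel, gene_id: str
) -> dict[str, KMCurve]:
    """KM curves for the high- and low-expression groups of one gene."""
    expr = panel.expression.gene_vector(gene_id)
    split = median_split(expr)
    if split.status != "ok":
        raise ValueError(f"{gene_id}: expression split is {split.status}")
    rfs, events = panel.rfs_days, panel.events
    return {
        "high": km_estimate(rfs[split.high_idx], events[split.high_idx]),
        "low": km_estimate(rfs[split.low_idx], events[split.low_idx]),
    }
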