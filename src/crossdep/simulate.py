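"""Synthetic paired panels and survival cohorts with planted ground truth.

The generators emulate the statistical structure the analysis assumes — log2
expression with gene-specific baselines, gene-level efficacy scores with
planted monotone expression-efficacy associations and missing entries, and a
patient cohort with exponential event times whose hazard depends on planted
prognostic genes — so every pipeline stage is testable without external
downloads.

Randomness is counter-based: gene ``g`` draws from an independent substream
keyed ``(seed, stream, g)``, so subsetting or reordering genes never
reshuffles the others.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .clinical import ClinicalRecord, derive_rfs
from .matrix import OmicsMatrix, PairedPanel, build_paired_panel
from .survival import SurvivalPanel

LABEL_NULL = "null"
LABEL_POSITIVE = "positive"
LABEL_NEGATIVE = "negative"
LABEL_PROGNOSTIC = "prognostic"


@dataclass
class SyntheticTruth:
    """Ground-truth label and effect size for one simulated gene."""

    gene_id: str
    label: str
    effect: float

    def __post_init__(self) -> None:
        if self.label == LABEL_NULL and self.effect != 0.0:
            raise ValueError("null genes must have zero effect")


@dataclass
class PanelSimConfig:
    """Conditions for a simulated expression/efficacy cell-line panel.

    Defaults describe a desk-scale colon-cancer-like screen: 2000 genes over
    40 cell lines, 25 positively and 25 negatively associated genes with an
    effect of 1.5 efficacy units per SD of expression against unit efficacy
    noise, and 10% missing efficacy entries.
    """

    n_genes: int = 2000
    n_samples: int = 40
    n_pos: int = 25
    n_neg: int = 25
    beta: float = 1.5
    expr_mu_range: tuple[float, float] = (2.0, 8.0)
    expr_sd: float = 1.0
    eff_mu: float = -0.5
    eff_sd: float = 1.0
    missing_rate: float = 0.1
    seed: int = 0

    def validate(self) -> None:
        if self.n_genes <= 0 or self.n_samples <= 0:
            raise ValueError("n_genes and n_samples must be positive")
        if self.n_pos < 0 or self.n_neg < 0 or self.n_pos + self.n_neg > self.n_genes:
            raise ValueError("n_pos + n_neg must not exceed n_genes")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ValueError("missing_rate must be in [0, 1)")
        if self.expr_sd <= 0 or self.eff_sd <= 0:
            raise ValueError("expr_sd and eff_sd must be positive")
        if self.expr_mu_range[0] > self.expr_mu_range[1]:
            raise ValueError("expr_mu_range must be (low, high)")


def _gene_ids(n: int) -> list[str]:
    return [f"G{i:05d} ({i + 1})" for i in range(n)]


def _gene_rng(seed: int, stream: int, gene: int) -> np.random.Generator:
    return np.random.default_rng([seed, stream, gene])


def _standardize(x: np.ndarray) -> np.ndarray:
    return (x - x.mean()) / x.std()


def simulate_paired_panel(cfg: PanelSimConfig) -> tuple[PairedPanel, list[SyntheticTruth]]:
    """Simulate a paired expression/efficacy panel with planted associations.

    Expression for gene g is Normal(mu_g, expr_sd) with mu_g uniform over
    ``expr_mu_range``.  Null-gene efficacy is Normal(eff_mu, eff_sd),
    independent of expression.  A planted gene adds ``s * beta * z`` where z
    is its standardized expression and s = +1 (positive label) or -1
    (negative).  Missing entries are planted uniformly at ``missing_rate`` in
    the efficacy matrix only.
    """
    cfg.validate()
    meta_rng = np.random.default_rng([cfg.seed, 0])
    genes = _gene_ids(cfg.n_genes)
    samples = [f"ACH-SIM{j:04d}" for j in range(cfg.n_samples)]
    mu = meta_rng.uniform(*cfg.expr_mu_range, size=cfg.n_genes)
    planted = meta_rng.permutation(cfg.n_genes)[: cfg.n_pos + cfg.n_neg]
    sign = np.zeros(cfg.n_genes)
    sign[planted[: cfg.n_pos]] = 1.0
    sign[planted[cfg.n_pos :]] = -1.0

    expr = np.empty((cfg.n_genes, cfg.n_samples))
    eff = np.empty((cfg.n_genes, cfg.n_samples))
    truths: list[SyntheticTruth] = []
    for g in range(cfg.n_genes):
        rng = _gene_rng(cfg.seed, 1, g)
        x = mu[g] + cfg.expr_sd * rng.standard_normal(cfg.n_samples)
        noise = cfg.eff_sd * rng.standard_normal(cfg.n_samples)
        y = cfg.eff_mu + sign[g] * cfg.beta * _standardize(x) + noise
        if cfg.missing_rate > 0:
            y[rng.random(cfg.n_samples) < cfg.missing_rate] = np.nan
        expr[g], eff[g] = x, y
        label = {1.0: LABEL_POSITIVE, -1.0: LABEL_NEGATIVE, 0.0: LABEL_NULL}[sign[g]]
        truths.append(SyntheticTruth(genes[g], label, sign[g] * cfg.beta))

    expression = OmicsMatrix(
        pd.DataFrame(expr, index=genes, columns=samples), "expression", "log2_expression"
    )
    efficacy = OmicsMatrix(
        pd.DataFrame(eff, index=genes, columns=samples), "shRNA", "dependency_score"
    )
    return build_paired_panel(expression, efficacy), truths


def truth_to_frame(truths: Sequence[SyntheticTruth]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "gene": [t.gene_id for t in truths],
            "label": [t.label for t in truths],
            "effect": [t.effect for t in truths],
        }
    )


def simulate_survival_cohort(
    n_patients: int = 200,
    n_genes: int = 1000,
    n_prognostic: int = 1,
    log_hazard_ratio: float = math.log(2.0),
    baseline_rate: float = 1.0 / 2000.0,
    censor_window: float = 3650.0,
    expr_mu_range: tuple[float, float] = (2.0, 8.0),
    expr_sd: float = 1.0,
    death_fraction: float = 0.3,
    seed: int = 0,
) -> tuple[SurvivalPanel, list[SyntheticTruth]]:
    """Simulate an expression + survival cohort with planted prognostic genes.

    Event times are exponential with patient rate
    ``baseline_rate * exp(log_hazard_ratio * sum_g z_g)`` over the planted
    genes' standardized expression z, so high expression of a prognostic gene
    shortens survival.  Censoring is independent and uniform on
    ``[0, censor_window]`` days.  Observed events are recorded as a new tumor
    event or (with probability ``death_fraction``) a death, and every patient
    is rebuilt through the raw-field RFS derivation so the clinical parsing
    path is exercised.
    """
    if n_patients <= 0 or n_genes <= 0 or n_prognostic < 0 or n_prognostic > n_genes:
        raise ValueError("invalid cohort dimensions")
    if baseline_rate <= 0 or censor_window <= 0:
        raise ValueError("baseline_rate and censor_window must be positive")
    if expr_sd <= 0:
        raise ValueError("expr_sd must be positive")

    meta_rng = np.random.default_rng([seed, 10])
    genes = _gene_ids(n_genes)
    patients = [f"PT-SIM{j:04d}" for j in range(n_patients)]
    mu = meta_rng.uniform(*expr_mu_range, size=n_genes)
    prognostic = set(meta_rng.permutation(n_genes)[:n_prognostic].tolist())

    expr = np.empty((n_genes, n_patients))
    truths: list[SyntheticTruth] = []
    z_sum = np.zeros(n_patients)
    for g in range(n_genes):
        rng = _gene_rng(seed, 11, g)
        x = mu[g] + expr_sd * rng.standard_normal(n_patients)
        expr[g] = x
        if g in prognostic:
            z_sum += _standardize(x)
            truths.append(SyntheticTruth(genes[g], LABEL_PROGNOSTIC, log_hazard_ratio))
        else:
            truths.append(SyntheticTruth(genes[g], LABEL_NULL, 0.0))

    event_rng = np.random.default_rng([seed, 12])
    rate = baseline_rate * np.exp(log_hazard_ratio * z_sum)
    t_event = event_rng.exponential(1.0 / rate)
    t_censor = event_rng.uniform(0.0, censor_window, size=n_patients)
    is_death = event_rng.random(n_patients) < death_fraction

    records: list[ClinicalRecord] = []
    for j, pid in enumerate(patients):
        followup = max(1.0, math.ceil(t_censor[j]))
        if t_event[j] <= t_censor[j]:
            day = max(1.0, math.ceil(t_event[j]))
            if is_death[j]:
                records.append(
                    derive_rfs(pid, "dead", days_to_death=day, days_to_last_followup=day)
                )
            else:
                records.append(
                    derive_rfs(
                        pid, "alive", days_to_new_tumor=day, days_to_last_followup=followup
                    )
                )
        else:
            records.append(derive_rfs(pid, "alive", days_to_last_followup=followup))

    expression = OmicsMatrix(
        pd.DataFrame(expr, index=genes, columns=patients), "expression", "log2_tpm"
    )
    return SurvivalPanel(expression=expression, records=records), truths
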