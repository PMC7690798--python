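"""Bidirectional cross-association scores between expression and efficacy.

For each gene, samples are dichotomized at the median of one variable and the
other variable is contrasted between the two groups:

* **predictivity** — split on expression; score = mean efficacy in the
  high-expression group minus mean efficacy in the low-expression group.
* **descriptivity** — split on efficacy; score = mean expression in the
  high-efficacy group minus mean expression in the low-efficacy group.

All values are log2-scale, so these mean differences are log fold changes.
Significance comes from a two-sample t-test on the contrasted groups, and a
"hit" gene is one whose predictivity and descriptivity are both significant
with concordant signs.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .matrix import PairedPanel

STATUS_OK = "ok"
STATUS_DEGENERATE_EXPRESSION = "degenerate_expression"
STATUS_DEGENERATE_EFFICACY = "degenerate_efficacy"
STATUS_INSUFFICIENT = "insufficient_group"

#: minimum samples on each side of a split for a defined variance
MIN_GROUP_SIZE = 2


@dataclass
class GroupSplit:
    """A median dichotomization of one per-sample vector.

    ``high_idx`` holds positions with value strictly greater than the median;
    ``low_idx`` holds positions at or below it (ties at the median go low).
    Indices refer to the input vector; missing entries are excluded.
    """

    high_idx: np.ndarray
    low_idx: np.ndarray
    median: float
    n_excluded_missing: int
    status: str  # ok | degenerate | insufficient


@dataclass
class AssociationRecord:
    """Per-gene bidirectional scores, p-values, group sizes and status."""

    gene_id: str
    predictivity: float
    predictivity_p: float
    descriptivity: float
    descriptivity_p: float
    n_high_exp: int
    n_low_exp: int
    n_high_phe: int
    n_low_phe: int
    status: str
    logrank_chi2: float | None = None
    logrank_p: float | None = None


@dataclass
class HitCall:
    """A dual-significant gene with its score direction."""

    gene_id: str
    direction: str  # positive | negative | discordant
    record: AssociationRecord


@dataclass
class PairScore:
    """Result of one directional score on one gene."""

    score: float
    p: float
    n_high: int
    n_low: int
    status: str


def median_split(values: Sequence[float] | np.ndarray) -> GroupSplit:
    """Dichotomize a vector at its median (midpoint convention, ties go low).

    The median is computed over non-missing values only.  With an even count
    it is the midpoint of the two central order statistics; with an odd count
    the central value itself, which the "<= goes low" rule assigns to the low
    group.  A constant vector leaves the high group empty (degenerate) and
    fewer than two observed values is insufficient.
    """
    v = np.asarray(values, dtype=float)
    obs = np.flatnonzero(~np.isnan(v))
    n_missing = v.size - obs.size
    if obs.size < 2:
        return GroupSplit(np.empty(0, int), obs, math.nan, n_missing, "insufficient")
    med = float(np.median(v[obs]))
    high = obs[v[obs] > med]
    low = obs[v[obs] <= med]
    status = "degenerate" if high.size == 0 else "ok"
    return GroupSplit(high, low, med, n_missing, status)


def two_group_test(
    a: Sequence[float] | np.ndarray,
    b: Sequence[float] | np.ndarray,
    variant: str = "student",
) -> tuple[float, float]:
    """Two-sided two-sample t-test.

    ``student`` pools the variance (df = n_a + n_b - 2); ``welch`` uses the
    Satterthwaite approximation.  Both groups need at least two values.  If
    both groups have zero variance the test degenerates: equal means give
    (t=0, p=1) and unequal means an infinite statistic with p=0.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < MIN_GROUP_SIZE or b.size < MIN_GROUP_SIZE:
        raise ValueError("each group needs at least two values")
    if variant not in {"student", "welch"}:
        raise ValueError(f"unknown t-test variant {variant!r}")
    if a.var(ddof=1) == 0.0 and b.var(ddof=1) == 0.0:
        if a.mean() == b.mean():
            return 0.0, 1.0
        return math.copysign(math.inf, a.mean() - b.mean()), 0.0
    with warnings.catch_warnings():
        # one constant group triggers a harmless precision warning in scipy
        warnings.simplefilter("ignore", RuntimeWarning)
        t, p = stats.ttest_ind(a, b, equal_var=(variant == "student"))
    return float(t), float(p)


def _directional_score(
    split_on: np.ndarray,
    contrast: np.ndarray,
    degenerate_status: str,
    variant: str,
) -> PairScore:
    """Median-split on one vector, contrast the other between the groups."""
    split = median_split(split_on)
    n_high, n_low = split.high_idx.size, split.low_idx.size
    if split.status == "insufficient":
        return PairScore(math.nan, math.nan, n_high, n_low, STATUS_INSUFFICIENT)
    if split.status == "degenerate":
        return PairScore(math.nan, math.nan, n_high, n_low, degenerate_status)
    if n_high < MIN_GROUP_SIZE or n_low < MIN_GROUP_SIZE:
        return PairScore(math.nan, math.nan, n_high, n_low, STATUS_INSUFFICIENT)
    hi, lo = contrast[split.high_idx], contrast[split.low_idx]
    score = float(hi.mean() - lo.mean())
    _, p = two_group_test(hi, lo, variant=variant)
    return PairScore(score, p, n_high, n_low, STATUS_OK)


def _paired_complete(expr: np.ndarray, eff: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    expr = np.asarray(expr, dtype=float)
    eff = np.asarray(eff, dtype=float)
    if expr.shape != eff.shape:
        raise ValueError("expression and efficacy vectors must be sample-aligned")
    keep = ~(np.isnan(expr) | np.isnan(eff))
    return expr[keep], eff[keep]


def predictivity(
    expr_g: Sequence[float] | np.ndarray,
    eff_g: Sequence[float] | np.ndarray,
    variant: str = "student",
) -> PairScore:
    """Mean efficacy difference between high- and low-expression samples.

    Samples missing in either vector are dropped for this gene before the
    median is computed.  A negative score means the high-expression group has
    the more negative (stronger) efficacy.
    """
    expr, eff = _paired_complete(expr_g, eff_g)
    return _directional_score(expr, eff, STATUS_DEGENERATE_EXPRESSION, variant)


def descriptivity(
    expr_g: Sequence[float] | np.ndarray,
    eff_g: Sequence[float] | np.ndarray,
    variant: str = "student",
) -> PairScore:
    """Mean expression difference between high- and low-efficacy samples.

    The split uses the numeric ordering of the efficacy score (dependency
    scores are more negative for stronger effects, so "high efficacy group"
    here means numerically greater values).
    """
    expr, eff = _paired_complete(expr_g, eff_g)
    return _directional_score(eff, expr, STATUS_DEGENERATE_EFFICACY, variant)


def cross_association_scan(panel: PairedPanel, variant: str = "student") -> list[AssociationRecord]:
    """Predictivity and descriptivity for every shared gene of a panel.

    Returns one record per gene in panel order.  Genes with a degenerate or
    undersized split carry the status flag and NaN scores.
    """
    expr_vals = panel.expression.values
    eff_vals = panel.efficacy.values
    records: list[AssociationRecord] = []
    for i, gene in enumerate(panel.shared_genes):
        pr = predictivity(expr_vals[i], eff_vals[i], variant=variant)
        de = descriptivity(expr_vals[i], eff_vals[i], variant=variant)
        status = pr.status if pr.status != STATUS_OK else de.status
        if status != STATUS_OK:
            pr = PairScore(math.nan, math.nan, pr.n_high, pr.n_low, pr.status)
            de = PairScore(math.nan, math.nan, de.n_high, de.n_low, de.status)
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
            )
        )
    return records


def call_hits(
    records: Sequence[AssociationRecord],
    alpha_pred: float = 0.01,
    alpha_desc: float = 0.01,
    require_sign_concordance: bool = True,
) -> list[HitCall]:
    """Select genes significant on both axes, with sign-concordant scores.

    A hit has status ok, predictivity p < ``alpha_pred``, descriptivity
    p < ``alpha_desc`` and (by default) the same nonzero sign on both scores.
    With ``require_sign_concordance=False``, dual-significant genes with
    discordant signs are also returned, labelled ``discordant``.
    """
    hits: list[HitCall] = []
    for r in records:
        if r.status != STATUS_OK:
            continue
        if not (r.predictivity_p < alpha_pred and r.descriptivity_p < alpha_desc):
            continue
        if r.predictivity > 0 and r.descriptivity > 0:
            direction = "positive"
        elif r.predictivity < 0 and r.descriptivity < 0:
            direction = "negative"
        else:
            if require_sign_concordance:
                continue
            direction = "discordant"
        hits.append(HitCall(gene_id=r.gene_id, direction=direction, record=r))
    return hits


def records_to_frame(
    records: Sequence[AssociationRecord],
    hits: Sequence[HitCall] | None = None,
    add_q: bool = True,
) -> pd.DataFrame:
    """Tabulate scan records (plus optional hit directions and BH q-values)."""
    df = pd.DataFrame(
        {
            "gene": [r.gene_id for r in records],
            "predictivity": [r.predictivity for r in records],
            "predictivity_p": [r.predictivity_p for r in records],
            "descriptivity": [r.descriptivity for r in records],
            "descriptivity_p": [r.descriptivity_p for r in records],
            "n_high_exp": [r.n_high_exp for r in records],
            "n_low_exp": [r.n_low_exp for r in records],
            "n_high_phe": [r.n_high_phe for r in records],
            "n_low_phe": [r.n_low_phe for r in records],
            "status": [r.status for r in records],
        }
    )
    if any(r.logrank_p is not None for r in records):
        df["logrank_chi2"] = [r.logrank_chi2 for r in records]
        df["logrank_p"] = [r.logrank_p for r in records]
    direction = pd.Series("", index=df.index, dtype=object)
    if hits is not None:
        by_gene = {h.gene_id: h.direction for h in hits}
        direction = df["gene"].map(lambda g: by_gene.get(g, ""))
    df["direction"] = direction
    if add_q:
        from statsmodels.stats.multitest import multipletests

        for col, qcol in [("predictivity_p", "q_pred"), ("descriptivity_p", "q_desc")]:
            q = np.full(len(df), np.nan)
            ok = df["status"].eq(STATUS_OK).to_numpy() & df[col].notna().to_numpy()
            if ok.any():
                q[ok] = multipletests(df.loc[ok, col].to_numpy(), method="fdr_bh")[1]
            df[qcol] = q
    return df


def gene_summary(panel: PairedPanel) -> pd.DataFrame:
    """Per-gene mean expression and mean efficacy over non-missing samples."""
    return pd.DataFrame(
        {
            "mean_expression": panel.expression.data.mean(axis=1, skipna=True),
            "mean_efficacy": panel.efficacy.data.mean(axis=1, skipna=True),
        }
    ).rename_axis("gene")


def top_efficacy_genes(summary: pd.DataFrame, cutoff: float) -> pd.DataFrame:
    """Genes with mean efficacy strictly below ``cutoff``.

    Dependency scores are negative for anti-proliferative effects, so typical
    cutoffs are -1.5 (shRNA knockdown) or -2 (sgRNA knockout).
    """
    return summary[summary["mean_efficacy"] < cutoff]


def platform_correlation(summary_a: pd.DataFrame, summary_b: pd.DataFrame) -> tuple[float, int]:
    """Pearson correlation of mean efficacy between two platforms.

    Correlates the ``mean_efficacy`` columns over the gene intersection of two
    ``gene_summary`` tables (e.g. shRNA vs sgRNA screens of the same panel).
    """
    shared = summary_a.index.intersection(summary_b.index)
    if len(shared) < 3:
        raise ValueError(f"need at least 3 shared genes, got {len(shared)}")
    a = summary_a.loc[shared, "mean_efficacy"].to_numpy()
    b = summary_b.loc[shared, "mean_efficacy"].to_numpy()
    if a.std() == 0 or b.std() == 0:
        raise ValueError("zero variance in mean efficacy; correlation undefined")
    r, _ = stats.pearsonr(a, b)
    return float(r), int(len(shared))
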