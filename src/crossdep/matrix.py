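"""Omics matrix container, DepMap-dialect I/O, filtering and normalization.

The in-memory convention is always genes x samples, with ``NaN`` as the
missing-value marker.  Gene identifiers are the full ``"SYMBOL (ENTREZID)"``
strings used by DepMap-style downloads; a symbol-only accessor is provided
because symbols alone are ambiguous.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

SCALES = frozenset({"log2_expression", "dependency_score", "fpkm", "log2_tpm"})
ASSAYS = frozenset({"expression", "shRNA", "sgRNA"})

#: default scale tag per assay, used by the reader when none is given
DEFAULT_SCALE = {
    "expression": "log2_expression",
    "shRNA": "dependency_score",
    "sgRNA": "dependency_score",
}

_GENE_HEADER = re.compile(r"^.+ \(\d+\)$")
#: strings treated as missing values in input tables
NA_STRINGS = frozenset({"", "NA", "NaN", "nan", "na", "N/A", "--", "null"})


class MatrixFormatError(ValueError):
    """Raised for malformed omics matrix input."""


def _duplicates(ids: Sequence[str]) -> list[str]:
    seen: set[str] = set()
    dups: list[str] = []
    for x in ids:
        if x in seen and x not in dups:
            dups.append(x)
        seen.add(x)
    return dups


@dataclass
class OmicsMatrix:
    """A genes x samples value grid with a missing mask and scale/assay tags.

    Parameters
    ----------
    data
        Float DataFrame indexed by gene id (``"SYMBOL (ENTREZID)"``) with
        sample ids as columns.  ``NaN`` marks missing values.
    assay
        One of ``expression``, ``shRNA``, ``sgRNA``.
    scale
        One of ``log2_expression``, ``dependency_score``, ``fpkm``,
        ``log2_tpm``.
    """

    data: pd.DataFrame
    assay: str
    scale: str

    def __post_init__(self) -> None:
        if self.assay not in ASSAYS:
            raise ValueError(f"unknown assay {self.assay!r}; expected one of {sorted(ASSAYS)}")
        if self.scale not in SCALES:
            raise ValueError(f"unknown scale {self.scale!r}; expected one of {sorted(SCALES)}")
        dup_g = _duplicates(list(self.data.index))
        if dup_g:
            raise MatrixFormatError(f"duplicate gene ids: {dup_g}")
        dup_s = _duplicates(list(self.data.columns))
        if dup_s:
            raise MatrixFormatError(f"duplicate sample ids: {dup_s}")
        self.data = self.data.astype(float)
        self.data.index = self.data.index.astype(str)
        self.data.columns = self.data.columns.astype(str)
        self.data.index.name = "gene"
        self.data.columns.name = None
        vals = self.data.to_numpy()
        if np.isinf(vals).any():
            g, s = np.argwhere(np.isinf(vals))[0]
            raise MatrixFormatError(
                f"non-finite value at gene {self.data.index[g]!r}, sample {self.data.columns[s]!r}"
            )

    # -- accessors ---------------------------------------------------------

    @property
    def gene_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy()

    @property
    def n_genes(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    def symbols(self) -> list[str]:
        """Gene symbols with any trailing ``" (ENTREZID)"`` stripped."""
        return [re.sub(r" \(\d+\)$", "", g) for g in self.gene_ids]

    def missing_fraction(self) -> pd.Series:
        """Per-gene fraction of missing (NaN) samples."""
        return self.data.isna().mean(axis=1)

    def gene_vector(self, gene_id: str) -> np.ndarray:
        return self.data.loc[gene_id].to_numpy()

    def subset_samples(self, sample_ids: Sequence[str]) -> "OmicsMatrix":
        return OmicsMatrix(self.data.loc[:, list(sample_ids)].copy(), self.assay, self.scale)

    def subset_genes(self, gene_ids: Sequence[str]) -> "OmicsMatrix":
        return OmicsMatrix(self.data.loc[list(gene_ids), :].copy(), self.assay, self.scale)


@dataclass
class PairedPanel:
    """Expression and efficacy matrices aligned to shared samples and genes."""

    expression: OmicsMatrix
    efficacy: OmicsMatrix
    shared_samples: list[str]
    shared_genes: list[str]
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.shared_samples:
            raise ValueError("PairedPanel requires a non-empty shared sample set")
        for m in (self.expression, self.efficacy):
            if m.sample_ids != self.shared_samples:
                raise ValueError("panel matrices must be restricted to shared_samples in order")


def _looks_like_genes(ids: Iterable[str]) -> bool:
    ids = list(ids)
    if not ids:
        return False
    hits = sum(bool(_GENE_HEADER.match(str(x))) for x in ids)
    return hits / len(ids) > 0.5


def read_omics_matrix(
    path: str | Path,
    assay: str,
    orientation: str = "auto",
    scale: str | None = None,
    sample_manifest: Sequence[str] | None = None,
    sep: str | None = None,
) -> OmicsMatrix:
    """Read a DepMap-dialect CSV (samples x genes) or its transpose.

    The result is always genes x samples.  ``"SYMBOL (ENTREZID)"`` headers are
    preserved verbatim and empty cells become NaN.

    Parameters
    ----------
    orientation
        ``samples_by_genes`` (DepMap download layout), ``genes_by_samples``
        (this package's canonical export) or ``auto``.  Auto-detection uses a
        supplied ``sample_manifest`` first (row labels found in the manifest
        mean rows are samples); failing that, the side whose labels match the
        ``"SYMBOL (ENTREZID)"`` pattern is taken as the gene axis.  If neither
        rule decides, an explicit orientation is required.
    sep
        Field separator; inferred from the file extension when None
        (``.tsv``/``.txt`` tab, otherwise comma).
    """
    path = Path(path)
    if sep is None:
        sep = "\t" if path.suffix.lower() in {".tsv", ".txt"} else ","
    raw = pd.read_csv(path, index_col=0, dtype=str, sep=sep, keep_default_na=False)
    raw.index = raw.index.astype(str)

    if orientation == "auto":
        rows, cols = list(raw.index), list(raw.columns)
        if sample_manifest is not None:
            manifest = set(sample_manifest)
            row_hit = len(manifest.intersection(rows)) / max(len(rows), 1)
            col_hit = len(manifest.intersection(cols)) / max(len(cols), 1)
            if row_hit > col_hit:
                orientation = "samples_by_genes"
            elif col_hit > row_hit:
                orientation = "genes_by_samples"
        if orientation == "auto":
            rows_genes, cols_genes = _looks_like_genes(rows), _looks_like_genes(cols)
            if cols_genes and not rows_genes:
                orientation = "samples_by_genes"
            elif rows_genes and not cols_genes:
                orientation = "genes_by_samples"
            else:
                raise MatrixFormatError(
                    f"cannot auto-detect orientation of {path}; pass orientation= explicitly"
                )
    if orientation not in {"samples_by_genes", "genes_by_samples"}:
        raise ValueError(f"unknown orientation {orientation!r}")
    if orientation == "samples_by_genes":
        raw = raw.T

    # parse cells, reporting coordinates of the first non-numeric entry
    cleaned = raw.apply(lambda col: col.map(lambda v: np.nan if str(v).strip() in NA_STRINGS else v))
    numeric = cleaned.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna() & cleaned.notna()
    if bad.to_numpy().any():
        g, s = np.argwhere(bad.to_numpy())[0]
        raise MatrixFormatError(
            f"non-numeric value {cleaned.iat[g, s]!r} at gene {raw.index[g]!r}, "
            f"sample {raw.columns[s]!r} in {path}"
        )
    return OmicsMatrix(numeric, assay=assay, scale=scale or DEFAULT_SCALE[assay])


def write_omics_matrix(m: OmicsMatrix, path: str | Path) -> None:
    """Write the canonical genes x samples TSV (round-trips exactly)."""
    m.data.to_csv(path, sep="\t", index_label="gene", na_rep="")


def filter_by_missingness(m: OmicsMatrix, max_missing_frac: float) -> OmicsMatrix:
    """Drop genes missing in strictly more than ``max_missing_frac`` of samples.

    The boundary is retained: a gene missing in exactly half the samples
    survives ``max_missing_frac=0.5``.  The sample axis is untouched.
    """
    if not 0.0 <= max_missing_frac <= 1.0:
        raise ValueError("max_missing_frac must be in [0, 1]")
    keep = m.missing_fraction() <= max_missing_frac
    return OmicsMatrix(m.data.loc[keep].copy(), m.assay, m.scale)


def aggregate_reagents(m: OmicsMatrix, reagent_to_gene: Mapping[str, str]) -> OmicsMatrix:
    """Collapse reagent-level rows (shRNA/sgRNA constructs) to gene level.

    Uses the unweighted mean over a gene's reagents, ignoring missing values.
    Reagents absent from the mapping are dropped.
    """
    mapped = m.data.loc[[r for r in m.gene_ids if r in reagent_to_gene]]
    genes = pd.Index([reagent_to_gene[r] for r in mapped.index], name="gene")
    agg = mapped.groupby(genes, sort=False).mean()
    return OmicsMatrix(agg, m.assay, m.scale)


def build_paired_panel(expression: OmicsMatrix, efficacy: OmicsMatrix) -> PairedPanel:
    """Align an expression and an efficacy matrix on shared samples and genes.

    Sample and gene order follow the expression matrix.  Drop counts are
    recorded in ``panel.provenance``.
    """
    expr_samples = set(expression.sample_ids)
    eff_samples = set(efficacy.sample_ids)
    shared_samples = [s for s in expression.sample_ids if s in eff_samples]
    if not shared_samples:
        raise ValueError("no shared samples between expression and efficacy matrices")
    eff_genes = set(efficacy.gene_ids)
    shared_genes = [g for g in expression.gene_ids if g in eff_genes]
    if not shared_genes:
        raise ValueError("no shared genes between expression and efficacy matrices")
    provenance = {
        "n_shared_samples": len(shared_samples),
        "n_shared_genes": len(shared_genes),
        "n_samples_dropped_expression": len(expr_samples) - len(shared_samples),
        "n_samples_dropped_efficacy": len(eff_samples) - len(shared_samples),
        "n_genes_dropped_expression": expression.n_genes - len(shared_genes),
        "n_genes_dropped_efficacy": efficacy.n_genes - len(shared_genes),
    }
    return PairedPanel(
        expression=expression.subset_samples(shared_samples).subset_genes(shared_genes),
        efficacy=efficacy.subset_samples(shared_samples).subset_genes(shared_genes),
        shared_samples=shared_samples,
        shared_genes=shared_genes,
        provenance=provenance,
    )


def fpkm_to_log2tpm(m: OmicsMatrix) -> OmicsMatrix:
    """Convert an FPKM matrix to log2(TPM + 1).

    TPM rescales each sample so that abundances sum to 10^6:
    ``TPM_g = FPKM_g / sum_g FPKM_g * 1e6``.
    """
    if m.scale != "fpkm":
        raise ValueError(f"expected scale 'fpkm', got {m.scale!r}")
    vals = m.values
    if np.nanmin(vals) < 0:
        raise ValueError("FPKM values must be nonnegative")
    colsum = np.nansum(vals, axis=0)
    zero = np.flatnonzero(colsum == 0)
    if zero.size:
        raise ValueError(f"sample {m.sample_ids[zero[0]]!r} has all-zero FPKM")
    tpm = vals / colsum * 1e6
    out = pd.DataFrame(np.log2(tpm + 1.0), index=m.data.index, columns=m.data.columns)
    return OmicsMatrix(out, assay=m.assay, scale="log2_tpm")
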