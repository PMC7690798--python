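from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from crossdep import OmicsMatrix, PairedPanel, build_paired_panel


def make_matrix(values, gene_ids=None, sample_ids=None, assay="expression",
                scale=None) -> OmicsMatrix:
    values = np.asarray(values, dtype=float)
    n_genes, n_samples = values.shape
    gene_ids = gene_ids or [f"G{i} ({i + 1})" for i in range(n_genes)]
    sample_ids = sample_ids or [f"S{j}" for j in range(n_samples)]
    if scale is None:
        scale = "log2_expression" if assay == "expression" else "dependency_score"
    return OmicsMatrix(pd.DataFrame(values, index=gene_ids, columns=sample_ids), assay, scale)


def random_panel(rng: np.random.Generator, n_genes=20, n_samples=12,
                 missing_rate=0.0) -> PairedPanel:
    expr = rng.normal(5.0, 1.5, size=(n_genes, n_samples))
    eff = rng.normal(-0.5, 1.0, size=(n_genes, n_samples))
    if missing_rate:
        eff[rng.random(eff.shape) < missing_rate] = np.nan
    return build_paired_panel(
        make_matrix(expr, assay="expression"),
        make_matrix(eff, assay="shRNA"),
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20200901)


@pytest.fixture
def small_panel(rng) -> PairedPanel:
    return random_panel(rng, n_genes=15, n_samples=14, missing_rate=0.1)
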