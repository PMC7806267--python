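"""Single-cell QC filtering and emx2 enrichment tests on count matrices.

The cell filter applies the canonical exclusion rules: a cell is removed when
it has (1) fewer than 400 unique genes, (2) more than 2500 unique genes,
(3) more than 10,000 UMIs, or (4) more than 5% mitochondrial counts.  All
four rules are strict on the excluded side (a cell with exactly 400 genes,
exactly 10,000 UMIs, or exactly 5% mitochondrial counts passes).  Genes
detected in fewer than 3 cells are flagged for removal.

Library-size normalization, clustering, and pseudotime are intentionally not
implemented here; only the filter and the two enrichment comparisons (read
counts and positivity of emx2 across clusters) are in scope.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Sequence

import numpy as np
import pandas as pd
from scipy import sparse

from .stats import ContingencyTable, TestResult, pearson_chi2, two_sample_t

__all__ = ["QCThresholds", "qc_filter", "emx2_enrichment"]


@dataclass(frozen=True)
class QCThresholds:
    """Overridable QC rule thresholds (defaults = the canonical rule set)."""

    min_unique_genes: int = 400
    max_unique_genes: int = 2500
    max_umi: int = 10000
    max_mito_fraction: float = 0.05
    min_cells_per_gene: int = 3


def qc_filter(
    counts: sparse.spmatrix,
    gene_names: Sequence[str],
    mito_gene_set: Sequence[str],
    thresholds: QCThresholds = QCThresholds(),
    cell_ids: Sequence[str] | None = None,
) -> dict:
    """Per-cell QC metrics and pass flags for a cells × genes count matrix.

    Returns ``{"cells": DataFrame, "genes": DataFrame}``.  The cells table has
    one row per cell (``cell_id, n_unique_genes, n_umi, mito_fraction,
    pass``); the genes table flags genes detected in fewer than
    ``min_cells_per_gene`` cells for removal.
    """
    counts = sparse.csr_matrix(counts)
    if counts.nnz == 0 or min(counts.shape) == 0:
        raise ValueError("empty count matrix")
    gene_names = list(gene_names)
    if counts.shape[1] != len(gene_names):
        raise ValueError("gene_names length must match the number of matrix columns")
    if len(set(gene_names)) != len(gene_names):
        raise ValueError("gene names must be unique")
    mito = set(mito_gene_set)
    if not mito:
        raise ValueError("mitochondrial gene set must be non-empty")
    missing = mito - set(gene_names)
    if missing:
        raise ValueError(f"mitochondrial genes absent from matrix: {sorted(missing)}")

    n_cells = counts.shape[0]
    if cell_ids is None:
        cell_ids = [f"cell{k:05d}" for k in range(n_cells)]
    mito_mask = np.array([g in mito for g in gene_names])

    detected = counts > 0
    n_unique = np.asarray(detected.sum(axis=1)).ravel()
    n_umi = np.asarray(counts.sum(axis=1)).ravel()
    mito_umi = np.asarray(counts[:, mito_mask].sum(axis=1)).ravel()
    with np.errstate(invalid="ignore", divide="ignore"):
        mito_fraction = np.where(n_umi > 0, mito_umi / np.maximum(n_umi, 1), 0.0)

    t = thresholds
    passed = (
        (n_unique >= t.min_unique_genes)
        & (n_unique <= t.max_unique_genes)
        & (n_umi <= t.max_umi)
        & (mito_fraction <= t.max_mito_fraction)
    )
    cells = pd.DataFrame({
        "cell_id": list(cell_ids),
        "n_unique_genes": n_unique.astype(int),
        "n_umi": n_umi.astype(int),
        "mito_fraction": mito_fraction.astype(float),
        "pass": passed.astype(bool),
    })
    cells_per_gene = np.asarray(detected.sum(axis=0)).ravel()
    genes = pd.DataFrame({
        "gene": gene_names,
        "n_cells_detected": cells_per_gene.astype(int),
        "keep": (cells_per_gene >= t.min_cells_per_gene).astype(bool),
    })
    return {"cells": cells, "genes": genes}


def emx2_enrichment(
    cluster_labels: Sequence[str],
    emx2_counts: Sequence[int],
    target_cluster: str,
) -> dict:
    """Compare emx2 expression in one cluster against all others.

    Returns two tests: a two-tailed t-test of per-cell log1p read counts
    (target cluster vs the rest) and a Pearson chi-squared test on the
    positive/negative × cluster table.
    """
    labels = np.asarray(cluster_labels)
    x = np.asarray(emx2_counts, dtype=float)
    if labels.shape != x.shape:
        raise ValueError("cluster_labels and emx2_counts must have equal length")
    clusters = sorted(set(labels.tolist()))
    if len(clusters) < 2:
        raise ValueError("need at least two clusters")
    if target_cluster not in clusters:
        raise ValueError(f"unknown target cluster {target_cluster!r}")

    in_target = labels == target_cluster
    count_test = two_sample_t(np.log1p(x[in_target]), np.log1p(x[~in_target]), variant="student")
    count_test.method = "t-test[log1p emx2 counts, target vs rest]"

    pos = x > 0
    table = np.array(
        [[int(pos[labels == c].sum()), int((~pos[labels == c]).sum())] for c in clusters]
    ).T  # rows: positive/negative, cols: clusters
    positivity_test = pearson_chi2(
        ContingencyTable(table, row_labels=["emx2+", "emx2-"], col_labels=list(clusters))
    )
    positivity_test.method = "pearson-chi2[emx2 positivity x cluster]"
    return {"count_test": count_test, "positivity_test": positivity_test}
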