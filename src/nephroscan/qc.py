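"""Cell- and gene-level quality control and sampling utilities.

Filters follow the conventions of droplet scRNA-seq preprocessing in
kidney tissue: cells are retained when strictly between the detected-gene
bounds (defaults 200 and 3000, both boundary values excluded) and at or
below a mitochondrial percentage ceiling (default 50%, deliberately
permissive because healthy proximal tubule cells carry high mitochondrial
content). Doublet removal consumes a boolean metadata column supplied by
the caller; no doublet detection algorithm is implemented here.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import scipy.sparse as sp
from anndata import AnnData
from dataclasses import dataclass

__all__ = [
    "QCThresholds",
    "compute_cell_qc",
    "filter_cells",
    "filter_genes_min_expression",
    "stratified_downsample",
]


@dataclass
class QCThresholds:
    """Exclusive detected-gene bounds and inclusive mito ceiling."""

    min_genes: int = 200
    max_genes: int = 3000
    max_mito_pct: float = 50.0

    def __post_init__(self) -> None:
        if self.min_genes >= self.max_genes:
            raise ValueError(
                f"min_genes ({self.min_genes}) must be < max_genes ({self.max_genes})"
            )


def _counts_matrix(adata: AnnData) -> sp.csr_matrix:
    X = adata.X
    if not sp.issparse(X):
        X = sp.csr_matrix(X)
    return X.tocsr()


def compute_cell_qc(adata: AnnData, mito_gene_ids: list[str]) -> pd.DataFrame:
    """Per-cell QC table: ``n_genes_detected``, ``mito_pct``, ``is_doublet``.

    ``mito_pct`` is 100 * (mitochondrial counts) / (total counts); cells
    with zero total counts get 0 for both statistics.
    """
    unknown = [g for g in mito_gene_ids if g not in adata.var_names]
    if unknown:
        raise KeyError(f"unknown mitochondrial gene id(s): {unknown[:5]}")
    X = _counts_matrix(adata)
    n_detected = np.asarray((X > 0).sum(axis=1)).ravel()
    total = np.asarray(X.sum(axis=1)).ravel()
    mito_idx = adata.var_names.get_indexer(mito_gene_ids)
    mito_counts = (
        np.asarray(X[:, mito_idx].sum(axis=1)).ravel()
        if len(mito_idx)
        else np.zeros(X.shape[0])
    )
    with np.errstate(invalid="ignore", divide="ignore"):
        mito_pct = np.where(total > 0, 100.0 * mito_counts / np.maximum(total, 1), 0.0)
    qc = pd.DataFrame(
        {
            "n_genes_detected": n_detected.astype(int),
            "mito_pct": mito_pct,
            "is_doublet": (
                adata.obs["is_doublet"].to_numpy(dtype=bool)
                if "is_doublet" in adata.obs
                else np.zeros(X.shape[0], dtype=bool)
            ),
        },
        index=adata.obs_names,
    )
    qc.index.name = "barcode"
    return qc


def filter_cells(
    qc: pd.DataFrame,
    thresholds: QCThresholds | None = None,
    drop_doublets: bool = True,
) -> list[str]:
    """Barcodes passing all QC gates.

    Retained iff min_genes < n_genes_detected < max_genes (strict) and
    mito_pct <= max_mito_pct and, when ``drop_doublets``, not flagged as a
    doublet.
    """
    t = thresholds or QCThresholds()
    keep = (
        (qc["n_genes_detected"] > t.min_genes)
        & (qc["n_genes_detected"] < t.max_genes)
        & (qc["mito_pct"] <= t.max_mito_pct)
    )
    if drop_doublets and "is_doublet" in qc:
        keep &= ~qc["is_doublet"].to_numpy(dtype=bool)
    return qc.index[keep].tolist()


def filter_genes_min_expression(
    adata: AnnData, min_reads: int = 3, min_cells: int = 10
) -> list[str]:
    """Genes with at least ``min_reads`` counts in at least ``min_cells`` cells."""
    X = _counts_matrix(adata)
    n_qualifying = np.asarray((X >= min_reads).sum(axis=0)).ravel()
    return adata.var_names[n_qualifying >= min_cells].tolist()


def stratified_downsample(
    cluster_labels: pd.Series, n_per_cluster: int, seed: int = 0
) -> list[str]:
    """Sample exactly ``n_per_cluster`` barcodes per cluster without
    replacement; raises if any cluster is smaller.

    Clusters are processed in sorted label order so the draw is
    deterministic under the seed regardless of input ordering.
    """
    rng = np.random.default_rng(seed)
    labels = pd.Series(cluster_labels)
    chosen: list[str] = []
    for cluster in sorted(labels.unique()):
        members = labels.index[labels == cluster].to_numpy()
        if len(members) < n_per_cluster:
            raise ValueError(
                f"cluster {cluster!r} has {len(members)} cells, "
                f"fewer than n_per_cluster={n_per_cluster}"
            )
        chosen.extend(rng.choice(members, size=n_per_cluster, replace=False))
    return chosen
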