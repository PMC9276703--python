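"""Ligand-receptor interaction scoring between cell clusters.

For every (ligand, receptor) pair and every ordered (sender, receiver)
cluster pair, the interaction score is the average of the ligand's mean
expression in the sender and the receptor's mean in the receiver. A pair
is only tested where both genes pass the expression gate (detected in
strictly more than ``min_frac`` of the cluster's cells). Significance comes
from a permutation test that shuffles cluster labels over all cells, with
Benjamini-Hochberg FDR correction across all tested triples.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import scipy.sparse as sp
from anndata import AnnData
from statsmodels.stats.multitest import multipletests

__all__ = ["expression_gate", "interaction_means", "lr_permutation_test"]


def _dense(adata: AnnData, genes: list[str]) -> np.ndarray:
    X = adata[:, genes].X
    if sp.issparse(X):
        X = X.toarray()
    return np.asarray(X, dtype=float)


def _check_pairs(adata: AnnData, pairs: pd.DataFrame) -> None:
    involved = set(pairs["ligand"]) | set(pairs["receptor"])
    unknown = sorted(involved - set(adata.var_names))
    if unknown:
        raise KeyError(f"pair genes missing from matrix: {unknown[:5]}")


def expression_gate(
    adata: AnnData, cluster_labels: pd.Series, min_frac: float = 0.05
) -> dict[str, set[str]]:
    """Per-cluster sets of genes detected in > ``min_frac`` of the cluster.

    Detection means a nonzero value; the gate is strict (a gene seen in
    exactly ``min_frac`` of cells is excluded).
    """
    labels = pd.Series(cluster_labels, index=adata.obs_names)
    X = adata.X
    if sp.issparse(X):
        X = X.toarray()
    detected = np.asarray(X) > 0
    out: dict[str, set[str]] = {}
    for cluster in sorted(labels.unique()):
        mask = (labels == cluster).to_numpy()
        if mask.sum() == 0:
            out[cluster] = set()
            continue
        frac = detected[mask].mean(axis=0)
        out[cluster] = set(np.asarray(adata.var_names)[frac > min_frac])
    return out


def interaction_means(
    adata: AnnData,
    cluster_labels: pd.Series,
    pairs: pd.DataFrame,
    min_frac: float = 0.05,
) -> pd.DataFrame:
    """Observed interaction means for all gated (pair, sender, receiver)
    triples; triples failing the gate in either cluster are absent."""
    _check_pairs(adata, pairs)
    labels = pd.Series(cluster_labels, index=adata.obs_names)
    clusters = sorted(labels.unique())
    gate = expression_gate(adata, labels, min_frac)
    genes = sorted(set(pairs["ligand"]) | set(pairs["receptor"]))
    gene_pos = {g: i for i, g in enumerate(genes)}
    X = _dense(adata, genes)
    cluster_means = {
        c: X[(labels == c).to_numpy()].mean(axis=0) for c in clusters
    }
    records = []
    for _, row in pairs.iterrows():
        lig, rec = row["ligand"], row["receptor"]
        for sender in clusters:
            if lig not in gate[sender]:
                continue
            for receiver in clusters:
                if rec not in gate[receiver]:
                    continue
                mean = 0.5 * (
                    cluster_means[sender][gene_pos[lig]]
                    + cluster_means[receiver][gene_pos[rec]]
                )
                records.append(
                    {
                        "ligand": lig,
                        "receptor": rec,
                        "sender": sender,
                        "receiver": receiver,
                        "interaction_mean": mean,
                    }
                )
    return pd.DataFrame(
        records, columns=["ligand", "receptor", "sender", "receiver", "interaction_mean"]
    )


def lr_permutation_test(
    adata: AnnData,
    cluster_labels: pd.Series,
    pairs: pd.DataFrame,
    n_iter: int = 1000,
    min_frac: float = 0.05,
    alpha: float = 0.05,
    seed: int = 0,
) -> pd.DataFrame:
    """Permutation test over all gated triples.

    Each iteration shuffles the cluster labels over all cells and
    recomputes every triple's interaction mean;
    p = (1 + #{null >= observed}) / (1 + n_iter), then Benjamini-Hochberg
    q-values across triples; ``significant`` iff q < ``alpha``.
    """
    labels = pd.Series(cluster_labels, index=adata.obs_names)
    clusters = sorted(labels.unique())
    if len(clusters) < 2:
        raise ValueError("need at least 2 clusters")
    observed = interaction_means(adata, labels, pairs, min_frac)
    if observed.empty:
        observed["p"] = []
        observed["q"] = []
        observed["significant"] = []
        return observed

    genes = sorted(set(pairs["ligand"]) | set(pairs["receptor"]))
    gene_pos = {g: i for i, g in enumerate(genes)}
    X = _dense(adata, genes)
    codes = pd.Categorical(labels, categories=clusters).codes.astype(np.int64)
    n_cells, k = len(codes), len(clusters)
    cluster_sizes = np.bincount(codes, minlength=k).astype(float)

    lig_idx = observed["ligand"].map(gene_pos).to_numpy()
    rec_idx = observed["receptor"].map(gene_pos).to_numpy()
    snd_idx = pd.Categorical(observed["sender"], categories=clusters).codes
    rcv_idx = pd.Categorical(observed["receiver"], categories=clusters).codes
    obs_vals = observed["interaction_mean"].to_numpy()

    rng = np.random.default_rng(seed)
    exceed = np.zeros(len(observed), dtype=np.int64)
    for _ in range(n_iter):
        perm = codes[rng.permutation(n_cells)]
        onehot = np.zeros((k, n_cells))
        onehot[perm, np.arange(n_cells)] = 1.0
        means = (onehot @ X) / cluster_sizes[:, None]  # cluster x gene
        null = 0.5 * (means[snd_idx, lig_idx] + means[rcv_idx, rec_idx])
        exceed += null >= obs_vals
    p = (1.0 + exceed) / (1.0 + n_iter)
    _, q, _, _ = multipletests(p, method="fdr_bh")
    out = observed.copy()
    out["p"] = p
    out["q"] = q
    out["significant"] = q < alpha
    return out
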