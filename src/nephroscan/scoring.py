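"""Condition signatures, per-cell injury scoring, and cell-state calls.

The injury (IRI) score contrasts two condition-specific gene programs.
Signatures are the top-k most specific differentially expressed genes per
condition (rank-sum test with minimum-detection and log-fold-change gates),
pruned by Pearson correlation so that each retained gene correlates with
its own program and anticorrelates with the opposing one. Cells are then
scored with the binned-control strategy of Tirosh et al.: the mean
expression of the signature minus the mean of expression-bin-matched
control genes, which removes the library-depth component of the raw mean.
A cell is called for whichever program scores higher, provided that score
is positive; otherwise it is "neither".
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp
import scipy.stats
from anndata import AnnData

__all__ = [
    "ScoreConfig",
    "Signature",
    "log_normalize",
    "rank_condition_degs",
    "prune_signature_by_correlation",
    "module_score",
    "classify_cells",
    "iri_score_pipeline",
    "bulk_cluster_enrichment",
]


@dataclass
class ScoreConfig:
    n_top_degs: int = 100
    n_bins: int = 24
    n_ctrl_per_gene: int = 100
    min_pct: float = 0.05
    logfc_threshold: float = 0.2  # natural-log fold change
    only_pos: bool = True  # signatures need genes UP in their condition
    auto_r_min: float = 0.1
    cross_r_max: float = 0.0
    margin: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_top_degs, self.n_bins, self.n_ctrl_per_gene) <= 0:
            raise ValueError("n_top_degs, n_bins, n_ctrl_per_gene must be positive")
        if not 0 < self.min_pct < 1:
            raise ValueError("min_pct must be in (0, 1)")


@dataclass
class Signature:
    """A condition program with pruning provenance."""

    condition: str
    genes_initial: list[str]
    genes_pruned: list[str] = field(default_factory=list)
    prune_log: pd.DataFrame | None = None


def log_normalize(adata: AnnData, target_sum: float = 1e4) -> AnnData:
    """Depth-normalize to ``target_sum`` counts per cell and log1p.

    Returns a new AnnData with a dense float matrix (the downstream
    statistics here are dense by nature: correlations, z-scores, means).
    """
    X = adata.X
    if sp.issparse(X):
        X = X.toarray()
    X = np.asarray(X, dtype=float)
    totals = X.sum(axis=1, keepdims=True)
    scale = np.divide(target_sum, totals, out=np.zeros_like(totals), where=totals > 0)
    out = adata.copy()
    out.X = np.log1p(X * scale)
    return out


def _dense(adata: AnnData) -> np.ndarray:
    X = adata.X
    if sp.issparse(X):
        X = X.toarray()
    return np.asarray(X, dtype=float)


def _seurat_logfc(expr_in: np.ndarray, expr_out: np.ndarray) -> np.ndarray:
    """ln((mean expm1 in-group + 1) / (mean expm1 out-group + 1)).

    Log-fold-change dialects differ between toolkits; this is the Seurat
    convention on log1p-normalized data, stated explicitly.
    """
    mean_in = np.expm1(expr_in).mean(axis=0)
    mean_out = np.expm1(expr_out).mean(axis=0)
    return np.log((mean_in + 1.0) / (mean_out + 1.0))


def rank_condition_degs(
    adata: AnnData,
    condition_labels: pd.Series,
    config: ScoreConfig | None = None,
) -> dict[str, pd.DataFrame]:
    """Per-condition ranked marker tables (one-vs-rest).

    For each condition: genes detected in at least ``min_pct`` of in-group
    cells and with |logFC| >= ``logfc_threshold`` are ranked by two-sided
    rank-sum p-value, ties broken by descending |logFC| then gene id;
    the top ``n_top_degs`` are returned with columns
    ``gene, p, logfc, pct_in``.

    With ``config.only_pos`` (the default) only genes upregulated in the
    condition are eligible: a condition-specific signature must consist of
    genes high in that condition, and with exactly two groups the
    one-vs-rest contrasts are mirror images, so without the direction
    restriction both signatures would collapse onto the same mixed gene
    list.
    """
    config = config or ScoreConfig()
    labels = pd.Series(condition_labels, index=adata.obs_names)
    conditions = sorted(labels.unique())
    if len(conditions) < 2:
        raise ValueError("need at least 2 conditions")
    X = _dense(adata)
    genes = np.asarray(adata.var_names)
    out: dict[str, pd.DataFrame] = {}
    for cond in conditions:
        mask = (labels == cond).to_numpy()
        if mask.sum() < 2 or (~mask).sum() < 2:
            raise ValueError(f"condition {cond!r} needs >= 2 cells on each side")
        expr_in, expr_out = X[mask], X[~mask]
        pct_in = (expr_in > 0).mean(axis=0)
        logfc = _seurat_logfc(expr_in, expr_out)
        passing = (pct_in >= config.min_pct) & (np.abs(logfc) >= config.logfc_threshold)
        if config.only_pos:
            passing &= logfc > 0
        idx = np.flatnonzero(passing)
        if len(idx) == 0:
            out[cond] = pd.DataFrame(columns=["gene", "p", "logfc", "pct_in"])
            continue
        stat = scipy.stats.mannwhitneyu(
            expr_in[:, idx], expr_out[:, idx], axis=0, alternative="two-sided"
        )
        table = pd.DataFrame(
            {
                "gene": genes[idx],
                "p": stat.pvalue,
                "logfc": logfc[idx],
                "pct_in": pct_in[idx],
            }
        )
        table["abs_logfc"] = table["logfc"].abs()
        table = table.sort_values(
            ["p", "abs_logfc", "gene"], ascending=[True, False, True]
        ).drop(columns="abs_logfc")
        out[cond] = table.head(config.n_top_degs).reset_index(drop=True)
    return out


def prune_signature_by_correlation(
    adata: AnnData,
    sig_a: Signature,
    sig_b: Signature,
    auto_r_min: float = 0.1,
    cross_r_max: float = 0.0,
) -> tuple[Signature, Signature]:
    """Single-pass correlation pruning of a signature pair.

    A gene is kept iff its mean Pearson correlation with the other genes of
    its own set is >= ``auto_r_min`` and its mean correlation with the
    opposing set is <= ``cross_r_max``. Means are computed on the initial
    sets (not iterated), so the result does not depend on pruning order.
    """
    if not sig_a.genes_initial or not sig_b.genes_initial:
        raise ValueError("signatures must be non-empty")
    union = list(dict.fromkeys(sig_a.genes_initial + sig_b.genes_initial))
    missing = [g for g in union if g not in adata.var_names]
    if missing:
        raise KeyError(f"signature genes missing from matrix: {missing[:5]}")
    X = _dense(adata[:, union])
    with np.errstate(invalid="ignore"):
        corr = np.corrcoef(X.T)
    corr = np.nan_to_num(corr, nan=0.0)
    pos = {g: i for i, g in enumerate(union)}

    def _prune(own: list[str], other: list[str], condition: str) -> Signature:
        own_idx = np.array([pos[g] for g in own])
        other_idx = np.array([pos[g] for g in other])
        records = []
        kept = []
        for g in own:
            i = pos[g]
            within = own_idx[own_idx != i]
            auto_r = corr[i, within].mean() if len(within) else 1.0
            cross_r = corr[i, other_idx].mean()
            keep = (auto_r >= auto_r_min) and (cross_r <= cross_r_max)
            records.append(
                {"gene": g, "auto_r": auto_r, "cross_r": cross_r, "kept": keep}
            )
            if keep:
                kept.append(g)
        if not kept:
            raise ValueError(
                f"pruning removed every gene of the {condition!r} signature; "
                "relax auto_r_min / cross_r_max"
            )
        return Signature(condition, list(own), kept, pd.DataFrame(records))

    return (
        _prune(sig_a.genes_initial, sig_b.genes_initial, sig_a.condition),
        _prune(sig_b.genes_initial, sig_a.genes_initial, sig_b.condition),
    )


def module_score(
    adata: AnnData,
    gene_set: list[str],
    config: ScoreConfig | None = None,
    seed: int | None = None,
) -> pd.Series:
    """Binned-control module score per cell.

    All genes are cut into ``n_bins`` equal-size bins by dataset-wide mean
    expression; for every signature gene, ``n_ctrl_per_gene`` control genes
    are drawn from its bin (without replacement when the bin is large
    enough, with replacement otherwise). The score is the mean expression
    over the signature minus the mean over the pooled controls.

    Signature genes are excluded from the control pools so the control
    average is a genuine background even in small gene universes; a bin
    holding nothing but signature genes falls back to the full bin.
    """
    config = config or ScoreConfig()
    if not gene_set:
        raise ValueError("gene_set must be non-empty")
    missing = [g for g in gene_set if g not in adata.var_names]
    if missing:
        raise KeyError(f"gene_set genes missing from matrix: {missing[:5]}")
    rng = np.random.default_rng(config.seed if seed is None else seed)
    X = _dense(adata)
    genes = np.asarray(adata.var_names)
    gene_means = X.mean(axis=0)
    # equal-size bins by mean-expression rank (lexicographic gene-id tie-break
    # via stable argsort keeps the binning deterministic)
    order = np.lexsort((genes, gene_means))
    n_genes = len(genes)
    bin_of = np.empty(n_genes, dtype=int)
    bin_of[order] = np.minimum(
        (np.arange(n_genes) * config.n_bins) // n_genes, config.n_bins - 1
    )
    set_idx = adata.var_names.get_indexer(gene_set)
    in_set = np.zeros(n_genes, dtype=bool)
    in_set[set_idx] = True
    bin_members = []
    for b in range(config.n_bins):
        members = np.flatnonzero((bin_of == b) & ~in_set)
        if len(members) == 0:
            members = np.flatnonzero(bin_of == b)
        bin_members.append(members)
    ctrl_idx: list[np.ndarray] = []
    for i in set_idx:
        members = bin_members[bin_of[i]]
        replace = len(members) < config.n_ctrl_per_gene
        ctrl_idx.append(
            rng.choice(members, size=config.n_ctrl_per_gene, replace=replace)
        )
    ctrl = np.concatenate(ctrl_idx)
    score = X[:, set_idx].mean(axis=1) - X[:, ctrl].mean(axis=1)
    return pd.Series(score, index=adata.obs_names, name="module_score")


def classify_cells(
    iri_scores: pd.Series, control_scores: pd.Series, margin: float = 0.0
) -> pd.DataFrame:
    """Three-way call per cell: IRI, Control, or neither.

    IRI if the injury score beats the control score by more than ``margin``
    and is positive; symmetrically for Control; everything else (including
    exact ties and all-nonpositive scores) is neither.
    """
    iri = np.asarray(iri_scores, dtype=float)
    ctrl = np.asarray(control_scores, dtype=float)
    if iri.shape != ctrl.shape:
        raise ValueError("score vectors must be aligned")
    call = np.full(iri.shape, "neither", dtype=object)
    call[(iri > ctrl + margin) & (iri > 0)] = "IRI"
    call[(ctrl > iri + margin) & (ctrl > 0)] = "Control"
    index = (
        iri_scores.index if isinstance(iri_scores, pd.Series) else pd.RangeIndex(len(iri))
    )
    return pd.DataFrame(
        {"iri_score": iri, "control_score": ctrl, "call": call}, index=index
    )


def iri_score_pipeline(
    adata: AnnData,
    condition_labels: pd.Series,
    config: ScoreConfig | None = None,
    injured_label: str = "IRI",
    control_label: str = "Control",
) -> tuple[Signature, Signature, pd.DataFrame]:
    """Derive, prune, score and classify in one pass.

    ``condition_labels`` must contain exactly the two labels named by
    ``injured_label`` and ``control_label``. Returns the pruned injury and
    control signatures plus the per-cell score/call table.
    """
    config = config or ScoreConfig()
    labels = pd.Series(condition_labels, index=adata.obs_names)
    present = set(labels.unique())
    if present != {injured_label, control_label}:
        raise ValueError(
            f"expected labels {{{injured_label!r}, {control_label!r}}}, got {present}"
        )
    degs = rank_condition_degs(adata, labels, config)
    sig_iri = Signature(injured_label, degs[injured_label]["gene"].tolist())
    sig_ctrl = Signature(control_label, degs[control_label]["gene"].tolist())
    sig_iri, sig_ctrl = prune_signature_by_correlation(
        adata, sig_iri, sig_ctrl, config.auto_r_min, config.cross_r_max
    )
    seeds = np.random.SeedSequence(config.seed).generate_state(2)
    iri_scores = module_score(adata, sig_iri.genes_pruned, config, seed=int(seeds[0]))
    ctrl_scores = module_score(adata, sig_ctrl.genes_pruned, config, seed=int(seeds[1]))
    calls = classify_cells(iri_scores, ctrl_scores, config.margin)
    return sig_iri, sig_ctrl, calls


def bulk_cluster_enrichment(
    bulk_deg_genes: list[str],
    adata: AnnData,
    cluster_labels: pd.Series,
) -> pd.DataFrame:
    """Mean per-cluster z-score of each bulk DEG.

    Each gene's normalized expression is z-scored across all single cells
    (population sd); the z-scores are then averaged within each cluster.
    Zero-variance genes are reported as all-zero rows.
    """
    missing = [g for g in bulk_deg_genes if g not in adata.var_names]
    if missing:
        raise KeyError(f"genes missing from single-cell matrix: {missing[:5]}")
    labels = pd.Series(cluster_labels, index=adata.obs_names)
    X = _dense(adata[:, bulk_deg_genes])
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    z = np.where(sd > 0, (X - mu) / np.where(sd > 0, sd, 1.0), 0.0)
    zdf = pd.DataFrame(z, index=adata.obs_names, columns=bulk_deg_genes)
    return zdf.groupby(labels, observed=True).mean().T
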