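"""Metacell construction and signed weighted coexpression network analysis.

Single-cell expression is too sparse for stable gene-gene correlation, so
cells are first pooled into metacells: each metacell is the mean
log-normalized profile of k cells drawn with replacement from one
cell-type x experimental-group stratum (bootstrapped aggregation). On the
metacell matrix, the signed similarity ((1 + r)/2)^beta is computed, turned
into a topological overlap matrix (TOM), and clustered by average-linkage
hierarchical clustering with a fixed-height cut. Modules smaller than the
minimum size are left unassigned ("grey"); modules whose eigengenes
correlate above the merge threshold are merged to a fixpoint. Module
eigengenes (first principal components), gene-eigengene correlations (kME),
hub genes, and per-group module specificity complete the output.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.cluster.hierarchy
import scipy.spatial.distance
from anndata import AnnData

__all__ = [
    "NetworkConfig",
    "MetacellMatrix",
    "CoexpressionNetwork",
    "build_metacells",
    "signed_adjacency",
    "topological_overlap",
    "detect_modules",
    "module_eigengene",
    "kme",
    "hub_genes",
    "module_group_specificity",
    "build_network",
    "scale_free_fit",
]

# WGCNA-style module color names, assigned by decreasing module size
_MODULE_COLORS = [
    "turquoise", "blue", "brown", "yellow", "green", "red", "black", "pink",
    "magenta", "purple", "greenyellow", "tan", "salmon", "cyan", "midnightblue",
    "lightcyan", "grey60", "lightgreen", "lightyellow", "royalblue", "darkred",
    "darkgreen", "darkturquoise", "darkgrey", "orange", "darkorange", "white",
    "skyblue", "saddlebrown", "steelblue", "paleturquoise", "violet",
]
GREY = "grey"


@dataclass
class NetworkConfig:
    beta: float = 12.0
    min_module_size: int = 50
    cut_correlation_threshold: float = 0.2
    merge_me_correlation: float = 0.8
    signed: bool = True

    def __post_init__(self) -> None:
        if self.beta < 1:
            raise ValueError("beta must be >= 1")
        for name in ("cut_correlation_threshold", "merge_me_correlation"):
            v = getattr(self, name)
            if not -1 <= v <= 1:
                raise ValueError(f"{name} must be in [-1, 1]")


@dataclass
class MetacellMatrix:
    """Gene expression aggregated over bootstrapped cell pools.

    ``expr`` is metacells x genes; ``provenance`` records each metacell's
    cell type, group, pool size k, and member barcodes.
    """

    expr: pd.DataFrame
    provenance: pd.DataFrame


@dataclass
class CoexpressionNetwork:
    adjacency: pd.DataFrame
    tom: pd.DataFrame
    modules: pd.Series  # gene -> module color, "grey" = unassigned
    eigengenes: pd.DataFrame  # metacell x module
    kme: pd.DataFrame  # gene x module
    hubs: dict[str, str] = field(default_factory=dict)
    group_specificity: pd.DataFrame | None = None


def build_metacells(
    adata: AnnData,
    k: int = 20,
    n_metacells_per_stratum: int = 20,
    seed: int = 0,
    cell_type_col: str = "cell_type",
    group_col: str = "condition",
) -> MetacellMatrix:
    """Bootstrapped metacell aggregation within cell-type x group strata.

    Each metacell is the mean of ``k`` cells sampled with replacement from
    one stratum of ``adata`` (expected to hold log-normalized expression).
    Empty strata are skipped with a warning.
    """
    if k <= 0 or n_metacells_per_stratum <= 0:
        raise ValueError("k and n_metacells_per_stratum must be positive")
    rng = np.random.default_rng(seed)
    obs = adata.obs
    X = adata.X
    if hasattr(X, "toarray"):
        X = X.toarray()
    X = np.asarray(X, dtype=float)
    strata = sorted(
        set(zip(obs[cell_type_col].astype(str), obs[group_col].astype(str)))
    )
    rows, prov = [], []
    for cell_type, group in strata:
        members = np.flatnonzero(
            (obs[cell_type_col].astype(str) == cell_type)
            & (obs[group_col].astype(str) == group)
        )
        if len(members) == 0:
            warnings.warn(f"empty stratum ({cell_type}, {group}); skipped")
            continue
        for m in range(n_metacells_per_stratum):
            pick = rng.choice(members, size=k, replace=True)
            rows.append(X[pick].mean(axis=0))
            prov.append(
                {
                    "metacell": f"{cell_type}|{group}|{m}",
                    "cell_type": cell_type,
                    "group": group,
                    "k": k,
                    "members": ";".join(adata.obs_names[pick]),
                }
            )
    provenance = pd.DataFrame(prov).set_index("metacell")
    expr = pd.DataFrame(
        np.vstack(rows), index=provenance.index, columns=adata.var_names
    )
    return MetacellMatrix(expr=expr, provenance=provenance)


def signed_adjacency(
    metacells: MetacellMatrix | pd.DataFrame, config: NetworkConfig | None = None
) -> pd.DataFrame:
    """Soft-thresholded signed adjacency a_ij = ((1 + cor_ij)/2)^beta.

    Zero-variance genes are dropped with a warning; with ``signed=False``
    the unsigned form |cor|^beta is used instead.
    """
    config = config or NetworkConfig()
    expr = metacells.expr if isinstance(metacells, MetacellMatrix) else metacells
    if expr.shape[0] < 3:
        raise ValueError("need at least 3 metacells to estimate correlations")
    sd = expr.std(axis=0, ddof=0)
    keep = sd > 0
    if not keep.all():
        warnings.warn(f"dropping {int((~keep).sum())} zero-variance genes")
        expr = expr.loc[:, keep]
    corr = np.corrcoef(expr.to_numpy().T)
    corr = np.clip(corr, -1.0, 1.0)
    if config.signed:
        adj = ((1.0 + corr) / 2.0) ** config.beta
    else:
        adj = np.abs(corr) ** config.beta
    np.fill_diagonal(adj, 1.0)
    return pd.DataFrame(adj, index=expr.columns, columns=expr.columns)


def topological_overlap(adjacency: pd.DataFrame) -> pd.DataFrame:
    """Topological overlap matrix of an adjacency.

    TOM_ij = (sum_u a_iu a_uj - a_ii a_ij - a_ij a_jj + a_ij)
             / (min(k_i, k_j) + 1 - a_ij),
    with connectivity k_i = sum_{u != i} a_iu; the diagonal is set to 1.
    """
    A = adjacency.to_numpy(dtype=float)
    L = A @ A
    diag = np.diag(A)
    numer = L - diag[:, None] * A - A * diag[None, :] + A
    k = A.sum(axis=1) - diag
    kmin = np.minimum(k[:, None], k[None, :])
    denom = kmin + 1.0 - A
    with np.errstate(invalid="ignore", divide="ignore"):
        tom = np.where(denom > 0, numer / denom, 0.0)
    np.fill_diagonal(tom, 1.0)
    return pd.DataFrame(tom, index=adjacency.index, columns=adjacency.columns)


def _assign_colors(labels: np.ndarray, genes: pd.Index) -> pd.Series:
    """Map integer cluster ids to color names by decreasing size (0 = grey)."""
    out = pd.Series(GREY, index=genes, dtype=object)
    ids, sizes = np.unique(labels[labels >= 0], return_counts=True)
    order = ids[np.argsort(-sizes, kind="stable")]
    for rank, cid in enumerate(order):
        color = (
            _MODULE_COLORS[rank]
            if rank < len(_MODULE_COLORS)
            else f"module{rank + 1}"
        )
        out.iloc[np.flatnonzero(labels == cid)] = color
    return out


def detect_modules(
    tom: pd.DataFrame,
    config: NetworkConfig | None = None,
    expr: pd.DataFrame | None = None,
) -> pd.Series:
    """Cut the TOM dendrogram into modules.

    Average-linkage hierarchical clustering on 1 - TOM, cut at height
    1 - ``cut_correlation_threshold``; clusters below ``min_module_size``
    are assigned grey. When ``expr`` (metacell x gene) is given, modules
    whose eigengenes correlate above ``merge_me_correlation`` are merged
    iteratively to a fixpoint. Labels are deterministic color names
    ordered by module size.
    """
    config = config or NetworkConfig()
    genes = tom.index
    dist = 1.0 - tom.to_numpy(dtype=float)
    np.fill_diagonal(dist, 0.0)
    dist = np.clip((dist + dist.T) / 2.0, 0.0, None)
    condensed = scipy.spatial.distance.squareform(dist, checks=False)
    Z = scipy.cluster.hierarchy.linkage(condensed, method="average")
    height = 1.0 - config.cut_correlation_threshold
    raw = scipy.cluster.hierarchy.fcluster(Z, t=height, criterion="distance")
    labels = raw.astype(int)
    for cid, size in zip(*np.unique(labels, return_counts=True)):
        if size < config.min_module_size:
            labels[labels == cid] = -1
    if (labels >= 0).sum() == 0:
        warnings.warn("no module reaches min_module_size; all genes grey")
        return pd.Series(GREY, index=genes, dtype=object)

    if expr is not None:
        # iterate ME-correlation merging to a fixpoint
        while True:
            modules = _assign_colors(labels, genes)
            names = [m for m in modules.unique() if m != GREY]
            if len(names) < 2:
                break
            mes = module_eigengene(expr, modules)
            corr = np.corrcoef(mes.to_numpy().T)
            merged = False
            for i in range(len(names)):
                for j in range(i + 1, len(names)):
                    if corr[mes.columns.get_loc(names[i]),
                            mes.columns.get_loc(names[j])] > config.merge_me_correlation:
                        a = modules == names[i]
                        b = modules == names[j]
                        new_id = labels[np.flatnonzero(a)[0]]
                        labels[b.to_numpy()] = new_id
                        merged = True
                        break
                if merged:
                    break
            if not merged:
                break
    return _assign_colors(labels, genes)


def module_eigengene(
    expr: MetacellMatrix | pd.DataFrame, modules: pd.Series
) -> pd.DataFrame:
    """First principal component scores per module (metacell x module).

    Gene columns are standardized; scores are scaled to unit variance and
    sign-oriented so the mean gene-eigengene correlation is positive.
    Grey genes are excluded.
    """
    X = expr.expr if isinstance(expr, MetacellMatrix) else expr
    out = {}
    for module in sorted(m for m in modules.unique() if m != GREY):
        members = modules.index[modules == module]
        if len(members) < 2:
            raise ValueError(f"module {module!r} has fewer than 2 genes")
        sub = X[members].to_numpy(dtype=float)
        sd = sub.std(axis=0, ddof=0)
        if (sd == 0).all():
            raise ValueError(f"module {module!r} has no expression variance")
        std = (sub - sub.mean(axis=0)) / np.where(sd > 0, sd, 1.0)
        u, s, vt = np.linalg.svd(std, full_matrices=False)
        me = u[:, 0] * s[0]
        me_sd = me.std(ddof=0)
        if me_sd == 0:
            raise ValueError(f"module {module!r} eigengene is degenerate")
        me = me / me_sd
        corr_sign = np.sign(np.mean([np.corrcoef(me, std[:, i])[0, 1]
                                     for i in range(std.shape[1])]))
        if corr_sign < 0:
            me = -me
        out[module] = me
    return pd.DataFrame(out, index=X.index)


def kme(
    expr: MetacellMatrix | pd.DataFrame, eigengenes: pd.DataFrame
) -> pd.DataFrame:
    """Gene x module Pearson correlations with the module eigengenes.

    Every gene (including grey) gets a kME value for every module.
    Zero-variance genes get kME 0.
    """
    X = expr.expr if isinstance(expr, MetacellMatrix) else expr
    xv = X.to_numpy(dtype=float)
    ev = eigengenes.to_numpy(dtype=float)
    xc = xv - xv.mean(axis=0)
    ec = ev - ev.mean(axis=0)
    xs = xc.std(axis=0, ddof=0)
    es = ec.std(axis=0, ddof=0)
    n = xv.shape[0]
    cov = xc.T @ ec / n
    denom = np.outer(xs, es)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.where(denom > 0, cov / np.where(denom > 0, denom, 1.0), 0.0)
    return pd.DataFrame(
        np.clip(r, -1.0, 1.0), index=X.columns, columns=eigengenes.columns
    )


def hub_genes(modules: pd.Series, kme_table: pd.DataFrame) -> dict[str, str]:
    """Per-module hub = member gene with maximal own-module kME (ties by id)."""
    hubs: dict[str, str] = {}
    for module in kme_table.columns:
        members = modules.index[modules == module]
        if len(members) == 0:
            continue
        vals = kme_table.loc[members, module]
        best = vals.max()
        hubs[module] = sorted(vals.index[vals == best])[0]
    return hubs


def module_group_specificity(
    eigengenes: pd.DataFrame, provenance: pd.DataFrame
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Mean eigengene per experimental group plus point-biserial correlation
    of each eigengene with each group's indicator."""
    groups = provenance.loc[eigengenes.index, "group"]
    mean_me = eigengenes.groupby(groups, observed=True).mean().T
    mean_me.index.name = "module"
    corrs = {}
    for g in sorted(groups.unique()):
        ind = (groups == g).to_numpy(dtype=float)
        if ind.std() == 0:
            corrs[g] = pd.Series(0.0, index=eigengenes.columns)
            continue
        corrs[g] = pd.Series(
            [np.corrcoef(eigengenes[m], ind)[0, 1] for m in eigengenes.columns],
            index=eigengenes.columns,
        )
    return mean_me, pd.DataFrame(corrs)


def scale_free_fit(adjacency: pd.DataFrame, n_breaks: int = 10) -> float:
    """R^2 of the log-log linear fit of the connectivity distribution.

    Diagnostic for choosing the soft power beta; not used to auto-select it.
    """
    A = adjacency.to_numpy(dtype=float)
    k = A.sum(axis=1) - np.diag(A)
    k = k[k > 0]
    if len(k) < n_breaks:
        return float("nan")
    hist, edges = np.histogram(k, bins=n_breaks)
    centers = (edges[:-1] + edges[1:]) / 2.0
    mask = (hist > 0) & (centers > 0)
    if mask.sum() < 3:
        return float("nan")
    x = np.log10(centers[mask])
    y = np.log10(hist[mask] / hist.sum())
    r = np.corrcoef(x, y)[0, 1]
    return float(r**2)


def build_network(
    metacells: MetacellMatrix, config: NetworkConfig | None = None
) -> CoexpressionNetwork:
    """Full pipeline: adjacency -> TOM -> modules -> MEs -> kME -> hubs."""
    config = config or NetworkConfig()
    adj = signed_adjacency(metacells, config)
    tom = topological_overlap(adj)
    expr = metacells.expr[adj.columns]
    modules = detect_modules(tom, config, expr=expr)
    if (modules != GREY).sum() == 0:
        empty = pd.DataFrame(index=metacells.expr.index)
        return CoexpressionNetwork(adj, tom, modules, empty,
                                   pd.DataFrame(index=adj.index), {}, None)
    mes = module_eigengene(expr, modules)
    kme_table = kme(expr, mes)
    hubs = hub_genes(modules, kme_table)
    mean_me, _ = module_group_specificity(mes, metacells.provenance)
    return CoexpressionNetwork(
        adjacency=adj,
        tom=tom,
        modules=modules,
        eigengenes=mes,
        kme=kme_table,
        hubs=hubs,
        group_specificity=mean_me,
    )
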