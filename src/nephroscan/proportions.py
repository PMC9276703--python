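"""Differential proportion analysis (DPA).

Permutation test for shifts in cluster fractions between two experimental
groups. The observed statistic per cluster is the difference in the
cluster's within-group fraction. The null distribution is built by
repeatedly drawing a random subsample of cells — the subsample fraction is
uniform on (w, 1], so the parameter w sets a floor on how much of the data
is reshuffled — and permuting the cluster labels of the subsampled cells
across the pooled groups while group labels stay fixed. Lower w values
trend toward a stricter test (fewer significant clusters), higher values
toward more.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["DPAConfig", "ProportionResult", "proportion_table", "dpa_test"]


@dataclass
class DPAConfig:
    w: float = 0.1
    n_iter: int = 100_000
    two_sided: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.w <= 1:
            raise ValueError("w must be in (0, 1]")
        if self.n_iter < 100:
            raise ValueError("n_iter must be >= 100")


@dataclass
class ProportionResult:
    table: pd.DataFrame  # cluster x group counts
    fractions: pd.DataFrame  # column-normalized
    observed_diff: pd.Series  # frac(A) - frac(B) per cluster
    p_values: pd.Series
    group_a: str
    group_b: str

    def to_frame(self) -> pd.DataFrame:
        out = pd.DataFrame(
            {
                f"count_{self.group_a}": self.table[self.group_a],
                f"count_{self.group_b}": self.table[self.group_b],
                f"frac_{self.group_a}": self.fractions[self.group_a],
                f"frac_{self.group_b}": self.fractions[self.group_b],
                "diff": self.observed_diff,
                "p": self.p_values,
            }
        )
        out.index.name = "cluster"
        return out


def proportion_table(
    cluster_labels: pd.Series, group_labels: pd.Series
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Cluster x group counts and column-normalized fractions."""
    clusters = pd.Series(cluster_labels).reset_index(drop=True)
    groups = pd.Series(group_labels).reset_index(drop=True)
    if len(clusters) != len(groups):
        raise ValueError("cluster and group labels must be aligned")
    if len(groups) == 0 or groups.isna().any() or clusters.isna().any():
        raise ValueError("labels must be non-empty and free of missing values")
    counts = pd.crosstab(clusters, groups)
    counts.index.name = "cluster"
    counts.columns.name = "group"
    if (counts.sum(axis=0) == 0).any():
        raise ValueError("every group needs at least one cell")
    fractions = counts / counts.sum(axis=0)
    return counts, fractions


def dpa_test(
    cluster_labels: pd.Series,
    group_labels: pd.Series,
    group_a: str,
    group_b: str,
    config: DPAConfig | None = None,
) -> ProportionResult:
    """Permutation test for per-cluster proportion differences A vs B.

    p-values use the add-one estimator
    p = (1 + #{|null diff| >= |observed diff|}) / (1 + n_iter)
    (one-sided on the observed direction when ``config.two_sided`` is
    False), so they are never exactly zero.
    """
    config = config or DPAConfig()
    clusters = pd.Series(cluster_labels).reset_index(drop=True)
    groups = pd.Series(group_labels).reset_index(drop=True)
    for g in (group_a, group_b):
        if g not in set(groups):
            raise ValueError(f"group {g!r} not present")
    counts, fractions = proportion_table(clusters, groups)
    cluster_ids = counts.index.to_numpy()
    observed = fractions[group_a] - fractions[group_b]

    rng = np.random.default_rng(config.seed)
    cl_codes = pd.Categorical(clusters, categories=cluster_ids).codes.astype(np.int64)
    in_a = (groups == group_a).to_numpy()
    in_b = (groups == group_b).to_numpy()
    n = len(cl_codes)
    n_a, n_b = int(in_a.sum()), int(in_b.sum())
    k = len(cluster_ids)
    obs = observed.to_numpy()

    exceed = np.zeros(k, dtype=np.int64)
    abs_obs = np.abs(obs)
    for _ in range(config.n_iter):
        f = rng.uniform(config.w, 1.0)
        m = int(np.ceil(f * n))
        idx = rng.choice(n, size=m, replace=False)
        perm = cl_codes.copy()
        perm[idx] = perm[idx[rng.permutation(m)]]
        frac_a = np.bincount(perm[in_a], minlength=k) / n_a
        frac_b = np.bincount(perm[in_b], minlength=k) / n_b
        null = frac_a - frac_b
        if config.two_sided:
            exceed += np.abs(null) >= abs_obs
        else:
            exceed += np.where(obs >= 0, null >= obs, null <= obs)
    p = (1.0 + exceed) / (1.0 + config.n_iter)
    return ProportionResult(
        table=counts,
        fractions=fractions,
        observed_diff=observed,
        p_values=pd.Series(p, index=counts.index, name="p"),
        group_a=group_a,
        group_b=group_b,
    )
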