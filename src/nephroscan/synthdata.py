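"""Synthetic single-cell cohorts and drug screens with known ground truth.

This module generates data whose statistical structure mirrors a mouse
bilateral ischemia-reperfusion injury (IRI) study design: three experimental
arms (uninjured controls, short ischemia with adaptive repair, long ischemia
with maladaptive/fibrotic repair), kidney cell types with marker genes,
injury-dose-dependent proportion shifts (immune expansion, proximal-tubule
depletion), a maladaptive proximal-tubule subpopulation co-expressing
inflammatory genes, mitochondrial gene content, planted low-quality cells
and doublets, and L1000-like drug-response experiments with planted
signature effects.

Counts follow a negative-binomial gene model with log-normal per-cell
library sizes (the standard generative stand-in for UMI data). Every
generator call draws all randomness from a single seeded
``numpy.random.Generator`` stream, so identical configs give byte-identical
output.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp
from anndata import AnnData

__all__ = [
    "CellTypeSpec",
    "CohortConfig",
    "DrugScreenConfig",
    "default_cohort_config",
    "generate_cohort",
    "generate_drug_screen",
    "generate_lr_pairs",
    "write_cohort",
    "read_cohort",
    "write_drug_screen",
    "write_lr_pairs",
]


class ConfigurationError(ValueError):
    """Raised when a generator config violates its invariants."""


@dataclass
class CellTypeSpec:
    """One simulated cell type.

    Parameters
    ----------
    name
        Cluster label recorded in the cell metadata.
    marker_genes
        Genes upregulated in this type relative to all others.
    marker_fold_change
        Multiplicative expression increase of the markers (must be > 1).
    baseline_mean
        Scalar multiplier on the shared per-gene baseline profile; lets a
        type be globally brighter or dimmer.
    maladaptive_flag
        If set, the cohort-level inflammatory gene block is additionally
        upregulated in this type (the profibrotic proximal-tubule
        phenotype co-expressing chemokines such as Il1b/Cxcl2/Ccl3).
    """

    name: str
    marker_genes: list[str] = field(default_factory=list)
    marker_fold_change: float = 4.0
    baseline_mean: float = 1.0
    maladaptive_flag: bool = False

    def validate(self, gene_universe: set[str]) -> None:
        if self.marker_fold_change <= 1:
            raise ConfigurationError(
                f"cell type {self.name!r}: marker_fold_change must be > 1, "
                f"got {self.marker_fold_change}"
            )
        if self.baseline_mean <= 0:
            raise ConfigurationError(
                f"cell type {self.name!r}: baseline_mean must be positive"
            )
        unknown = set(self.marker_genes) - gene_universe
        if unknown:
            raise ConfigurationError(
                f"cell type {self.name!r}: marker genes not in universe: "
                f"{sorted(unknown)[:5]}"
            )


@dataclass
class CohortConfig:
    """Full specification of a synthetic cohort.

    ``conditions`` maps a condition label to its cell-type proportion
    vector (same order as ``cell_types``, summing to 1).
    ``condition_programs`` optionally plants condition-specific expression
    programs: label -> (gene list, fold change); cells of that condition
    have the program genes upregulated, providing ground truth for
    injury-score recovery tests.
    """

    n_cells_per_sample: int = 500
    n_samples_per_condition: int = 2
    conditions: dict[str, list[float]] = field(default_factory=dict)
    cell_types: list[CellTypeSpec] = field(default_factory=list)
    n_genes: int = 2000
    mito_gene_count: int = 13
    library_size_mean: float = 5000.0
    library_size_dispersion: float = 0.3
    nb_theta: float = 5.0
    mito_baseline_weight: float = 0.12
    lowq_fraction: float = 0.03
    doublet_fraction: float = 0.03
    condition_programs: dict[str, tuple[list[str], float]] = field(
        default_factory=dict
    )
    inflammatory_genes: list[str] = field(default_factory=list)
    inflammatory_fold_change: float = 6.0
    timepoint: str = "d14"
    seed: int = 0

    def gene_names(self) -> list[str]:
        """Gene universe: a reserved ``mt-`` prefixed mitochondrial block
        followed by nuclear genes."""
        if self.mito_gene_count >= self.n_genes:
            raise ConfigurationError("mito_gene_count must be < n_genes")
        mito = [f"mt-{i + 1}" for i in range(self.mito_gene_count)]
        nuc = [f"g{i:05d}" for i in range(self.n_genes - self.mito_gene_count)]
        return mito + nuc

    def validate(self) -> None:
        if self.n_cells_per_sample <= 0 or self.n_samples_per_condition <= 0:
            raise ConfigurationError("cell and sample counts must be positive")
        if self.n_genes <= 0 or self.mito_gene_count < 0:
            raise ConfigurationError("gene counts must be positive")
        if not self.conditions:
            raise ConfigurationError("at least one condition is required")
        if not self.cell_types:
            raise ConfigurationError("at least one cell type is required")
        if self.library_size_mean < 0 or self.library_size_dispersion < 0:
            raise ConfigurationError("library size parameters must be >= 0")
        if not 0 <= self.lowq_fraction < 1:
            raise ConfigurationError("lowq_fraction must be in [0, 1)")
        if not 0 <= self.doublet_fraction < 1:
            raise ConfigurationError("doublet_fraction must be in [0, 1)")
        universe = set(self.gene_names())
        for cond, props in self.conditions.items():
            if len(props) != len(self.cell_types):
                raise ConfigurationError(
                    f"condition {cond!r}: proportion vector length "
                    f"{len(props)} != number of cell types {len(self.cell_types)}"
                )
            if any(p < 0 for p in props):
                raise ConfigurationError(f"condition {cond!r}: negative proportion")
            if abs(sum(props) - 1.0) > 1e-9:
                raise ConfigurationError(
                    f"condition {cond!r}: proportions sum to {sum(props)}, not 1"
                )
        for ct in self.cell_types:
            ct.validate(universe)
        for cond, (genes, fc) in self.condition_programs.items():
            if cond not in self.conditions:
                raise ConfigurationError(f"program for unknown condition {cond!r}")
            unknown = set(genes) - universe
            if unknown:
                raise ConfigurationError(
                    f"program genes not in universe: {sorted(unknown)[:5]}"
                )
            if fc <= 0:
                raise ConfigurationError("program fold change must be positive")


@dataclass
class DrugScreenConfig:
    """L1000-like drug screen layout.

    ``planted_drugs`` maps drug ids to the mean log2 fold-change shift
    applied to signature genes in every experiment of that drug; all other
    gene effects are pure Gaussian noise.
    """

    n_drugs: int = 50
    n_experiments_per_drug: int = 3
    n_genes: int = 978
    planted_drugs: dict[str, float] = field(default_factory=dict)
    noise_sd: float = 1.0
    seed: int = 0

    def drug_ids(self) -> list[str]:
        return [f"drug{i:03d}" for i in range(self.n_drugs)]

    def validate(self) -> None:
        if self.n_drugs <= 0 or self.n_experiments_per_drug <= 0:
            raise ConfigurationError("drug and experiment counts must be positive")
        if self.n_genes < 10:
            raise ConfigurationError("n_genes must be >= 10")
        if self.noise_sd <= 0:
            raise ConfigurationError("noise_sd must be positive")
        ids = set(self.drug_ids())
        unknown = set(self.planted_drugs) - ids
        if unknown:
            raise ConfigurationError(f"planted drugs not in screen: {sorted(unknown)}")
        for d, eff in self.planted_drugs.items():
            if not np.isfinite(eff):
                raise ConfigurationError(f"non-finite effect for {d!r}")


def default_cohort_config(seed: int = 0, n_cells_per_sample: int = 500) -> CohortConfig:
    """Study-design defaults.

    Three arms with injury-dose-dependent composition: immune cells rise
    from 10% to 45% to 66% of cells while the proximal tubule (PT)
    fraction falls from 54% to 12% to 8%; a maladaptive inflammatory PT
    subpopulation appears only after long ischemia. An injury expression
    program is planted in both IRI arms and a homeostatic program in
    controls, so injury-state classification has ground truth.
    """
    genes = CohortConfig(n_genes=2000, mito_gene_count=13).gene_names()
    nuclear = [g for g in genes if not g.startswith("mt-")]
    # carve disjoint, deterministic gene blocks out of the nuclear universe
    pt_markers = nuclear[0:20]
    immune_markers = nuclear[20:40]
    endo_markers = nuclear[40:55]
    loh_markers = nuclear[55:70]
    inflammatory = nuclear[70:100]  # Il1b/Cxcl2/Ccl3-like chemokine block
    # broad condition responses: ischemic injury remodels hundreds of genes,
    # so the planted programs are wide enough to dominate top-k DEG lists
    injury_program = nuclear[100:200]
    control_program = nuclear[200:300]

    cell_types = [
        CellTypeSpec("PT", pt_markers, marker_fold_change=5.0),
        CellTypeSpec(
            "PT_maladaptive",
            pt_markers,
            marker_fold_change=3.0,
            maladaptive_flag=True,
        ),
        CellTypeSpec("Immune", immune_markers, marker_fold_change=5.0),
        CellTypeSpec("Endo", endo_markers, marker_fold_change=5.0),
        CellTypeSpec("LOH", loh_markers, marker_fold_change=5.0),
    ]
    # order: PT, PT_maladaptive, Immune, Endo, LOH
    conditions = {
        "Control": [0.54, 0.00, 0.10, 0.18, 0.18],
        "IRI_short": [0.12, 0.03, 0.45, 0.20, 0.20],
        "IRI_long": [0.08, 0.10, 0.66, 0.08, 0.08],
    }
    programs = {
        "IRI_short": (injury_program, 3.0),
        "IRI_long": (injury_program, 3.0),
        "Control": (control_program, 3.0),
    }
    return CohortConfig(
        n_cells_per_sample=n_cells_per_sample,
        conditions=conditions,
        cell_types=cell_types,
        condition_programs=programs,
        inflammatory_genes=inflammatory,
        seed=seed,
    )


def _expression_profile(
    config: CohortConfig,
    baseline: np.ndarray,
    gene_index: dict[str, int],
    cell_type: CellTypeSpec,
    condition: str,
) -> np.ndarray:
    """Relative expression rates (sum 1) for one cell type x condition."""
    rate = baseline * cell_type.baseline_mean
    rate = rate.copy()
    for g in cell_type.marker_genes:
        rate[gene_index[g]] *= cell_type.marker_fold_change
    if cell_type.maladaptive_flag:
        for g in config.inflammatory_genes:
            rate[gene_index[g]] *= config.inflammatory_fold_change
    if condition in config.condition_programs:
        genes, fc = config.condition_programs[condition]
        for g in genes:
            rate[gene_index[g]] *= fc
    return rate / rate.sum()


def generate_cohort(config: CohortConfig) -> AnnData:
    """Draw a full cohort as an :class:`~anndata.AnnData` of raw counts.

    ``adata.X`` is a sparse cells x genes integer count matrix;
    ``adata.obs`` records ground truth per cell: ``sample``, ``condition``,
    ``timepoint``, ``cell_type``, ``cluster`` (alias of cell type),
    ``is_doublet`` and ``is_lowq``.

    Low-quality cells are planted to fail standard filters: half receive a
    near-zero library (fewer than 200 detected genes), half a mitochondrial
    load above 50% of counts. Doublets are elementwise sums of two parent
    cells rescaled back to a singlet depth.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    genes = config.gene_names()
    gene_index = {g: i for i, g in enumerate(genes)}
    n_genes = len(genes)

    # shared per-gene baseline: gamma-distributed relative rates, with the
    # mitochondrial block pinned to a fixed share of expression
    baseline = rng.gamma(shape=0.4, scale=1.0, size=n_genes) + 1e-4
    mito_mask = np.array([g.startswith("mt-") for g in genes])
    if mito_mask.any():
        baseline[mito_mask] = (
            baseline[~mito_mask].sum()
            * config.mito_baseline_weight
            / (1 - config.mito_baseline_weight)
            / mito_mask.sum()
        )

    profiles: dict[tuple[str, str], np.ndarray] = {}
    for cond in config.conditions:
        for ct in config.cell_types:
            profiles[(cond, ct.name)] = _expression_profile(
                config, baseline, gene_index, ct, cond
            )

    type_names = [ct.name for ct in config.cell_types]
    rows: list[sp.csr_matrix] = []
    meta: dict[str, list] = {
        "sample": [],
        "condition": [],
        "timepoint": [],
        "cell_type": [],
        "is_doublet": [],
        "is_lowq": [],
    }

    theta = config.nb_theta

    def _draw_counts(profile: np.ndarray, lib: float) -> np.ndarray:
        mu = profile * lib
        lam = rng.gamma(theta, mu / theta)
        return rng.poisson(lam)

    for cond in config.conditions:
        props = np.asarray(config.conditions[cond], dtype=float)
        for s in range(config.n_samples_per_condition):
            sample_id = f"{cond}_s{s + 1}"
            n = config.n_cells_per_sample
            assignments = rng.choice(len(type_names), size=n, p=props)
            lowq = rng.random(n) < config.lowq_fraction
            if config.library_size_mean > 0:
                libs = rng.lognormal(
                    mean=np.log(config.library_size_mean),
                    sigma=config.library_size_dispersion,
                    size=n,
                )
            else:
                libs = np.zeros(n)
            block = np.zeros((n, n_genes), dtype=np.int64)
            for i in range(n):
                profile = profiles[(cond, type_names[assignments[i]])]
                lib = libs[i]
                if lowq[i]:
                    if rng.random() < 0.5:
                        # shredded cell: tiny library -> <200 detected genes
                        lib = min(lib, 100.0)
                        block[i] = _draw_counts(profile, lib)
                    else:
                        # dying cell: mito block dominates (>50% of counts)
                        p = profile.copy()
                        p[mito_mask] *= 20.0
                        block[i] = _draw_counts(p / p.sum(), lib)
                else:
                    block[i] = _draw_counts(profile, lib)
            rows.append(sp.csr_matrix(block))
            meta["sample"].extend([sample_id] * n)
            meta["condition"].extend([cond] * n)
            meta["timepoint"].extend([config.timepoint] * n)
            meta["cell_type"].extend(type_names[a] for a in assignments)
            meta["is_doublet"].extend([False] * n)
            meta["is_lowq"].extend(lowq.tolist())

    X = sp.vstack(rows).tocsr()
    n_cells = X.shape[0]

    # doublets: sum two random parents, rescale to the first parent's depth
    n_doublets = int(round(config.doublet_fraction * n_cells))
    if n_doublets > 0:
        parents_a = rng.choice(n_cells, size=n_doublets, replace=False)
        parents_b = rng.integers(0, n_cells, size=n_doublets)
        d_rows = []
        for a, b in zip(parents_a, parents_b):
            summed = (X[a] + X[b]).toarray().ravel().astype(float)
            target = X[a].sum()
            total = summed.sum()
            if total > 0:
                scaled = rng.poisson(summed * (target / total))
            else:
                scaled = summed.astype(np.int64)
            d_rows.append(sp.csr_matrix(scaled.astype(np.int64)))
            meta["sample"].append(meta["sample"][a])
            meta["condition"].append(meta["condition"][a])
            meta["timepoint"].append(meta["timepoint"][a])
            meta["cell_type"].append(meta["cell_type"][a])
            meta["is_doublet"].append(True)
            meta["is_lowq"].append(False)
        X = sp.vstack([X] + d_rows).tocsr()

    obs = pd.DataFrame(meta)
    obs.index = [f"cell{i:06d}" for i in range(X.shape[0])]
    obs["cluster"] = obs["cell_type"]
    var = pd.DataFrame(index=pd.Index(genes, name="gene_id"))
    var["is_mito"] = mito_mask if X.shape[1] == n_genes else mito_mask
    adata = AnnData(X=X.astype(np.int32), obs=obs, var=var)
    return adata


def generate_drug_screen(
    config: DrugScreenConfig, signature: list[str]
) -> dict[str, list[pd.DataFrame]]:
    """Per-drug lists of experiment fold-change tables.

    Each table has columns ``gene_id`` and ``log2fc``. Planted drugs shift
    the signature genes' fold changes by the configured effect in every
    experiment; all other entries are N(0, noise_sd) noise.
    """
    config.validate()
    if not signature:
        raise ConfigurationError("signature must be non-empty")
    rng = np.random.default_rng(config.seed)
    genes = [f"g{i:05d}" for i in range(config.n_genes)]
    gene_set = set(genes)
    missing = set(signature) - gene_set
    if missing:
        raise ConfigurationError(
            f"signature genes outside the screen universe: {sorted(missing)[:5]}"
        )
    sig_idx = np.array([genes.index(g) for g in signature])
    screen: dict[str, list[pd.DataFrame]] = {}
    for drug in config.drug_ids():
        effect = config.planted_drugs.get(drug, 0.0)
        tables = []
        for _ in range(config.n_experiments_per_drug):
            fc = rng.normal(0.0, config.noise_sd, size=config.n_genes)
            fc[sig_idx] += effect
            tables.append(pd.DataFrame({"gene_id": genes, "log2fc": fc}))
        screen[drug] = tables
    return screen


def generate_lr_pairs(
    n_pairs: int, gene_universe: list[str], seed: int = 0
) -> pd.DataFrame:
    """Disjoint ordered (ligand, receptor) pairs sampled from the universe."""
    if n_pairs < 0:
        raise ConfigurationError("n_pairs must be >= 0")
    if 2 * n_pairs > len(gene_universe):
        raise ConfigurationError(
            f"need {2 * n_pairs} distinct genes but universe has "
            f"{len(gene_universe)}"
        )
    rng = np.random.default_rng(seed)
    chosen = rng.choice(len(gene_universe), size=2 * n_pairs, replace=False)
    ligands = [gene_universe[i] for i in chosen[:n_pairs]]
    receptors = [gene_universe[i] for i in chosen[n_pairs:]]
    return pd.DataFrame({"ligand": ligands, "receptor": receptors})


# ---------------------------------------------------------------------------
# plain-text IO: MatrixMarket + TSV, round-trippable


def write_cohort(adata: AnnData, outdir: str | Path) -> None:
    """Write counts as genes x cells MatrixMarket plus TSV sidecars."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    scipy.io.mmwrite(str(outdir / "matrix.mtx"), sp.csc_matrix(adata.X.T))
    pd.DataFrame({"gene_id": adata.var_names}).to_csv(
        outdir / "features.tsv", sep="\t", index=False
    )
    pd.DataFrame({"barcode": adata.obs_names}).to_csv(
        outdir / "barcodes.tsv", sep="\t", index=False
    )
    adata.obs.rename_axis("barcode").to_csv(outdir / "cell_metadata.tsv", sep="\t")


def read_cohort(outdir: str | Path) -> AnnData:
    """Load a cohort written by :func:`write_cohort`."""
    outdir = Path(outdir)
    X = sp.csr_matrix(scipy.io.mmread(str(outdir / "matrix.mtx")).T)
    features = pd.read_csv(outdir / "features.tsv", sep="\t")
    obs = pd.read_csv(outdir / "cell_metadata.tsv", sep="\t", index_col="barcode")
    for col in ("is_doublet", "is_lowq"):
        if col in obs:
            obs[col] = obs[col].astype(bool)
    var = pd.DataFrame(index=pd.Index(features["gene_id"], name="gene_id"))
    var["is_mito"] = var.index.str.startswith("mt-")
    return AnnData(X=X.astype(np.int32), obs=obs, var=var)


def write_drug_screen(
    screen: dict[str, list[pd.DataFrame]], outdir: str | Path
) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for drug, tables in screen.items():
        for i, table in enumerate(tables):
            table.to_csv(outdir / f"{drug}_exp{i + 1}.tsv", sep="\t", index=False)


def write_lr_pairs(pairs: pd.DataFrame, path: str | Path) -> None:
    pairs.to_csv(path, sep="\t", index=False)
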