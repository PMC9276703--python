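"""End-to-end orchestration of the synthetic study.

Runs the stages in dependency order — cohort generation, quality control,
injury scoring, differential proportion analysis, coexpression network,
ligand-receptor screening, druggability screen — with one global seed that
deterministically spawns per-stage sub-seeds (hashed by stage name, so
toggling one stage never perturbs another's randomness). Each stage writes
its outputs under ``<outdir>/<stage>/`` and contributes counters to a run
manifest.
"""

from __future__ import annotations

import json
import logging
import time
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import coexpression, druggability, lri, proportions, qc, scoring, synthdata

__all__ = ["RunConfig", "DependencyError", "run_all", "stage_seed"]

log = logging.getLogger("nephroscan")

STAGES = [
    "synthdata",
    "qc",
    "scoring",
    "proportions",
    "coexpression",
    "lri",
    "druggability",
]


class DependencyError(RuntimeError):
    """A stage's required upstream product is missing."""


@dataclass
class RunConfig:
    outdir: str = "nephroscan_run"
    seed: int = 0
    n_cells_per_sample: int = 300
    stages: list[str] = field(default_factory=lambda: list(STAGES))
    qc_thresholds: qc.QCThresholds = field(default_factory=qc.QCThresholds)
    score_config: scoring.ScoreConfig = field(default_factory=scoring.ScoreConfig)
    dpa_config: proportions.DPAConfig = field(
        default_factory=lambda: proportions.DPAConfig(n_iter=2000)
    )
    network_config: coexpression.NetworkConfig = field(
        default_factory=coexpression.NetworkConfig
    )
    metacell_k: int = 20
    metacells_per_stratum: int = 20
    n_lr_pairs: int = 20
    lr_iters: int = 1000
    n_drugs: int = 20
    drug_perms: int = 1000

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        cfg = cls()
        for key in (
            "outdir", "seed", "n_cells_per_sample", "stages", "metacell_k",
            "metacells_per_stratum", "n_lr_pairs", "lr_iters", "n_drugs",
            "drug_perms",
        ):
            if key in raw:
                setattr(cfg, key, raw[key])
        if "qc" in raw:
            cfg.qc_thresholds = qc.QCThresholds(**raw["qc"])
        if "scoring" in raw:
            cfg.score_config = scoring.ScoreConfig(**raw["scoring"])
        if "dpa" in raw:
            cfg.dpa_config = proportions.DPAConfig(**raw["dpa"])
        if "network" in raw:
            cfg.network_config = coexpression.NetworkConfig(**raw["network"])
        unknown = [s for s in cfg.stages if s not in STAGES]
        if unknown:
            raise ValueError(f"unknown stages: {unknown}")
        return cfg


def stage_seed(global_seed: int, stage: str) -> int:
    """Deterministic per-stage sub-seed below 2^31."""
    state = np.random.SeedSequence(
        [int(global_seed), zlib.crc32(stage.encode())]
    ).generate_state(1)[0]
    return int(state % (2**31))


def run_all(config: RunConfig) -> dict:
    """Execute the enabled stages and return the run manifest."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"seed": config.seed, "stages": {}}
    products: dict = {}

    def _require(stage: str, *keys: str) -> None:
        missing = [k for k in keys if k not in products]
        if missing:
            raise DependencyError(
                f"stage {stage!r} requires upstream products {missing}; "
                "enable the producing stage(s)"
            )

    def _record(stage: str, t0: float, **counters) -> None:
        manifest["stages"][stage] = {
            "seed": stage_seed(config.seed, stage),
            "wall_time_s": round(time.perf_counter() - t0, 3),
            **counters,
        }

    if "synthdata" in config.stages:
        t0 = time.perf_counter()
        cohort_cfg = synthdata.default_cohort_config(
            seed=stage_seed(config.seed, "synthdata"),
            n_cells_per_sample=config.n_cells_per_sample,
        )
        adata = synthdata.generate_cohort(cohort_cfg)
        synthdata.write_cohort(adata, outdir / "synthdata")
        products["cohort"] = adata
        products["cohort_config"] = cohort_cfg
        _record("synthdata", t0, n_cells=adata.n_obs, n_genes=adata.n_vars)
        log.info("synthdata: %d cells x %d genes", adata.n_obs, adata.n_vars)

    if "qc" in config.stages:
        t0 = time.perf_counter()
        _require("qc", "cohort")
        adata = products["cohort"]
        mito = [g for g in adata.var_names if g.startswith("mt-")]
        cell_qc = qc.compute_cell_qc(adata, mito)
        keep = qc.filter_cells(cell_qc, config.qc_thresholds, drop_doublets=True)
        pd.DataFrame({"barcode": keep}).to_csv(
            _stage_dir(outdir, "qc") / "retained_barcodes.tsv", sep="\t", index=False
        )
        products["filtered"] = adata[keep].copy()
        _record("qc", t0, cells_in=adata.n_obs, cells_out=len(keep))
        log.info("qc: %d -> %d cells", adata.n_obs, len(keep))

    if "scoring" in config.stages:
        t0 = time.perf_counter()
        _require("scoring", "filtered")
        filtered = products["filtered"]
        lognorm = scoring.log_normalize(filtered)
        products["lognorm"] = lognorm
        binary = lognorm.obs["condition"].map(
            lambda c: "Control" if c == "Control" else "IRI"
        )
        cfg = scoring.ScoreConfig(
            **{**config.score_config.__dict__, "seed": stage_seed(config.seed, "scoring")}
        )
        sig_iri, sig_ctrl, calls = scoring.iri_score_pipeline(lognorm, binary, cfg)
        d = _stage_dir(outdir, "scoring")
        calls.rename_axis("barcode").to_csv(d / "cell_calls.tsv", sep="\t")
        for sig in (sig_iri, sig_ctrl):
            sig.prune_log.to_csv(d / f"prune_log_{sig.condition}.tsv",
                                 sep="\t", index=False)
        _write_gmt(
            d / "signatures.gmt",
            {
                f"{sig_iri.condition}_signature": sig_iri.genes_pruned,
                f"{sig_ctrl.condition}_signature": sig_ctrl.genes_pruned,
            },
        )
        products["signature_iri"] = sig_iri
        products["calls"] = calls
        _record("scoring", t0, n_iri_genes=len(sig_iri.genes_pruned),
                n_control_genes=len(sig_ctrl.genes_pruned),
                n_called_iri=int((calls["call"] == "IRI").sum()))

    if "proportions" in config.stages:
        t0 = time.perf_counter()
        _require("proportions", "filtered")
        filtered = products["filtered"]
        cfg = proportions.DPAConfig(
            **{**config.dpa_config.__dict__, "seed": stage_seed(config.seed, "proportions")}
        )
        res = proportions.dpa_test(
            filtered.obs["cluster"], filtered.obs["condition"],
            "Control", "IRI_long", cfg,
        )
        res.to_frame().to_csv(_stage_dir(outdir, "proportions") / "dpa.tsv", sep="\t")
        products["dpa"] = res
        _record("proportions", t0, n_clusters=len(res.p_values),
                n_significant=int((res.p_values < 0.05).sum()))

    if "coexpression" in config.stages:
        t0 = time.perf_counter()
        _require("coexpression", "lognorm")
        metacells = coexpression.build_metacells(
            products["lognorm"], k=config.metacell_k,
            n_metacells_per_stratum=config.metacells_per_stratum,
            seed=stage_seed(config.seed, "coexpression"),
        )
        net = coexpression.build_network(metacells, config.network_config)
        d = _stage_dir(outdir, "coexpression")
        net.modules.rename("module").rename_axis("gene").to_csv(
            d / "modules.tsv", sep="\t"
        )
        net.eigengenes.rename_axis("metacell").to_csv(d / "MEs.tsv", sep="\t")
        net.kme.rename_axis("gene").to_csv(d / "kME.tsv", sep="\t")
        (d / "network_config.yaml").write_text(
            yaml.safe_dump(config.network_config.__dict__)
        )
        products["network"] = net
        n_modules = len([m for m in net.modules.unique() if m != coexpression.GREY])
        _record("coexpression", t0, n_metacells=metacells.expr.shape[0],
                n_modules=n_modules)

    if "lri" in config.stages:
        t0 = time.perf_counter()
        _require("lri", "lognorm")
        lognorm = products["lognorm"]
        pairs = synthdata.generate_lr_pairs(
            config.n_lr_pairs, list(lognorm.var_names),
            seed=stage_seed(config.seed, "lri"),
        )
        results = lri.lr_permutation_test(
            lognorm, lognorm.obs["cluster"], pairs,
            n_iter=config.lr_iters, seed=stage_seed(config.seed, "lri"),
        )
        results.to_csv(_stage_dir(outdir, "lri") / "interactions.tsv",
                       sep="\t", index=False)
        products["lri"] = results
        _record("lri", t0, n_tested=len(results),
                n_significant=int(results["significant"].sum()) if len(results) else 0)

    if "druggability" in config.stages:
        t0 = time.perf_counter()
        _require("druggability", "signature_iri")
        sub_seed = stage_seed(config.seed, "druggability")
        screen_cfg = synthdata.DrugScreenConfig(
            n_drugs=config.n_drugs,
            planted_drugs={"drug000": 4.0},
            seed=sub_seed,
        )
        genes = [f"g{i:05d}" for i in range(screen_cfg.n_genes)]
        signature = genes[100:140]  # the planted injury program block
        screen = synthdata.generate_drug_screen(screen_cfg, signature)
        prls: dict[str, list[str]] = {}
        for drug, tables in screen.items():
            rankings = []
            for table in tables:
                # each table is already a per-experiment fold-change profile;
                # treat it as a single treated replicate against a zero baseline
                treated = table.set_index("gene_id")["log2fc"].to_frame().T
                _, ranking = druggability.drug_effect_ranking(
                    treated, treated * 0.0, drug_id=drug
                )
                rankings.append(ranking)
            prls[drug] = druggability.merge_prl(rankings)
        results = druggability.screen_drugs(
            prls, signature, n_perm=config.drug_perms, seed=sub_seed
        )
        d = _stage_dir(outdir, "druggability")
        out = results.copy()
        out["leading_edge"] = out["leading_edge"].map(";".join)
        out.to_csv(d / "drug_screen.tsv", sep="\t", index=False)
        products["drug_screen"] = results
        _record("druggability", t0, n_drugs=len(results),
                top_drug=str(results.iloc[0]["drug"]),
                n_pass_bonferroni=int((results["p_bonferroni"] < 0.05).sum()))

    manifest_path = outdir / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2))
    products["manifest"] = manifest
    return manifest


def _stage_dir(outdir: Path, stage: str) -> Path:
    d = outdir / stage
    d.mkdir(parents=True, exist_ok=True)
    return d


def _write_gmt(path: Path, sets: dict[str, list[str]]) -> None:
    lines = [
        "\t".join([name, "nephroscan"] + list(genes)) for name, genes in sets.items()
    ]
    path.write_text("\n".join(lines) + "\n")
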