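# nephroscan

Single-cell analysis toolkit for studying adaptive versus maladaptive
(fibrotic) kidney repair after ischemia-reperfusion injury (IRI).

After acute kidney injury, proximal tubule (PT) cells either regenerate or
adopt a profibrotic, cytokine-expressing "maladaptive" state that drives
chronic kidney disease. Dissecting that transition from single-cell
RNA-seq requires a set of bespoke statistical stages beyond standard
clustering, and this package implements them as a tested, reusable
library:

- **Quality control** — detected-gene and mitochondrial-percentage cell
  filters (strict 200 < n < 3000 bounds, mito ≤ 50%), minimum-expression
  gene filters, exact stratified downsampling.
- **Injury scoring** — condition signatures from rank-sum DEGs (min.pct
  0.05, logFC 0.2), correlation pruning, Tirosh-style binned-control
  module scores *s = mean(expr<sub>sig</sub>) − mean(expr<sub>ctrl</sub>)*
  with expression-bin-matched control genes, and a three-way
  IRI / Control / neither call per cell.
- **Differential proportion analysis (DPA)** — a permutation test for
  cluster-fraction shifts between groups: each iteration reshuffles the
  cluster labels of a random subsample (fraction ~ U(w, 1], w = 0.1) and
  p = (1 + #{|null Δ| ≥ |Δ|}) / (1 + n_iter).
- **Metacell coexpression networks** — bootstrapped metacell aggregation,
  signed adjacency *a<sub>ij</sub> = ((1 + r<sub>ij</sub>)/2)<sup>β</sup>*,
  topological overlap, fixed-height module cutting (min size 50, eigengene
  merge at r > 0.8), module eigengenes, kME and hub genes, per-group
  module specificity.
- **Ligand-receptor screening** — 5% expression gating, cluster-pair
  interaction means, 1000-iteration label-permutation test with
  Benjamini-Hochberg FDR.
- **Druggability screen** — L1000-style weighted fold-change drug
  rankings, prototype-ranked-list (PRL) consensus via hierarchical Borda
  merging, pre-ranked GSEA (ES/NES, permutation p, Bonferroni), leading
  edges and cross-drug leading-edge frequency.
- **Synthetic data** — a negative-binomial cohort generator emulating the
  study design (3 ischemia arms, injury-dose proportion shifts, a
  maladaptive inflammatory PT subpopulation, planted low-quality cells and
  doublets) plus L1000-like drug screens with planted effects, so every
  stage is testable against known ground truth.

The library operates on `AnnData` objects and plain-text interchange
formats (MatrixMarket + TSV/GMT/YAML), and ships a thin `nephroscan` CLI
over the same functions.

## Worked example

```python
from nephroscan import synthdata, qc, scoring, proportions

cfg = synthdata.default_cohort_config(seed=0, n_cells_per_sample=400)
adata = synthdata.generate_cohort(cfg)

mito = [g for g in adata.var_names if g.startswith("mt-")]
keep = qc.filter_cells(qc.compute_cell_qc(adata, mito), qc.QCThresholds(), True)
filtered = adata[keep].copy()

lognorm = scoring.log_normalize(filtered)
binary = lognorm.obs["condition"].map(lambda c: "Control" if c == "Control" else "IRI")
sig_iri, sig_ctrl, calls = scoring.iri_score_pipeline(
    lognorm, binary, scoring.ScoreConfig(seed=0))

res = proportions.dpa_test(
    filtered.obs["cluster"], filtered.obs["condition"], "Control", "IRI_long",
    proportions.DPAConfig(n_iter=10000, seed=0))
```

This prints (via the obvious `print` calls):

```
cohort: 2472 cells x 2000 genes
QC retained 2338/2472 cells
IRI signature: 93 genes (pruned from 100)
call
IRI        1549
Control     784
neither       5
                count_Control  count_IRI_long  frac_Control  frac_IRI_long    diff       p
cluster
Endo                      130              74        0.1660         0.0948  0.0713  0.0273
Immune                     75             492        0.0958         0.6300 -0.5342  0.0001
LOH                       138              58        0.1762         0.0743  0.1020  0.0053
PT                        440              66        0.5619         0.0845  0.4774  0.0001
PT_maladaptive              0              91        0.0000         0.1165 -0.1165  0.0002
```

Reading the output: all 134 planted low-quality cells and doublets are
removed by QC; the injury signature retains 93 of its initial 100 genes
after correlation pruning; cells from the injured arms are called `IRI`
and controls `Control` (the few `neither` calls sit at the score
boundary). The DPA table recovers the planted composition shift — immune
expansion (9.6% → 63%, p = 1e-4), proximal-tubule depletion (56% → 8.5%,
p = 1e-4) and the maladaptive PT population appearing only after long
ischemia (0% → 11.7%, p = 2e-4). p-values are add-one permutation
estimates, so 1e-4 is the floor at 10,000 iterations.

The full chain — including coexpression networks, ligand-receptor
screening and the drug screen — runs with one command:

```bash
nephroscan run --outdir run1 --seed 0
```

## Layout

```
src/nephroscan/
  synthdata.py      # cohort / drug-screen / LR-pair generators + IO
  qc.py             # cell & gene filters, stratified downsampling
  scoring.py        # DEG ranking, pruning, module scores, cell calls
  proportions.py    # differential proportion analysis
  coexpression.py   # metacells, adjacency/TOM, modules, MEs, kME
  lri.py            # ligand-receptor permutation testing
  druggability.py   # PRLs, pre-ranked GSEA, leading edges
  pipeline.py       # end-to-end orchestration, manifests
  cli.py            # click CLI over all of the above
docs/methods.md     # model and algorithm documentation
tests/              # unit, property and acceptance suites
```
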