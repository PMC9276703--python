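# Methods

`nephroscan` implements the bespoke computational stages of a single-cell
study design contrasting adaptive and maladaptive (fibrotic) kidney repair
after ischemia-reperfusion injury (IRI): quality control, injury-state
scoring, differential proportion analysis, metacell coexpression networks,
ligand-receptor screening, and an L1000-style druggability screen. Every
stage is exercised end-to-end on a synthetic cohort generator with planted
ground truth, so each method's recovery and calibration properties are
testable without any external download.

## Synthetic cohort model

Counts are negative-binomial per gene: for cell *c* with library size
*L<sub>c</sub>* and relative gene rate *p<sub>g</sub>*, counts are
Gamma-Poisson with mean *L<sub>c</sub> p<sub>g</sub>* and shape θ (default
θ = 5, a typical UMI overdispersion level; exposed as `nb_theta`). Library
sizes are log-normal (mean 5 000, log-sd 0.3). Gene baselines are gamma
draws shared across cell types; a reserved `mt-` block of 13 genes (the
mouse mitochondrial protein-coding count) is pinned to ~12% of baseline
expression so mitochondrial QC behaves realistically for tubule cells.

The default cohort mirrors the study design: three arms (Control,
IRI_short, IRI_long) × 2 samples; five cell types whose per-condition
proportions encode the injury-dose composition shift (immune cells 10 → 45
→ 66% of cells; proximal tubule 54 → 12 → 8%); and a maladaptive PT
subpopulation, present only after injury, that additionally upregulates a
30-gene inflammatory (chemokine-like) block. Condition-specific expression
programs — 100 genes upregulated 3-fold in injured cells, 100 in control
cells — give the injury score a known truth. The programs are deliberately
broad: an ischemic transcriptional response remodels hundreds of genes, and
a broad program is what makes top-k condition DEG lists dominated by
genuine response genes rather than by cell-type markers that merely track
the composition shift. Low-quality cells (default 3%) are planted either
with a shredded library (< 200 detected genes) or a dominant mitochondrial
load (> 50% of counts); doublets (default 3%) are element-wise sums of two
parent cells rescaled to a singlet depth. All randomness flows through one
seeded `numpy.random.Generator`, so output is byte-identical under a fixed
config.

What the generator does **not** emulate: batch effects, ambient RNA,
spliced/unspliced layers, realistic gene-gene correlation beyond the
planted programs, and continuous differentiation trajectories. Passing
recovery tests therefore demonstrates correctness of the statistical
machinery under the stated generative model, not performance on real
tissue.

## Quality control

Cells are retained when strictly inside the detected-gene bounds
(200 < n < 3000 — both boundary values excluded, following the stricter
figure-legend/Seurat convention) and at or below 50% mitochondrial counts
(a tie at exactly 50% is retained; the ceiling is deliberately permissive
because healthy proximal tubule carries high mitochondrial content).
Doublet removal consumes a boolean metadata column; no detection algorithm
is reimplemented. Gene filtering for trajectory-style analyses keeps genes
with ≥ 3 counts in ≥ 10 cells, and stratified downsampling draws an exact
per-cluster quota without replacement (e.g. 11 tubule subclusters × 150
cells = 1 650 cells).

## Injury scoring

Signatures are the top-100 most specific DEGs per condition from a
one-vs-rest two-sided Wilcoxon rank-sum test, gated on detection in ≥ 5%
of in-group cells and |logFC| ≥ 0.2. The log fold change uses the Seurat
dialect, ln((mean expm1 in + 1)/(mean expm1 out + 1)), stated explicitly
because dialects differ. Ranking is ascending p, ties by descending
|logFC|, then gene id. By default only genes upregulated in their
condition are eligible (`only_pos=True`): a condition signature must
consist of genes *high* in that condition, and with exactly two groups the
one-vs-rest contrasts are mirror images, so without the restriction both
signatures collapse onto one mixed list. The rank-sum test replaces a
hurdle model (MAST-style); for strong markers the orderings agree and no
extra dependency is needed.

Signature pairs are then pruned in a single pass computed on the initial
sets: a gene is kept iff its mean Pearson correlation with its own set is
≥ `auto_r_min` (default 0.1) and with the opposing set is ≤ `cross_r_max`
(default 0.0). Defaults are exposed because no canonical values exist.

Per-cell scores use the binned-control strategy (Tirosh-style): all genes
are cut into 24 equal-size bins by dataset-wide mean expression; each
signature gene draws 100 control genes from its bin (without replacement
when the bin suffices); the score is mean signature expression minus mean
pooled-control expression. Controls exclude signature genes (falling back
to the full bin if nothing else remains) so the control average is a true
background even in small gene universes. Cells are called `IRI` when the
injury score exceeds the control score by more than `margin` (default 0)
and is positive, symmetrically `Control`, otherwise `neither` — exact ties
and all-non-positive scores are `neither`, making the three-way partition
exhaustive and exclusive.

Bulk-DEG cluster enrichment z-scores each gene across all cells
(population SD; zero-variance genes map to all-zero rows) and averages
within clusters, so cluster-size-weighted row means are exactly zero.

## Differential proportion analysis

The observed statistic per cluster is the difference in within-group
fractions between two named groups. Each null iteration draws a subsample
fraction f ~ Uniform(w, 1] (default w = 0.1), selects ⌈f·n⌉ cells, and
permutes their cluster labels across the pooled groups with group labels
fixed; p-values are add-one two-sided, p = (1 + #{|null| ≥ |obs|})/(1 +
n_iter), never exactly zero. The default iteration count is 100 000;
simulations here use 2 000, which preserves calibration at the resolutions
tested. The subsample floor w controls strictness: smaller w reshuffles
less of the data on average, widening the null and yielding fewer
significant clusters (verified by simulation). Validity is established by
calibration — type-I error ≤ 0.07 at α = 0.05 under an exchangeable null —
rather than line-by-line identity with any particular prior
implementation, whose exact mechanism is not public.

## Metacell coexpression networks

Metacells are means of k cells (default 20) drawn with replacement from
one cell-type × experimental-group stratum of log-normalized expression
(mean rather than sum keeps the scale comparable across k); empty strata
are skipped with a warning. The signed adjacency is
a<sub>ij</sub> = ((1 + r<sub>ij</sub>)/2)<sup>β</sup> with soft power
β = 12 (the standard signed-network convention; a scale-free-fit R²
diagnostic is provided but β is never auto-selected). The topological
overlap matrix is

TOM<sub>ij</sub> = (Σ<sub>u</sub> a<sub>iu</sub>a<sub>uj</sub> −
a<sub>ii</sub>a<sub>ij</sub> − a<sub>ij</sub>a<sub>jj</sub> + a<sub>ij</sub>)
/ (min(k<sub>i</sub>, k<sub>j</sub>) + 1 − a<sub>ij</sub>),

with connectivity k<sub>i</sub> = Σ<sub>u≠i</sub> a<sub>iu</sub> and unit
diagonal. Modules come from average-linkage hierarchical clustering on
1 − TOM cut at height 1 − 0.2 (the correlation threshold interpreted as
the cut height; the dynamic tree-cut algorithm with its deepSplit
parameter is deliberately not reimplemented). Clusters under 50 genes are
unassigned ("grey"); modules whose eigengenes correlate above 0.8 are
merged iteratively to a fixpoint. Labels are WGCNA-style color names
ordered by module size, so results are invariant to gene ordering up to
nothing at all. Module eigengenes are first-principal-component scores of
the standardized module submatrix, unit variance, sign-oriented so the
mean gene-eigengene correlation is positive; kME is the gene × eigengene
Pearson correlation (computed for every gene including grey, which is
excluded only from hub calls); the hub is the member gene with maximal
own-module kME, ties by gene id.

## Ligand-receptor screening

A gene enters a cluster's expressed set when detected (count > 0) in
strictly more than 5% of that cluster's cells (detection rather than a
normalized-expression threshold, the simplest reading of a percent-of-cells
gate). For every gated (pair, sender, receiver) triple the score is the
mean of the ligand's sender-cluster mean and the receptor's
receiver-cluster mean; triples failing the gate are absent, not zero. The
null shuffles cluster labels over all cells (1 000 iterations), p is
add-one one-sided, and Benjamini-Hochberg controls FDR across all tested
triples (the generic "FDR methods" fixed to BH). Multi-subunit complexes
are not modeled; pairs are single genes.

## Druggability screen

Per-experiment drug effects are weighted average fold-change differences
between treated and untreated replicates; genes are ranked descending with
lexicographic tie-break. Per-drug rankings are merged into a prototype
ranked list (PRL) by hierarchical Borda aggregation: repeatedly merge the
two most Spearman-correlated rankings by summing rank vectors and
re-ranking until one consensus remains — idempotent for identical inputs,
lexicographic under full ties.

Pre-ranked GSEA uses the weighted Kolmogorov-Smirnov running sum: hit
increments |score|^p (p = 1 by default; the classic p = 0 form applies
when no per-gene scores exist, as with PRLs), miss decrements
1/(N − |S|), ES the extremum. The null is 1 000 random same-size gene
sets; NES divides ES by the mean |null ES| of the same sign. The p-value
is two-sided on |ES| over all permutations with the add-one estimator
(floor 1/(n_perm + 1)): a same-sign-only estimator's floor (≈ 2/n_perm)
would make family-wise correction across a 50-drug screen structurally
impossible at 1 000 permutations. The magnitude convention is very
slightly conservative mid-range when the null's sign split is uneven, and
its extreme tail is empirically calibrated (verified in the tests).
Bonferroni across drugs is min(1, p·n_drugs). Leading edges are the set
genes at or before the running-sum maximum (positive ES) or at or after
the minimum (negative ES), located with classic increments; leading-edge
frequency counts each signature gene's occurrences across the top-k drugs
(default 24).

## Orchestration and determinism

`pipeline.run_all` executes the stages in dependency order, failing fast
with a stage-tagged error when a disabled stage's product is required.
One global seed spawns per-stage sub-seeds by hashing the stage name into
a `SeedSequence`, so toggling one stage never perturbs another's draws;
manifests are identical across reruns modulo wall times. Every stage's
outputs are plain text (MatrixMarket + TSV/GMT/YAML/JSON) and re-loadable
as the next stage's input.

## Problem sizes

The reference analyses run at desk scale, chosen so the full suite and the
reproduction script each finish in about a minute: cohorts of 250-1 000
cells per sample over 2 000 genes, DPA calibration on 200 replicate
datasets of 2 000 cells at 2 000 iterations, networks of 140-200 genes
over 60-90 metacells, and 50-drug screens over a 978-gene (L1000-sized)
universe at 1 000 permutations. All sizes are arguments, not constants.

## Known limitations

- Fixed-height tree cutting is cruder than dynamic tree cut; closely
  spaced modules that the dendrogram joins below the cut height are never
  separated, regardless of the eigengene-merge rule.
- The DPA null is a reconstruction from a one-sentence description;
  equivalence is demonstrated by calibration, not provenance.
- Signature derivation on whole-cohort labels conflates composition and
  state when condition proportions shift extremely; the broad-program
  generator default reflects the biology but narrow planted programs will
  degrade classification (demonstrably so in development).
- The LR permutation null does not re-apply the expression gate per
  permutation, matching the common practice of gating observed triples
  only.
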