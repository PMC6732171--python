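# Methods

This note documents the statistics implemented in `cellstab`, the choices
made where the underlying procedures are commonly described only at the
contract level, and what the synthetic benchmarks do and do not demonstrate.

## The perturbation scheme

A stability analysis consists of a reference partition and `B` perturbation
runs. The reference is the clustering of the full, unperturbed matrix using
the master seed — per-cell persistence needs a fixed anchor. Run `b`
(1-based) removes a uniformly random `⌊f·n⌋`-subset of cells and
re-clusters the retained `⌈(1−f)·n⌉` cells. Both the removed subset and the
clusterer's own randomness in run `b` derive from the child seed
`master_seed + b` and nothing else, so runs are independent, order-free and
parallelisable, and the whole report is a pure function of
`(data, spec, B, f, master_seed)`. Defaults: `f = 0.1`, `B = 160`, with
`B ≥ 100` recommended.

Cells removed in a run contribute nothing for that run — no imputation of
their assignment. A cell retained in zero runs (probability `f^B`, ~1e-160
at the defaults) is reported as missing, never silently zero.

## Cell stability score (CSS)

The published description of per-cell Jaccard stability fixes the intent —
the persistence of a cell in a specific cluster under jackknife resampling —
but not a formula. We adopt the one comparison that is defined per cell and
per cluster and consistent with that intent: the Jaccard index between the
cell's reference co-cluster set (restricted to retained cells) and the run
cluster containing the cell, both sets including the cell itself, averaged
over retaining runs. **This is a reconstruction**, not a numerical
reproduction of any particular implementation. Two consequences worth
knowing:

- `CSS ∈ (0, 1]` wherever defined (self-membership makes the intersection
  non-empty), and `J(i,b) = 1` iff the restricted reference co-cluster set
  equals the run cluster exactly;
- CSS depends only on co-membership, never on label values, so it is
  invariant to relabelling on either side.

A thresholded variant (fraction of runs with `J ≥ t`) is exposed via
`css_threshold`; the mean-Jaccard form is the default and the one the tests
characterise.

Computation uses the per-run contingency table between reference and run
labels: for a cell with reference label `r` and run label `l`,
`J = n_rl / (a_r + b_l − n_rl)` where `a_r` is the retained size of
reference cluster `r` and `b_l` the size of run cluster `l`. This is exact
and `O(n)` per run; the test suite cross-checks it against a brute-force
set-arithmetic oracle on small cases.

## Cluster-level stability and silhouette

Per-cluster stability follows the bootstrap convention of cluster-wise
Jaccard assessment: `γ(C,b) = max_D |C∩ret_b∩D| / |(C∩ret_b)∪D|` over run
clusters `D`, averaged over runs where `C` retains at least one cell.
Clusters removed entirely in every run are flagged undefined.

Silhouettes use the standard `(b−a)/max(a,b)` with Euclidean distances in
the **same transform/PCA space the clusterer operated in**. This keeps the
silhouette comparable across k within one sweep; computing it in raw gene
space would measure a different geometry from the one that produced the
labels. Singleton clusters and fully degenerate (zero-distance) data score
0 by convention; k = 1 is an error.

## Choosing k by CSS sweep

`css_sweep` runs the full analysis for each candidate k, sharing the
perturbation schedule (the removed subsets depend only on the master seed
and run index, not on k), so per-k mean CSS values are paired comparisons.
Selected k = argmax of mean CSS, ties to the smallest k. Under-clustering
typically destabilises because which true clusters merge flips between
runs; over-clustering destabilises because spurious splits are re-drawn
differently each run. When an under-clustered merge is strongly preferred
by the geometry, its CSS can stay high — the sweep table (mean, median,
IQR, silhouette) should be read as a whole rather than reduced to the
argmax alone.

## Clustering engines

Both built-in engines operate on the top `P = 10` (configurable) principal
components of the transformed matrix; full-gene-space distances are
noise-dominated at realistic gene counts. PCA is computed by
eigendecomposition on the smaller side of the centred data; components with
near-zero variance are dropped, and fully constant input degrades to a
single-cluster partition with a warning (never an error, so perturbation
runs cannot crash mid-schedule).

- `kmeans_log`: k-means with k-means++ initialisation, 10 restarts, best
  inertia (scikit-learn), on `log10(count+1)` by default — the convention
  of k-taking engines.
- `graph_community`: symmetrised unweighted kNN graph (default
  `n_neighbors = 15`, Euclidean in PCA space) with greedy modularity
  maximisation (agglomerative CNM, deterministic). k emerges from the data
  and `propose_k` reports it.

Transforms: `log10p1`, `lognorm10k` (`ln(1 + 10^4·count/cell_total)`, the
global-scaling LogNormalize convention), or `none`. External clusterers
plug in through a subprocess contract (argv + matrix CSV path + k + output
path, returning a `barcode,label` CSV) or an in-process callable; their
internals are out of scope.

**Known limitation:** modularity maximisation on a kNN graph of
*homogeneous* data still finds geometric communities, so `propose_k`
over-estimates k on structureless data (it does not return 1 for a single
isotropic blob). It is reliable when clusters are actually separated; the
stability analysis itself is the tool for judging whether proposed clusters
are real.

## QC statistics and filters

- A gene is *detected* in a cell when it has ≥ `min_units` counts (default
  3 for UMI data; 5 is the usual choice for read-level counts).
- Mito/ribo percentages are fractions **of detected genes** (not of UMIs);
  an UMI-weighted variant exists behind `weight="umi"` without any claim of
  equivalence. Mito = case-insensitive `MT-` symbol prefix; ribo =
  `^RP[SL]\d` (cytosolic `Rps*/Rpl*`); mitochondrial-ribosomal `Mrp*` genes
  are excluded unless `include_mrp=True`. Zero-detection cells get NaN
  percentages, never a division by zero.
- `filter_cells` defaults: ≥ 100 detected genes, ≥ 100 total UMI,
  mito-percentage cap disabled unless set. All rules are evaluated on the
  full matrix, a cell is removed if it fails any enabled rule, and mito/ribo
  gene rows are dropped only after the cell rules. The audit attributes each
  removed cell to the first rule it failed, in application order.
- `lorenz_filter` is an explicit **reconstruction** of
  estimate-background-then-discard outlier filtering: per cell, the Gini
  coefficient of its gene count vector (twice the area between the Lorenz
  curve of cumulative count share vs cumulative gene share and the
  diagonal) summarises library complexity; cells are removed when their
  Gini is a one-sided robust outlier (median/MAD z, normal upper-tail p,
  BH-adjusted) at level alpha. `alpha = 0` removes nothing; at least 20
  cells are required for the score distribution to be meaningful.
- `count_depth_fit` regresses `log(count+1)` on `log(total UMI)` per gene
  by median (τ = 0.5) quantile regression over the cells where the gene is
  nonzero (expression-conditional fitting), for genes nonzero in ≥ 10
  cells; slopes are binned into equal-frequency groups. It is a diagnostic
  only — no depth normalisation is applied anywhere in the package.

## Marker signatures

`anova_like` tests each gene expressed in ≥ 3 cells by one-way ANOVA on
`log2(CPM+1)` across clusters, BH-corrected over tested genes. This is a
deliberate functional substitute for count-model (quasi-likelihood)
ANOVA-like testing: downstream consumers need per-gene across-cluster
signal plus an FDR, and the Gaussian ANOVA on log-CPM provides calibrated
type-I behaviour at the sample sizes involved (verified on pure-null
simulations). It is not a numerical reproduction of any count-model test.
Constant genes get statistic 0, p = 1. `top_markers` assigns each passing
gene to its highest-mean-CPM cluster and orders by (fdr ↑, statistic ↓,
gene id). `heatmap_export` orders cells by cluster then barcode and genes
by average-linkage hierarchical clustering of row-standardised
`log2(CPM+1)`; zero-variance rows standardise to zeros.

## Synthetic data generator

`generate` draws `counts[g,c] ~ NB(mean = baseline_g · fold(g, cluster(c)),
dispersion)` with gene baselines log-normal (meanlog 0.5, sdlog 1.2 on the
count scale), dispersion 0.1 (`var = μ + 0.1·μ²`), and fold
`marker_fold_change = 8` for each cluster's 20 marker genes inside that
cluster. Markers are drawn among genes with baseline mean ≥ 0.5 — planted
signatures should be detectably expressed, as real marker genes are.
Mito/ribo families are named with flaggable symbols (`mt-*`, `Rps*/Rpl*`;
2% / 5% of genes). Stressed cells are *constructed* (columns overwritten
with 25 detected genes at 3 counts each, 60% of them mitochondrial, total
UMI 75), which makes QC-filter tests exact set comparisons rather than
statistical ones.

What the generator does **not** emulate: per-cell library-size variation
beyond NB sampling noise, ambient RNA, doublets, batch effects, or
cell-cycle structure. Passing the planted-truth benchmarks therefore
demonstrates the correctness of the stability/QC/signature machinery under
clean, well-separated conditions — not clustering performance on real
tissue, where separation is weaker and depth effects are material.

Frozen presets (`easy2`, `easy3`, `easy5`, `null1`, `stressed_mix`) pin all
parameters including the seed; all generate in well under ten seconds.

## Problem sizes used in the checks

The automated checks run at desk scale by design: 300-cell / 2000-gene
matrices, `B = 100` perturbations, sweeps over k ∈ {2..6}, 10 master seeds
for the k-recovery experiment, 500-gene null simulations for the ANOVA
calibration. These sizes are large enough for the statistics to be
well-resolved while keeping the full suite in minutes on a single CPU;
production analyses simply scale `B`, the candidate-k grid and the matrix
dimensions up through the same interfaces.

## Numerical conventions collected

- Jaccard computations are exact integer arithmetic until the final
  division.
- PCA eigenvalues are clipped at zero; components below 1e-12 variance are
  dropped.
- k-means ties between equal-inertia restarts resolve to scikit-learn's
  deterministic choice for a fixed seed.
- BH correction is applied over exactly the set of tested/scored items,
  never over skipped ones.
- Undefined values (never-retained cells, zero-detection percentages,
  fully-removed clusters) propagate as NaN and are omitted-with-count in
  exports.
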