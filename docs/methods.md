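# Methods

## Model and procedure

The imputation model is deliberately simple: conditional on a cell
clustering being the true hidden classification, the expected value of a
dropout entry is the mean of its gene over the cells of its cluster, zeros
included. Because no single clustering is trusted, the estimate is averaged
over an ensemble of H clusterings that vary the similarity metric and the
number of clusters. The only entries ever modified are those that are zero
in the input; this "hot deck" restriction is what distinguishes the method
from smoothing-based approaches that also perturb observed values.

Pipeline stages and their conventions:

1. **Gene filtering.** A gene is "expressed" in a cell if its count is
   strictly positive; genes expressed in fewer than `min_cells` (default 2)
   cells are removed before anything else.
2. **Size factors.** Median-of-ratios: each cell's factor is the median,
   over genes positive in every cell, of the cell's count divided by the
   gene's geometric mean. Sparse matrices often have *no* gene positive in
   every cell; the fallback then takes geometric means over expressing
   cells only and medians over the genes each cell expresses. It reduces to
   the dense estimator when all genes are usable and is logged as a warning
   when active. Size factors are relative quantities: rescaling one cell
   moves the geometric-mean reference too, so per-cell factors are defined
   only up to a common constant (the test suite asserts exactly this
   equivariance).
3. **Log transform.** `log10(count/s + 1)`; a zero count maps to exactly
   0.0, so the zero pattern of the expression matrix identifies the
   candidate dropouts.
4. **Base clusterings.** Pearson and Spearman correlation among cells
   (Spearman = Pearson on per-cell average ranks), PCA of the
   column-centered similarity matrix keeping `d = clamp(ceil(0.05·p), 2,
   p−1)` components, then k-means (k-means++ seeding, 10 restarts) for each
   k in 10..15. Component signs are fixed by making each component's
   largest-magnitude loading positive, so scores are reproducible across
   runs and solvers.
5. **Imputation.** Per clustering, gene-wise cluster means are computed
   vectorized; the per-clustering estimates at zero entries are averaged
   arithmetically. The target cell's own zero and zero-valued cluster
   mates enter the mean — the estimator conditions only on cluster
   membership — which yields the true-zero preservation property: if a
   gene is zero across the cell's cluster in every clustering, the imputed
   value is exactly 0.

## Parameters that matter

| parameter | default | meaning |
|---|---|---|
| `min_cells` | 2 | gene filter threshold (cells with count > 0) |
| `ks` | 10..15 | k-means cluster counts in the ensemble |
| `metrics` | pearson, spearman | similarity constructions |
| PCA fraction | 0.05 | fraction of components kept (min 2) |
| `n_start` | 10 | k-means restarts per configuration |
| `m_landmarks` | 1000 | landmark cells in large-scale mode |
| `batch_size` | 100 | mini-batch size in large-scale mode |
| large-scale threshold | 5000 cells | `mode="auto"` switchover |

The k range 10..15 is intentionally larger than the expected number of cell
types in most datasets: over-clustering splits true populations into pure
sub-clusters, which keeps cluster means homogeneous, while under-clustering
would mix populations and contaminate the means. When `max(ks)` is
infeasible for the cohort size the range is shrunk to
`max_k = max(2, p // 3)` with the lower end scaled proportionally (10..15
at 30 cells becomes 6..10) and the adjustment is logged; the clamp fires
automatically only when `max(ks) >= p`, where k-means itself would be
ill-posed.

Seeding: one master seed; each stage derives a child seed by CRC-32 hashing
of `(master, stage, metric, k)`, giving independent, stable streams and
bitwise-reproducible end-to-end runs in both exact and large-scale modes.

## Evaluation framework

Down-sampling is implemented as binomial count thinning — each count is
replaced by a Binomial(count, rate) draw — which is the matrix-level
equivalent of resampling raw reads (thinning compositions multiply:
thinning at 0.5 twice is distributionally thinning at 0.25, a property the
tests check over 200 seeds). Zeros of the thinned matrix are labeled
against the full matrix: *dropout zero* if the full value is positive,
*true zero* if the gene is zero across every cell of the cell's reference
cluster in the full data, *unlabeled* otherwise. Unlabeled zeros are
excluded from precision/recall/F1 since they fall in neither class; "an
entry was imputed" means its value exceeds `eps` (default 0, exposed as a
flag). The adjusted Rand index uses the Hubert–Arabie contingency-table
form, with ARI defined as 1 when the chance-corrected denominator vanishes
(e.g. both labelings trivial); cross-ARI averages pairwise ARIs over the
intersection of cell ids for each pair of runs. Kendall tau-b (scipy) is
provided for comparing pseudotime to ordinal stage labels.

## Synthetic data

The generator emulates what the benchmark needs and nothing more: K cell
populations with balanced sizes; per-gene baseline means lognormal around
`base_mean = 2` counts (spread 0.5 on the natural-log scale); 10% of genes
per cluster shifted up by `log_fc = 1` (≈ e-fold 2.7, a typical marker
effect); 10% of genes per cluster silenced to mean zero (the source of
cluster-consistent true zeros); per-cell library sizes lognormal with
spread 0.3; negative-binomial counts with dispersion 0.2 (gamma–Poisson
mixture) so that dropout is distinguishable from low expression; and a
dropout layer, by default binomial thinning at rate 0.3, alternatively an
expression-dependent logistic zeroing model. Default scale is 2000 genes ×
300 cells × 3 clusters.

What it does **not** emulate: batch effects, doublets, ambient RNA,
cell-cycle structure, continuous trajectories, or realistic gene–gene
correlation beyond cluster structure. Passing benchmarks on these data
therefore show that the algorithm behaves as designed under its own model
assumptions — clustered populations with technical zeros — not that it
resolves every failure mode of real datasets.

## Numerical choices and degenerate inputs

- Correlations of a constant cell are set to 0 (diagonal stays 1) with a
  warning rather than an error.
- Similarity entries are clipped to [−1, 1] against floating-point
  overshoot; the PCA of the similarity matrix uses scikit-learn's solver
  with a fixed internal random state so the randomized path at large p is
  deterministic.
- Cells left empty by aggressive thinning get size factor 1 (with a
  warning) inside the evaluation pipeline; the strict API still rejects
  empty cells.
- Singleton clusters are legal; zeros in them impute to 0.
- Labels attached to no cell (possible in hand-built assignments) keep a
  cluster mean of 0 rather than propagating NaN.
- Real-valued matrices are written with 6 significant digits; counts are
  written exactly and round-trip bit-perfectly through MTX/CSV/TSV.

## Design choices where the design was open

- Whether the target cell's own zero enters its cluster mean is ambiguous;
  it is included (the literal reading of the conditional mean), and
  `exclude_self=True` / `--exclude-self` flips to the leave-one-out mean.
- The landmark construction for large data — correlations of all cells
  against a sampled subset followed by PCA of that rectangular matrix —
  is one of several reasonable sampling-PCA schemes; it was chosen because
  it reuses the exact pipeline's machinery and degrades gracefully (at
  `m_landmarks = p` it coincides with the exact construction up to column
  subsetting).
- Benchmark problem sizes (2000×300 for discrimination, 5000 cells for the
  large-scale comparison, 200 seeds for thinning statistics) were chosen
  as the smallest scales at which the measured quantities are stable.

## Known limitations

- Only cell-level similarity is modeled; gene–gene correlation is unused.
- Nonzero entries are never revised, so under-counted (but nonzero)
  entries remain under-counted.
- The true-zero definition is cluster-relative: with a poor reference
  clustering, genuinely expressed-but-silent-in-cluster patterns can be
  mislabeled.
- Very sparse matrices rely on the sparse size-factor fallback, which is a
  pragmatic extension of median-of-ratios rather than a published
  estimator.
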