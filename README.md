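# drimpute

Ensemble hot-deck imputation of dropout zeros in single-cell RNA-seq
gene×cell count matrices, with the down-sampling machinery to measure how
well imputation separates technical dropouts from genuine absence of
expression.

## The problem

Droplet and plate-based scRNA-seq capture only a fraction of each cell's
transcripts, so the expression matrix is riddled with zeros of two kinds:
**true zeros** (the gene is not expressed in that cell type) and **dropout
zeros** (the transcript was present but not captured). Treating dropouts as
real zeros distorts clustering, visualization and pseudotime inference.
This package is for analysts who want to fill in dropouts *before* running
such downstream tools, without touching any observed (nonzero) value.

## The method

Let `X` be the n×p log-expression matrix (genes × cells) after gene
filtering, median-of-ratios size-factor normalization and `log10(x + 1)`.
Cells are clustered H times: Pearson and Spearman cell-cell correlation
matrices, PCA onto the first 5% of components, and k-means for each
k ∈ {10, …, 15} — H = 2 × 6 = 12 base clusterings `C_1..C_H` by default.
Under clustering `C_h`, every zero entry is estimated by the mean of its
gene over the cells of its cluster,

    E(x_ij | C_h) = mean(x_ij : cells in the same cluster as j under C_h),

and the final value is the ensemble average

    E(x_ij) = (1/H) Σ_h E(x_ij | C_h).

Nonzero entries are copied through untouched, and a zero whose gene is zero
across the whole cluster in every clustering stays exactly zero — true
zeros are preserved, dropouts bordered by expressing cluster-mates are
filled. For large datasets (> 5000 cells by default) the full p×p
correlation matrix is replaced by correlations against a random landmark
subset and k-means by mini-batch k-means.

## Worked example

```sh
drimpute simulate --genes 2000 --cells 300 --clusters 3 --seed 1 --out-prefix sim
drimpute impute --input sim.observed.mtx --out imputed.csv --seed 1
drimpute evaluate --full sim.observed.mtx --labels sim.labels.tsv \
    --rates 0.25 --seeds 1 --out report.tsv
```

`report.tsv` from the run above contains (abridged):

```
rate  seed  tp      tn     fp  fn   precision  recall    f1        f1_gene_mean  rmse_imputed  rmse_zero
0.25  1     159148  59400  0   290  1          0.998181  0.99909   0.842972      0.364525      0.427719
```

Reading: of the zeros created by thinning the matrix to 25% of its reads,
159 148 were dropouts that the method filled (`tp`) and only 290 were
missed (`fn`); all 59 400 cluster-consistent true zeros were left at zero
(`tn`, `fp = 0`), for an F1 of 0.999 versus 0.843 for a naive gene-mean
imputer. The root-mean-square error to the full-depth log expression at
dropout entries falls from 0.428 (leaving zeros) to 0.365 (imputing).

The same pipeline is available as a library:

```python
from drimpute import SyntheticParams, generate_dataset, drimpute

ds = generate_dataset(SyntheticParams(seed=1))
result, X = drimpute(ds.observed_counts, seed=1)   # H = 12 clusterings
result.X_imputed                                   # n×p, zeros filled
```

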