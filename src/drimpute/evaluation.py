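"""Down-sampling evaluation of dropout imputation.

The evaluation treats a deeply sequenced count matrix as ground truth,
simulates a shallower experiment by binomial thinning of counts, and asks
whether imputation can tell the two kinds of zeros in the thinned matrix
apart:

* **true zeros** — entries whose gene is zero across *all* cells of the
  cell's reference cluster in the full data (genuine absence);
* **dropout zeros** — entries that are zero after thinning but positive in
  the full data (technical loss).

An imputer should fill the dropout zeros (true positives) and leave the true
zeros at zero (true negatives); discrimination is summarized by precision,
recall and F1.  The module also provides the clustering-agreement metrics
used to assess robustness: the Hubert–Arabie adjusted Rand index, mean
pairwise (partial) ARI across repeated runs, Kendall tau-b for pseudotime
concordance, and Pearson concordance of imputed values between settings.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import sparse
from scipy.special import comb
from scipy.stats import kendalltau

from .ensemble_clustering import ClusterAssignment, build_ensemble, child_seed
from .impute_core import ImputationResult, ensemble_impute
from .matrix_io import CountMatrix, MatrixValidationError
from .preprocess import ExpressionMatrix, filter_genes, normalize_log, size_factors

logger = logging.getLogger(__name__)

# codes in ZeroLabels.codes
NOT_ZERO = -1
TRUE_ZERO = 0
DROPOUT_ZERO = 1
UNLABELED = 2

DEFAULT_RATES = (0.1, 0.15, 0.25, 0.4, 0.63)


@dataclass(frozen=True, eq=False)
class ZeroLabels:
    """Classification of the zero entries of a down-sampled matrix.

    ``codes`` has one entry per matrix cell: −1 where the down-sampled value
    is nonzero, else TRUE_ZERO (0), DROPOUT_ZERO (1) or UNLABELED (2).
    """

    codes: np.ndarray

    @property
    def true_zero(self) -> np.ndarray:
        return self.codes == TRUE_ZERO

    @property
    def dropout_zero(self) -> np.ndarray:
        return self.codes == DROPOUT_ZERO

    @property
    def unlabeled(self) -> np.ndarray:
        return self.codes == UNLABELED

    @property
    def entries(self) -> dict[tuple[int, int], str]:
        names = {TRUE_ZERO: "true_zero", DROPOUT_ZERO: "dropout_zero",
                 UNLABELED: "unlabeled"}
        rows, cols = np.nonzero(self.codes >= 0)
        return {
            (int(i), int(j)): names[int(self.codes[i, j])]
            for i, j in zip(rows, cols)
        }


@dataclass(frozen=True)
class PRF1:
    """Confusion counts and derived precision/recall/F1."""

    tp: int
    tn: int
    fp: int
    fn: int

    @property
    def precision(self) -> float:
        d = self.tp + self.fp
        return self.tp / d if d else 0.0

    @property
    def recall(self) -> float:
        d = self.tp + self.fn
        return self.tp / d if d else 0.0

    @property
    def f1(self) -> float:
        p, r = self.precision, self.recall
        return 2 * p * r / (p + r) if (p + r) else 0.0


def downsample_counts(m: CountMatrix, rate: float, seed: int) -> CountMatrix:
    """Binomial thinning: each count c is replaced by a Binomial(c, rate) draw.

    Simulates sequencing the same library at ``rate`` times the depth.
    """
    if not 0 < rate <= 1:
        raise ValueError("rate must be in (0, 1]")
    if rate == 1.0:
        return m
    rng = np.random.default_rng(seed)
    coo = m.values.tocoo()
    data = rng.binomial(coo.data, rate)
    thinned = sparse.csr_matrix(
        (data, (coo.row, coo.col)), shape=m.values.shape
    )
    return CountMatrix(thinned, m.gene_ids, m.cell_ids)


def _labels_array(
    reference: ClusterAssignment | np.ndarray | Sequence[int], p: int
) -> np.ndarray:
    labels = reference.labels if isinstance(reference, ClusterAssignment) else reference
    labels = np.asarray(labels)
    if labels.shape != (p,):
        raise MatrixValidationError(
            f"reference clustering covers {labels.size} cells, expected {p}"
        )
    _, dense = np.unique(labels, return_inverse=True)
    return dense


def classify_zeros(
    full_X: ExpressionMatrix,
    down_X: ExpressionMatrix,
    reference_clusters: ClusterAssignment | np.ndarray | Sequence[int],
) -> ZeroLabels:
    """Label each zero of ``down_X`` as true zero, dropout zero or unlabeled.

    A zero is a *true zero* if its gene is zero in ``full_X`` across every
    cell of the cell's reference cluster, a *dropout zero* if the full value
    is positive, and *unlabeled* otherwise (zero in the full data but not
    uniformly zero over the cluster).
    """
    if full_X.gene_ids != down_X.gene_ids or full_X.cell_ids != down_X.cell_ids:
        raise MatrixValidationError(
            "full and down-sampled matrices must share gene and cell ids"
        )
    labels = _labels_array(reference_clusters, full_X.n_cells)
    k = int(labels.max()) + 1
    full_pos = full_X.X > 0
    cluster_any_pos = np.zeros((full_X.n_genes, k), dtype=bool)
    for c in range(k):
        cluster_any_pos[:, c] = full_pos[:, labels == c].any(axis=1)
    uniformly_zero = ~cluster_any_pos[:, labels]  # n×p, per cell's own cluster

    codes = np.full(down_X.X.shape, NOT_ZERO, dtype=np.int8)
    zeros = down_X.X == 0
    codes[zeros & full_pos] = DROPOUT_ZERO
    codes[zeros & ~full_pos & uniformly_zero] = TRUE_ZERO
    codes[zeros & ~full_pos & ~uniformly_zero] = UNLABELED
    return ZeroLabels(codes)


def discrimination_scores(
    result: ImputationResult | np.ndarray,
    labels: ZeroLabels,
    eps: float = 0.0,
) -> PRF1:
    """Score dropout-vs-true-zero discrimination of an imputation.

    An entry counts as imputed iff its value exceeds ``eps``.  Only labeled
    zeros (true zero / dropout zero) enter the tally; unlabeled zeros are
    ignored.
    """
    X = result.X_imputed if isinstance(result, ImputationResult) else np.asarray(result)
    if X.shape != labels.codes.shape:
        raise MatrixValidationError("imputation and labels shapes differ")
    imputed = X > eps
    dropout, true_zero = labels.dropout_zero, labels.true_zero
    if not (dropout.any() or true_zero.any()):
        raise ValueError("no labeled zero entries to score")
    return PRF1(
        tp=int((dropout & imputed).sum()),
        tn=int((true_zero & ~imputed).sum()),
        fp=int((true_zero & imputed).sum()),
        fn=int((dropout & ~imputed).sum()),
    )


def adjusted_rand_index(a: Sequence[int], b: Sequence[int]) -> float:
    """Hubert–Arabie adjusted Rand index between two labelings.

    Computed from the contingency table as (Σ C(n_ij,2) − E) / (M − E) with
    E the chance expectation and M the mean of the two marginal pair sums.
    Degenerate case: if the chance-corrected denominator vanishes (e.g. both
    labelings put everything in one cluster) the index is 1.
    """
    a = np.asarray(a)
    b = np.asarray(b)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("labelings must be 1-D and of equal length")
    n = a.size
    if n < 2:
        raise ValueError("need at least 2 items")
    _, ai = np.unique(a, return_inverse=True)
    _, bi = np.unique(b, return_inverse=True)
    contingency = sparse.coo_matrix(
        (np.ones(n), (ai, bi)), shape=(ai.max() + 1, bi.max() + 1)
    ).toarray()
    sum_ij = comb(contingency, 2).sum()
    sum_a = comb(contingency.sum(axis=1), 2).sum()
    sum_b = comb(contingency.sum(axis=0), 2).sum()
    expected = sum_a * sum_b / comb(n, 2)
    mean_marg = 0.5 * (sum_a + sum_b)
    if np.isclose(mean_marg, expected):
        return 1.0
    return float((sum_ij - expected) / (mean_marg - expected))


def cross_ari(
    labelings: Sequence[tuple[Sequence, Sequence[int]] | Sequence[int]],
) -> float:
    """Mean pairwise ARI over all pairs of repeated clustering runs.

    Each element is either a plain label vector (all runs on the same cells)
    or a ``(cell_ids, labels)`` pair; for pairs, the ARI of two runs is the
    partial ARI computed on the intersection of their cell ids.  Pairs with
    fewer than 2 overlapping cells are skipped with a warning.
    """
    if len(labelings) < 2:
        raise ValueError("need at least 2 labelings")
    normalized: list[dict] = []
    for item in labelings:
        if (
            isinstance(item, tuple)
            and len(item) == 2
            and hasattr(item[0], "__len__")
            and hasattr(item[1], "__len__")
            and len(item[0]) == len(item[1])
        ):
            ids, labels = item
        else:
            labels = item
            ids = range(len(labels))
        normalized.append(dict(zip(ids, labels)))

    aris = []
    for d1, d2 in combinations(normalized, 2):
        overlap = [cid for cid in d1 if cid in d2]
        if len(overlap) < 2:
            logger.warning("pair with < 2 overlapping cells skipped")
            continue
        aris.append(
            adjusted_rand_index(
                [d1[c] for c in overlap], [d2[c] for c in overlap]
            )
        )
    if not aris:
        raise ValueError("no pair had >= 2 overlapping cells")
    return float(np.mean(aris))


def kendall_tau(pseudotime: Sequence[float], time_labels: Sequence) -> float:
    """Kendall tau-b (tie-corrected) between a pseudotime and ordinal labels."""
    x = np.asarray(pseudotime, dtype=float)
    y = np.asarray(time_labels, dtype=float)
    if x.shape != y.shape or x.size < 2:
        raise ValueError("vectors must have equal length >= 2")
    if np.all(x == x[0]) or np.all(y == y[0]):
        logger.warning("constant vector; Kendall tau undefined, returning 0")
        return 0.0
    return float(kendalltau(x, y).statistic)


def imputation_concordance(r1: ImputationResult, r2: ImputationResult) -> float:
    """Pearson correlation of imputed values over the shared zero entries."""
    if r1.zero_mask.shape != r2.zero_mask.shape or not np.array_equal(
        r1.zero_mask, r2.zero_mask
    ):
        raise ValueError("results were not computed on the same input matrix")
    v1, v2 = r1.imputed_values, r2.imputed_values
    if np.array_equal(v1, v2):
        return 1.0
    if np.std(v1) == 0 or np.std(v2) == 0:
        logger.warning("constant imputed values; concordance undefined, returning 0")
        return 0.0
    return float(np.corrcoef(v1, v2)[0, 1])


def gene_mean_impute(X: ExpressionMatrix | np.ndarray) -> np.ndarray:
    """Baseline: replace every zero with the gene's global mean expression."""
    A = X.X if isinstance(X, ExpressionMatrix) else np.asarray(X, float)
    out = A.copy()
    means = A.mean(axis=1, keepdims=True)
    zeros = A == 0
    out[zeros] = np.broadcast_to(means, A.shape)[zeros]
    return out


def _safe_size_factors(m: CountMatrix) -> np.ndarray:
    """Size factors tolerating all-zero cells (s = 1 for empty cells)."""
    totals = np.asarray(m.values.sum(axis=0)).ravel()
    if (totals > 0).all():
        return size_factors(m)
    logger.warning(
        "%d cell(s) empty after down-sampling; their size factors set to 1",
        int((totals == 0).sum()),
    )
    keep = totals > 0
    sub = CountMatrix(
        m.values[:, keep],
        m.gene_ids,
        tuple(c for c, k in zip(m.cell_ids, keep) if k),
    )
    s = np.ones(m.n_cells)
    s[keep] = size_factors(sub)
    return s


def evaluate_downsampling(
    full_counts: CountMatrix,
    reference_clusters: ClusterAssignment | np.ndarray | Sequence[int],
    rates: Iterable[float] = DEFAULT_RATES,
    seeds: Iterable[int] = (1,),
    *,
    ks: Iterable[int] = range(10, 16),
    metrics: Sequence[str] = ("pearson", "spearman"),
    mode: str = "auto",
    min_cells: int = 2,
    eps: float = 0.0,
) -> pd.DataFrame:
    """Run the full down-sampling benchmark and return one row per (rate, seed).

    For each condition: thin the (gene-filtered) full counts, normalize both
    matrices, impute the thinned one, label its zeros against the full data,
    and report the confusion counts, precision/recall/F1, the F1 of a
    gene-mean baseline imputer, and the RMSE to the full log expression at
    dropout entries with and without imputation.
    """
    filtered = filter_genes(full_counts, min_cells=min_cells)
    full_X = normalize_log(filtered, size_factors(filtered))
    labels = _labels_array(reference_clusters, filtered.n_cells)

    records = []
    for rate in rates:
        for seed in seeds:
            down = downsample_counts(
                filtered, rate, child_seed(seed, "downsample", rate)
            )
            down_X = normalize_log(down, _safe_size_factors(down))
            assignments = build_ensemble(
                down_X, ks=ks, metrics=metrics, mode=mode, seed=seed
            )
            result = ensemble_impute(down_X, assignments)
            zl = classify_zeros(full_X, down_X, labels)
            prf = discrimination_scores(result, zl, eps=eps)
            baseline = discrimination_scores(gene_mean_impute(down_X), zl, eps=eps)

            dropout = zl.dropout_zero
            truth = full_X.X[dropout]
            err_imp = result.X_imputed[dropout] - truth
            records.append(
                {
                    "rate": rate,
                    "seed": seed,
                    "tp": prf.tp, "tn": prf.tn, "fp": prf.fp, "fn": prf.fn,
                    "precision": prf.precision,
                    "recall": prf.recall,
                    "f1": prf.f1,
                    "f1_gene_mean": baseline.f1,
                    "rmse_imputed": float(np.sqrt(np.mean(err_imp**2))),
                    "rmse_zero": float(np.sqrt(np.mean(truth**2))),
                }
            )
    return pd.DataFrame.from_records(records)
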