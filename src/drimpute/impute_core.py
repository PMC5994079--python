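"""Hot-deck imputation of zero entries by cluster-mean averaging.

Given a log-expression matrix X and an ensemble of base clusterings
C_1..C_H, each zero entry x_ij is estimated, under each clustering, as the
mean of gene i over all cells in the cluster containing cell j — including
zero-valued cluster mates and cell j's own zero, since the estimator
conditions only on cluster membership.  The final imputed value is the
arithmetic mean of the H per-clustering estimates:

    E(x_ij) = (1/H) Σ_h E(x_ij | C_h)

Nonzero entries are never touched, and a zero whose gene is zero across the
whole cluster in every clustering remains exactly zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .ensemble_clustering import ClusterAssignment, ClusteringConfig, build_ensemble
from .matrix_io import CountMatrix
from .preprocess import ExpressionMatrix, preprocess


@dataclass(frozen=True, eq=False)
class ImputationResult:
    """Imputed matrix plus the zero mask and the configurations used."""

    X_imputed: np.ndarray
    zero_mask: np.ndarray
    configs: tuple[ClusteringConfig, ...]
    gene_ids: tuple[str, ...] = ()
    cell_ids: tuple[str, ...] = ()
    per_config_estimates: tuple[np.ndarray, ...] | None = None

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "X_imputed", np.asarray(self.X_imputed, dtype=np.float64)
        )
        object.__setattr__(self, "zero_mask", np.asarray(self.zero_mask, bool))
        if self.X_imputed.shape != self.zero_mask.shape:
            raise ValueError("zero_mask shape does not match matrix")
        if self.X_imputed.size and self.X_imputed.min() < 0:
            raise ValueError("imputed values must be non-negative")

    @property
    def imputed_values(self) -> np.ndarray:
        """Values at the entries that were zero in the input (flat vector)."""
        return self.X_imputed[self.zero_mask]


def _zero_estimates(
    A: np.ndarray,
    labels: np.ndarray,
    rows: np.ndarray,
    cols: np.ndarray,
    exclude_self: bool = False,
) -> np.ndarray:
    """Cluster-mean estimates at the zero entries ``(rows, cols)``.

    A label value with no cells (legal in hand-built assignments) and a
    singleton cluster under ``exclude_self`` both yield an estimate of 0.
    """
    k = int(labels.max()) + 1
    counts = np.bincount(labels, minlength=k).astype(np.float64)
    sums = np.zeros((A.shape[0], k))
    np.add.at(sums.T, labels, A.T)
    num = sums[rows, labels[cols]]
    den = counts[labels[cols]]
    if exclude_self:
        den = den - 1.0  # the target entry is 0, so the sum is unchanged
    est = np.zeros_like(num)
    np.divide(num, den, out=est, where=den > 0)
    return est


def cluster_mean_estimates(
    X: ExpressionMatrix | np.ndarray,
    a: ClusterAssignment,
    exclude_self: bool = False,
) -> dict[tuple[int, int], float]:
    """Estimates for every zero entry under one clustering.

    Returns a map {(gene_index, cell_index): estimate} where the estimate is
    the mean of the gene over the cluster containing the cell (zeros
    included).  Singleton clusters are legal: their zeros estimate to 0.
    ``exclude_self`` drops the target cell's own zero from the mean.
    """
    A = X.X if isinstance(X, ExpressionMatrix) else np.asarray(X, float)
    labels = a.labels
    if labels.size != A.shape[1]:
        raise ValueError("assignment does not cover all cells")
    rows, cols = np.nonzero(A == 0)
    est = _zero_estimates(A, labels, rows, cols, exclude_self)
    return {(int(i), int(j)): float(e) for i, j, e in zip(rows, cols, est)}


def ensemble_impute(
    X: ExpressionMatrix | np.ndarray,
    assignments: Sequence[ClusterAssignment],
    *,
    keep_per_config: bool = False,
    exclude_self: bool = False,
    gene_ids: Iterable[str] = (),
    cell_ids: Iterable[str] = (),
) -> ImputationResult:
    """Replace each zero of X by the mean over clusterings of its cluster mean."""
    if isinstance(X, ExpressionMatrix):
        A, gene_ids, cell_ids = X.X, X.gene_ids, X.cell_ids
    else:
        A = np.asarray(X, dtype=np.float64)
    if not assignments:
        raise ValueError("need at least one cluster assignment")
    p = A.shape[1]
    for a in assignments:
        if a.labels.size != p:
            raise ValueError("all assignments must cover the same cells")

    zero_mask = A == 0
    rows, cols = np.nonzero(zero_mask)
    acc = np.zeros(rows.size)
    per_config: list[np.ndarray] = []
    for a in assignments:
        est = _zero_estimates(A, a.labels, rows, cols, exclude_self)
        acc += est
        if keep_per_config:
            per_config.append(est)
    imputed = A.copy()
    imputed[rows, cols] = acc / len(assignments)
    return ImputationResult(
        imputed,
        zero_mask,
        tuple(a.config for a in assignments),
        tuple(gene_ids),
        tuple(cell_ids),
        tuple(per_config) if keep_per_config else None,
    )


def drimpute(
    counts: CountMatrix,
    ks: Iterable[int] = range(10, 16),
    metrics: Sequence[str] = ("pearson", "spearman"),
    mode: str = "auto",
    seed: int = 0,
    *,
    min_cells: int = 2,
    normalize: bool = True,
    m_landmarks: int = 1000,
    batch_size: int = 100,
    keep_per_config: bool = False,
    exclude_self: bool = False,
) -> tuple[ImputationResult, ExpressionMatrix]:
    """Full pipeline: preprocess → base-clustering ensemble → averaged imputation.

    Returns the imputation result together with the preprocessed expression
    matrix it was computed on.
    """
    X = preprocess(counts, min_cells=min_cells, normalize=normalize)
    assignments = build_ensemble(
        X, ks=ks, metrics=metrics, mode=mode, seed=seed,
        m_landmarks=m_landmarks, batch_size=batch_size,
    )
    result = ensemble_impute(
        X, assignments, keep_per_config=keep_per_config, exclude_self=exclude_self
    )
    return result, X
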