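"""Base clusterings for the imputation ensemble.

Cells are clustered by (1) building a cell-cell similarity matrix from
Pearson or Spearman correlation of their expression profiles, (2) projecting
onto the first 5% of principal components of that similarity matrix, and
(3) running k-means over a grid of cluster counts.  The grid
{Pearson, Spearman} × k ∈ [10, 15] gives the default ensemble of H = 12
clusterings.

For large datasets an approximate mode avoids the full p×p similarity
matrix: correlations are computed against a random landmark subset of cells
and mini-batch k-means replaces full k-means.
"""

from __future__ import annotations

import logging
import zlib
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy.stats import rankdata
from sklearn.cluster import KMeans, MiniBatchKMeans
from sklearn.decomposition import PCA

from .preprocess import ExpressionMatrix

logger = logging.getLogger(__name__)

METRICS = ("pearson", "spearman")
DEFAULT_KS = range(10, 16)
LARGE_SCALE_THRESHOLD = 5000  # cells; above this, mode="auto" goes approximate


@dataclass(frozen=True)
class ClusteringConfig:
    metric: str
    k: int
    seed: int
    mode: str = "exact"

    def __post_init__(self) -> None:
        if self.metric not in METRICS:
            raise ValueError(f"metric must be one of {METRICS}")
        if self.k < 2:
            raise ValueError("k must be >= 2")
        if self.mode not in ("exact", "large_scale"):
            raise ValueError("mode must be 'exact' or 'large_scale'")


@dataclass(frozen=True, eq=False)
class ClusterAssignment:
    """One base-clustering result: a label per cell plus its configuration."""

    labels: np.ndarray
    config: ClusteringConfig

    def __post_init__(self) -> None:
        labels = np.asarray(self.labels, dtype=np.int64)
        object.__setattr__(self, "labels", labels)
        if labels.ndim != 1:
            raise ValueError("labels must be a 1-D vector")
        if labels.size and (labels.min() < 0 or labels.max() >= self.config.k):
            raise ValueError("labels out of range [0, k)")

    @property
    def n_cells(self) -> int:
        return self.labels.size


def child_seed(master_seed: int, *tokens: object) -> int:
    """Stable child seed derived from a master seed and context tokens."""
    key = ":".join(str(t) for t in (master_seed, *tokens))
    return zlib.crc32(key.encode()) & 0x7FFFFFFF


def _as_array(X: ExpressionMatrix | np.ndarray) -> np.ndarray:
    if isinstance(X, ExpressionMatrix):
        return X.X
    return np.asarray(X, dtype=np.float64)


def _standardize_cells(A: np.ndarray) -> np.ndarray:
    """Z-score each column (cell) over genes; constant cells become 0."""
    mu = A.mean(axis=0, keepdims=True)
    sd = A.std(axis=0, keepdims=True)
    constant = sd[0] == 0
    if constant.any():
        logger.warning(
            "%d cell(s) have constant expression; their correlations are set to 0",
            int(constant.sum()),
        )
    sd = np.where(sd == 0, 1.0, sd)
    Z = (A - mu) / sd
    Z[:, constant] = 0.0
    return Z


def similarity_matrix(
    X: ExpressionMatrix | np.ndarray, metric: str = "pearson"
) -> np.ndarray:
    """p×p cell-cell correlation matrix (Pearson, or Spearman on ranks)."""
    A = _as_array(X)
    if A.shape[1] < 2:
        raise ValueError("need at least 2 cells")
    if metric == "spearman":
        A = rankdata(A, axis=0)
    elif metric != "pearson":
        raise ValueError(f"metric must be one of {METRICS}")
    Z = _standardize_cells(A)
    S = (Z.T @ Z) / A.shape[0]
    np.clip(S, -1.0, 1.0, out=S)
    np.fill_diagonal(S, 1.0)
    return S


def _n_components(p_features: int, frac: float) -> int:
    return int(np.clip(np.ceil(frac * p_features), 2, p_features - 1))


def _pca_transform(M: np.ndarray, d: int) -> np.ndarray:
    """Top-d PC scores of the column-centered matrix, with deterministic signs.

    Each component's sign is fixed so that its largest-magnitude loading is
    positive.
    """
    pca = PCA(n_components=d, random_state=0)
    scores = pca.fit_transform(M)
    loadings = pca.components_
    flip = loadings[np.arange(d), np.abs(loadings).argmax(axis=1)] < 0
    scores[:, flip] *= -1.0
    return scores


def pca_scores(S: np.ndarray, frac: float = 0.05) -> np.ndarray:
    """Scores of the first ``ceil(frac·p)`` (min 2) principal components of S."""
    S = np.asarray(S, dtype=np.float64)
    p = S.shape[0]
    if p < 3:
        raise ValueError("too few cells to cluster (p < 3)")
    if S.shape != (p, p) or not np.allclose(S, S.T, atol=1e-8):
        raise ValueError("similarity matrix must be square and symmetric")
    return _pca_transform(S, _n_components(p, frac))


def kmeans_cluster(
    scores: np.ndarray,
    k: int,
    seed: int,
    n_start: int = 10,
    max_iter: int = 300,
    *,
    mode: str = "exact",
    metric: str = "pearson",
) -> ClusterAssignment:
    """Best-of-``n_start`` k-means labeling; deterministic given ``seed``."""
    scores = np.asarray(scores, dtype=np.float64)
    p = scores.shape[0]
    if k < 2:
        raise ValueError("k must be >= 2")
    if k >= p:
        raise ValueError(f"k={k} must be < number of cells ({p})")
    km = KMeans(
        n_clusters=k, n_init=n_start, max_iter=max_iter, random_state=seed
    ).fit(scores)
    return ClusterAssignment(km.labels_, ClusteringConfig(metric, k, seed, mode))


def minibatch_kmeans(
    scores: np.ndarray,
    k: int,
    seed: int,
    batch_size: int = 100,
    n_start: int = 10,
    max_iter: int = 300,
    *,
    metric: str = "pearson",
) -> ClusterAssignment:
    """Mini-batch k-means (per-center learning rates); deterministic per seed."""
    scores = np.asarray(scores, dtype=np.float64)
    p = scores.shape[0]
    if k < 2:
        raise ValueError("k must be >= 2")
    if k >= p:
        raise ValueError(f"k={k} must be < number of cells ({p})")
    km = MiniBatchKMeans(
        n_clusters=k,
        batch_size=batch_size,
        n_init=n_start,
        max_iter=max_iter,
        random_state=seed,
    ).fit(scores)
    return ClusterAssignment(
        km.labels_, ClusteringConfig(metric, k, seed, "large_scale")
    )


def landmark_scores(
    X: ExpressionMatrix | np.ndarray,
    metric: str = "pearson",
    m_landmarks: int = 1000,
    seed: int = 0,
) -> np.ndarray:
    """Approximate PC scores from correlations against a landmark subset.

    Samples ``m_landmarks`` cells without replacement, forms the p×m
    correlation matrix of all cells against the landmarks, and returns the
    top-d PC scores of that rectangular matrix
    (d = clamp(ceil(0.05·m), 2, m−1)).  Falls back to the exact similarity
    PCA when ``m_landmarks >= p``.
    """
    A = _as_array(X)
    p = A.shape[1]
    if m_landmarks >= p:
        logger.warning(
            "m_landmarks=%d >= %d cells; falling back to exact similarity PCA",
            m_landmarks,
            p,
        )
        return pca_scores(similarity_matrix(A, metric))
    rng = np.random.default_rng(seed)
    landmarks = np.sort(rng.choice(p, size=m_landmarks, replace=False))
    if metric == "spearman":
        A = rankdata(A, axis=0)
    elif metric != "pearson":
        raise ValueError(f"metric must be one of {METRICS}")
    Z = _standardize_cells(A)
    R = (Z.T @ Z[:, landmarks]) / A.shape[0]
    np.clip(R, -1.0, 1.0, out=R)
    return _pca_transform(R, _n_components(m_landmarks, 0.05))


def clamp_k_range(ks: Iterable[int], n_cells: int) -> range:
    """Shrink/shift a k range so it is feasible for ``n_cells`` cells.

    The largest k is capped at ``max(2, n_cells // 3)`` and the smallest is
    scaled proportionally, e.g. 10..15 at 30 cells becomes 6..10.
    """
    ks = sorted(set(int(k) for k in ks))
    if not ks:
        raise ValueError("empty k range")
    new_max = max(2, n_cells // 3)
    if ks[-1] <= new_max:
        return range(ks[0], ks[-1] + 1)
    new_min = max(2, (new_max * ks[0]) // ks[-1])
    return range(new_min, new_max + 1)


def build_ensemble(
    X: ExpressionMatrix | np.ndarray,
    ks: Iterable[int] = DEFAULT_KS,
    metrics: Sequence[str] = METRICS,
    mode: str = "auto",
    seed: int = 0,
    *,
    m_landmarks: int = 1000,
    batch_size: int = 100,
    n_start: int = 10,
) -> list[ClusterAssignment]:
    """One ClusterAssignment per (metric, k) pair; H = |metrics|·|ks|.

    ``mode`` is ``"exact"``, ``"large_scale"`` or ``"auto"`` (approximate
    above 5000 cells).  Child seeds are derived deterministically from
    ``(seed, metric, k)`` so the whole ensemble is reproducible from one
    master seed.
    """
    A = _as_array(X)
    p = A.shape[1]
    ks = sorted(set(int(k) for k in ks))
    if not ks or any(k < 2 for k in ks):
        raise ValueError("ks must be a non-empty collection of integers >= 2")
    if ks[-1] >= p:
        clamped = clamp_k_range(ks, p)
        logger.warning(
            "k range %d..%d infeasible for %d cells; clamped to %d..%d",
            ks[0], ks[-1], p, clamped.start, clamped.stop - 1,
        )
        ks = list(clamped)
        if not ks or ks[-1] >= p:
            raise ValueError(
                f"no feasible k for {p} cells; set ks explicitly (k < p)"
            )
    metrics = tuple(metrics)
    if not metrics or any(mt not in METRICS for mt in metrics):
        raise ValueError(f"metrics must be a non-empty subset of {METRICS}")
    if mode not in ("auto", "exact", "large_scale"):
        raise ValueError("mode must be 'auto', 'exact' or 'large_scale'")
    if mode == "auto":
        mode = "large_scale" if p > LARGE_SCALE_THRESHOLD else "exact"

    assignments: list[ClusterAssignment] = []
    for metric in metrics:
        if mode == "large_scale" and m_landmarks < p:
            scores = landmark_scores(
                A, metric, m_landmarks, child_seed(seed, "landmarks", metric)
            )
        else:
            scores = pca_scores(similarity_matrix(A, metric))
        for k in ks:
            s = child_seed(seed, "kmeans", metric, k)
            if mode == "large_scale":
                assignments.append(
                    minibatch_kmeans(
                        scores, k, s, batch_size, n_start, metric=metric
                    )
                )
            else:
                assignments.append(
                    kmeans_cluster(scores, k, s, n_start, metric=metric)
                )
    return assignments
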