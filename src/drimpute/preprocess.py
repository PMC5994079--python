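"""Gene filtering, size-factor normalization and log transformation.

The pipeline mirrors standard scRNA-seq preprocessing for count matrices:
genes seen in fewer than ``min_cells`` cells are dropped, each cell is scaled
by a median-of-ratios size factor, and the result is log10(x + 1) transformed.
Zeros are preserved exactly (log10(0/s + 1) = 0), which is what lets the
imputation stage treat the zero pattern of the expression matrix as the set
of candidate dropouts.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import sparse

from .matrix_io import CountMatrix, MatrixValidationError

logger = logging.getLogger(__name__)


class EmptyResultError(ValueError):
    """A filtering step removed every gene."""


@dataclass(frozen=True, eq=False)
class ExpressionMatrix:
    """Normalized log10 gene expression; entry is 0 iff the count was 0."""

    X: np.ndarray
    gene_ids: tuple[str, ...]
    cell_ids: tuple[str, ...]

    def __post_init__(self) -> None:
        X = np.asarray(self.X, dtype=np.float64)
        object.__setattr__(self, "X", X)
        object.__setattr__(self, "gene_ids", tuple(self.gene_ids))
        object.__setattr__(self, "cell_ids", tuple(self.cell_ids))
        if X.ndim != 2:
            raise MatrixValidationError("expression matrix must be 2-D")
        if X.shape != (len(self.gene_ids), len(self.cell_ids)):
            raise MatrixValidationError("identifier lengths do not match matrix")
        if X.size and X.min() < 0:
            raise MatrixValidationError("negative expression values")

    @property
    def n_genes(self) -> int:
        return self.X.shape[0]

    @property
    def n_cells(self) -> int:
        return self.X.shape[1]

    @property
    def zero_mask(self) -> np.ndarray:
        return self.X == 0


def filter_genes(m: CountMatrix, min_cells: int = 2) -> CountMatrix:
    """Drop genes expressed (count > 0) in fewer than ``min_cells`` cells."""
    if min_cells < 1:
        raise ValueError("min_cells must be >= 1")
    n_expressing = (m.values > 0).sum(axis=1).A1
    keep = n_expressing >= min_cells
    if not keep.any():
        raise EmptyResultError(
            f"no gene is expressed in >= {min_cells} cells"
        )
    if keep.all():
        return m
    return CountMatrix(
        m.values[keep],
        tuple(g for g, k in zip(m.gene_ids, keep) if k),
        m.cell_ids,
    )


def size_factors(m: CountMatrix) -> np.ndarray:
    """Median-of-ratios size factors, one positive scalar per cell.

    For each gene with strictly positive counts in every cell, compute the
    ratio of each cell's count to the gene's geometric mean across cells; the
    cell's size factor is the median of these ratios.  When no gene is
    positive in all cells (common in sparse data) a sparse fallback is used:
    geometric means are taken over the expressing cells only and each cell's
    median runs over the genes it expresses.
    """
    counts = m.to_dense().astype(np.float64)
    if np.any(counts.sum(axis=0) == 0):
        raise MatrixValidationError("a cell has zero total count")
    positive = counts > 0
    usable = positive.all(axis=1)
    logc = np.zeros_like(counts)
    np.log(counts, where=positive, out=logc)

    if usable.any():
        log_gm = logc[usable].mean(axis=1, keepdims=True)
        ratios = counts[usable] / np.exp(log_gm)
        s = np.median(ratios, axis=0)
    else:
        logger.warning(
            "no gene is expressed in all cells; using sparse median-of-ratios "
            "fallback (geometric means over expressing cells only)"
        )
        n_pos = positive.sum(axis=1, keepdims=True)
        log_gm = np.zeros_like(n_pos, dtype=np.float64)
        np.divide(
            logc.sum(axis=1, keepdims=True), n_pos, out=log_gm, where=n_pos > 0
        )
        log_ratios = np.where(positive, logc - log_gm, np.nan)
        s = np.exp(np.nanmedian(log_ratios, axis=0))
    if np.any(~np.isfinite(s)) or np.any(s <= 0):
        raise MatrixValidationError("size factor estimation failed (s <= 0)")
    return s


def normalize_log(m: CountMatrix, s: np.ndarray) -> ExpressionMatrix:
    """X_ij = log10(count_ij / s_j + 1).  Zero counts map exactly to 0."""
    s = np.asarray(s, dtype=np.float64)
    if s.shape != (m.n_cells,):
        raise MatrixValidationError(
            f"expected {m.n_cells} size factors, got shape {s.shape}"
        )
    if np.any(s <= 0):
        raise MatrixValidationError("size factors must be positive")
    X = np.log10(m.to_dense() / s[np.newaxis, :] + 1.0)
    return ExpressionMatrix(X, m.gene_ids, m.cell_ids)


def preprocess(
    m: CountMatrix,
    min_cells: int = 2,
    normalize: bool = True,
) -> ExpressionMatrix:
    """filter_genes → size_factors → normalize_log.

    With ``normalize=False`` all size factors are fixed at 1 and only the
    log transform is applied.
    """
    filtered = filter_genes(m, min_cells=min_cells)
    s = size_factors(filtered) if normalize else np.ones(filtered.n_cells)
    return normalize_log(filtered, s)
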