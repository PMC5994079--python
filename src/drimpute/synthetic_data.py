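"""Clustered scRNA-seq count simulator with known ground truth.

The generator emulates the structure the evaluation framework needs: a few
distinct cell populations, gene-level heterogeneity, per-cell library-size
variation, negative-binomial counts (overdispersed, so dropout is
distinguishable from mere low expression), structural zeros (genes switched
off in some clusters — the source of *true zeros*), and a dropout layer that
zeroes a fraction of truly expressed entries.  Every run is fully
reproducible from its seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import sparse

from .matrix_io import CountMatrix


@dataclass(frozen=True)
class SyntheticParams:
    """Simulation parameters.

    ``dropout`` is ``("binomial_thin", rate)`` — every count thinned
    binomially, emulating shallow sequencing — or
    ``("logistic", midpoint, slope)`` — entry-wise zeroing with probability
    following a decreasing logistic in the log mean, emulating
    expression-dependent capture failure.
    """

    n_genes: int = 2000
    n_cells: int = 300
    n_clusters: int = 3
    frac_marker: float = 0.1
    log_fc: float = 1.0           # natural-log fold change of marker genes
    base_mean: float = 2.0        # expected counts of a typical gene
    gene_sigma: float = 0.5       # lognormal spread of gene baseline means
    libsize_sigma: float = 0.3    # lognormal spread of cell library scale
    dispersion: float = 0.2       # NB dispersion; 0 gives Poisson
    frac_structural_zero: float = 0.1  # genes silenced per cluster
    dropout: tuple = ("binomial_thin", 0.3)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 1 or self.n_cells < 1:
            raise ValueError("n_genes and n_cells must be positive")
        if not 1 <= self.n_clusters <= self.n_cells:
            raise ValueError("need 1 <= n_clusters <= n_cells")
        if not 0 < self.frac_marker <= 1:
            raise ValueError("frac_marker must be in (0, 1]")
        if not 0 <= self.frac_structural_zero < 1:
            raise ValueError("frac_structural_zero must be in [0, 1)")
        if self.log_fc < 0 or self.base_mean <= 0 or self.libsize_sigma < 0:
            raise ValueError("scales must be positive")
        if self.dispersion < 0:
            raise ValueError("dispersion must be >= 0")
        kind = self.dropout[0]
        if kind == "binomial_thin":
            if len(self.dropout) != 2 or not 0 < self.dropout[1] <= 1:
                raise ValueError("binomial_thin needs a rate in (0, 1]")
        elif kind == "logistic":
            if len(self.dropout) != 3 or self.dropout[2] <= 0:
                raise ValueError("logistic needs (midpoint, slope) with slope > 0")
        else:
            raise ValueError("dropout kind must be 'binomial_thin' or 'logistic'")


@dataclass(frozen=True, eq=False)
class SyntheticDataset:
    true_counts: CountMatrix
    observed_counts: CountMatrix
    labels: np.ndarray
    true_log_means: np.ndarray  # n_genes × n_clusters; −inf marks structural zeros
    dropout_mask: np.ndarray    # True where a positive true count was zeroed
    params: SyntheticParams = field(repr=False, default=None)


def generate_dataset(p: SyntheticParams) -> SyntheticDataset:
    """Draw one dataset; bitwise-reproducible from ``p.seed``."""
    rng = np.random.default_rng(p.seed)
    n, m, K = p.n_genes, p.n_cells, p.n_clusters

    # gene baseline means, lognormal around base_mean
    base_log = np.log(p.base_mean) + rng.normal(0.0, p.gene_sigma, size=n)
    log_means = np.tile(base_log[:, None], (1, K)).astype(float)

    n_marker = max(1, int(round(p.frac_marker * n)))
    n_silent = int(round(p.frac_structural_zero * n))
    for c in range(K):
        markers = rng.choice(n, size=n_marker, replace=False)
        log_means[markers, c] += p.log_fc
        if n_silent:
            silent = rng.choice(n, size=n_silent, replace=False)
            log_means[silent, c] = -np.inf

    labels = rng.permutation(np.arange(m) % K)
    libsize = rng.lognormal(0.0, p.libsize_sigma, size=m)

    mu = np.exp(log_means)[:, labels] * libsize[None, :]
    if p.dispersion > 0:
        shape = 1.0 / p.dispersion
        lam = rng.gamma(shape, mu * p.dispersion)
        true = rng.poisson(lam)
    else:
        true = rng.poisson(mu)

    if p.dropout[0] == "binomial_thin":
        observed = rng.binomial(true, p.dropout[1])
    else:
        _, midpoint, slope = p.dropout
        p_drop = 1.0 / (1.0 + np.exp(slope * (np.log1p(mu) - midpoint)))
        observed = np.where(rng.random(size=true.shape) < p_drop, 0, true)
    dropout_mask = (observed == 0) & (true > 0)

    gene_ids = tuple(f"gene{i}" for i in range(n))
    cell_ids = tuple(f"cell{j}" for j in range(m))
    return SyntheticDataset(
        true_counts=CountMatrix(sparse.csr_matrix(true), gene_ids, cell_ids),
        observed_counts=CountMatrix(sparse.csr_matrix(observed), gene_ids, cell_ids),
        labels=labels,
        true_log_means=log_means,
        dropout_mask=dropout_mask,
        params=p,
    )
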