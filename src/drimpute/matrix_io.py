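"""Reading, writing and validation of gene×cell matrices.

Supported on-disk formats:

* Matrix Market triplet files (``.mtx``) with plain-text sidecar lists of
  gene and cell (barcode) identifiers, one per line.  Genes are rows and
  cells are columns; indices are 1-based per the Matrix Market standard.
  Transposed (cell×gene) files are *not* auto-detected — callers holding a
  10x-style cell-major file must transpose explicitly.
* Dense CSV/TSV with a header row of cell identifiers and a first column of
  gene identifiers.  Numeric fields are never quoted.
"""

from __future__ import annotations

import os
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import sparse
from scipy.io import mmread, mmwrite


class MatrixFormatError(ValueError):
    """Malformed file: bad header, wrong field count, unparseable entries."""


class MatrixValidationError(ValueError):
    """Structurally valid file whose contents violate count-matrix invariants."""


@dataclass(frozen=True)
class CountMatrix:
    """Raw non-negative integer counts, genes in rows and cells in columns.

    ``values`` is a CSR sparse matrix of shape ``(n_genes, n_cells)``;
    identifiers are duplicate-free and ordered as on disk.
    """

    values: sparse.csr_matrix
    gene_ids: tuple[str, ...]
    cell_ids: tuple[str, ...]

    def __post_init__(self) -> None:
        vals = sparse.csr_matrix(self.values)
        vals.eliminate_zeros()
        object.__setattr__(self, "values", vals)
        object.__setattr__(self, "gene_ids", tuple(str(g) for g in self.gene_ids))
        object.__setattr__(self, "cell_ids", tuple(str(c) for c in self.cell_ids))
        n, p = self.values.shape
        if n == 0 or p == 0:
            raise MatrixValidationError("empty matrix (zero genes or zero cells)")
        if len(self.gene_ids) != n:
            raise MatrixValidationError(
                f"{len(self.gene_ids)} gene ids for {n} rows"
            )
        if len(self.cell_ids) != p:
            raise MatrixValidationError(
                f"{len(self.cell_ids)} cell ids for {p} columns"
            )
        for name, ids in (("gene", self.gene_ids), ("cell", self.cell_ids)):
            if len(set(ids)) != len(ids):
                raise MatrixValidationError(f"duplicate {name} identifiers")
        data = self.values.data
        if data.size:
            if np.any(data < 0):
                raise MatrixValidationError("negative count entries")
            if not np.allclose(data, np.round(data)):
                raise MatrixValidationError("non-integer count entries")
        object.__setattr__(
            self, "values", self.values.astype(np.int64, copy=False)
        )

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_cells(self) -> int:
        return self.values.shape[1]

    def to_dense(self) -> np.ndarray:
        return np.asarray(self.values.todense())

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, CountMatrix):
            return NotImplemented
        return (
            self.gene_ids == other.gene_ids
            and self.cell_ids == other.cell_ids
            and (self.values != other.values).nnz == 0
        )


def _sidecar_paths(mtx_path: Path) -> tuple[Path, Path]:
    stem = mtx_path.with_suffix("")
    return Path(f"{stem}.genes.txt"), Path(f"{stem}.barcodes.txt")


def _read_id_list(path: Path) -> tuple[str, ...]:
    with open(path) as fh:
        return tuple(line.strip() for line in fh if line.strip())


def read_matrix(
    path: str | os.PathLike,
    format: str | None = None,
    *,
    genes: str | os.PathLike | None = None,
    barcodes: str | os.PathLike | None = None,
) -> CountMatrix:
    """Read a gene×cell count matrix from ``path``.

    ``format`` is one of ``{"mtx", "csv", "tsv"}``; if omitted it is inferred
    from the file extension.  For ``mtx``, gene and barcode lists default to
    the adjacent ``<stem>.genes.txt`` / ``<stem>.barcodes.txt`` sidecars
    unless given explicitly.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(str(path))
    if format is None:
        format = path.suffix.lstrip(".").lower()
    if format not in {"mtx", "csv", "tsv"}:
        raise MatrixFormatError(f"unsupported format: {format!r}")

    if format == "mtx":
        default_genes, default_barcodes = _sidecar_paths(path)
        gene_path = Path(genes) if genes is not None else default_genes
        bc_path = Path(barcodes) if barcodes is not None else default_barcodes
        for p in (gene_path, bc_path):
            if not p.exists():
                raise FileNotFoundError(
                    f"sidecar identifier list not found: {p}"
                )
        try:
            mat = mmread(path)
        except Exception as exc:  # scipy raises bare ValueError on bad headers
            raise MatrixFormatError(f"malformed Matrix Market file: {exc}") from exc
        return CountMatrix(
            sparse.csr_matrix(mat), _read_id_list(gene_path), _read_id_list(bc_path)
        )

    sep = "," if format == "csv" else "\t"
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split(sep)
    cell_ids = tuple(h.strip() for h in header[1:])  # pandas mangles duplicates
    try:
        df = pd.read_csv(path, sep=sep, index_col=0)
    except Exception as exc:
        raise MatrixFormatError(f"malformed {format} file: {exc}") from exc
    values = df.to_numpy()
    if values.dtype == object or not np.issubdtype(values.dtype, np.number):
        raise MatrixFormatError("non-numeric entries in dense matrix")
    return CountMatrix(
        sparse.csr_matrix(values), tuple(map(str, df.index)), cell_ids
    )


def write_matrix(
    m: CountMatrix | tuple[np.ndarray, Sequence[str], Sequence[str]],
    path: str | os.PathLike,
    format: str | None = None,
    *,
    precision: int = 6,
) -> None:
    """Write a count matrix or a real-valued ``(values, gene_ids, cell_ids)``
    triple to ``path``.

    Real values are written with ``precision`` significant digits; counts are
    written exactly.  For ``mtx``, sidecar identifier lists are written next
    to the matrix file.
    """
    path = Path(path)
    if format is None:
        format = path.suffix.lstrip(".").lower()
    if format not in {"mtx", "csv", "tsv"}:
        raise MatrixFormatError(f"unsupported format: {format!r}")

    if isinstance(m, CountMatrix):
        values: np.ndarray | sparse.spmatrix = m.values
        gene_ids, cell_ids = m.gene_ids, m.cell_ids
        integral = True
    else:
        values, gene_ids, cell_ids = m
        values = np.asarray(values)
        if values.ndim != 2 or values.shape[0] == 0 or values.shape[1] == 0:
            raise MatrixValidationError("matrix must be 2-D and non-empty")
        if len(gene_ids) != values.shape[0] or len(cell_ids) != values.shape[1]:
            raise MatrixValidationError("identifier lengths do not match matrix")
        integral = False

    if format == "mtx":
        gene_path, bc_path = _sidecar_paths(path)
        field = "integer" if integral else "real"
        mmwrite(
            str(path), sparse.coo_matrix(values), field=field, precision=precision
        )
        gene_path.write_text("\n".join(gene_ids) + "\n")
        bc_path.write_text("\n".join(cell_ids) + "\n")
        return

    sep = "," if format == "csv" else "\t"
    dense = values.toarray() if sparse.issparse(values) else np.asarray(values)
    df = pd.DataFrame(dense, index=list(gene_ids), columns=list(cell_ids))
    float_format = None if integral else f"%.{precision}g"
    df.to_csv(path, sep=sep, float_format=float_format)
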