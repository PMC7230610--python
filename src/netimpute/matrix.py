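"""Labeled gene-by-cell expression matrix and its on-disk formats.

The :class:`ExpressionMatrix` is the object every pipeline stage consumes and
produces: an ``m`` genes x ``n`` cells array of non-negative finite reals with
unique gene and cell identifiers, plus a ``scale_tag`` recording where in the
pipeline the values sit (``counts`` -> ``normalized`` -> ``lognormalized`` ->
``imputed``).

Two interchange formats are supported: a dense labeled TSV/CSV (genes as rows,
header row of cell IDs, first column gene IDs) whose round-trip is loss-free
at the written precision, and MatrixMarket ``.mtx`` with sidecar gene/cell ID
text files for sparse inputs.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

SCALE_TAGS = ("counts", "normalized", "lognormalized", "imputed")


@dataclass
class ExpressionMatrix:
    values: np.ndarray
    gene_ids: np.ndarray
    cell_ids: np.ndarray
    scale_tag: str = "counts"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.gene_ids = np.asarray(self.gene_ids, dtype=object)
        self.cell_ids = np.asarray(self.cell_ids, dtype=object)
        if self.values.ndim != 2:
            raise ValueError("expression values must be a 2-D matrix")
        m, n = self.values.shape
        if m == 0 or n == 0:
            raise ValueError("expression matrix must be non-empty")
        if len(self.gene_ids) != m:
            raise ValueError(f"{len(self.gene_ids)} gene_ids for {m} rows")
        if len(self.cell_ids) != n:
            raise ValueError(f"{len(self.cell_ids)} cell_ids for {n} columns")
        if len(set(self.gene_ids)) != m:
            raise ValueError("gene_ids must be unique")
        if len(set(self.cell_ids)) != n:
            raise ValueError("cell_ids must be unique")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("expression values must be finite")
        if self.values.min() < 0:
            raise ValueError("expression values must be non-negative")
        if self.scale_tag not in SCALE_TAGS:
            raise ValueError(
                f"scale_tag must be one of {SCALE_TAGS}, got {self.scale_tag!r}"
            )

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_cells(self) -> int:
        return self.values.shape[1]

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def copy(self) -> "ExpressionMatrix":
        return replace(
            self,
            values=self.values.copy(),
            gene_ids=self.gene_ids.copy(),
            cell_ids=self.cell_ids.copy(),
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=list(self.gene_ids), columns=list(self.cell_ids)
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame, scale_tag: str = "counts") -> "ExpressionMatrix":
        return cls(
            values=df.to_numpy(dtype=float),
            gene_ids=np.asarray(df.index.astype(str)),
            cell_ids=np.asarray(df.columns.astype(str)),
            scale_tag=scale_tag,
        )


def read_dense(path: str | os.PathLike, scale_tag: str = "counts") -> ExpressionMatrix:
    """Read a labeled genes x cells TSV (or CSV, by extension)."""
    sep = "," if str(path).endswith(".csv") else "\t"
    df = pd.read_csv(path, sep=sep, index_col=0)
    return ExpressionMatrix.from_frame(df, scale_tag=scale_tag)


def write_dense(E: ExpressionMatrix, path: str | os.PathLike,
                float_format: str = "%.6g") -> None:
    sep = "," if str(path).endswith(".csv") else "\t"
    E.to_frame().to_csv(path, sep=sep, float_format=float_format)


def read_mtx(mtx_path: str | os.PathLike, genes_path: str | os.PathLike,
             cells_path: str | os.PathLike, scale_tag: str = "counts") -> ExpressionMatrix:
    """Read MatrixMarket matrix (genes x cells) with sidecar ID files."""
    M = scipy.io.mmread(mtx_path)
    if sp.issparse(M):
        M = M.toarray()
    genes = _read_ids(genes_path)
    cells = _read_ids(cells_path)
    return ExpressionMatrix(np.asarray(M, dtype=float), genes, cells, scale_tag)


def write_mtx(E: ExpressionMatrix, mtx_path: str | os.PathLike,
              genes_path: str | os.PathLike, cells_path: str | os.PathLike) -> None:
    scipy.io.mmwrite(str(mtx_path), sp.csr_matrix(E.values))
    _write_ids(E.gene_ids, genes_path)
    _write_ids(E.cell_ids, cells_path)


def _read_ids(path: str | os.PathLike) -> np.ndarray:
    with open(path) as fh:
        return np.asarray([line.strip() for line in fh if line.strip()], dtype=object)


def _write_ids(ids: np.ndarray, path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        for name in ids:
            fh.write(f"{name}\n")
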