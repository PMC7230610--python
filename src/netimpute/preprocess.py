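"""Gene filtering, library-size normalization and log transform.

Cell-to-cell variation in library size (the column total of the count
matrix) is largely technical, so counts are rescaled so every cell carries
the median library size; a log transform with pseudo-count then damps the
influence of a few large observations. Genes never observed in any cell are
removed first — they carry no information and would have undefined
correlation.
"""

from __future__ import annotations

import numpy as np

from .matrix import ExpressionMatrix

__all__ = [
    "filter_unexpressed_genes",
    "normalize_library_size",
    "log_transform",
    "standard_pipeline",
]


def filter_unexpressed_genes(E: ExpressionMatrix) -> ExpressionMatrix:
    """Drop genes with no non-zero entry in any cell; gene order preserved."""
    expressed = (E.values != 0).any(axis=1)
    if not expressed.any():
        raise ValueError("all genes are unexpressed; nothing left after filtering")
    if expressed.all():
        return E.copy()
    return ExpressionMatrix(
        E.values[expressed], E.gene_ids[expressed], E.cell_ids.copy(), E.scale_tag
    )


def normalize_library_size(E: ExpressionMatrix) -> ExpressionMatrix:
    """Scale each cell to the median library size.

    ``E_norm[i, j] = E[i, j] / colsum_j * median(colsums)``; afterwards every
    column sums to the median of the original column totals.
    """
    colsums = E.values.sum(axis=0)
    if np.any(colsums <= 0):
        bad = [str(c) for c in E.cell_ids[colsums <= 0]]
        raise ValueError(
            "cells with zero total counts cannot be normalized; "
            f"filter empty cells first: {bad[:10]}"
        )
    median = float(np.median(colsums))
    values = E.values / colsums[None, :] * median
    return ExpressionMatrix(values, E.gene_ids.copy(), E.cell_ids.copy(), "normalized")


def log_transform(E: ExpressionMatrix, pseudo: float = 1.0) -> ExpressionMatrix:
    """Natural-log transform ``log(x + pseudo)``; zero stays zero for pseudo=1."""
    if pseudo <= 0:
        raise ValueError(f"pseudo count must be positive, got {pseudo}")
    values = np.log(E.values + pseudo)
    return ExpressionMatrix(values, E.gene_ids.copy(), E.cell_ids.copy(), "lognormalized")


def standard_pipeline(E: ExpressionMatrix, pseudo: float = 1.0) -> ExpressionMatrix:
    """Filter unexpressed genes, then bring the matrix to the log scale.

    Count input goes through library-size normalization and log1p; input
    already on the log scale (e.g., the simulator's output) is only
    gene-filtered, since renormalizing logged values is not meaningful.
    """
    E = filter_unexpressed_genes(E)
    if E.scale_tag in ("lognormalized", "imputed"):
        return E
    return log_transform(normalize_library_size(E), pseudo=pseudo)
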