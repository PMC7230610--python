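"""Co-expression graph construction and PPI ingestion.

Similarity between genes (or cells) is the Pearson correlation of their
log-scale expression profiles. The co-expression graph connects node pairs
that are mutually among each other's top-``k`` most similar nodes (mutual
KNN); the asymmetric variant requires only one-sided membership and is
noisier. A third graph flavor ingests a STRING-style scored protein-protein
interaction edge list, keeping only the most confident interactions (top
decile of the combined score by default).

Graphs are always undirected and unweighted with no self-loops. Nodes whose
expression vector has zero variance have undefined correlation; they are
flagged *isolated* — excluded from neighborhoods on both sides — rather than
removed, so the matrix shape is preserved through imputation and an isolated
gene simply keeps its own value.

For large gene counts the top-k neighborhoods are computed block-wise so the
full similarity matrix is never materialized; the result is identical to the
dense path.
"""

from __future__ import annotations

import os
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .matrix import ExpressionMatrix

__all__ = [
    "SimilarityMatrix",
    "CoexpressionGraph",
    "similarity",
    "mutual_knn",
    "asymmetric_knn",
    "knn_graph",
    "load_ppi",
    "read_edgelist",
    "write_edgelist",
]

_VAR_EPS = 0.0  # exact zero variance flags a node isolated


@dataclass
class SimilarityMatrix:
    """Dense symmetric Pearson similarity with an isolation mask."""

    values: np.ndarray
    node_ids: np.ndarray
    axis: str  # "gene" or "cell"
    isolated: np.ndarray  # bool mask over nodes with undefined correlation


@dataclass
class CoexpressionGraph:
    adjacency: sp.csr_matrix  # binary, symmetric, zero diagonal
    node_ids: np.ndarray
    flavor: str  # mutual_knn | asymmetric_knn | ppi
    k: int | None = None

    @property
    def n_nodes(self) -> int:
        return self.adjacency.shape[0]

    @property
    def degrees(self) -> np.ndarray:
        return np.asarray(self.adjacency.sum(axis=1)).ravel().astype(int)


def _node_vectors(E: ExpressionMatrix, axis: str) -> tuple[np.ndarray, np.ndarray]:
    if axis == "gene":
        return E.values, E.gene_ids
    if axis == "cell":
        return E.values.T, E.cell_ids
    raise ValueError(f"axis must be 'gene' or 'cell', got {axis!r}")


def _standardize(X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Rows scaled so that Z @ Z.T is the Pearson correlation matrix.

    Zero-variance rows are returned as all-zero and flagged isolated.
    """
    n = X.shape[1]
    mu = X.mean(axis=1, keepdims=True)
    centered = X - mu
    ss = np.einsum("ij,ij->i", centered, centered)
    isolated = ss <= _VAR_EPS
    norm = np.sqrt(np.where(isolated, 1.0, ss))
    Z = centered / norm[:, None]
    Z[isolated] = 0.0
    return Z, isolated


def similarity(E: ExpressionMatrix, axis: str = "gene") -> SimilarityMatrix:
    """Pairwise Pearson correlation between genes (rows) or cells (columns)."""
    X, ids = _node_vectors(E, axis)
    Z, isolated = _standardize(X)
    S = np.clip(Z @ Z.T, -1.0, 1.0)
    S[isolated, :] = 0.0
    S[:, isolated] = 0.0
    np.fill_diagonal(S, 1.0)
    return SimilarityMatrix(values=S, node_ids=ids.copy(), axis=axis, isolated=isolated)


def _topk_membership(S_rows: np.ndarray, row_offset: int, k: int,
                     isolated: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Row/col indices of each row's top-k neighbors.

    Self and isolated nodes are excluded as candidates; ties in similarity
    are broken by ascending node index (stable sort on the negated scores).
    """
    B, p = S_rows.shape
    S2 = S_rows.astype(float, copy=True)
    S2[:, isolated] = -np.inf
    rows_global = np.arange(row_offset, row_offset + B)
    S2[np.arange(B), rows_global] = -np.inf  # exclude self
    S2[isolated[rows_global], :] = -np.inf  # isolated sources get no neighbors
    order = np.argsort(-S2, axis=1, kind="stable")[:, :k]
    valid = np.take_along_axis(S2, order, axis=1) > -np.inf
    rr = np.repeat(rows_global, k).reshape(B, k)
    return rr[valid], order[valid]


def _graph_from_membership(rows: np.ndarray, cols: np.ndarray, p: int,
                           mutual: bool) -> sp.csr_matrix:
    N = sp.csr_matrix(
        (np.ones(len(rows), dtype=np.int8), (rows, cols)), shape=(p, p)
    )
    if mutual:
        A = N.multiply(N.T)
    else:
        A = ((N + N.T) > 0).astype(np.int8)
    A = A.tocsr()
    A.setdiag(0)
    A.eliminate_zeros()
    return A.astype(np.int8)


def _knn_from_similarity(S: SimilarityMatrix, k: int, mutual: bool) -> CoexpressionGraph:
    p = S.values.shape[0]
    if not (1 <= k <= p - 1):
        raise ValueError(f"k must satisfy 1 <= k <= p-1 = {p - 1}, got {k}")
    rows, cols = _topk_membership(S.values, 0, k, S.isolated)
    A = _graph_from_membership(rows, cols, p, mutual)
    flavor = "mutual_knn" if mutual else "asymmetric_knn"
    return CoexpressionGraph(adjacency=A, node_ids=S.node_ids.copy(), flavor=flavor, k=k)


def mutual_knn(S: SimilarityMatrix, k: int) -> CoexpressionGraph:
    """Edge (i, j) iff each node is in the other's top-k neighborhood."""
    return _knn_from_similarity(S, k, mutual=True)


def asymmetric_knn(S: SimilarityMatrix, k: int) -> CoexpressionGraph:
    """Edge (i, j) iff either node is in the other's top-k neighborhood."""
    return _knn_from_similarity(S, k, mutual=False)


def knn_graph(E: ExpressionMatrix, axis: str = "gene", k: int = 128,
              flavor: str = "mutual_knn", block_size: int = 2048) -> CoexpressionGraph:
    """KNN co-expression graph computed block-wise over the similarity matrix.

    Identical output to ``mutual_knn(similarity(E, axis), k)`` (resp.
    ``asymmetric_knn``) without materializing the full p x p similarity.
    """
    if flavor not in ("mutual_knn", "asymmetric_knn"):
        raise ValueError(f"flavor must be mutual_knn or asymmetric_knn, got {flavor!r}")
    X, ids = _node_vectors(E, axis)
    p = X.shape[0]
    if not (1 <= k <= p - 1):
        raise ValueError(f"k must satisfy 1 <= k <= p-1 = {p - 1}, got {k}")
    Z, isolated = _standardize(X)
    all_rows, all_cols = [], []
    for start in range(0, p, block_size):
        stop = min(start + block_size, p)
        S_block = np.clip(Z[start:stop] @ Z.T, -1.0, 1.0)
        rr, cc = _topk_membership(S_block, start, k, isolated)
        all_rows.append(rr)
        all_cols.append(cc)
    rows = np.concatenate(all_rows) if all_rows else np.empty(0, dtype=int)
    cols = np.concatenate(all_cols) if all_cols else np.empty(0, dtype=int)
    A = _graph_from_membership(rows, cols, p, mutual=(flavor == "mutual_knn"))
    return CoexpressionGraph(adjacency=A, node_ids=ids.copy(), flavor=flavor, k=k)


def load_ppi(edges: pd.DataFrame | str | os.PathLike, expressed_genes,
             confidence_quantile: float = 0.90) -> CoexpressionGraph:
    """Build a graph from a scored interaction table over the expressed genes.

    Keeps edges whose score reaches the ``confidence_quantile`` quantile of
    all scores, drops edges touching genes outside ``expressed_genes``,
    symmetrizes and removes self-loops. Gene matching is exact string match
    after upper-casing; unmatched or edgeless genes remain isolated nodes.
    """
    if not (0.0 <= confidence_quantile <= 1.0):
        raise ValueError(f"confidence_quantile must be in [0, 1], got {confidence_quantile}")
    df = _read_ppi_table(edges)
    node_ids = np.asarray(list(expressed_genes), dtype=object)
    index = {str(g).upper(): i for i, g in enumerate(node_ids)}

    scores = df["score"].to_numpy(dtype=float)
    cutoff = np.quantile(scores, confidence_quantile) if len(scores) else np.inf
    kept = df[scores >= cutoff]

    ga = kept["geneA"].astype(str).str.upper().map(index)
    gb = kept["geneB"].astype(str).str.upper().map(index)
    ok = ga.notna() & gb.notna()
    ii = ga[ok].to_numpy(dtype=int)
    jj = gb[ok].to_numpy(dtype=int)
    self_loop = ii == jj
    ii, jj = ii[~self_loop], jj[~self_loop]

    p = len(node_ids)
    A = sp.csr_matrix((np.ones(len(ii), dtype=np.int8), (ii, jj)), shape=(p, p))
    A = ((A + A.T) > 0).astype(np.int8).tocsr()
    if A.nnz == 0:
        warnings.warn(
            "no PPI edges survive confidence/expression filtering; "
            "graph is fully isolated and imputation will be the identity",
            stacklevel=2,
        )
    return CoexpressionGraph(adjacency=A, node_ids=node_ids, flavor="ppi", k=None)


def _read_ppi_table(edges) -> pd.DataFrame:
    """Accept a 3-column DataFrame or a whitespace/tab-delimited file with an
    optional header (STRING protein-links style)."""
    if isinstance(edges, pd.DataFrame):
        df = edges.iloc[:, :3].copy()
    else:
        df = pd.read_csv(edges, sep=r"\s+", header=None, comment="#", dtype=str)
        first = df.iloc[0]
        try:
            float(first.iloc[2])
        except (TypeError, ValueError):
            df = df.iloc[1:].reset_index(drop=True)  # header row
        df = df.iloc[:, :3]
    df.columns = ["geneA", "geneB", "score"]
    df["score"] = pd.to_numeric(df["score"], errors="raise")
    return df


def write_edgelist(graph: CoexpressionGraph, path: str | os.PathLike) -> None:
    """Export the upper triangle as a two-column TSV of node IDs."""
    coo = sp.triu(graph.adjacency, k=1).tocoo()
    with open(path, "w") as fh:
        fh.write("nodeA\tnodeB\n")
        for i, j in zip(coo.row, coo.col):
            fh.write(f"{graph.node_ids[i]}\t{graph.node_ids[j]}\n")


def read_edgelist(path: str | os.PathLike, node_ids) -> CoexpressionGraph:
    """Read a two-column edge-list TSV over a known node set."""
    node_ids = np.asarray(list(node_ids), dtype=object)
    index = {str(g): i for i, g in enumerate(node_ids)}
    df = pd.read_csv(path, sep="\t")
    ii = df.iloc[:, 0].astype(str).map(index)
    jj = df.iloc[:, 1].astype(str).map(index)
    if ii.isna().any() or jj.isna().any():
        missing = sorted(
            set(df.iloc[:, 0][ii.isna()].astype(str))
            | set(df.iloc[:, 1][jj.isna()].astype(str))
        )
        raise ValueError(f"edge list references unknown nodes: {missing[:10]}")
    p = len(node_ids)
    A = sp.csr_matrix(
        (np.ones(len(df), dtype=np.int8), (ii.to_numpy(int), jj.to_numpy(int))),
        shape=(p, p),
    )
    A = ((A + A.T) > 0).astype(np.int8).tocsr()
    A.setdiag(0)
    A.eliminate_zeros()
    return CoexpressionGraph(adjacency=A.astype(np.int8), node_ids=node_ids,
                             flavor="mutual_knn", k=None)
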