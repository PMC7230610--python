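"""Random walk with restart (RWR) over the co-expression graph and the
imputation step that turns its stationary probabilities into smoothed
expression.

Let ``A`` be the binary adjacency and ``P`` its row-normalized transition
matrix. A walker starting at node ``v`` moves to a uniformly random neighbor
each step and restarts at ``v`` with probability ``alpha``. The stationary
matrix ``F`` solves

    F = (1 - alpha) * F @ P + alpha * I       i.e.  F = alpha * (I - (1 - alpha) P)^-1

Row ``v`` of ``F`` is a probability vector (the *outgoing* probabilities of
``v``): it sums to one and keeps weight ``f_vv >= alpha`` on the start node.
The imputed expression of gene ``v`` in cell ``c`` is the outgoing-weighted
average ``sum_j f_vj e_jc`` — a convex combination of the cell's values, so
every gene's imputed value stays within the cell's observed range and keeps
at least an ``alpha`` share of its own value. Column ``v`` (the *incoming*
probabilities) has no such constraint: its total grows with node degree,
which is exactly the hub bias the incoming mode exhibits.

``F`` is dense even for sparse graphs, so imputation never materializes it:
``X = F @ E`` is obtained by iterating ``X <- (1 - alpha) * P @ X + alpha * E``
(p x n work per sweep), which converges geometrically at rate ``1 - alpha``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp

from .matrix import ExpressionMatrix
from .network import CoexpressionGraph, knn_graph, load_ppi
from .preprocess import standard_pipeline

__all__ = [
    "TransitionMatrix",
    "StationaryMatrix",
    "row_normalize",
    "rwr_stationary",
    "diffuse_expression",
    "netimpute",
]


@dataclass
class TransitionMatrix:
    """Row-stochastic random-walk matrix; isolated nodes carry a self-loop."""

    values: sp.csr_matrix
    node_ids: np.ndarray

    @property
    def n_nodes(self) -> int:
        return self.values.shape[0]


@dataclass
class StationaryMatrix:
    """RWR equilibrium; row v holds the outgoing distribution of node v."""

    values: np.ndarray
    alpha: float
    tol: float
    node_ids: np.ndarray


def _check_alpha(alpha: float) -> None:
    if not (0.0 < alpha <= 1.0):
        raise ValueError(f"restart probability alpha must be in (0, 1], got {alpha}")


def row_normalize(A: CoexpressionGraph) -> TransitionMatrix:
    """Divide each adjacency row by its degree.

    Zero-degree (isolated) nodes get a self-loop row ``P[v, v] = 1`` so the
    matrix stays stochastic and the node retains its own expression value
    through diffusion.
    """
    adj = A.adjacency.astype(float).tocsr()
    deg = np.asarray(adj.sum(axis=1)).ravel()
    isolated = deg == 0
    inv = np.where(isolated, 0.0, 1.0 / np.where(isolated, 1.0, deg))
    P = sp.diags(inv) @ adj
    if isolated.any():
        P = P + sp.diags(isolated.astype(float))
    return TransitionMatrix(values=P.tocsr(), node_ids=A.node_ids.copy())


def rwr_stationary(P: TransitionMatrix, alpha: float, tol: float = 1e-6,
                   max_iter: int = 1000) -> StationaryMatrix:
    """Iterate ``F <- (1 - alpha) F P + alpha I`` to its fixed point.

    The fixed point is ``alpha * (I - (1 - alpha) P)^-1``. Iteration stops
    when the maximum absolute entry change drops below ``tol``. Dense p x p
    output — intended for moderate p (diagnostics, small graphs); imputation
    itself uses :func:`diffuse_expression` which never forms F.
    """
    _check_alpha(alpha)
    p = P.n_nodes
    Pt = P.values.T.tocsr()  # F @ P == (P.T @ F.T).T
    I = np.eye(p)
    F = alpha * I
    if alpha == 1.0:
        return StationaryMatrix(values=F, alpha=alpha, tol=tol, node_ids=P.node_ids.copy())
    for _ in range(max_iter):
        F_new = (1.0 - alpha) * (Pt @ F.T).T + alpha * I
        residual = np.abs(F_new - F).max()
        F = F_new
        if residual < tol:
            return StationaryMatrix(values=F, alpha=alpha, tol=tol,
                                    node_ids=P.node_ids.copy())
    raise RuntimeError(
        f"RWR did not converge in {max_iter} iterations (residual {residual:.3e})"
    )


def _implicit_diffuse(P: sp.csr_matrix, E: np.ndarray, alpha: float, tol: float,
                      max_iter: int) -> np.ndarray:
    X = E.copy()
    if alpha == 1.0:
        return X
    for _ in range(max_iter):
        X_new = (1.0 - alpha) * (P @ X) + alpha * E
        residual = np.abs(X_new - X).max()
        X = X_new
        if residual < tol:
            return X
    raise RuntimeError(
        f"diffusion did not converge in {max_iter} iterations (residual {residual:.3e})"
    )


def diffuse_expression(P: TransitionMatrix, E: ExpressionMatrix, alpha: float,
                       mode: str = "outgoing", tol: float = 1e-6,
                       max_iter: int = 1000) -> ExpressionMatrix:
    """Smooth ``E`` over the graph: ``F @ E`` (outgoing) or ``F.T @ E``
    (incoming), computed implicitly without materializing F."""
    _check_alpha(alpha)
    if mode not in ("outgoing", "incoming"):
        raise ValueError(f"mode must be 'outgoing' or 'incoming', got {mode!r}")
    if P.n_nodes != E.n_genes or list(P.node_ids) != list(E.gene_ids):
        missing = sorted(set(map(str, P.node_ids)) ^ set(map(str, E.gene_ids)))
        raise ValueError(
            f"transition-matrix nodes do not match expression genes; "
            f"mismatched IDs: {missing[:10]}"
        )
    M = P.values if mode == "outgoing" else P.values.T.tocsr()
    X = _implicit_diffuse(M, E.values, alpha, tol, max_iter)
    return ExpressionMatrix(np.maximum(X, 0.0), E.gene_ids.copy(), E.cell_ids.copy(),
                            scale_tag="imputed")


def build_graph(E_log: ExpressionMatrix, network_type: str, k: int,
                ppi_edges=None, knn_block_size: int = 2048) -> CoexpressionGraph:
    """Graph over genes or cells from log-scale expression, or a filtered PPI."""
    if network_type in ("gene", "cell"):
        return knn_graph(E_log, axis=network_type, k=k, block_size=knn_block_size)
    if network_type == "ppi":
        if ppi_edges is None:
            raise ValueError("network_type='ppi' requires a ppi_edges table")
        return load_ppi(ppi_edges, expressed_genes=E_log.gene_ids)
    raise ValueError(f"network_type must be gene, cell or ppi, got {network_type!r}")


def netimpute(E_raw: ExpressionMatrix, network_type: str = "gene", k: int = 128,
              alpha: float = 0.5, ppi_edges=None, mode: str = "outgoing",
              tol: float = 1e-6, max_iter: int = 1000,
              back_transform: bool = False, knn_block_size: int = 2048,
              return_graph: bool = False):
    """End-to-end network imputation.

    Pipeline: filter unexpressed genes -> library-size normalize -> log1p
    (count input; log-scale input is only filtered) -> build graph
    (mutual-KNN over genes or cells, or confidence-filtered PPI) ->
    row-normalize -> RWR diffusion. For ``network_type='cell'`` the graph is
    over cells and each gene's profile is smoothed across cells:
    ``imputed e_gc = sum_d f_cd e_gd``.

    Output is on the log scale unless ``back_transform`` (expm1) is set.
    With ``return_graph`` the co-expression graph is returned alongside the
    imputed matrix for diagnostics such as the hub-effect report.
    """
    _check_alpha(alpha)
    E_log = standard_pipeline(E_raw)
    graph = build_graph(E_log, network_type, k, ppi_edges, knn_block_size)
    P = row_normalize(graph)
    if network_type == "cell":
        M = P.values if mode == "outgoing" else P.values.T.tocsr()
        if mode not in ("outgoing", "incoming"):
            raise ValueError(f"mode must be 'outgoing' or 'incoming', got {mode!r}")
        X = _implicit_diffuse(M, E_log.values.T, alpha, tol, max_iter).T
        imputed = ExpressionMatrix(np.maximum(X, 0.0), E_log.gene_ids.copy(),
                                   E_log.cell_ids.copy(), scale_tag="imputed")
    else:
        imputed = diffuse_expression(P, E_log, alpha, mode=mode, tol=tol,
                                     max_iter=max_iter)
    if back_transform:
        imputed = ExpressionMatrix(np.expm1(imputed.values), imputed.gene_ids,
                                   imputed.cell_ids, scale_tag="imputed")
    if return_graph:
        return imputed, graph
    return imputed
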