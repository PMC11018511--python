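"""Random walk with restart: initial node features H(0).

Every node of the (Nm+Nd)-node bipartite association graph diffuses a
one-hot restart vector through D <- (1-r) * A_N * D + r * D0 until the
Frobenius residual drops below tolerance.  Stacking the converged
per-node distributions gives the (Nm+Nd) x (Nm+Nd) feature matrix the
graph convolution consumes: row t is the proximity profile of node t.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io_formats import AssociationMatrix

__all__ = [
    "RwrParams",
    "FeatureMatrix",
    "bipartite_adjacency",
    "normalize_adjacency",
    "rwr",
    "rwr_features",
]


@dataclass
class RwrParams:
    restart_prob: float = 0.7
    tol: float = 1e-6
    max_iter: int = 1000

    def __post_init__(self) -> None:
        if not 0 < self.restart_prob <= 1:
            raise ValueError("restart probability must be in (0, 1]")
        if self.tol <= 0:
            raise ValueError("tolerance must be positive")
        if self.max_iter < 1:
            raise ValueError("max_iter must be at least 1")


@dataclass
class FeatureMatrix:
    """(Nm+Nd) x d real feature matrix with a layer tag.

    ``layer`` is 0 for the walk output H(0), a positive integer for a
    convolution layer output, or ``"fused"`` for the attention-combined H.
    """

    values: np.ndarray
    layer: int | str = 0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("feature matrix must be 2-D")
        if not np.isfinite(self.values).all():
            raise ValueError("feature matrix contains non-finite entries")

    @property
    def n_nodes(self) -> int:
        return self.values.shape[0]


class ConvergenceError(RuntimeError):
    """Iteration cap reached before the residual dropped below tolerance."""


def bipartite_adjacency(A: AssociationMatrix) -> np.ndarray:
    """Symmetric (Nm+Nd)-square adjacency [[0, A], [A^T, 0]] of the association graph."""
    nm, nd = A.n_mirna, A.n_disease
    M = np.zeros((nm + nd, nm + nd))
    M[:nm, nm:] = A.values
    M[nm:, :nm] = A.values.T
    return M


def normalize_adjacency(M: np.ndarray) -> np.ndarray:
    """Column-normalize so each column is a probability distribution.

    Isolated nodes (zero column) get a self-loop so the matrix stays
    column-stochastic and the walk restarts in place.
    """
    M = np.asarray(M, dtype=float)
    if (M < 0).any():
        raise ValueError("adjacency weights must be non-negative")
    col = M.sum(axis=0)
    A_N = np.array(M)
    isolated = col == 0
    A_N[:, ~isolated] = M[:, ~isolated] / col[~isolated]
    A_N[isolated, isolated] = 1.0
    return A_N


def rwr(A_N: np.ndarray, params: RwrParams | None = None) -> FeatureMatrix:
    """Run restarts from every node simultaneously; return H(0).

    Iterates ``D <- (1-r) A_N D + r I`` from D = I until the Frobenius
    norm of the update is <= tol.  The geometric contraction rate is
    (1-r), so convergence is guaranteed for r > 0.  Row t of the result
    is node t's converged proximity profile (column t of the stationary
    matrix).
    """
    params = params or RwrParams()
    A_N = np.asarray(A_N, dtype=float)
    n = A_N.shape[0]
    if A_N.shape != (n, n):
        raise ValueError("A_N must be square")
    if not np.allclose(A_N.sum(axis=0), 1.0, atol=1e-9):
        raise ValueError("A_N must be column-stochastic")
    r = params.restart_prob
    D0 = np.eye(n)
    D = D0.copy()
    for _ in range(params.max_iter):
        D_new = (1 - r) * (A_N @ D) + r * D0
        residual = float(np.linalg.norm(D_new - D, "fro"))
        D = D_new
        if residual <= params.tol:
            return FeatureMatrix(values=D.T, layer=0)
    raise ConvergenceError(
        f"random walk did not converge in {params.max_iter} iterations "
        f"(residual {residual:.3e} > tol {params.tol:.1e})"
    )


def rwr_features(A: AssociationMatrix, params: RwrParams | None = None) -> FeatureMatrix:
    """Convenience: build the bipartite graph, normalize, and run the walk."""
    return rwr(normalize_adjacency(bipartite_adjacency(A)), params)
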