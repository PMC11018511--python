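"""Reliable-negative screening from the unlabeled pair pool.

Known associations are positives; every other miRNA-disease pair is
merely unlabeled, and training on random unlabeled pairs risks learning
against false negatives.  The screen is a constrained 2-means:

1. centroids C_p (mean of positive pair features) and C_u (mean of
   unlabeled pair features);
2. one cosine pass splits the unlabeled pool into likely-positive P_l
   and likely-negative N_l;
3. centroids are recomputed from P_l / N_l and the pool is repeatedly
   re-split by Euclidean similarity ``ES = 1 / (1 + ||F - C||^2)``
   until both centroid shifts (Frobenius norm) fall below tolerance.

The final likely-negative side is the reliable negative pool.  Each
pair (i, j) is represented by a length-(Nm+Nd) vector: by default the
concatenation of miRNA i's integrated-similarity row with disease j's,
optionally the concatenation of the pair's association profiles.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .io_formats import AssociationMatrix, SimilarityMatrix

__all__ = [
    "SelectionState",
    "SelectionResult",
    "pair_feature",
    "pair_feature_matrix",
    "centroid",
    "partition_cosine",
    "partition_euclidean",
    "select_negatives",
    "kmeans_negatives",
    "random_negatives",
]

logger = logging.getLogger(__name__)

Pair = tuple[int, int]


@dataclass
class SelectionState:
    """Tolerance and iteration policy for the centroid iteration."""

    tol: float = 1e-3
    max_iter: int = 100
    augment_with_positives: bool = False  # recompute C_p from P_set + P_l

    def __post_init__(self) -> None:
        if self.tol <= 0:
            raise ValueError("tolerance must be positive")
        if self.max_iter < 1:
            raise ValueError("max_iter must be at least 1")


@dataclass
class SelectionResult:
    """Outcome of the screen: final partition plus per-iteration centroid shifts."""

    negatives: list[Pair]
    likely_positives: list[Pair]
    history: list[tuple[float, float]] = field(default_factory=list)
    converged: bool = True
    n_iter: int = 0


def _values(m: SimilarityMatrix | np.ndarray | None) -> np.ndarray | None:
    if m is None:
        return None
    return m.values if isinstance(m, SimilarityMatrix) else np.asarray(m, dtype=float)


def pair_feature_matrix(
    pairs: Sequence[Pair],
    IM: SimilarityMatrix | np.ndarray | None = None,
    ID: SimilarityMatrix | np.ndarray | None = None,
    A: AssociationMatrix | np.ndarray | None = None,
    source: str = "similarity",
) -> np.ndarray:
    """Feature vectors for many pairs, stacked as rows (each length Nm+Nd).

    ``source='similarity'``: row i of IM concatenated with row j of ID.
    ``source='association'``: row i of A (length Nd) concatenated with
    column j of A (length Nm).
    """
    idx = np.asarray(pairs, dtype=int).reshape(-1, 2)
    if source == "similarity":
        IMv, IDv = _values(IM), _values(ID)
        if IMv is None or IDv is None:
            raise ValueError("similarity source requires IM and ID")
        nm, nd = IMv.shape[0], IDv.shape[0]
        _check_range(idx, nm, nd)
        return np.hstack([IMv[idx[:, 0]], IDv[idx[:, 1]]])
    if source == "association":
        Av = A.values if isinstance(A, AssociationMatrix) else _values(A)
        if Av is None:
            raise ValueError("association source requires A")
        nm, nd = Av.shape
        _check_range(idx, nm, nd)
        return np.hstack([Av[idx[:, 0], :], Av[:, idx[:, 1]].T])
    raise ValueError(f"unknown feature source {source!r}")


def _check_range(idx: np.ndarray, nm: int, nd: int) -> None:
    if idx.size == 0:
        return
    if idx[:, 0].min() < 0 or idx[:, 0].max() >= nm:
        raise IndexError("miRNA index out of range")
    if idx[:, 1].min() < 0 or idx[:, 1].max() >= nd:
        raise IndexError("disease index out of range")


def pair_feature(
    i: int,
    j: int,
    IM: SimilarityMatrix | np.ndarray | None = None,
    ID: SimilarityMatrix | np.ndarray | None = None,
    A: AssociationMatrix | np.ndarray | None = None,
    source: str = "similarity",
) -> np.ndarray:
    """Length-(Nm+Nd) representation of the single pair (i, j)."""
    return pair_feature_matrix([(i, j)], IM, ID, A, source)[0]


def centroid(features: np.ndarray) -> np.ndarray:
    """Arithmetic mean of feature rows; empty input is degenerate."""
    features = np.atleast_2d(np.asarray(features, dtype=float))
    if features.shape[0] == 0:
        raise ValueError("cannot take the centroid of an empty set")
    return features.mean(axis=0)


def partition_cosine(
    U: np.ndarray, C_p: np.ndarray, C_u: np.ndarray
) -> np.ndarray:
    """Boolean mask: True -> likely positive (strictly more cosine-similar to C_p).

    Ties and zero-norm features fall to the likely-negative side — an
    ambiguous pair should stay available as a negative candidate.
    """
    U = np.atleast_2d(U)
    norms = np.linalg.norm(U, axis=1)
    np_p, np_u = np.linalg.norm(C_p), np.linalg.norm(C_u)
    if np_p == 0 or np_u == 0:
        raise ValueError("cosine partition requires non-zero centroids")
    zero = norms == 0
    if zero.any():
        logger.warning("%d zero-norm pair features assigned to the negative side", zero.sum())
    safe = np.where(zero, 1.0, norms)
    cs_p = (U @ C_p) / (safe * np_p)
    cs_u = (U @ C_u) / (safe * np_u)
    return (cs_p > cs_u) & ~zero


def partition_euclidean(
    U: np.ndarray, C_p: np.ndarray, C_u: np.ndarray
) -> np.ndarray:
    """Boolean mask: True -> likely positive (ES_p > ES_u, i.e. nearer C_p).

    ``ES = 1 / (1 + ||F - C||^2)`` is monotone-decreasing in distance,
    so this is exactly a nearest-centroid assignment; ties go negative.
    """
    U = np.atleast_2d(U)
    es_p = 1.0 / (1.0 + ((U - C_p) ** 2).sum(axis=1))
    es_u = 1.0 / (1.0 + ((U - C_u) ** 2).sum(axis=1))
    return es_p > es_u


def select_negatives(
    P_set: Sequence[Pair],
    U_set: Sequence[Pair],
    IM: SimilarityMatrix | np.ndarray | None = None,
    ID: SimilarityMatrix | np.ndarray | None = None,
    A: AssociationMatrix | np.ndarray | None = None,
    source: str = "similarity",
    state: SelectionState | None = None,
    F_p: np.ndarray | None = None,
    F_u: np.ndarray | None = None,
) -> SelectionResult:
    """Run the full two-phase screen; returns the reliable negative pool.

    The per-iteration history records the Frobenius shifts of the two
    centroids.  If one side of a partition empties, its centroid is
    frozen and iteration continues.  Precomputed feature matrices
    ``F_p`` / ``F_u`` (one row per pair) bypass the similarity lookup —
    useful when pairs live in an externally defined feature space.
    """
    state = state or SelectionState()
    P_set, U_set = list(P_set), list(U_set)
    if not P_set or not U_set:
        raise ValueError("both the positive and unlabeled sets must be non-empty")
    if set(P_set) & set(U_set):
        raise ValueError("positive and unlabeled sets overlap")
    if F_p is None:
        F_p = pair_feature_matrix(P_set, IM, ID, A, source)
    if F_u is None:
        F_u = pair_feature_matrix(U_set, IM, ID, A, source)
    F_p, F_u = np.atleast_2d(F_p), np.atleast_2d(F_u)
    if F_p.shape[0] != len(P_set) or F_u.shape[0] != len(U_set):
        raise ValueError("feature matrices must have one row per pair")

    C_p, C_u = centroid(F_p), centroid(F_u)
    lp_mask = partition_cosine(F_u, C_p, C_u)
    history: list[tuple[float, float]] = []
    converged = False
    n_iter = 0
    for n_iter in range(1, state.max_iter + 1):
        # recompute centroids from the current partition
        if lp_mask.any():
            pos_feats = F_u[lp_mask]
            if state.augment_with_positives:
                pos_feats = np.vstack([F_p, pos_feats])
            C_p_new = centroid(pos_feats)
        else:
            logger.warning("likely-positive side empty at iteration %d; centroid frozen", n_iter)
            C_p_new = C_p
        if (~lp_mask).any():
            C_u_new = centroid(F_u[~lp_mask])
        else:
            logger.warning("likely-negative side empty at iteration %d; centroid frozen", n_iter)
            C_u_new = C_u
        shift_p = float(np.linalg.norm(C_p - C_p_new))
        shift_u = float(np.linalg.norm(C_u - C_u_new))
        history.append((shift_p, shift_u))
        C_p, C_u = C_p_new, C_u_new
        if shift_p <= state.tol and shift_u <= state.tol:
            converged = True
            break
        lp_mask = partition_euclidean(F_u, C_p, C_u)
    else:
        logger.warning(
            "negative selection hit max_iter=%d without centroid convergence "
            "(last shifts %.2e / %.2e)",
            state.max_iter,
            *history[-1],
        )
    negatives = [U_set[k] for k in np.flatnonzero(~lp_mask)]
    likely_pos = [U_set[k] for k in np.flatnonzero(lp_mask)]
    return SelectionResult(
        negatives=negatives,
        likely_positives=likely_pos,
        history=history,
        converged=converged,
        n_iter=n_iter,
    )


def kmeans_negatives(
    P_set: Sequence[Pair],
    U_set: Sequence[Pair],
    IM: SimilarityMatrix | np.ndarray | None = None,
    ID: SimilarityMatrix | np.ndarray | None = None,
    A: AssociationMatrix | np.ndarray | None = None,
    source: str = "similarity",
    seed: int = 0,
) -> SelectionResult:
    """Baseline: plain 2-means on the unlabeled pool.

    The cluster whose centroid is farther from the positive centroid is
    taken as the negative pool — no positive anchoring during the
    iteration, which is what distinguishes this from the two-phase screen.
    """
    from sklearn.cluster import KMeans

    P_set, U_set = list(P_set), list(U_set)
    F_p = pair_feature_matrix(P_set, IM, ID, A, source)
    F_u = pair_feature_matrix(U_set, IM, ID, A, source)
    km = KMeans(n_clusters=2, n_init=10, random_state=seed).fit(F_u)
    C_p = centroid(F_p)
    dists = np.linalg.norm(km.cluster_centers_ - C_p, axis=1)
    neg_cluster = int(np.argmax(dists))
    neg_mask = km.labels_ == neg_cluster
    return SelectionResult(
        negatives=[U_set[k] for k in np.flatnonzero(neg_mask)],
        likely_positives=[U_set[k] for k in np.flatnonzero(~neg_mask)],
        history=[],
        converged=True,
        n_iter=int(km.n_iter_),
    )


def random_negatives(U_set: Sequence[Pair], seed: int = 0) -> SelectionResult:
    """Baseline: treat the whole unlabeled pool as negatives (random order)."""
    U_set = list(U_set)
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(U_set))
    return SelectionResult(
        negatives=[U_set[k] for k in order],
        likely_positives=[],
        history=[],
        converged=True,
        n_iter=0,
    )
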