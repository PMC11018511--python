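"""Similarity networks and the heterogeneous block adjacency.

Four similarity sources feed the model:

* **GIP kernel** (``gip_kernel``): a Gaussian kernel over binary
  interaction profiles, ``exp(-a * ||R_i - R_j||^2)`` with the bandwidth
  ``a`` scaled by the mean squared profile norm, computed for miRNAs
  (rows of A) and diseases (columns of A).
* **Semantic similarity** (``semantic_similarity``): diseases live in a
  MeSH-style DAG; each ancestor contributes decayed semantic weight to a
  disease, and pairwise similarity is the shared-ancestor contribution
  mass over the total semantic mass.  Two contribution schemes (a
  decay recursion and a DAG-frequency log score) are averaged.
* **lncRNA profile similarity** (``lncrna_similarity``): entities with
  similar lncRNA association profiles are similar; profiles are binary
  strings compared by unit-cost Levenshtein distance, mapped to
  ``1 - ED/L``.
* **Functional similarity** (FM): an input, supplied precomputed.

``fuse_similarities`` combines sources by convex weights; the fused
miRNA and disease matrices plus the association matrix A assemble into
the symmetric block adjacency M = [[IM, A], [A^T, ID]] that drives the
graph convolution.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .io_formats import AssociationMatrix, DiseaseDAG, FormatError, SimilarityMatrix

__all__ = [
    "GipParams",
    "SemanticParams",
    "FusionWeights",
    "HeteroAdjacency",
    "gip_kernel",
    "semantic_contribution",
    "semantic_similarity",
    "lncrna_similarity",
    "levenshtein",
    "fuse_similarities",
    "build_hetero_matrix",
]


@dataclass
class GipParams:
    """Bandwidth numerators for the Gaussian interaction-profile kernel."""

    alpha_prime: float = 1.0  # miRNA axis
    beta_prime: float = 1.0  # disease axis

    def __post_init__(self) -> None:
        if self.alpha_prime <= 0 or self.beta_prime <= 0:
            raise ValueError("GIP bandwidth numerators must be positive")


@dataclass
class SemanticParams:
    """Decay factor for ancestor semantic contributions (0 < delta <= 1)."""

    delta: float = 0.5

    def __post_init__(self) -> None:
        if not 0 < self.delta <= 1:
            raise ValueError("semantic decay factor must be in (0, 1]")


def _simplex(v: Sequence[float], name: str) -> np.ndarray:
    v = np.asarray(v, dtype=float)
    if (v < 0).any():
        raise ValueError(f"{name} fusion weights must be non-negative")
    s = v.sum()
    if s <= 0:
        raise ValueError(f"{name} fusion weights must not all be zero")
    return v / s


@dataclass
class FusionWeights:
    """Convex combination weights for (functional, GIP, lncRNA) sources.

    Defaults are the converged values of the learnable-fusion run on the
    reference corpus: the functional source dominates on the miRNA side,
    the GIP source on the disease side.
    """

    alpha: np.ndarray = field(default_factory=lambda: np.array([0.77, 0.19, 0.04]))
    beta: np.ndarray = field(default_factory=lambda: np.array([0.16, 0.82, 0.02]))
    learnable: bool = False

    def __post_init__(self) -> None:
        self.alpha = _simplex(self.alpha, "miRNA")
        self.beta = _simplex(self.beta, "disease")


@dataclass
class HeteroAdjacency:
    """(Nm+Nd)-square block matrix M = [[IM, A], [A^T, ID]]."""

    values: np.ndarray
    nm: int
    nd: int

    def __post_init__(self) -> None:
        n = self.nm + self.nd
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (n, n):
            raise FormatError(f"hetero adjacency must be {n}x{n}")
        if not np.allclose(self.values, self.values.T, atol=1e-9, rtol=0):
            raise FormatError("hetero adjacency must be symmetric")

    @property
    def mirna_block(self) -> np.ndarray:
        return self.values[: self.nm, : self.nm]

    @property
    def disease_block(self) -> np.ndarray:
        return self.values[self.nm :, self.nm :]

    @property
    def assoc_block(self) -> np.ndarray:
        return self.values[: self.nm, self.nm :]


# ---------------------------------------------------------------------------
# GIP kernel


def gip_kernel(
    A: AssociationMatrix, axis: str = "mirna", params: GipParams | None = None
) -> SimilarityMatrix:
    """Gaussian interaction-profile kernel similarity from the association matrix.

    ``axis='mirna'`` uses rows of A as profiles (GM); ``axis='disease'``
    uses columns (GD).  The kernel bandwidth is the numerator divided by
    the mean squared profile norm, so an all-zero matrix is degenerate.
    """
    params = params or GipParams()
    if axis == "mirna":
        profiles, ids, num = A.values, A.mirna_ids, params.alpha_prime
    elif axis == "disease":
        profiles, ids, num = A.values.T, A.disease_ids, params.beta_prime
    else:
        raise ValueError(f"axis must be 'mirna' or 'disease', got {axis!r}")
    sq_norms = (profiles**2).sum(axis=1)
    mean_sq = sq_norms.mean()
    if mean_sq == 0:
        raise ValueError("all interaction profiles are zero: GIP bandwidth undefined")
    bandwidth = num / mean_sq
    # ||R_i - R_j||^2 via the Gram expansion; clip tiny negatives.
    gram = profiles @ profiles.T
    d2 = sq_norms[:, None] + sq_norms[None, :] - 2 * gram
    np.clip(d2, 0, None, out=d2)
    K = np.exp(-bandwidth * d2)
    K = (K + K.T) / 2
    np.fill_diagonal(K, 1.0)
    return SimilarityMatrix(values=K, ids=list(ids), kind="gip")


# ---------------------------------------------------------------------------
# DAG semantic similarity


def semantic_contribution(
    dag: DiseaseDAG,
    D: str,
    scheme: str = "dm1",
    params: SemanticParams | None = None,
    total_diseases: int | None = None,
    universe: Sequence[str] | None = None,
) -> dict[str, float]:
    """Semantic contribution of every ancestor of ``D`` (including ``D``).

    ``scheme='dm1'``: ``D`` itself contributes 1; each strict ancestor
    contributes the decayed maximum over its children inside T(D).

    ``scheme='dm2'``: each term contributes ``-log(f)`` where ``f`` is
    the fraction of disease DAGs that contain it — rarer terms are more
    informative, independently of where they sit relative to ``D``.
    ``universe`` fixes the disease set over which DAG membership is
    counted (default: every node of the supplied hierarchy);
    ``total_diseases`` overrides the denominator.
    """
    params = params or SemanticParams()
    if D not in dag:
        raise KeyError(f"unknown disease {D!r}")
    T = dag.ancestors(D)
    if scheme == "dm1":
        scores: dict[str, float] = {D: 1.0}
        # process ancestors in order of increasing distance from D
        remaining = set(T) - {D}
        while remaining:
            progressed = False
            for d in sorted(remaining):
                kids = [c for c in dag.children(d) if c in T]
                if all(c in scores for c in kids) and kids:
                    scores[d] = params.delta * max(scores[c] for c in kids)
                    remaining.discard(d)
                    progressed = True
            if not progressed:  # pragma: no cover - acyclicity guarantees progress
                raise RuntimeError("semantic contribution recursion stalled")
        return scores
    if scheme == "dm2":
        uni = list(universe) if universe is not None else list(dag.nodes)
        total = total_diseases if total_diseases is not None else len(uni)
        if total <= 0:
            raise ValueError("total_diseases must be positive for dm2")
        memberships = {u: dag.ancestors(u) for u in uni if u in dag}
        out: dict[str, float] = {}
        for d in T:
            count = sum(1 for anc in memberships.values() if d in anc)
            out[d] = -float(np.log(count / total)) if count else 0.0
        return out
    raise ValueError(f"unknown scheme {scheme!r}; expected 'dm1' or 'dm2'")


def _pairwise_fd(contrib: Mapping[str, Mapping[str, float]]) -> np.ndarray:
    """Shared-ancestor similarity for one contribution scheme.

    ``FD(i, j) = sum_{r in T(i) & T(j)} (c_i(r) + c_j(r)) / (S(i) + S(j))``
    with S the per-disease total contribution.  A vanishing denominator
    (possible for the frequency scheme when every term is ubiquitous)
    yields 1 on the diagonal and 0 off it.
    """
    ids = list(contrib)
    n = len(ids)
    totals = {d: sum(contrib[d].values()) for d in ids}
    out = np.zeros((n, n))
    for a, di in enumerate(ids):
        for b in range(a, n):
            dj = ids[b]
            shared = contrib[di].keys() & contrib[dj].keys()
            num = sum(contrib[di][r] + contrib[dj][r] for r in shared)
            den = totals[di] + totals[dj]
            if den > 0:
                val = num / den
            else:
                val = 1.0 if a == b else 0.0
            out[a, b] = out[b, a] = val
    np.fill_diagonal(out, 1.0)
    return np.clip(out, 0.0, 1.0)


def semantic_similarity(
    dag: DiseaseDAG,
    params: SemanticParams | None = None,
    diseases: Sequence[str] | None = None,
    total_diseases: int | None = None,
    scheme: str = "both",
) -> SimilarityMatrix:
    """DAG-based disease semantic similarity FD = (FD1 + FD2) / 2.

    ``diseases`` selects and orders the diseases of interest (default:
    all DAG nodes); they also form the universe for DAG-membership
    frequencies unless ``total_diseases`` overrides the denominator.
    ``scheme`` restricts the output to one component: ``'dm1'`` (decay
    recursion, FD1), ``'dm2'`` (DAG-frequency, FD2) or ``'both'``.
    """
    params = params or SemanticParams()
    if scheme not in ("both", "dm1", "dm2"):
        raise ValueError(f"unknown scheme {scheme!r}")
    ids = list(diseases) if diseases is not None else list(dag.nodes)
    for d in ids:
        if d not in dag:
            raise KeyError(f"disease {d!r} missing from the hierarchy")
    parts = []
    if scheme in ("both", "dm1"):
        c1 = {d: semantic_contribution(dag, d, "dm1", params) for d in ids}
        parts.append(_pairwise_fd(c1))
    if scheme in ("both", "dm2"):
        c2 = {
            d: semantic_contribution(
                dag, d, "dm2", params, total_diseases=total_diseases, universe=ids
            )
            for d in ids
        }
        parts.append(_pairwise_fd(c2))
    fd = sum(parts) / len(parts)
    np.fill_diagonal(fd, 1.0)
    return SimilarityMatrix(values=fd, ids=ids, kind="semantic")


# ---------------------------------------------------------------------------
# lncRNA edit-distance similarity


def levenshtein(a: Sequence[int], b: Sequence[int]) -> int:
    """Unit-cost edit distance between two sequences."""
    a, b = list(a), list(b)
    prev = list(range(len(b) + 1))
    for i, x in enumerate(a, 1):
        cur = [i]
        for j, y in enumerate(b, 1):
            cur.append(min(prev[j] + 1, cur[j - 1] + 1, prev[j - 1] + (x != y)))
        prev = cur
    return prev[-1]


def _batched_levenshtein(P: np.ndarray, Q: np.ndarray) -> np.ndarray:
    """Edit distances between row pairs P[k] vs Q[k] (equal length L).

    Row-wise DP where the in-row insertion recurrence is resolved by a
    prefix-minimum scan: dp[k] = min_{j<=k} (cand[j] + (k - j)).
    """
    npairs, L = P.shape
    idx = np.arange(L + 1)
    dp = np.broadcast_to(idx, (npairs, L + 1)).astype(np.int32).copy()
    for i in range(1, L + 1):
        cost = (P[:, i - 1 : i] != Q).astype(np.int32)  # (npairs, L)
        cand = np.empty_like(dp)
        cand[:, 0] = i
        cand[:, 1:] = np.minimum(dp[:, 1:] + 1, dp[:, :-1] + cost)
        dp = np.minimum.accumulate(cand - idx, axis=1) + idx
    return dp[:, -1]


def lncrna_similarity(
    profiles: np.ndarray, ids: Sequence[str], kind: str = "lncrna"
) -> SimilarityMatrix:
    """Similarity from binary lncRNA association profiles, 1 - ED/L.

    Each entity's profile (a row) is treated as a length-L binary string;
    similarity is one minus the normalized unit-cost edit distance.  The
    diagonal is forced to 1.
    """
    profiles = np.asarray(profiles)
    if profiles.ndim != 2:
        raise FormatError("lncRNA profile matrix must be 2-D")
    if not np.isin(profiles, (0, 1)).all():
        raise FormatError("lncRNA profiles must be binary")
    n, L = profiles.shape
    if L == 0:
        raise FormatError("lncRNA profiles are empty")
    iu, ju = np.triu_indices(n, k=1)
    S = np.eye(n)
    if iu.size:
        d = _batched_levenshtein(
            profiles[iu].astype(np.int8), profiles[ju].astype(np.int8)
        )
        S[iu, ju] = S[ju, iu] = 1.0 - d / L
    return SimilarityMatrix(values=S, ids=list(ids), kind=kind)


# ---------------------------------------------------------------------------
# fusion and block assembly


def fuse_similarities(
    FM: SimilarityMatrix | None,
    GM: SimilarityMatrix | None,
    LM: SimilarityMatrix | None,
    weights: Sequence[float],
) -> SimilarityMatrix:
    """Convex combination of up to three similarity sources.

    Missing sources (``None``) drop out and the remaining weights are
    renormalized — this is the single code path behind the
    per-source ablations.
    """
    weights = np.asarray(weights, dtype=float)
    sources = [FM, GM, LM]
    if len(weights) != 3:
        raise ValueError("expected 3 fusion weights (functional, gip, lncrna)")
    avail = [(m, w) for m, w in zip(sources, weights) if m is not None]
    if not avail:
        raise ValueError("at least one similarity source required")
    ids = avail[0][0].ids
    for m, _ in avail[1:]:
        if m.ids != ids:
            raise FormatError("similarity sources disagree on identifier order")
    w = _simplex([wt for _, wt in avail], "fusion")
    out = sum(wi * m.values for (m, _), wi in zip(avail, w))
    out = np.clip((out + out.T) / 2, 0.0, 1.0)
    np.fill_diagonal(out, 1.0)
    return SimilarityMatrix(values=out, ids=list(ids), kind="integrated")


def build_hetero_matrix(
    IM: SimilarityMatrix, ID: SimilarityMatrix, A: AssociationMatrix
) -> HeteroAdjacency:
    """Assemble M = [[IM, A], [A^T, ID]] over Nm miRNA + Nd disease nodes."""
    nm, nd = A.n_mirna, A.n_disease
    if IM.values.shape != (nm, nm) or ID.values.shape != (nd, nd):
        raise FormatError(
            f"block shapes do not conform: IM {IM.values.shape}, "
            f"ID {ID.values.shape}, A {A.values.shape}"
        )
    M = np.block([[IM.values, A.values], [A.values.T, ID.values]])
    return HeteroAdjacency(values=M, nm=nm, nd=nd)
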