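"""Linear multi-layer graph convolution over the block adjacency.

The encoder is deliberately activation-free: layer l computes
``H(l) = M . H(l-1) . W(l)``, which collapses to
``M^l . H(0) . W(1) ... W(l)``.  The power ``M^l`` is exactly the
meta-path weight matrix whose (u, v) entry sums the edge-weight
products over every length-l path from u to v, so each layer captures
meta-path semantics of one more hop.  Per-layer outputs are combined by
attention coefficients gamma on the simplex:
``H = gamma_1 H(1) + ... + gamma_l H(l)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .rwr import FeatureMatrix
from .similarity import HeteroAdjacency

__all__ = [
    "EncoderParams",
    "init_weights",
    "gcn_layer",
    "meta_path_weight_matrix",
    "fuse_layers",
    "encode",
]


@dataclass
class EncoderParams:
    """Meta-path depth, embedding width and layer-combination weights."""

    n_layers: int = 2
    embed_dim: int = 256
    gamma: np.ndarray | None = None  # default: uniform over layers
    gamma_learnable: bool = False
    weight_init_seed: int = 0
    normalize_m: bool = False  # optional symmetric degree normalization of M

    def __post_init__(self) -> None:
        if self.n_layers < 1:
            raise ValueError("need at least one convolution layer")
        if self.embed_dim < 1:
            raise ValueError("embedding dimension must be at least 1")
        if self.gamma is None:
            self.gamma = np.full(self.n_layers, 1.0 / self.n_layers)
        self.gamma = np.asarray(self.gamma, dtype=float)
        if self.gamma.shape != (self.n_layers,):
            raise ValueError("gamma must have one weight per layer")
        if (self.gamma < 0).any():
            raise ValueError("gamma weights must be non-negative")
        s = self.gamma.sum()
        if s <= 0:
            raise ValueError("gamma weights must not all be zero")
        self.gamma = self.gamma / s


def init_weights(
    n_in: int, params: EncoderParams
) -> list[np.ndarray]:
    """Glorot-uniform weight matrices W(1): n_in x d, W(l>1): d x d, seeded."""
    rng = np.random.default_rng(params.weight_init_seed)
    dims = [n_in] + [params.embed_dim] * params.n_layers
    weights = []
    for fan_in, fan_out in zip(dims[:-1], dims[1:]):
        limit = np.sqrt(6.0 / (fan_in + fan_out))
        weights.append(rng.uniform(-limit, limit, size=(fan_in, fan_out)))
    return weights


def _maybe_normalize(M: np.ndarray, normalize: bool) -> np.ndarray:
    if not normalize:
        return M
    deg = M.sum(axis=1)
    deg[deg == 0] = 1.0
    d = 1.0 / np.sqrt(deg)
    return M * d[:, None] * d[None, :]


def gcn_layer(
    M: HeteroAdjacency | np.ndarray, H_prev: FeatureMatrix | np.ndarray, W: np.ndarray
) -> FeatureMatrix:
    """One linear propagation step H = M . H_prev . W (no bias, no activation)."""
    Mv = M.values if isinstance(M, HeteroAdjacency) else np.asarray(M, dtype=float)
    Hv = H_prev.values if isinstance(H_prev, FeatureMatrix) else np.asarray(H_prev)
    layer = H_prev.layer if isinstance(H_prev, FeatureMatrix) else 0
    if Mv.shape[1] != Hv.shape[0] or Hv.shape[1] != W.shape[0]:
        raise ValueError(
            f"shapes do not conform: M {Mv.shape}, H {Hv.shape}, W {W.shape}"
        )
    nxt = layer + 1 if isinstance(layer, int) else "fused"
    return FeatureMatrix(values=Mv @ Hv @ W, layer=nxt)


def meta_path_weight_matrix(M: HeteroAdjacency | np.ndarray, length: int) -> np.ndarray:
    """M^length: entry (u, v) sums edge-weight products over length-l paths u -> v."""
    if length < 1:
        raise ValueError("meta-path length must be at least 1")
    Mv = M.values if isinstance(M, HeteroAdjacency) else np.asarray(M, dtype=float)
    return np.linalg.matrix_power(Mv, length)


def fuse_layers(
    H_list: Sequence[FeatureMatrix | np.ndarray], gamma: Sequence[float]
) -> FeatureMatrix:
    """Attention-weighted sum of per-layer features."""
    if len(H_list) != len(gamma):
        raise ValueError("one gamma weight per layer output required")
    if not H_list:
        raise ValueError("no layer outputs to fuse")
    mats = [h.values if isinstance(h, FeatureMatrix) else np.asarray(h) for h in H_list]
    shape = mats[0].shape
    for m in mats[1:]:
        if m.shape != shape:
            raise ValueError("layer outputs must share a shape")
    out = sum(g * m for g, m in zip(gamma, mats))
    return FeatureMatrix(values=out, layer="fused")


def encode(
    M: HeteroAdjacency | np.ndarray,
    H0: FeatureMatrix | np.ndarray,
    params: EncoderParams,
    weights: Sequence[np.ndarray] | None = None,
) -> tuple[FeatureMatrix, list[FeatureMatrix]]:
    """Run all layers and fuse; returns (H, [H(1), ..., H(l)]).

    ``weights`` lets a training loop supply its current parameters;
    otherwise fresh seeded Glorot matrices are drawn.  Per-layer outputs
    are returned for meta-path-length ablations (restricting to a layer
    subset is equivalent to zeroing the other gamma entries).
    """
    Mv = M.values if isinstance(M, HeteroAdjacency) else np.asarray(M, dtype=float)
    Mv = _maybe_normalize(Mv, params.normalize_m)
    H0v = H0.values if isinstance(H0, FeatureMatrix) else np.asarray(H0, dtype=float)
    if weights is None:
        weights = init_weights(H0v.shape[1], params)
    if len(weights) != params.n_layers:
        raise ValueError("one weight matrix per layer required")
    per_layer: list[FeatureMatrix] = []
    H = FeatureMatrix(values=H0v, layer=0)
    for W in weights:
        H = gcn_layer(Mv, H, W)
        per_layer.append(H)
    fused = fuse_layers(per_layer, params.gamma)
    return fused, per_layer
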