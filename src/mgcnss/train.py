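"""Training of the linear graph-convolution encoder and pair scoring.

The decoder is an inner product: pair (m, d) gets probability
``sigmoid(<H_m, H_d>)`` where H is the fused encoder output.  Training
minimizes the summed binary cross-entropy over positive pairs and the
screened negative pairs:

    L = - sum_P log sigma(<H_m, H_d>) - sum_N log(1 - sigma(<H_m', H_d'>))

Because every stage of the encoder is a linear map, the gradients with
respect to the layer weights W(l), the layer-attention logits and the
similarity-fusion logits are available in closed form; they are
implemented here directly (validated against central finite
differences in the test suite) and driven by an Adam optimizer with
decoupled-free L2 weight decay folded into the gradient, matching the
reference hyperparameters (lr 5e-4, weight decay 5e-4).  Everything is
full-batch and seeded, so runs are bitwise reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .encoder import EncoderParams, init_weights, _maybe_normalize
from .io_formats import AssociationMatrix, SimilarityMatrix
from .rwr import FeatureMatrix
from .similarity import FusionWeights, HeteroAdjacency, build_hetero_matrix, fuse_similarities

__all__ = [
    "TrainConfig",
    "SimilarityStack",
    "ModelState",
    "score_pair",
    "bce_loss",
    "bce_loss_grad",
    "train",
    "predict_all",
]

Pair = tuple[int, int]
_LOG_CLAMP = 1e-12


@dataclass
class TrainConfig:
    learning_rate: float = 5e-4
    weight_decay: float = 5e-4
    epochs: int = 2000
    seed: int = 0
    neg_pos_ratio: int = 1  # used by the CV driver when sampling negatives

    def __post_init__(self) -> None:
        if self.learning_rate <= 0:
            raise ValueError("learning rate must be positive")
        if self.epochs < 0:
            raise ValueError("epochs must be non-negative")
        if self.neg_pos_ratio < 1:
            raise ValueError("neg_pos_ratio must be at least 1")


@dataclass
class SimilarityStack:
    """Cached similarity sources so learnable fusion can reassemble M."""

    A: AssociationMatrix
    FM: SimilarityMatrix | None = None
    GM: SimilarityMatrix | None = None
    LM: SimilarityMatrix | None = None
    FD: SimilarityMatrix | None = None
    GD: SimilarityMatrix | None = None
    LD: SimilarityMatrix | None = None

    def mirna_sources(self) -> tuple[list[np.ndarray], list[int]]:
        """Available miRNA-side source matrices and their slot indices
        (0=functional, 1=gip, 2=lncrna)."""
        present = [(k, s) for k, s in enumerate((self.FM, self.GM, self.LM)) if s is not None]
        return [s.values for _, s in present], [k for k, _ in present]

    def disease_sources(self) -> tuple[list[np.ndarray], list[int]]:
        present = [(k, s) for k, s in enumerate((self.FD, self.GD, self.LD)) if s is not None]
        return [s.values for _, s in present], [k for k, _ in present]


@dataclass
class ModelState:
    """Learned parameters plus the fused embedding they produce."""

    weights: list[np.ndarray]
    gamma: np.ndarray
    alpha: np.ndarray | None
    beta: np.ndarray | None
    loss_history: list[float]
    H: FeatureMatrix
    nm: int
    nd: int


def _sigmoid(z: np.ndarray | float) -> np.ndarray | float:
    return 1.0 / (1.0 + np.exp(-np.clip(z, -500, 500)))


def _pair_logits(H: np.ndarray, pairs: np.ndarray, nm: int) -> np.ndarray:
    return (H[pairs[:, 0]] * H[nm + pairs[:, 1]]).sum(axis=1)


def score_pair(H: FeatureMatrix | np.ndarray, m: int, d: int, nm: int) -> float:
    """sigmoid(<H_m, H_d>) for miRNA m and disease d (disease rows offset by Nm)."""
    Hv = H.values if isinstance(H, FeatureMatrix) else np.asarray(H)
    if not 0 <= m < nm or not 0 <= nm + d < Hv.shape[0]:
        raise IndexError(f"pair ({m}, {d}) out of range for nm={nm}")
    return float(_sigmoid(float(Hv[m] @ Hv[nm + d])))


def bce_loss(
    H: FeatureMatrix | np.ndarray,
    positives: Sequence[Pair],
    negatives: Sequence[Pair],
    nm: int,
) -> float:
    """Summed binary cross-entropy of Eq. above; logs clamped at 1e-12."""
    loss, _ = bce_loss_grad(H, positives, negatives, nm)
    return loss


def bce_loss_grad(
    H: FeatureMatrix | np.ndarray,
    positives: Sequence[Pair],
    negatives: Sequence[Pair],
    nm: int,
) -> tuple[float, np.ndarray]:
    """Loss and its analytic gradient with respect to the embedding H.

    d loss / d z = sigma(z) - y for each pair logit z, pushed back onto
    the two participating embedding rows.
    """
    Hv = H.values if isinstance(H, FeatureMatrix) else np.asarray(H, dtype=float)
    pos = np.asarray(list(positives), dtype=int).reshape(-1, 2)
    neg = np.asarray(list(negatives), dtype=int).reshape(-1, 2)
    if pos.shape[0] == 0:
        raise ValueError("positive pair set is empty")
    G = np.zeros_like(Hv)
    loss = 0.0
    for pairs, y in ((pos, 1.0), (neg, 0.0)):
        if pairs.shape[0] == 0:
            continue
        z = _pair_logits(Hv, pairs, nm)
        p = np.clip(_sigmoid(z), _LOG_CLAMP, 1 - _LOG_CLAMP)
        loss += float(-(y * np.log(p) + (1 - y) * np.log(1 - p)).sum())
        g = _sigmoid(z) - y  # d loss / d z
        np.add.at(G, pairs[:, 0], g[:, None] * Hv[nm + pairs[:, 1]])
        np.add.at(G, nm + pairs[:, 1], g[:, None] * Hv[pairs[:, 0]])
    return loss, G


def _softmax(x: np.ndarray) -> np.ndarray:
    e = np.exp(x - x.max())
    return e / e.sum()


def _softmax_vjp(p: np.ndarray, grad_p: np.ndarray) -> np.ndarray:
    return p * (grad_p - float(p @ grad_p))


class _Adam:
    """Minimal Adam with L2 weight decay folded into the gradient."""

    def __init__(self, lr: float, wd: float, beta1=0.9, beta2=0.999, eps=1e-8):
        self.lr, self.wd, self.b1, self.b2, self.eps = lr, wd, beta1, beta2, eps
        self.m: dict[int, np.ndarray] = {}
        self.v: dict[int, np.ndarray] = {}
        self.t = 0

    def step(self, params: list[np.ndarray], grads: list[np.ndarray]) -> None:
        self.t += 1
        for k, (p, g) in enumerate(zip(params, grads)):
            g = g + self.wd * p
            m = self.m.setdefault(k, np.zeros_like(p))
            v = self.v.setdefault(k, np.zeros_like(p))
            m += (1 - self.b1) * (g - m)
            v += (1 - self.b2) * (g * g - v)
            mhat = m / (1 - self.b1**self.t)
            vhat = v / (1 - self.b2**self.t)
            p -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


class _LinearGCN:
    """Forward/backward engine for the linear encoder.

    Parameters: layer weights W(1..L); optionally layer-attention logits
    (softmax -> gamma) and fusion logits (softmax -> alpha, beta) when
    the respective flags are set.  With fixed fusion the meta-path
    propagations X_l = M^l H0 are precomputed once.
    """

    def __init__(
        self,
        H0: np.ndarray,
        enc: EncoderParams,
        M: np.ndarray | None,
        stack: SimilarityStack | None,
        fusion: FusionWeights | None,
    ):
        self.H0 = H0
        self.enc = enc
        self.L = enc.n_layers
        self.stack = stack
        self.fusion = fusion
        self.learn_fusion = bool(fusion is not None and fusion.learnable)
        if self.learn_fusion:
            if stack is None:
                raise ValueError("learnable fusion requires the similarity stack")
            self.Sm, slots_m = stack.mirna_sources()
            self.Sd, slots_d = stack.disease_sources()
            if not self.Sm or not self.Sd:
                raise ValueError("learnable fusion requires at least one source per side")
            self.nm, self.nd = stack.A.n_mirna, stack.A.n_disease
            self.Ablock = stack.A.values
            wa = fusion.alpha[slots_m]
            wb = fusion.beta[slots_d]
            self.a_logits = np.log(np.clip(wa / wa.sum(), 1e-8, None))
            self.b_logits = np.log(np.clip(wb / wb.sum(), 1e-8, None))
        else:
            if M is None:
                raise ValueError("fixed fusion requires a prebuilt hetero adjacency")
            self.M = _maybe_normalize(np.asarray(M, dtype=float), enc.normalize_m)
            self.X = [H0]
            for _ in range(self.L):
                self.X.append(self.M @ self.X[-1])
        self.weights = init_weights(H0.shape[1], enc)
        self.learn_gamma = enc.gamma_learnable
        self.g_logits = np.log(np.clip(enc.gamma, 1e-8, None))

    # -- parameter plumbing -------------------------------------------------
    def params(self) -> list[np.ndarray]:
        out = list(self.weights)
        if self.learn_gamma:
            out.append(self.g_logits)
        if self.learn_fusion:
            out += [self.a_logits, self.b_logits]
        return out

    def gamma(self) -> np.ndarray:
        return _softmax(self.g_logits) if self.learn_gamma else self.enc.gamma

    def alphas(self) -> tuple[np.ndarray | None, np.ndarray | None]:
        if not self.learn_fusion:
            if self.fusion is None:
                return None, None
            return self.fusion.alpha, self.fusion.beta
        return _softmax(self.a_logits), _softmax(self.b_logits)

    def _assemble_M(self) -> np.ndarray:
        a, b = _softmax(self.a_logits), _softmax(self.b_logits)
        IM = sum(ai * S for ai, S in zip(a, self.Sm))
        ID = sum(bi * S for bi, S in zip(b, self.Sd))
        n = self.nm + self.nd
        M = np.empty((n, n))
        M[: self.nm, : self.nm] = IM
        M[: self.nm, self.nm :] = self.Ablock
        M[self.nm :, : self.nm] = self.Ablock.T
        M[self.nm :, self.nm :] = ID
        return _maybe_normalize(M, self.enc.normalize_m)

    # -- forward ------------------------------------------------------------
    def forward(self) -> tuple[np.ndarray, list[np.ndarray], list[np.ndarray], np.ndarray]:
        """Returns (H, per-layer Y_l, propagations X_l, M used)."""
        if self.learn_fusion:
            M = self._assemble_M()
            X = [self.H0]
            for _ in range(self.L):
                X.append(M @ X[-1])
        else:
            M, X = self.M, self.X
        # cumulative weight products C_l = W1 ... Wl
        C: list[np.ndarray] = []
        for W in self.weights:
            C.append(W if not C else C[-1] @ W)
        Y = [X[l + 1] @ C[l] for l in range(self.L)]
        gamma = self.gamma()
        H = sum(g * y for g, y in zip(gamma, Y))
        return H, Y, X, M

    # -- backward -----------------------------------------------------------
    def grads(
        self, G_H: np.ndarray, Y: list[np.ndarray], X: list[np.ndarray], M: np.ndarray
    ) -> list[np.ndarray]:
        gamma = self.gamma()
        G_Y = [g * G_H for g in gamma]
        # layer weight gradients: dW_k = sum_{l>=k} (X_{l} C_{k-1})^T G_Yl S_{k+1..l}^T
        dW = [np.zeros_like(W) for W in self.weights]
        C: list[np.ndarray | None] = [None]  # C[k] = W1..Wk, C[0] = identity marker
        for W in self.weights:
            C.append(W if C[-1] is None else C[-1] @ W)
        for l in range(self.L):  # contribution of Y_l, zero-based layer index
            suffix: np.ndarray | None = None  # W_{k+2} .. W_{l+1} (1-based: k+1..l)
            for k in range(l, -1, -1):
                prefix = X[l + 1] if k == 0 else X[l + 1] @ C[k]
                G = G_Y[l] if suffix is None else G_Y[l] @ suffix.T
                dW[k] += prefix.T @ G
                suffix = self.weights[k] if suffix is None else self.weights[k] @ suffix
        out = dW
        if self.learn_gamma:
            dgamma = np.array([float((G_H * y).sum()) for y in Y])
            out.append(_softmax_vjp(_softmax(self.g_logits), dgamma))
        if self.learn_fusion:
            # back through X_l = M X_{l-1}
            dM = np.zeros_like(M)
            GX = [np.zeros_like(x) for x in X]
            for l in range(self.L - 1, -1, -1):
                GX[l + 1] += G_Y[l] @ C[l + 1].T
                dM += GX[l + 1] @ X[l].T
                GX[l] += M.T @ GX[l + 1]
            a, b = _softmax(self.a_logits), _softmax(self.b_logits)
            dIM = dM[: self.nm, : self.nm]
            dID = dM[self.nm :, self.nm :]
            da = np.array([float((dIM * S).sum()) for S in self.Sm])
            db = np.array([float((dID * S).sum()) for S in self.Sd])
            out.append(_softmax_vjp(a, da))
            out.append(_softmax_vjp(b, db))
        return out


def train(
    H0: FeatureMatrix | np.ndarray,
    positives: Sequence[Pair],
    negatives: Sequence[Pair],
    cfg: TrainConfig,
    enc: EncoderParams | None = None,
    M: HeteroAdjacency | np.ndarray | None = None,
    stack: SimilarityStack | None = None,
    fusion: FusionWeights | None = None,
    nm: int | None = None,
) -> ModelState:
    """Full-batch BCE training; deterministic given the config seed.

    Either a prebuilt hetero adjacency ``M`` (fixed fusion) or a
    ``stack`` of similarity sources with ``fusion.learnable`` must be
    supplied.  ``nm`` (miRNA count) defaults to the stack's or must be
    given with ``M``.
    """
    enc = enc or EncoderParams()
    H0v = H0.values if isinstance(H0, FeatureMatrix) else np.asarray(H0, dtype=float)
    if isinstance(M, HeteroAdjacency):
        nm = M.nm if nm is None else nm
        M = M.values
    if nm is None and stack is not None:
        nm = stack.A.n_mirna
    if nm is None:
        raise ValueError("the miRNA count nm is required")
    enc = EncoderParams(
        n_layers=enc.n_layers,
        embed_dim=enc.embed_dim,
        gamma=enc.gamma,
        gamma_learnable=enc.gamma_learnable,
        weight_init_seed=cfg.seed if enc.weight_init_seed == 0 else enc.weight_init_seed,
        normalize_m=enc.normalize_m,
    )
    model = _LinearGCN(H0v, enc, M, stack, fusion)
    opt = _Adam(cfg.learning_rate, cfg.weight_decay)
    history: list[float] = []
    for epoch in range(cfg.epochs):
        H, Y, X, Mu = model.forward()
        loss, G_H = bce_loss_grad(H, positives, negatives, nm)
        if not np.isfinite(loss):
            raise FloatingPointError(f"training diverged (non-finite loss) at epoch {epoch}")
        history.append(loss)
        opt.step(model.params(), model.grads(G_H, Y, X, Mu))
    H = model.forward()[0]
    alpha, beta = model.alphas()
    nd = H.shape[0] - nm
    return ModelState(
        weights=model.weights,
        gamma=model.gamma(),
        alpha=alpha,
        beta=beta,
        loss_history=history,
        H=FeatureMatrix(values=H, layer="fused"),
        nm=nm,
        nd=nd,
    )


def predict_all(state: ModelState) -> np.ndarray:
    """Score every miRNA-disease pair: sigmoid(H_m . H_d^T), shape (Nm, Nd)."""
    Hv = state.H.values
    Hm, Hd = Hv[: state.nm], Hv[state.nm :]
    return np.asarray(_sigmoid(Hm @ Hd.T))
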