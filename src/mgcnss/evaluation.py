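"""Cross-validated evaluation, metrics, and ranked candidate lists.

The 5-fold protocol: screen reliable negatives once on the full data,
sample ratio * |P| of them, split positives and sampled negatives into
five folds, and for each fold *mask the test positives out of A* before
rebuilding the GIP similarities, the block adjacency and the walk
features — otherwise test labels leak into the encoder input.  Metrics
are AUC (rank statistic), AUPR (step-wise precision-recall
integration) and accuracy at a 0.5 probability threshold, reported as
mean +/- sd over folds.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from sklearn.metrics import average_precision_score, roc_auc_score

from .encoder import EncoderParams
from .io_formats import AssociationMatrix
from .negative_selection import (
    SelectionState,
    kmeans_negatives,
    random_negatives,
    select_negatives,
)
from .rwr import RwrParams, rwr_features
from .similarity import FusionWeights, build_hetero_matrix, fuse_similarities, gip_kernel
from .train import ModelState, SimilarityStack, TrainConfig, predict_all, train

__all__ = [
    "CvPlan",
    "MetricReport",
    "compute_metrics",
    "five_fold_cv",
    "rank_candidates",
    "overlap_stats",
]

logger = logging.getLogger(__name__)

Pair = tuple[int, int]


@dataclass
class CvPlan:
    n_folds: int = 5
    ratio: int = 1  # negatives per positive
    seed: int = 0
    nsst_scope: str = "train_and_test"  # or "train_only" (selection not applied to test)

    def __post_init__(self) -> None:
        if self.n_folds < 2:
            raise ValueError("need at least 2 folds")
        if self.ratio < 1:
            raise ValueError("ratio must be at least 1")
        if self.nsst_scope not in ("train_and_test", "train_only"):
            raise ValueError(f"unknown nsst_scope {self.nsst_scope!r}")


@dataclass
class MetricReport:
    auc: float
    acc: float
    aupr: float
    auc_sd: float
    acc_sd: float
    aupr_sd: float
    per_fold: list[dict] = field(default_factory=list)

    def as_dict(self) -> dict:
        return {
            "auc": self.auc,
            "acc": self.acc,
            "aupr": self.aupr,
            "auc_sd": self.auc_sd,
            "acc_sd": self.acc_sd,
            "aupr_sd": self.aupr_sd,
            "per_fold": self.per_fold,
        }


def compute_metrics(
    scores: Sequence[float], labels: Sequence[int], threshold: float = 0.5
) -> dict:
    """AUC, accuracy at the threshold, and AUPR for one score/label set."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if len(set(labels.tolist())) < 2:
        raise ValueError("metrics undefined: only one class present")
    return {
        "auc": float(roc_auc_score(labels, scores)),
        "acc": float(((scores >= threshold).astype(int) == labels).mean()),
        "aupr": float(average_precision_score(labels, scores)),
    }


def _unlabeled_pairs(A: AssociationMatrix) -> list[Pair]:
    return [tuple(p) for p in np.argwhere(A.values == 0)]


def _screen(
    strategy: str,
    P: list[Pair],
    U: list[Pair],
    IM,
    ID,
    A: AssociationMatrix,
    source: str,
    sel_state: SelectionState,
    seed: int,
):
    if strategy == "distance_based":
        return select_negatives(P, U, IM, ID, A, source, sel_state)
    if strategy == "kmeans":
        return kmeans_negatives(P, U, IM, ID, A, source, seed=seed)
    if strategy == "random":
        return random_negatives(U, seed=seed)
    raise ValueError(f"unknown negative-selection strategy {strategy!r}")


def five_fold_cv(
    stack: SimilarityStack,
    plan: CvPlan,
    cfg: TrainConfig,
    enc: EncoderParams | None = None,
    fusion: FusionWeights | None = None,
    rwr_params: RwrParams | None = None,
    sel_state: SelectionState | None = None,
    strategy: str = "distance_based",
    feature_source: str = "similarity",
    include_gip: bool = True,
    mask_test_positives: bool = True,
) -> MetricReport:
    """Run the full cross-validation protocol and report mean +/- sd metrics.

    ``stack`` carries the association matrix and the A-independent
    similarity sources (FM, LM, FD, LD); the GIP similarities are
    recomputed per fold from the masked A.  ``strategy`` switches the
    negative screen (``distance_based`` / ``kmeans`` / ``random``);
    ``include_gip=False`` drops the GIP source everywhere (the
    per-source ablation).

    ``mask_test_positives=True`` (default) zeroes each fold's test
    positives out of A before the GIP/adjacency/walk rebuild, so no test
    label reaches the encoder input.  ``False`` reproduces the reference
    protocol, in which the full A feeds the encoder — optimistic, since
    test associations then shape the similarity graph the model reads.
    """
    enc = enc or EncoderParams()
    fusion = fusion or FusionWeights()
    rwr_params = rwr_params or RwrParams()
    sel_state = sel_state or SelectionState()
    A = stack.A
    rng = np.random.default_rng(plan.seed)

    P = A.positives()
    U = _unlabeled_pairs(A)
    gm_full = gip_kernel(A, "mirna") if include_gip else None
    gd_full = gip_kernel(A, "disease") if include_gip else None
    IM_full = fuse_similarities(stack.FM, gm_full, stack.LM, fusion.alpha)
    ID_full = fuse_similarities(stack.FD, gd_full, stack.LD, fusion.beta)

    result = _screen(
        strategy, P, U, IM_full, ID_full, A, feature_source, sel_state, plan.seed
    )
    pool = result.negatives
    n_neg = plan.ratio * len(P)
    if len(pool) < n_neg:
        raise ValueError(
            f"selected negative pool too small: need {n_neg}, have {len(pool)}"
        )
    chosen = rng.choice(len(pool), size=n_neg, replace=False)
    negatives = [pool[k] for k in chosen]

    pos_folds = np.array_split(rng.permutation(len(P)), plan.n_folds)
    neg_folds = np.array_split(rng.permutation(n_neg), plan.n_folds)

    per_fold: list[dict] = []
    for f in range(plan.n_folds):
        test_pos = [P[k] for k in pos_folds[f]]
        train_pos = [P[k] for g in range(plan.n_folds) if g != f for k in pos_folds[g]]
        sel_test_neg = [negatives[k] for k in neg_folds[f]]
        train_neg = [
            negatives[k] for g in range(plan.n_folds) if g != f for k in neg_folds[g]
        ]
        if plan.nsst_scope == "train_and_test":
            test_neg = sel_test_neg
        else:
            # unscreened test negatives: uniform over the unlabeled pool
            take = rng.choice(len(U), size=plan.ratio * len(test_pos), replace=False)
            test_neg = [U[k] for k in take]

        if mask_test_positives:
            # mask test positives out of A for everything the fold trains on
            A_train_vals = A.values.copy()
            for i, j in test_pos:
                A_train_vals[i, j] = 0
            A_train = AssociationMatrix(
                values=A_train_vals, mirna_ids=A.mirna_ids, disease_ids=A.disease_ids
            )
            gm = gip_kernel(A_train, "mirna") if include_gip else None
            gd = gip_kernel(A_train, "disease") if include_gip else None
            IM = fuse_similarities(stack.FM, gm, stack.LM, fusion.alpha)
            ID = fuse_similarities(stack.FD, gd, stack.LD, fusion.beta)
            M = build_hetero_matrix(IM, ID, A_train)
            H0 = rwr_features(A_train, rwr_params)
        else:
            A_train = A
            gm, gd = gm_full, gd_full
            M = build_hetero_matrix(IM_full, ID_full, A)
            H0 = rwr_features(A, rwr_params)
        if fusion.learnable:
            fold_stack = SimilarityStack(
                A=A_train, FM=stack.FM, GM=gm, LM=stack.LM,
                FD=stack.FD, GD=gd, LD=stack.LD,
            )
            state = train(
                H0, train_pos, train_neg, cfg, enc,
                stack=fold_stack, fusion=fusion,
            )
        else:
            state = train(H0, train_pos, train_neg, cfg, enc, M=M)
        scores_mat = predict_all(state)
        pairs = test_pos + test_neg
        y = [1] * len(test_pos) + [0] * len(test_neg)
        s = [scores_mat[i, j] for i, j in pairs]
        per_fold.append(compute_metrics(s, y))

    def agg(key: str) -> tuple[float, float]:
        vals = np.array([m[key] for m in per_fold])
        return float(vals.mean()), float(vals.std())

    (auc, auc_sd), (acc, acc_sd), (aupr, aupr_sd) = agg("auc"), agg("acc"), agg("aupr")
    return MetricReport(
        auc=auc, acc=acc, aupr=aupr,
        auc_sd=auc_sd, acc_sd=acc_sd, aupr_sd=aupr_sd,
        per_fold=per_fold,
    )


def rank_candidates(
    scores: np.ndarray,
    mirna_ids: Sequence[str],
    disease_ids: Sequence[str],
    disease: str,
    k: int = 50,
    A: AssociationMatrix | None = None,
    exclude_known: bool = False,
) -> list[tuple[str, float]]:
    """Top-k miRNAs for one disease by score, ties broken by identifier.

    ``exclude_known`` drops miRNAs already associated in A.  Requests
    beyond the candidate count are truncated with a warning.
    """
    scores = np.asarray(scores, dtype=float)
    disease_ids = [str(d) for d in disease_ids]
    if disease not in disease_ids:
        raise KeyError(f"unknown disease {disease!r}")
    j = disease_ids.index(disease)
    candidates = list(range(scores.shape[0]))
    if exclude_known:
        if A is None:
            raise ValueError("exclude_known requires the association matrix")
        candidates = [i for i in candidates if A.values[i, j] == 0]
    if k > len(candidates):
        logger.warning(
            "requested top %d but only %d candidates; truncating", k, len(candidates)
        )
        k = len(candidates)
    order = sorted(candidates, key=lambda i: (-scores[i, j], str(mirna_ids[i])))
    return [(str(mirna_ids[i]), float(scores[i, j])) for i in order[:k]]


def overlap_stats(a: Sequence[str], b: Sequence[str]) -> tuple[float, float, float]:
    """Jaccard-style overlap ratios (|A&B|/|A|B|, |A|/|A|B|, |B|/|A|B|)."""
    sa, sb = set(a), set(b)
    union = sa | sb
    if not union:
        raise ValueError("overlap undefined for two empty sets")
    return (len(sa & sb) / len(union), len(sa) / len(union), len(sb) / len(union))
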