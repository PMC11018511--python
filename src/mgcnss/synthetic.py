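"""Seeded synthetic benchmark data with planted block structure.

The generator states a small world in which the method's premise holds
by construction: miRNAs and diseases are partitioned into blocks
(co-association communities), within-block pairs associate with
probability ``density`` and off-block pairs with probability ``noise``,
and every similarity source is correlated with block membership —
functional similarity is block agreement plus Gaussian jitter, lncRNA
profiles are noisy copies of a block prototype, and the disease DAG
hangs each block's diseases under a shared ancestor chain.  The planted
block labels are returned so recovery can be measured.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .io_formats import AssociationMatrix, DiseaseDAG, SimilarityMatrix
from .similarity import lncrna_similarity

__all__ = ["SynthConfig", "SyntheticDataset", "generate", "hold_out"]

logger = logging.getLogger(__name__)


@dataclass
class SynthConfig:
    """Stated world of the default benchmark: 100 x 80 nodes, 5 blocks,
    30% within-block association density, 2% off-block noise."""

    n_mirna: int = 100
    n_disease: int = 80
    n_blocks: int = 5
    density: float = 0.3
    noise: float = 0.02  # off-block positive rate and similarity jitter sd
    n_lncrna: int = 40
    dag_depth: int = 3
    seed: int = 1

    def __post_init__(self) -> None:
        if self.n_mirna < 2 or self.n_disease < 2:
            raise ValueError("need at least 2 miRNAs and 2 diseases")
        if self.n_blocks < 1 or self.n_blocks > min(self.n_mirna, self.n_disease):
            raise ValueError("block count must fit both node sets")
        if not 0 < self.density <= 1:
            raise ValueError("density must be in (0, 1]")
        if self.noise < 0:
            raise ValueError("noise must be non-negative")
        if self.n_lncrna < 1:
            raise ValueError("need at least one lncRNA")
        if self.dag_depth < 1:
            raise ValueError("DAG depth must be at least 1")


@dataclass
class SyntheticDataset:
    A: AssociationMatrix
    FM: SimilarityMatrix
    LM: SimilarityMatrix
    LD: SimilarityMatrix
    mirna_lnc: np.ndarray
    disease_lnc: np.ndarray
    dag: DiseaseDAG
    mirna_blocks: np.ndarray
    disease_blocks: np.ndarray
    config: SynthConfig = field(repr=False, default_factory=SynthConfig)


def _block_labels(n: int, n_blocks: int) -> np.ndarray:
    # contiguous, near-equal blocks
    return np.repeat(np.arange(n_blocks), np.diff(np.linspace(0, n, n_blocks + 1).astype(int)))


def _block_similarity(labels: np.ndarray, jitter_sd: float, rng: np.random.Generator) -> np.ndarray:
    base = (labels[:, None] == labels[None, :]).astype(float)
    if jitter_sd > 0:
        base = base + rng.normal(0, jitter_sd, size=base.shape)
    S = np.clip((base + base.T) / 2, 0.0, 1.0)
    np.fill_diagonal(S, 1.0)
    return S


def _block_profiles(
    labels: np.ndarray, n_lnc: int, flip: float, rng: np.random.Generator
) -> np.ndarray:
    protos = rng.integers(0, 2, size=(labels.max() + 1, n_lnc))
    prof = protos[labels]
    flips = rng.random(prof.shape) < flip
    return np.where(flips, 1 - prof, prof)


def generate(cfg: SynthConfig | None = None) -> SyntheticDataset:
    """Draw one dataset; regenerates (up to 5 attempts) if A comes out empty."""
    cfg = cfg or SynthConfig()
    rng = np.random.default_rng(cfg.seed)
    mb = _block_labels(cfg.n_mirna, cfg.n_blocks)
    db = _block_labels(cfg.n_disease, cfg.n_blocks)
    mirna_ids = [f"mir-{i:03d}" for i in range(cfg.n_mirna)]
    disease_ids = [f"dis-{j:03d}" for j in range(cfg.n_disease)]

    for attempt in range(5):
        same = mb[:, None] == db[None, :]
        p = np.where(same, cfg.density, cfg.noise)
        A_vals = (rng.random((cfg.n_mirna, cfg.n_disease)) < p).astype(float)
        if A_vals.sum() > 0:
            break
        logger.warning("generated an all-zero association matrix; retrying (%d)", attempt + 1)
    else:
        raise RuntimeError("could not generate a non-empty association matrix in 5 attempts")

    A = AssociationMatrix(values=A_vals, mirna_ids=mirna_ids, disease_ids=disease_ids)
    FM = SimilarityMatrix(
        values=_block_similarity(mb, cfg.noise, rng), ids=mirna_ids, kind="functional"
    )
    m_lnc = _block_profiles(mb, cfg.n_lncrna, cfg.noise, rng)
    d_lnc = _block_profiles(db, cfg.n_lncrna, cfg.noise, rng)
    LM = lncrna_similarity(m_lnc, mirna_ids)
    LD = lncrna_similarity(d_lnc, disease_ids)

    # DAG: root -> per-block ancestor chain of length dag_depth-1 -> diseases
    nodes = ["root"]
    edges: list[tuple[str, str]] = []
    for b in range(cfg.n_blocks):
        chain_parent = "root"
        for depth in range(max(cfg.dag_depth - 1, 1)):
            anc = f"block-{b}-anc-{depth}"
            nodes.append(anc)
            edges.append((anc, chain_parent))
            chain_parent = anc
        for j in np.flatnonzero(db == b):
            nodes.append(disease_ids[j])
            edges.append((disease_ids[j], chain_parent))
    dag = DiseaseDAG(nodes=nodes, parent_edges=edges)

    return SyntheticDataset(
        A=A, FM=FM, LM=LM, LD=LD,
        mirna_lnc=m_lnc, disease_lnc=d_lnc, dag=dag,
        mirna_blocks=mb, disease_blocks=db, config=cfg,
    )


def hold_out(
    A: AssociationMatrix, fraction: float, seed: int = 0
) -> tuple[AssociationMatrix, list[tuple[int, int]]]:
    """Uniformly remove round(fraction * |P|) positives; return (A_train, hidden).

    Conservation: A_train plus the hidden positives reconstructs A exactly.
    """
    if not 0 < fraction < 1:
        raise ValueError("fraction must be in (0, 1)")
    pos = A.positives()
    n_remove = int(round(fraction * len(pos)))
    if n_remove >= len(pos):
        raise ValueError("removal would leave no positives")
    rng = np.random.default_rng(seed)
    hidden_idx = rng.choice(len(pos), size=n_remove, replace=False)
    hidden = [pos[k] for k in hidden_idx]
    vals = A.values.copy()
    for i, j in hidden:
        vals[i, j] = 0
    A_train = AssociationMatrix(
        values=vals, mirna_ids=A.mirna_ids, disease_ids=A.disease_ids
    )
    return A_train, hidden
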