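import numpy as np
import pytest

from mgcnss import (
    AssociationMatrix,
    SimilarityMatrix,
    SynthConfig,
    generate,
    semantic_similarity,
)
from mgcnss.train import SimilarityStack


def random_similarity(n: int, rng: np.random.Generator, ids=None) -> SimilarityMatrix:
    """A valid random similarity matrix (symmetric, unit diagonal, [0, 1])."""
    X = rng.random((n, n))
    S = np.clip((X + X.T) / 2, 0.0, 1.0)
    np.fill_diagonal(S, 1.0)
    return SimilarityMatrix(values=S, ids=ids or [f"x{i}" for i in range(n)])


def random_association(nm: int, nd: int, rng: np.random.Generator) -> AssociationMatrix:
    """A random binary association matrix guaranteed non-empty."""
    vals = (rng.random((nm, nd)) < 0.3).astype(float)
    if vals.sum() == 0:
        vals[0, 0] = 1.0
    return AssociationMatrix(
        values=vals,
        mirna_ids=[f"m{i}" for i in range(nm)],
        disease_ids=[f"d{j}" for j in range(nd)],
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_dataset():
    """A small planted-block dataset shared across tests (read-only)."""
    return generate(SynthConfig(n_mirna=30, n_disease=24, n_blocks=3, seed=7))


@pytest.fixture(scope="session")
def small_stack(small_dataset):
    ds = small_dataset
    FD = semantic_similarity(
        ds.dag, diseases=ds.A.disease_ids, total_diseases=ds.A.n_disease
    )
    return SimilarityStack(A=ds.A, FM=ds.FM, LM=ds.LM, FD=FD, LD=ds.LD)
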