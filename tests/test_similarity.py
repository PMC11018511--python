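import numpy as np
import pytest

from mgcnss import (
    AssociationMatrix,
    DiseaseDAG,
    SemanticParams,
    build_hetero_matrix,
    fuse_similarities,
    gip_kernel,
    lncrna_similarity,
    semantic_contribution,
    semantic_similarity,
)
from mgcnss.similarity import levenshtein, _batched_levenshtein

from conftest import random_association, random_similarity


def check_similarity_invariants(S):
    assert np.allclose(S.values, S.values.T, atol=1e-9)
    assert np.allclose(np.diag(S.values), 1.0)
    assert S.values.min() >= -1e-9 and S.values.max() <= 1 + 1e-9


class TestGipKernel:
    def test_hand_derived_two_by_two(self):
        """A = I2: bandwidth 1/((1+1)/2) = 1, off-diagonal exp(-2)."""
        A = AssociationMatrix(np.eye(2), ["m1", "m2"], ["d1", "d2"])
        GM = gip_kernel(A, "mirna")
        assert GM.values[0, 1] == pytest.approx(np.exp(-2), abs=1e-12)
        GD = gip_kernel(A, "disease")
        assert GD.values[0, 1] == pytest.approx(np.exp(-2), abs=1e-12)

    def test_identical_profiles_give_one(self):
        A = AssociationMatrix(
            np.array([[1.0, 0.0], [1.0, 0.0], [0.0, 1.0]]),
            ["m1", "m2", "m3"], ["d1", "d2"],
        )
        GM = gip_kernel(A, "mirna")
        assert GM.values[0, 1] == pytest.approx(1.0)

    def test_monotone_in_profile_distance(self, rng):
        """Larger squared profile distance never gives larger similarity."""
        for _ in range(10):
            A = random_association(8, 6, rng)
            GM = gip_kernel(A, "mirna")
            prof = A.values
            d2 = ((prof[:, None, :] - prof[None, :, :]) ** 2).sum(-1)
            iu = np.triu_indices(8, 1)
            order = np.argsort(d2[iu])
            sims = GM.values[iu][order]
            assert (np.diff(d2[iu][order]) >= 0).all()
            # similarity must be non-increasing along increasing distance
            assert all(
                s2 <= s1 + 1e-12
                for s1, s2, e1, e2 in zip(
                    sims, sims[1:], d2[iu][order], d2[iu][order][1:]
                )
                if e2 > e1
            )

    def test_invariants_fuzzed(self, rng):
        for _ in range(20):
            A = random_association(
                int(rng.integers(3, 12)), int(rng.integers(3, 12)), rng
            )
            check_similarity_invariants(gip_kernel(A, "mirna"))
            check_similarity_invariants(gip_kernel(A, "disease"))

    def test_all_zero_matrix_rejected(self):
        A = AssociationMatrix.__new__(AssociationMatrix)
        A.values = np.zeros((3, 3))
        A.mirna_ids = ["m1", "m2", "m3"]
        A.disease_ids = ["d1", "d2", "d3"]
        with pytest.raises(ValueError, match="bandwidth"):
            gip_kernel(A, "mirna")


class TestSemanticContribution:
    def test_self_contribution_is_one(self):
        dag = DiseaseDAG(["D", "p", "g"], [("D", "p"), ("p", "g")])
        for node in ("D", "p", "g"):
            assert semantic_contribution(dag, node)[node] == 1.0

    def test_chain_decay(self):
        """Chain D -> p -> g at delta 0.5: contributions 1, 0.5, 0.25."""
        dag = DiseaseDAG(["D", "p", "g"], [("D", "p"), ("p", "g")])
        c = semantic_contribution(dag, "D", "dm1", SemanticParams(0.5))
        assert c == {"D": 1.0, "p": 0.5, "g": 0.25}

    def test_diamond_takes_max_over_children(self):
        # D has parents p1, p2; both have parent g: g gets delta^2 via max
        dag = DiseaseDAG(
            ["D", "p1", "p2", "g"],
            [("D", "p1"), ("D", "p2"), ("p1", "g"), ("p2", "g")],
        )
        c = semantic_contribution(dag, "D", "dm1", SemanticParams(0.5))
        assert c["g"] == 0.25

    def test_dm2_ubiquitous_term_contributes_zero(self):
        """A term present in every disease DAG has -log(1) = 0 weight."""
        dag = DiseaseDAG(["root", "a", "b"], [("a", "root"), ("b", "root")])
        c = semantic_contribution(dag, "a", "dm2", universe=["root", "a", "b"])
        assert c["root"] == pytest.approx(0.0)
        assert c["a"] == pytest.approx(-np.log(1 / 3))

    def test_unknown_disease_raises(self):
        dag = DiseaseDAG(["a"], [])
        with pytest.raises(KeyError):
            semantic_contribution(dag, "zzz")


class TestSemanticSimilarity:
    def test_shared_parent_decay_component(self):
        """Two siblings under one parent: FD1 = (0.5+0.5)/(1.5+1.5) = 1/3."""
        dag = DiseaseDAG(["d1", "d2", "a"], [("d1", "a"), ("d2", "a")])
        FD1 = semantic_similarity(dag, diseases=["d1", "d2"], scheme="dm1")
        assert FD1.values[0, 1] == pytest.approx(1 / 3, abs=1e-12)

    def test_self_similarity_one(self, small_dataset):
        ds = small_dataset
        FD = semantic_similarity(ds.dag, diseases=ds.A.disease_ids)
        assert np.allclose(np.diag(FD.values), 1.0)
        check_similarity_invariants(FD)

    def test_disjoint_components_zero(self):
        dag = DiseaseDAG(["a", "b", "c", "d"], [("a", "b"), ("c", "d")])
        FD1 = semantic_similarity(dag, diseases=["a", "c"], scheme="dm1")
        assert FD1.values[0, 1] == 0.0

    def test_unrelated_disease_leaves_fd1_unchanged(self):
        """FD1(d1, d2) is local: an extra disjoint disease cannot change it."""
        dag1 = DiseaseDAG(["d1", "d2", "a"], [("d1", "a"), ("d2", "a")])
        dag2 = DiseaseDAG(
            ["d1", "d2", "a", "z"], [("d1", "a"), ("d2", "a")]
        )
        v1 = semantic_similarity(dag1, diseases=["d1", "d2"], scheme="dm1").values[0, 1]
        v2 = semantic_similarity(dag2, diseases=["d1", "d2", "z"], scheme="dm1").values[0, 1]
        assert v1 == pytest.approx(v2)


class TestLncrnaSimilarity:
    def test_identical_profiles(self):
        prof = np.array([[1, 0, 1], [1, 0, 1]])
        S = lncrna_similarity(prof, ["a", "b"])
        assert S.values[0, 1] == pytest.approx(1.0)

    def test_spec_example_distance_two_over_three(self):
        """'100' vs '010': edit distance 2, similarity 1 - 2/3."""
        S = lncrna_similarity(np.array([[1, 0, 0], [0, 1, 0]]), ["a", "b"])
        assert S.values[0, 1] == pytest.approx(1 / 3, abs=1e-12)

    def test_batched_matches_reference_dp(self, rng):
        """Vectorized DP equals the classic O(L^2) Levenshtein on random pairs."""
        for _ in range(30):
            L = int(rng.integers(1, 15))
            a = rng.integers(0, 2, L)
            b = rng.integers(0, 2, L)
            batched = _batched_levenshtein(a[None, :], b[None, :])[0]
            assert batched == levenshtein(a, b)
            assert levenshtein(a, b) == levenshtein(b, a)

    def test_invariants(self, rng):
        prof = rng.integers(0, 2, (8, 12))
        check_similarity_invariants(lncrna_similarity(prof, [f"e{i}" for i in range(8)]))

    def test_rejects_non_binary(self):
        with pytest.raises(Exception):
            lncrna_similarity(np.array([[0.5, 1]]), ["a"])


class TestFuseSimilarities:
    def test_one_hot_returns_first_source(self, rng):
        FM, GM, LM = (random_similarity(5, rng) for _ in range(3))
        out = fuse_similarities(FM, GM, LM, [1, 0, 0])
        np.testing.assert_allclose(out.values, FM.values)

    def test_equal_matrices_fixed_point(self, rng):
        S = random_similarity(5, rng)
        out = fuse_similarities(S, S, S, [1 / 3, 1 / 3, 1 / 3])
        np.testing.assert_allclose(out.values, S.values, atol=1e-12)

    def test_linearity_in_weights(self, rng):
        FM, GM, LM = (random_similarity(6, rng) for _ in range(3))
        w = np.array([0.5, 0.3, 0.2])
        out = fuse_similarities(FM, GM, LM, w)
        manual = w[0] * FM.values + w[1] * GM.values + w[2] * LM.values
        np.testing.assert_allclose(out.values, manual, atol=1e-12)

    def test_missing_source_renormalizes(self, rng):
        FM, GM = random_similarity(5, rng), random_similarity(5, rng)
        out = fuse_similarities(FM, GM, None, [0.6, 0.2, 0.2])
        manual = (0.6 * FM.values + 0.2 * GM.values) / 0.8
        np.testing.assert_allclose(out.values, np.clip(manual, 0, 1), atol=1e-12)

    def test_id_mismatch_rejected(self, rng):
        FM = random_similarity(4, rng)
        GM = random_similarity(4, rng, ids=["q0", "q1", "q2", "q3"])
        with pytest.raises(Exception, match="identifier"):
            fuse_similarities(FM, GM, None, [0.5, 0.5, 0.0])


class TestHeteroMatrix:
    def test_minimal_blocks(self):
        A = AssociationMatrix(np.ones((2, 2)), ["m1", "m2"], ["d1", "d2"])
        IM = random_similarity(2, np.random.default_rng(0), ids=["m1", "m2"])
        ID = random_similarity(2, np.random.default_rng(1), ids=["d1", "d2"])
        M = build_hetero_matrix(IM, ID, A)
        np.testing.assert_array_equal(M.assoc_block, A.values)
        np.testing.assert_array_equal(M.mirna_block, IM.values)
        np.testing.assert_array_equal(M.disease_block, ID.values)

    def test_symmetry_random_inputs(self, rng):
        for _ in range(20):
            nm, nd = int(rng.integers(2, 8)), int(rng.integers(2, 8))
            A = random_association(nm, nd, rng)
            M = build_hetero_matrix(
                random_similarity(nm, rng), random_similarity(nd, rng), A
            )
            np.testing.assert_allclose(M.values, M.values.T, atol=1e-12)

    def test_shape_mismatch_rejected(self, rng):
        A = random_association(3, 4, rng)
        with pytest.raises(Exception, match="conform"):
            build_hetero_matrix(
                random_similarity(2, rng), random_similarity(4, rng), A
            )
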