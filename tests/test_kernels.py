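import math

import numpy as np
import pytest

from circda.containers import (
    DiseaseDAG,
    EntityIndex,
    GeneAssociationMatrix,
    SimilarityMatrix,
)
from circda.kernels import (
    fuse_circrna_similarity,
    fuse_disease_similarity,
    gene_based_similarity,
    gip_kernel_matrix,
    gip_width,
    semantic_contribution,
    semantic_similarity_matrix,
)


def make_dag(ancestors):
    closure = {k: frozenset(v) for k, v in ancestors.items()}
    nodes = frozenset().union(*closure.values()) if closure else frozenset()
    return DiseaseDAG(ancestors=closure, nodes=nodes)


class TestSemanticContribution:
    def setup_method(self):
        # root a; children b, c; disease d has no DAG
        self.dag = make_dag({"a": {"a"}, "b": {"a", "b"}, "c": {"a", "c"}})
        self.diseases = ("a", "b", "c", "d")

    def test_node_in_every_dag_contributes_ln2(self):
        assert semantic_contribution("a", self.dag, self.diseases) == pytest.approx(
            math.log(2)
        )

    def test_direct_ratio_evaluation(self):
        # b appears in 1 of 3 DAGs -> ln(1 + 1/3)
        assert semantic_contribution("b", self.dag, self.diseases) == pytest.approx(
            math.log(1 + 1 / 3)
        )

    def test_universe_all_counts_every_disease(self):
        assert semantic_contribution(
            "b", self.dag, self.diseases, universe="all"
        ) == pytest.approx(math.log(1 + 1 / 4))

    def test_unknown_node_rejected(self):
        with pytest.raises(KeyError):
            semantic_contribution("zzz", self.dag, self.diseases)


class TestSemanticSimilarity:
    def test_three_disease_tree_matches_hand_computation(self):
        dag = make_dag({"a": {"a"}, "b": {"a", "b"}, "c": {"a", "c"}})
        index = EntityIndex(("c0",), ("a", "b", "c"))
        sim, has_dag = semantic_similarity_matrix(dag, index)
        s_a = math.log(2)          # a in all 3 closures
        s_b = math.log(1 + 1 / 3)  # b only in its own
        s_c = math.log(1 + 1 / 3)
        expected_bc = 2 * s_a / ((s_a + s_b) + (s_a + s_c))
        assert sim.values[1, 2] == pytest.approx(expected_bc)
        np.testing.assert_allclose(np.diag(sim.values), 1.0)
        assert has_dag.all()

    def test_disjoint_closures_score_zero(self):
        dag = make_dag({"a": {"a"}, "b": {"b"}})
        index = EntityIndex(("c0",), ("a", "b"))
        sim, _ = semantic_similarity_matrix(dag, index)
        assert sim.values[0, 1] == 0.0

    def test_missing_dag_flagged(self):
        dag = make_dag({"a": {"a"}})
        index = EntityIndex(("c0",), ("a", "b"))
        sim, has_dag = semantic_similarity_matrix(dag, index)
        assert list(has_dag) == [True, False]
        assert sim.missing[0, 1] and sim.missing[1, 1]

    def test_values_within_unit_interval(self):
        dag = make_dag(
            {"a": {"a"}, "b": {"a", "b"}, "c": {"a", "b", "c"}, "e": {"a", "e"}}
        )
        index = EntityIndex(("c0",), ("a", "b", "c", "e"))
        sim, _ = semantic_similarity_matrix(dag, index)
        assert (sim.values >= 0).all() and (sim.values <= 1 + 1e-12).all()


class TestGipKernel:
    def test_identity_profiles_width_one(self):
        assert gip_width(np.eye(2)) == pytest.approx(1.0)

    def test_all_zero_profiles_fall_back_to_one(self):
        assert gip_width(np.zeros((3, 4))) == 1.0

    def test_scaling_law_doubled_profiles_quarter_the_width(self):
        profiles = np.array([[1, 0, 0, 0], [0, 0, 1, 0]], dtype=float)
        assert gip_width(2 * profiles) == pytest.approx(gip_width(profiles) / 4)

    def test_identity_profiles_offdiagonal_exp_minus_two(self):
        kernel = gip_kernel_matrix(np.eye(2), tau=1.0)
        assert kernel[0, 1] == pytest.approx(math.exp(-2))
        np.testing.assert_allclose(np.diag(kernel), 1.0)

    def test_matches_elementwise_bruteforce(self):
        rng = np.random.default_rng(2)
        profiles = rng.integers(0, 2, size=(4, 6)).astype(float)
        tau = gip_width(profiles)
        kernel = gip_kernel_matrix(profiles, tau)
        for i in range(4):
            for j in range(4):
                expected = math.exp(-tau * np.sum((profiles[i] - profiles[j]) ** 2))
                assert kernel[i, j] == pytest.approx(expected)

    def test_monotone_in_shared_associations(self):
        # adding a shared 1 to both profiles never decreases the kernel value
        p = np.array([[1, 0, 0, 0], [0, 1, 0, 0]], dtype=float)
        q = p.copy()
        q[:, 3] = 1  # shared new association
        tau = 0.5
        assert gip_kernel_matrix(q, tau)[0, 1] >= gip_kernel_matrix(p, tau)[0, 1]

    def test_entries_in_unit_interval(self):
        rng = np.random.default_rng(4)
        kernel = gip_kernel_matrix(rng.integers(0, 2, size=(6, 5)).astype(float))
        assert (kernel > 0).all() and (kernel <= 1).all()
        np.testing.assert_allclose(kernel, kernel.T)

    def test_dimension_mismatch_rejected(self):
        with pytest.raises(ValueError):
            gip_kernel_matrix(np.array([1.0, 2.0]))


class TestGeneSimilarity:
    def test_all_zero_map_gives_zero_matrix(self):
        acg = GeneAssociationMatrix(np.zeros((3, 2), dtype=int), ("a", "b", "c"), ("g1", "g2"))
        sim = gene_based_similarity(acg)
        assert not sim.values.any()

    def test_identical_gene_profiles_score_one(self):
        acg = GeneAssociationMatrix(
            np.array([[1, 0], [1, 0], [0, 1]]), ("a", "b", "c"), ("g1", "g2")
        )
        sim = gene_based_similarity(acg)
        assert sim.values[0, 1] == pytest.approx(1.0)
        assert sim.values[0, 0] == 1.0

    def test_raw_mode_matches_bruteforce_triple_product(self):
        rng = np.random.default_rng(1)
        values = rng.integers(0, 2, size=(3, 2))
        acg = GeneAssociationMatrix(values, ("a", "b", "c"), ("g1", "g2"))
        sim = gene_based_similarity(acg, mode="raw")
        gene_kernel = gip_kernel_matrix(values.T.astype(float))
        expected = values @ gene_kernel @ values.T
        np.testing.assert_allclose(sim.values, expected, atol=1e-12)


class TestFusion:
    def make(self, values, labels=("x", "y"), missing=None):
        return SimilarityMatrix(values=np.array(values, dtype=float),
                                labels=labels, missing=missing)

    def test_disease_mean_where_both_have_dag(self):
        sem = self.make([[1.0, 0.6], [0.6, 1.0]])
        gip = self.make([[1.0, 0.4], [0.4, 1.0]])
        fused = fuse_disease_similarity(sem, gip, np.array([True, True]))
        assert fused.values[0, 1] == pytest.approx(0.5)
        np.testing.assert_allclose(np.diag(fused.values), 1.0)

    def test_disease_falls_back_to_gip_without_dag(self):
        sem = self.make([[1.0, 0.6], [0.6, 1.0]])
        gip = self.make([[1.0, 0.4], [0.4, 1.0]])
        fused = fuse_disease_similarity(sem, gip, np.array([True, False]))
        assert fused.values[0, 1] == pytest.approx(0.4)

    def test_label_mismatch_rejected(self):
        sem = self.make([[1.0, 0.0], [0.0, 1.0]])
        gip = self.make([[1.0, 0.0], [0.0, 1.0]], labels=("p", "q"))
        with pytest.raises(ValueError, match="labels"):
            fuse_disease_similarity(sem, gip, np.array([True, True]))

    def test_circrna_three_way_mean_when_sequence_available(self):
        gene = self.make([[1.0, 0.3], [0.3, 1.0]])
        gip = self.make([[1.0, 0.6], [0.6, 1.0]])
        seq = self.make([[1.0, 0.9], [0.9, 1.0]],
                        missing=np.zeros((2, 2), dtype=bool))
        fused = fuse_circrna_similarity(gene, gip, seq)
        assert fused.values[0, 1] == pytest.approx(0.6)

    def test_circrna_two_way_mean_when_sequence_missing(self):
        gene = self.make([[1.0, 0.4], [0.4, 1.0]])
        gip = self.make([[1.0, 0.8], [0.8, 1.0]])
        missing = np.array([[False, True], [True, True]])
        seq = self.make([[1.0, 0.0], [0.0, 0.0]], missing=missing)
        fused = fuse_circrna_similarity(gene, gip, seq)
        assert fused.values[0, 1] == pytest.approx(0.6)

    def test_zero_sentinel_mode_treats_true_zero_as_missing(self):
        gene = self.make([[1.0, 0.4], [0.4, 1.0]])
        gip = self.make([[1.0, 0.8], [0.8, 1.0]])
        seq = self.make([[1.0, 0.0], [0.0, 1.0]],
                        missing=np.zeros((2, 2), dtype=bool))
        masked = fuse_circrna_similarity(gene, gip, seq, mode="mask")
        sentinel = fuse_circrna_similarity(gene, gip, seq, mode="zero_sentinel")
        assert masked.values[0, 1] == pytest.approx((0.4 + 0.8 + 0.0) / 3)
        assert sentinel.values[0, 1] == pytest.approx((0.4 + 0.8) / 2)

    def test_all_ones_fuse_to_one(self):
        ones = self.make([[1.0, 1.0], [1.0, 1.0]])
        seq = self.make([[1.0, 1.0], [1.0, 1.0]],
                        missing=np.zeros((2, 2), dtype=bool))
        fused = fuse_circrna_similarity(ones, ones, seq)
        np.testing.assert_allclose(fused.values, 1.0)
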