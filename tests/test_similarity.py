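"""Semantic similarity models, GIP kernels and integration against hand-computed
values and independent brute-force oracles."""

import math

import numpy as np
import pytest

from drmda.io import AssociationMatrix, SimilarityMatrix
from drmda.similarity import (
    disease_semantic_matrix,
    gip_kernel,
    integrated_similarity,
    semantic_contributions_m1,
    semantic_similarity_m1,
    semantic_similarity_m2,
    semantic_value_m2,
    specificity_contributions_m2,
)

from .conftest import make_dag, oracle_contributions_m1, oracle_ss1, oracle_ss2, random_dag


class TestModel1:
    @pytest.mark.parametrize("delta", [0.1, 0.5, 1.0])
    def test_target_only_dag(self, delta):
        table = semantic_contributions_m1(make_dag("D", []), delta)
        assert table.contributions == {"D": 1.0}
        assert table.semantic_value == 1.0

    def test_single_parent_chain(self, chain_dag):
        table = semantic_contributions_m1(chain_dag, 0.5)
        assert table.contributions["p"] == 0.5
        assert table.semantic_value == 1.5

    def test_diamond_takes_best_path(self, diamond_dag):
        # g reaches D directly (0.5) and through p (0.25): max wins
        table = semantic_contributions_m1(diamond_dag, 0.5)
        assert table.contributions["g"] == 0.5
        assert table.semantic_value == 2.0

    def test_delta_out_of_range(self, chain_dag):
        with pytest.raises(ValueError):
            semantic_contributions_m1(chain_dag, 0.0)
        with pytest.raises(ValueError):
            semantic_contributions_m1(chain_dag, 1.5)

    def test_identical_dags_similarity_one(self, diamond_dag):
        table = semantic_contributions_m1(diamond_dag, 0.5)
        assert semantic_similarity_m1(table, table) == pytest.approx(1.0)

    def test_disjoint_dags_similarity_zero(self):
        ta = semantic_contributions_m1(make_dag("a", [("x", "a")]), 0.5)
        tb = semantic_contributions_m1(make_dag("b", [("y", "b")]), 0.5)
        assert semantic_similarity_m1(ta, tb) == 0.0

    def test_shared_parent_gives_one_third(self, shared_parent_trio):
        t1 = semantic_contributions_m1(shared_parent_trio["d1"], 0.5)
        t2 = semantic_contributions_m1(shared_parent_trio["d2"], 0.5)
        assert semantic_similarity_m1(t1, t2) == pytest.approx(1.0 / 3.0, abs=1e-12)

    def test_mismatched_delta_rejected(self, chain_dag):
        ta = semantic_contributions_m1(chain_dag, 0.5)
        tb = semantic_contributions_m1(chain_dag, 0.4)
        with pytest.raises(ValueError):
            semantic_similarity_m1(ta, tb)


class TestModel2:
    def test_specificity_values(self, shared_parent_trio):
        spec = specificity_contributions_m2(shared_parent_trio)
        assert spec["p"] == pytest.approx(-math.log(2 / 3), abs=1e-12)  # ~0.4055
        assert spec["d1"] == pytest.approx(-math.log(1 / 3), abs=1e-12)  # ~1.0986

    def test_universal_term_contributes_zero(self):
        dags = {d: make_dag(d, [("root", d)]) for d in ("a", "b", "c")}
        spec = specificity_contributions_m2(dags)
        assert spec["root"] == 0.0

    def test_shared_parent_value(self, shared_parent_trio):
        spec = specificity_contributions_m2(shared_parent_trio)
        got = semantic_similarity_m2(shared_parent_trio["d1"], shared_parent_trio["d2"], spec)
        expected = (2 * -math.log(2 / 3)) / (2 * (-math.log(2 / 3) - math.log(1 / 3)))
        assert got == pytest.approx(expected, abs=1e-12)
        assert got == pytest.approx(0.2696, abs=1e-4)

    def test_identical_dags_similarity_one(self, shared_parent_trio):
        dags = dict(shared_parent_trio)
        spec = specificity_contributions_m2(dags)
        assert semantic_similarity_m2(dags["d1"], dags["d1"], spec) == pytest.approx(1.0)

    def test_empty_intersection_zero(self, shared_parent_trio):
        spec = specificity_contributions_m2(shared_parent_trio)
        assert semantic_similarity_m2(shared_parent_trio["d1"], shared_parent_trio["d3"], spec) == 0.0

    def test_all_universal_terms_warn_and_zero(self):
        # every term carries zero specificity, so both semantic values vanish
        deg = {"a": make_dag("a", []), "b": make_dag("b", [])}
        spec = {"a": 0.0, "b": 0.0}
        with pytest.warns(UserWarning, match="universal"):
            assert semantic_similarity_m2(deg["a"], deg["b"], spec) == 0.0

    def test_missing_term_rejected(self, shared_parent_trio):
        with pytest.raises(ValueError, match="missing"):
            semantic_value_m2(shared_parent_trio["d1"], {"d1": 1.0})


class TestSemanticMatrix:
    def test_average_of_both_models(self, shared_parent_trio):
        ss = disease_semantic_matrix(shared_parent_trio, 0.5)
        i, j = ss.index("d1"), ss.index("d2")
        assert ss.values[i, j] == pytest.approx(0.3014, abs=1e-4)
        assert np.all(np.diag(ss.values) == 1.0)

    def test_disjoint_pair_zero(self, shared_parent_trio):
        ss = disease_semantic_matrix(shared_parent_trio, 0.5)
        assert ss.values[ss.index("d1"), ss.index("d3")] == 0.0

    def test_oracle_agreement_on_random_dags(self):
        rng = np.random.default_rng(42)
        pool = [f"t{k}" for k in range(12)]
        dags = {f"D{i}": random_dag(rng, f"D{i}", pool) for i in range(8)}
        spec = specificity_contributions_m2(dags)
        names = sorted(dags)
        for a in names:
            for b in names:
                ta = semantic_contributions_m1(dags[a], 0.5)
                tb = semantic_contributions_m1(dags[b], 0.5)
                assert semantic_similarity_m1(ta, tb) == pytest.approx(
                    oracle_ss1(dags[a], dags[b], 0.5), abs=1e-12
                )
                assert semantic_similarity_m2(dags[a], dags[b], spec) == pytest.approx(
                    oracle_ss2(dags, a, b), abs=1e-12
                )

    def test_adding_shared_ancestor_never_decreases_ss1(self):
        rng = np.random.default_rng(7)
        pool = [f"t{k}" for k in range(10)]
        for trial in range(25):
            da = random_dag(rng, "Da", pool)
            db = random_dag(rng, "Db", pool)
            before = oracle_ss1(da, db, 0.5)
            da2 = make_dag("Da", sorted(da.edges) + [("NEW", "Da")])
            db2 = make_dag("Db", sorted(db.edges) + [("NEW", "Db")])
            after = semantic_similarity_m1(
                semantic_contributions_m1(da2, 0.5), semantic_contributions_m1(db2, 0.5)
            )
            assert after >= before - 1e-12


class TestGipKernel:
    def test_orthogonal_unit_profiles(self):
        assoc = AssociationMatrix(("dA", "dB"), ("m1", "m2", "m3"), np.array([[1, 0, 0], [0, 1, 0]]))
        kernel, bw = gip_kernel(assoc, "diseases", 1.0)
        assert bw.alpha == pytest.approx(1.0)
        assert kernel.values[0, 1] == pytest.approx(math.exp(-2), abs=1e-12)

    def test_unit_diagonal_and_identical_profiles(self):
        assoc = AssociationMatrix(("dA", "dB"), ("m1", "m2"), np.array([[1, 0], [1, 0]]))
        kernel, _ = gip_kernel(assoc, "diseases", 1.0)
        assert np.all(np.diag(kernel.values) == 1.0)
        assert kernel.values[0, 1] == pytest.approx(1.0)

    def test_permutation_equivariance(self):
        rng = np.random.default_rng(3)
        values = (rng.random((6, 9)) < 0.4).astype(float)
        values[0, 0] = 1  # guarantee non-empty
        labels_d = tuple(f"d{i}" for i in range(6))
        labels_m = tuple(f"m{j}" for j in range(9))
        assoc = AssociationMatrix(labels_d, labels_m, values)
        kernel, _ = gip_kernel(assoc, "diseases", 1.0)
        perm = rng.permutation(6)
        assoc_p = AssociationMatrix(tuple(labels_d[i] for i in perm), labels_m, values[perm])
        kernel_p, _ = gip_kernel(assoc_p, "diseases", 1.0)
        np.testing.assert_allclose(kernel_p.values, kernel.values[np.ix_(perm, perm)], atol=1e-14)

    def test_mirna_axis_uses_columns(self):
        assoc = AssociationMatrix(("dA", "dB"), ("m1", "m2"), np.array([[1, 0], [0, 1]]))
        kernel, bw = gip_kernel(assoc, "mirnas", 1.0)
        assert kernel.labels == ("m1", "m2")
        assert kernel.values[0, 1] == pytest.approx(math.exp(-2.0), abs=1e-12)

    def test_all_zero_matrix_rejected(self):
        with pytest.raises(ValueError, match="bandwidth"):
            gip_kernel(
                AssociationMatrix(("a", "b"), ("x", "y"), np.zeros((2, 2))), "diseases", 1.0
            )


class TestIntegratedSimilarity:
    def _mats(self):
        kernel = SimilarityMatrix(("a", "b", "c"), np.array([[1.0, 0.9, 0.8], [0.9, 1.0, 0.7], [0.8, 0.7, 1.0]]))
        semantic = SimilarityMatrix(("a", "b"), np.array([[1.0, 0.3], [0.3, 1.0]]))
        return semantic, kernel

    def test_semantic_where_both_covered(self):
        semantic, kernel = self._mats()
        sd = integrated_similarity(semantic, kernel)
        assert sd.values[0, 1] == 0.3

    def test_kernel_where_one_uncovered(self):
        semantic, kernel = self._mats()
        sd = integrated_similarity(semantic, kernel)
        assert sd.values[0, 2] == 0.8
        assert sd.values[1, 2] == 0.7

    def test_full_coverage_returns_semantic_exactly(self):
        semantic, _ = self._mats()
        kernel = SimilarityMatrix(("a", "b"), np.array([[1.0, 0.95], [0.95, 1.0]]))
        sd = integrated_similarity(semantic, kernel)
        np.testing.assert_array_equal(sd.values, semantic.values)

    def test_positive_mode_falls_back_on_zero_entries(self):
        kernel = SimilarityMatrix(("a", "b"), np.array([[1.0, 0.95], [0.95, 1.0]]))
        semantic = SimilarityMatrix(("a", "b"), np.array([[1.0, 0.0], [0.0, 1.0]]))
        sd = integrated_similarity(semantic, kernel, mode="positive")
        assert sd.values[0, 1] == 0.95

    def test_label_mismatch_rejected(self):
        semantic = SimilarityMatrix(("a", "zz"), np.eye(2))
        kernel = SimilarityMatrix(("a", "b"), np.eye(2))
        with pytest.raises(ValueError, match="label mismatch"):
            integrated_similarity(semantic, kernel)

    def test_none_semantic_returns_kernel(self):
        _, kernel = self._mats()
        sd = integrated_similarity(None, kernel)
        np.testing.assert_array_equal(sd.values, kernel.values)
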