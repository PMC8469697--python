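"""Bias-matrix assembly, PCA and Ward clustering of ligand profiles."""

import math

import numpy as np
import pandas as pd
import pytest

from biasquant import BiasMatrix, build_bias_matrix, cluster_pca, linkage_to_newick, run_pca


def _table(values: dict[str, list[float]], pairs, displays=None) -> pd.DataFrame:
    rows = []
    for lig, vec in values.items():
        for (r1, r2), v in zip(pairs, vec):
            disp = "significant" if displays is None else displays.get(lig, "significant")
            rows.append(dict(cell_model="WT", ligand=lig, response1=r1, response2=r2,
                             ddlogbf=v, display=disp))
    return pd.DataFrame(rows)


PAIRS = [("A", "B"), ("A", "C"), ("B", "C")]


class TestBuildBiasMatrix:
    def test_reference_row_is_identically_zero(self):
        bm = build_bias_matrix(_table({"L1": [1, 2, 3]}, PAIRS), "WT", reference="FSH")
        assert bm.ligands[0] == "FSH"
        np.testing.assert_array_equal(bm.values[0], 0.0)

    def test_shape_matches_ligands_by_pairs(self):
        vals = {f"L{i}": [0.1 * i, 0.2 * i, 0.3 * i] for i in range(1, 5)}
        bm = build_bias_matrix(_table(vals, PAIRS), "WT")
        assert bm.values.shape == (5, 3)  # 4 test ligands + reference row

    def test_all_nd_ligand_imputes_to_reference_row(self):
        with pytest.warns(UserWarning, match="no determined bias"):
            bm = build_bias_matrix(
                _table({"L1": [1, 2, 3], "ND": [math.nan] * 3}, PAIRS,
                       displays={"ND": "nd"}), "WT")
        i_nd = bm.ligands.index("ND")
        np.testing.assert_array_equal(bm.values[i_nd], bm.values[0])
        assert bm.mask[i_nd].all()

    def test_drop_policy_removes_incomplete_ligands(self):
        with pytest.warns(UserWarning):
            bm = build_bias_matrix(
                _table({"L1": [1, 2, 3], "ND": [math.nan] * 3}, PAIRS,
                       displays={"ND": "nd"}), "WT", impute="drop")
        assert "ND" not in bm.ligands

    def test_unknown_policy_rejected(self):
        with pytest.raises(ValueError, match="imputation policy"):
            build_bias_matrix(_table({"L1": [1, 2, 3]}, PAIRS), "WT", impute="magic")

    def test_missing_cell_model_rejected(self):
        with pytest.raises(ValueError, match="no rows"):
            build_bias_matrix(_table({"L1": [1, 2, 3]}, PAIRS), "KO")


class TestRunPca:
    def test_identical_rows_get_identical_scores(self):
        bm = build_bias_matrix(_table({"L1": [1, 2, 3], "L2": [1, 2, 3],
                                       "L3": [0, 1, 0]}, PAIRS), "WT")
        p = run_pca(bm)
        i, j = p.ligands.index("L1"), p.ligands.index("L2")
        np.testing.assert_allclose(p.scores[i], p.scores[j], atol=1e-12)

    def test_variance_fractions_sum_to_one(self):
        bm = build_bias_matrix(_table({"L1": [1, 2, 3], "L2": [3, 1, 2],
                                       "L3": [0, 1, 0]}, PAIRS), "WT")
        assert run_pca(bm).explained_variance_ratio.sum() == pytest.approx(1.0, abs=1e-12)

    def test_collinear_rows_put_all_variance_on_pc1(self):
        m = BiasMatrix("WT", ["a", "b", "c"], [("A", "B"), ("A", "C")],
                       np.array([[0.0, 0.0], [1.0, 1.0], [2.0, 2.0]]),
                       np.zeros((3, 2), dtype=bool), "a")
        p = run_pca(m)
        assert p.explained_variance_ratio[0] == pytest.approx(1.0, abs=1e-12)

    def test_zero_column_leaves_scores_unchanged(self):
        vals = np.array([[0.0, 1.0], [2.0, -1.0], [1.0, 3.0]])
        m1 = BiasMatrix("WT", list("abc"), [("A", "B"), ("A", "C")], vals,
                        np.zeros((3, 2), bool), "a")
        with_zero = np.hstack([vals, np.zeros((3, 1))])
        m2 = BiasMatrix("WT", list("abc"), [("A", "B"), ("A", "C"), ("B", "C")],
                        with_zero, np.zeros((3, 3), bool), "a")
        np.testing.assert_allclose(run_pca(m1).scores, run_pca(m2).scores[:, :2], atol=1e-12)

    def test_row_permutation_permutes_scores(self):
        vals = np.array([[0.0, 0.0], [1.0, -2.0], [3.0, 1.0], [2.0, 2.0]])
        m = BiasMatrix("WT", list("abcd"), [("A", "B"), ("A", "C")], vals,
                       np.zeros((4, 2), bool), "a")
        perm = [2, 0, 3, 1]
        mp = BiasMatrix("WT", [m.ligands[i] for i in perm], m.pairs, vals[perm],
                        np.zeros((4, 2), bool), "a")
        np.testing.assert_allclose(run_pca(mp).scores, run_pca(m).scores[perm], atol=1e-10)

    def test_rank_zero_matrix_degenerates_gracefully(self):
        m = BiasMatrix("WT", list("abc"), [("A", "B"), ("A", "C")],
                       np.ones((3, 2)), np.zeros((3, 2), bool), "a")
        p = run_pca(m)
        assert p.degenerate
        np.testing.assert_array_equal(p.scores, 0.0)

    def test_too_small_matrix_rejected(self):
        m = BiasMatrix("WT", ["a", "b"], [("A", "B"), ("A", "C")],
                       np.ones((2, 2)), np.zeros((2, 2), bool), "a")
        with pytest.raises(ValueError, match="at least 3"):
            run_pca(m)


class TestClusterPca:
    @staticmethod
    def _pca(values):
        n = len(values)
        m = BiasMatrix("WT", [f"L{i}" for i in range(n)],
                       [("A", "B"), ("A", "C"), ("B", "C")],
                       np.asarray(values, float), np.zeros((n, 3), bool), "L0")
        return run_pca(m)

    def test_k_equals_n_gives_singletons(self):
        p = self._pca([[0, 0, 0], [1, 0, 1], [2, 2, 0], [0, 3, 1]])
        labels, _, _ = cluster_pca(p, k=4)
        assert len(set(labels)) == 4

    def test_identical_rows_always_co_cluster(self):
        p = self._pca([[0, 0, 0], [1.5, 0, 1], [1.5, 0, 1], [4, 4, 4]])
        for k in (2, 3):
            labels, _, _ = cluster_pca(p, k=k)
            assert labels[1] == labels[2]

    def test_planted_groups_recovered_exactly(self):
        from biasquant.validation import multivariate_sanity

        res = multivariate_sanity(seed=2)
        assert res["planted_group_ari"] == 1.0
        assert res["identical_rows_identical_scores"] == 1.0
        assert res["identical_rows_co_cluster"] == 1.0

    def test_ward_merge_heights_non_decreasing(self):
        p = self._pca([[0, 0, 0], [1, 0, 1], [2, 2, 0], [0, 3, 1], [5, 5, 5]])
        _, Z, _ = cluster_pca(p, k=2)
        heights = Z[:, 2]
        assert np.all(np.diff(heights) >= -1e-12)

    def test_k_larger_than_n_rejected(self):
        p = self._pca([[0, 0, 0], [1, 0, 1], [2, 2, 0]])
        with pytest.raises(ValueError, match="exceeds"):
            cluster_pca(p, k=5)

    def test_newick_output_parses(self):
        import dendropy

        p = self._pca([[0, 0, 0], [1, 0, 1], [2, 2, 0], [0, 3, 1]])
        _, _, newick = cluster_pca(p, k=2)
        tree = dendropy.Tree.get(data=newick, schema="newick")
        taxa = {leaf.taxon.label for leaf in tree.leaf_node_iter()}
        assert taxa == {"L0", "L1", "L2", "L3"}

    def test_label_renumbering_is_permutation_stable(self):
        vals = [[0, 0, 0], [0.1, 0, 0], [5, 5, 5], [5.1, 5, 5]]
        p1 = self._pca(vals)
        p2 = self._pca(vals[::-1])
        l1, _, _ = cluster_pca(p1, k=2)
        l2, _, _ = cluster_pca(p2, k=2)
        assert (l1 == l1[::-1][::-1]).all()
        # same partition after reversing the row order
        assert [l2[3 - i] == l2[3 - j] for i in range(4) for j in range(4)] == \
               [l1[i] == l1[j] for i in range(4) for j in range(4)]


def test_linkage_to_newick_round_trips_leaf_names():
    from scipy.cluster import hierarchy

    X = np.array([[0.0, 0.0], [0.1, 0.0], [4.0, 4.0]])
    Z = hierarchy.linkage(X, method="ward")
    nwk = linkage_to_newick(Z, ["x", "y", "z"])
    assert nwk.endswith(";") and all(n in nwk for n in ("x", "y", "z"))
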