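"""Ordination and clustering: IBS distances, PCA, classical MDS, UPGMA."""

import itertools

import numpy as np
import pandas as pd
import pytest

from clonalpop import (MISSING, GroupSpec, SimulationConfig, classical_mds,
                       genotype_pca, ibs_distance, simulate_cohort, trait_pca,
                       upgma_tree)

from conftest import make_matrix


class TestIBSDistance:
    def test_hand_examples(self):
        m = make_matrix([[0, 0, 0], [0, 0, 0], [2, 2, 2], [0, 1, 2]])
        D = ibs_distance(m)
        assert D.loc["s1", "s2"] == 0.0
        assert D.loc["s1", "s3"] == 1.0
        m2 = make_matrix([[0, 1, 2], [1, 1, 0]])
        # per-site shares: 0.5, 1, 0 -> distance 1 - 0.5 = 0.5
        assert ibs_distance(m2).loc["s1", "s2"] == pytest.approx(0.5)

    def test_missing_sites_excluded(self):
        m = make_matrix([[0, 1, MISSING], [0, MISSING, 2]])
        assert ibs_distance(m).loc["s1", "s2"] == 0.0  # only site 1 shared

    def test_no_shared_sites_flagged_nan(self):
        m = make_matrix([[0, MISSING], [MISSING, 2]])
        assert np.isnan(ibs_distance(m).loc["s1", "s2"])

    def test_triangle_inequality_on_complete_data(self):
        rng = np.random.default_rng(2)
        calls = rng.choice([0, 1, 2], size=(8, 60))
        D = ibs_distance(make_matrix(calls))
        for i, j, k in itertools.permutations(range(8), 3):
            assert D.iloc[i, j] <= D.iloc[i, k] + D.iloc[k, j] + 1e-12


class TestGenotypePCA:
    def test_identical_samples_coincide(self):
        calls = np.array([[0, 1, 2, 1], [0, 1, 2, 1], [2, 1, 0, 0]],
                         dtype=np.int8)
        res = genotype_pca(make_matrix(calls))
        np.testing.assert_allclose(res.coordinates.iloc[0],
                                   res.coordinates.iloc[1], atol=1e-10)

    def test_contributions_sum_to_hundred_full_rank(self):
        rng = np.random.default_rng(9)
        calls = rng.choice([0, 1, 2], size=(10, 80))
        res = genotype_pca(make_matrix(calls))
        assert res.contributions.sum() == pytest.approx(100.0)

    def test_three_populations_separate(self):
        from sklearn.metrics import silhouette_score
        cfg = SimulationConfig(
            n_sites=1500, K=3, drift=(0.15, 0.15, 0.15),
            group_specs=tuple(GroupSpec(f"P{k}", 12, "outbred", population=k)
                              for k in range(3)),
            seed=8)
        m, truth = simulate_cohort(cfg)
        res = genotype_pca(m, n_components=2)
        labels = truth.true_group_label.loc[res.sample_ids]
        assert silhouette_score(res.coordinates, labels) > 0.5

    def test_order_invariance_up_to_sign(self):
        rng = np.random.default_rng(14)
        calls = rng.choice([0, 1, 2], size=(6, 50))
        ids = [f"s{i + 1}" for i in range(6)]
        res1 = genotype_pca(make_matrix(calls, sample_ids=ids), n_components=3)
        perm = rng.permutation(6)
        res2 = genotype_pca(
            make_matrix(calls[perm], sample_ids=[ids[i] for i in perm]),
            n_components=3)
        a = res1.coordinates.loc[ids].to_numpy()
        b = res2.coordinates.loc[ids].to_numpy()
        for c in range(3):
            assert (np.allclose(a[:, c], b[:, c], atol=1e-8)
                    or np.allclose(a[:, c], -b[:, c], atol=1e-8))

    def test_degenerate_input_rejected(self):
        with pytest.raises(ValueError):
            genotype_pca(make_matrix([[0, 0], [0, 0]]))


class TestClassicalMDS:
    def test_equilateral_triangle_exact(self):
        D = pd.DataFrame([[0, 1, 1], [1, 0, 1], [1, 1, 0]],
                         index=list("abc"), columns=list("abc"), dtype=float)
        res = classical_mds(D, k=2)
        X = res.coordinates.to_numpy()
        for i, j in itertools.combinations(range(3), 2):
            assert np.linalg.norm(X[i] - X[j]) == pytest.approx(1.0, abs=1e-9)

    def test_planar_configuration_recovered(self):
        rng = np.random.default_rng(3)
        pts = rng.normal(size=(7, 2))
        D = pd.DataFrame(
            np.linalg.norm(pts[:, None] - pts[None, :], axis=-1),
            index=[f"p{i}" for i in range(7)], columns=[f"p{i}" for i in range(7)])
        res = classical_mds(D, k=2)
        X = res.coordinates.to_numpy()
        rec = np.linalg.norm(X[:, None] - X[None, :], axis=-1)
        np.testing.assert_allclose(rec, D.to_numpy(), atol=1e-9)

    def test_k_reduced_when_rank_deficient(self):
        # 3 collinear points span one dimension
        D = pd.DataFrame([[0, 1, 2], [1, 0, 1], [2, 1, 0]],
                         index=list("abc"), columns=list("abc"), dtype=float)
        res = classical_mds(D, k=2)
        assert res.coordinates.shape[1] == 1

    def test_undefined_distances_rejected(self):
        D = pd.DataFrame([[0, np.nan], [np.nan, 0]], index=list("ab"),
                         columns=list("ab"))
        with pytest.raises(ValueError, match="undefined"):
            classical_mds(D)


class TestUPGMA:
    def test_two_leaves_newick(self):
        D = pd.DataFrame([[0, 0.4], [0.4, 0]], index=["A", "B"],
                         columns=["A", "B"])
        assert upgma_tree(D).newick() == "(A:0.2,B:0.2);"

    def test_ultrametric_input_recovered_exactly(self):
        # ((a,b):..,(c,d):..) with heights 0.2 and 0.6
        ids = list("abcd")
        D = pd.DataFrame(0.0, index=ids, columns=ids)
        for x, y in itertools.combinations(ids, 2):
            D.loc[x, y] = D.loc[y, x] = 0.2 if {x, y} <= {"a", "b"} or \
                {x, y} <= {"c", "d"} else 0.6
        tree = upgma_tree(D)
        pd.testing.assert_frame_equal(tree.cophenetic(), D, atol=1e-12)

    def test_row_permutation_invariant(self):
        rng = np.random.default_rng(6)
        A = rng.uniform(0.1, 1.0, size=(5, 5))
        A = (A + A.T) / 2
        np.fill_diagonal(A, 0.0)
        ids = [f"s{i}" for i in range(5)]
        D = pd.DataFrame(A, index=ids, columns=ids)
        perm = ["s3", "s0", "s4", "s2", "s1"]
        assert upgma_tree(D).newick() == upgma_tree(D.loc[perm, perm]).newick()

    def test_clones_form_tight_subtrees(self):
        cfg = SimulationConfig(
            n_sites=1500, K=2, drift=(0.2, 0.2),
            group_specs=(GroupSpec("L", 4, "clonal", population=0),
                         GroupSpec("O", 6, "outbred", population=1)),
            dropout_d=0.2, seed=10)
        m, _ = simulate_cohort(cfg)
        tree = upgma_tree(ibs_distance(m))
        C = tree.cophenetic()
        clones = [f"L_{i:02d}" for i in range(1, 5)]
        within = max(C.loc[a, b] for a, b in itertools.combinations(clones, 2))
        between = min(C.loc[a, b] for a in clones
                      for b in C.index if b.startswith("O"))
        assert within < between


class TestTraitPCA:
    def test_duplicated_rows_coincide(self):
        df = pd.DataFrame({"t1": [1.0, 1.0, 4.0], "t2": [2.0, 2.0, 8.0],
                           "t3": [0.5, 0.5, 3.0]}, index=["a", "b", "c"])
        res = trait_pca(df)
        np.testing.assert_allclose(res.coordinates.loc["a"],
                                   res.coordinates.loc["b"], atol=1e-10)

    def test_zero_variance_trait_dropped(self):
        df = pd.DataFrame({"flat": [1.0, 1.0, 1.0], "x": [1.0, 2.0, 3.0]})
        res = trait_pca(df)
        assert res.coordinates.shape[1] == 1

    def test_isotropic_data_spreads_contributions(self):
        rng = np.random.default_rng(0)
        df = pd.DataFrame(rng.normal(size=(400, 4)))
        res = trait_pca(df)
        assert np.all(np.abs(res.contributions - 25.0) < 5.0)

    def test_missing_values_rejected(self):
        with pytest.raises(ValueError, match="missing"):
            trait_pca(pd.DataFrame({"x": [1.0, np.nan]}))
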