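"""Co-abundance clustering: bicor against the literal formula, TOM hand
cases, adaptive tree cut, two-stage recovery, eigen-metabolites, merging."""

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

from gutmet.cag import (
    CAGParams,
    UndefinedCorrelationError,
    bicor,
    bicor_matrix,
    dynamic_tree_cut,
    eigen_metabolite,
    merge_cags,
    primary_cag,
    run_cag_pipeline,
    secondary_cag,
    soft_adjacency,
    tom_similarity,
)
from tests.conftest import make_block_data


def literal_bicor(x, y):
    """Independent straight-from-the-textbook biweight midcorrelation."""
    def terms(v):
        med = np.median(v)
        mad = np.median(np.abs(v - med))
        u = (v - med) / (9 * mad)
        w = (1 - u**2) ** 2 * (np.abs(u) < 1)
        return (v - med) * w

    ax, ay = terms(np.asarray(x, float)), terms(np.asarray(y, float))
    return np.sum(ax * ay) / np.sqrt(np.sum(ax**2) * np.sum(ay**2))


class TestBicor:
    def test_self_and_antisymmetry(self, rng):
        x = rng.standard_normal(25)
        assert bicor(x, x) == pytest.approx(1.0, abs=1e-12)
        assert bicor(x, -x) == pytest.approx(-1.0, abs=1e-12)

    def test_matches_literal_formula_with_outlier(self, rng):
        x = rng.standard_normal(20)
        y = 0.7 * x + 0.3 * rng.standard_normal(20)
        y[3] += 8.0  # outlier the 9-MAD weights should down-weight
        assert bicor(x, y) == pytest.approx(literal_bicor(x, y), abs=1e-12)

    def test_matrix_agrees_with_pairwise(self, rng):
        X = rng.standard_normal((30, 5))
        C = bicor_matrix(X)
        for i in range(5):
            for j in range(i + 1, 5):
                assert C[i, j] == pytest.approx(bicor(X[:, i], X[:, j]), abs=1e-12)

    def test_mad_zero_falls_back_to_pearson(self):
        # majority-constant vector: MAD = 0 but Pearson is defined
        x = np.array([1.0, 1, 1, 1, 1, 1, 1, 5, 9, 13])
        y = np.arange(10, dtype=float)
        r = bicor(x, y)
        assert -1 <= r <= 1

    def test_constant_vector_raises(self):
        with pytest.raises(UndefinedCorrelationError):
            bicor(np.ones(10), np.arange(10, dtype=float))


class TestAdjacencyTom:
    def test_soft_adjacency_values(self):
        C = np.array([[1.0, 0.5], [0.5, 1.0]])
        A = soft_adjacency(C, 12)
        assert A[0, 1] == pytest.approx(0.000244140625, abs=1e-18)
        assert A[0, 0] == 1.0

    def test_soft_adjacency_monotone_in_abs_corr(self):
        C1 = np.array([[1.0, 0.3], [0.3, 1.0]])
        C2 = np.array([[1.0, -0.6], [-0.6, 1.0]])
        assert soft_adjacency(C1, 6)[0, 1] < soft_adjacency(C2, 6)[0, 1]

    def test_soft_adjacency_rejects_asymmetric(self):
        with pytest.raises(ValueError):
            soft_adjacency(np.array([[1.0, 0.2], [0.3, 1.0]]), 2)

    def test_tom_identity_adjacency(self):
        assert np.allclose(tom_similarity(np.eye(4)), np.eye(4))

    def test_tom_three_node_hand_case(self):
        A = np.full((3, 3), 0.5)
        np.fill_diagonal(A, 1.0)
        T = tom_similarity(A)
        # (0.25 + 0.5) / (1 + 1 - 0.5) = 0.5 for every off-diagonal pair
        assert np.allclose(T[np.triu_indices(3, 1)], 0.5, atol=1e-12)

    def test_tom_bounds_and_symmetry(self, rng):
        C = np.corrcoef(rng.standard_normal((40, 8)), rowvar=False)
        T = tom_similarity(soft_adjacency(C, 6))
        assert np.allclose(T, T.T)
        assert T.min() >= 0 and T.max() <= 1


class TestDynamicTreeCut:
    def test_three_separated_blocks_recovered(self, rng):
        X, truth = make_block_data(rng, 150, [8, 8, 8], rho=0.9)
        C = bicor_matrix(X)
        D = 1 - np.abs(C)
        np.fill_diagonal(D, 0)
        labels = dynamic_tree_cut(D, CAGParams(cut_height=0.8))
        assert adjusted_rand_score(truth, labels) == 1.0

    def test_all_equal_dissimilarity_above_cut_height_unassigned(self):
        D = np.full((10, 10), 0.99995)
        np.fill_diagonal(D, 0.0)
        labels = dynamic_tree_cut(D, CAGParams())
        assert (labels == 0).all()

    def test_block_below_min_size_unassigned(self, rng):
        X, truth = make_block_data(rng, 120, [6, 6, 2], rho=0.95)
        C = bicor_matrix(X)
        D = 1 - np.abs(C)
        np.fill_diagonal(D, 0)
        labels = dynamic_tree_cut(D, CAGParams(min_cluster_size=3, cut_height=0.8))
        assert (labels[truth == 3] == 0).all()
        assert (labels[truth != 3] > 0).all()

    def test_fewer_features_than_min_size_warns(self):
        D = np.zeros((2, 2))
        with pytest.warns(UserWarning):
            labels = dynamic_tree_cut(D, CAGParams(min_cluster_size=3))
        assert (labels == 0).all()


class TestTwoStage:
    def test_primary_recovers_planted_blocks(self, rng):
        X, truth = make_block_data(rng, 200, [12, 12, 12, 12], rho=0.75)
        labels = primary_cag(X, CAGParams())
        assigned = labels > 0
        assert assigned.mean() >= 0.75
        assert adjusted_rand_score(truth[assigned], labels[assigned]) >= 0.8

    def test_permuted_data_mostly_unassigned(self, rng):
        X, _ = make_block_data(rng, 200, [12, 12, 12, 12], rho=0.75)
        Xp = X.apply(lambda col: rng.permutation(col.to_numpy()))
        labels = primary_cag(Xp, CAGParams())
        assert (labels == 0).mean() >= 0.9

    def test_duplicate_columns_share_label(self, rng):
        X, _ = make_block_data(rng, 100, [10, 10], rho=0.8)
        X["dup"] = X["f000"]
        labels = primary_cag(X, CAGParams())
        assert labels["dup"] == labels["f000"]

    def test_secondary_empty_input(self, rng):
        out = secondary_cag(pd.DataFrame(index=range(10)), CAGParams())
        assert out.empty

    def test_secondary_perfect_pair_min_size_two(self, rng):
        f = rng.standard_normal(50)
        X = pd.DataFrame({"a": f, "b": f + 1.0, "c": rng.standard_normal(50),
                          "d": rng.standard_normal(50)})
        labels = secondary_cag(X, CAGParams(min_cluster_size=2, cut_height=0.5))
        assert labels["a"] == labels["b"] > 0

    def test_secondary_recovers_leftover_block(self, rng):
        X, truth = make_block_data(rng, 150, [6, 6], rho=0.85, n_noise=10)
        labels = secondary_cag(X, CAGParams(cut_height=0.7), label_offset=5)
        assigned = labels > 0
        assert adjusted_rand_score(truth[assigned.to_numpy()],
                                   labels[assigned].to_numpy()) >= 0.8
        assert set(labels[assigned]) <= set(range(6, 20))  # offset applied

    def test_pipeline_partition_covers_all_features(self, rng):
        X, _ = make_block_data(rng, 120, [10, 10, 10], rho=0.7, n_noise=15)
        res = run_cag_pipeline(X, CAGParams())
        assert set(res.labels.index) == set(X.columns)
        sizes = res.labels[res.labels > 0].value_counts()
        assert (sizes >= 3).all()  # min size holds after merging
        assert set(res.stage.unique()) <= {"primary", "secondary", "unassigned"}


class TestEigenMetabolite:
    def test_identical_columns_give_standardised_column(self, rng):
        f = rng.standard_normal(40)
        X = pd.DataFrame({"a": f, "b": f, "c": f})
        labels = pd.Series([1, 1, 1], index=["a", "b", "c"])
        eig = eigen_metabolite(X, labels)
        z = (f - f.mean()) / f.std(ddof=1)
        assert np.corrcoef(eig[1], z)[0, 1] == pytest.approx(1.0, abs=1e-12)

    def test_sign_convention_and_unit_variance(self, rng):
        X, truth = make_block_data(rng, 80, [6, 6], rho=0.8)
        labels = pd.Series(truth, index=X.columns)
        eig = eigen_metabolite(X, labels)
        for lab in eig.columns:
            assert eig[lab].std(ddof=1) == pytest.approx(1.0, abs=1e-9)
            mem = labels.index[labels == lab]
            Z = (X[mem] - X[mem].mean()) / X[mem].std(ddof=1)
            assert np.corrcoef(eig[lab], Z.mean(axis=1))[0, 1] >= 0

    def test_anticorrelated_pair_symmetric_loadings(self, rng):
        f = rng.standard_normal(60)
        X = pd.DataFrame({"a": f + 0.1 * rng.standard_normal(60),
                          "b": -f + 0.1 * rng.standard_normal(60)})
        eig = eigen_metabolite(X, pd.Series([1, 1], index=["a", "b"]))
        ra = abs(np.corrcoef(eig[1], X["a"])[0, 1])
        rb = abs(np.corrcoef(eig[1], X["b"])[0, 1])
        assert ra == pytest.approx(rb, abs=1e-10)

    def test_zero_variance_member_dropped_with_warning(self, rng):
        f = rng.standard_normal(30)
        X = pd.DataFrame({"a": f, "b": f + 0.05 * rng.standard_normal(30),
                          "c": np.ones(30)})
        with pytest.warns(UserWarning):
            eig = eigen_metabolite(X, pd.Series([1, 1, 1], index=["a", "b", "c"]))
        assert eig.shape[1] == 1


class TestMerge:
    def test_high_correlation_pair_merged(self, rng):
        f = rng.standard_normal(100)
        cols = {f"a{i}": f + 0.2 * rng.standard_normal(100) for i in range(3)}
        cols.update({f"b{i}": f + 0.2 * rng.standard_normal(100) for i in range(3)})
        X = pd.DataFrame(cols)
        labels = pd.Series([1, 1, 1, 2, 2, 2], index=X.columns)
        res = merge_cags(X, labels, 0.8)
        assert res.labels.max() == 1
        assert len(res.merge_log) == 1
        assert res.merge_log[0]["bicor"] > 0.8

    def test_low_correlation_left_alone(self, rng):
        X, truth = make_block_data(rng, 100, [4, 4], rho=0.9)
        labels = pd.Series(truth, index=X.columns)
        res = merge_cags(X, labels, 0.8)
        assert res.labels.max() == 2
        assert res.merge_log == []

    def test_three_mutually_high_clusters_collapse(self, rng):
        f = rng.standard_normal(200)
        cols = {}
        for b in "abc":
            for i in range(3):
                cols[f"{b}{i}"] = f + 0.15 * rng.standard_normal(200)
        X = pd.DataFrame(cols)
        labels = pd.Series([1] * 3 + [2] * 3 + [3] * 3, index=X.columns)
        res = merge_cags(X, labels, 0.8)
        assert res.labels.max() == 1
        assert len(res.merge_log) == 2
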