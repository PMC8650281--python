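import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy.cluster.hierarchy import fcluster

from ipfnet import (
    choose_k,
    clinical_correlation,
    compare_categorical,
    compare_groups,
    ward_cluster,
)


def _blobs(n_per=25, sep=10.0, d=5, seed=0):
    rng = np.random.default_rng(seed)
    a = rng.normal(0, 1, size=(n_per, d))
    b = rng.normal(sep, 1, size=(n_per, d))
    X = np.vstack([a, b]).T  # features x samples
    cols = [f"s{j:02d}" for j in range(2 * n_per)]
    return pd.DataFrame(X, index=[f"f{i}" for i in range(d)], columns=cols)


class TestWardCluster:
    def test_nearest_pair_merges_first_in_one_dimension(self):
        df = pd.DataFrame([[0.0, 1.0, 10.0]], index=["f"], columns=["a", "b", "c"])
        tree = ward_cluster(df, standardize=False)
        assert set(tree[0, :2].astype(int)) == {0, 1}  # samples a and b

    def test_identical_samples_merge_at_height_zero(self):
        df = pd.DataFrame([[1.0, 1.0, 5.0], [2.0, 2.0, 7.0]],
                          index=["f1", "f2"], columns=["a", "b", "c"])
        tree = ward_cluster(df, standardize=False)
        assert tree[0, 2] == pytest.approx(0.0)

    def test_merge_heights_non_decreasing(self):
        df = _blobs(seed=1)
        tree = ward_cluster(df)
        assert (np.diff(tree[:, 2]) >= -1e-9).all()

    def test_sample_order_permutation_gives_same_heights(self):
        df = _blobs(n_per=10, seed=2)
        perm = df.sample(frac=1, axis=1, random_state=3)
        h1 = np.sort(ward_cluster(df)[:, 2])
        h2 = np.sort(ward_cluster(perm)[:, 2])
        np.testing.assert_allclose(h1, h2, atol=1e-8)

    def test_too_few_samples_rejected(self):
        df = pd.DataFrame([[1.0]], index=["f"], columns=["a"])
        with pytest.raises(ValueError):
            ward_cluster(df)


class TestChooseK:
    def test_two_separated_blobs_select_k2(self):
        df = _blobs(n_per=25, sep=10.0, seed=4)
        tree = ward_cluster(df)
        res = choose_k(tree, df, k_max=6)
        assert res.chosen_k == 2
        assert res.silhouette[2] > 0.8
        assert sorted(res.sizes.values()) == [25, 25]

    def test_single_blob_has_weak_silhouette(self):
        rng = np.random.default_rng(5)
        df = pd.DataFrame(rng.normal(size=(5, 40)),
                          index=[f"f{i}" for i in range(5)],
                          columns=[f"s{j}" for j in range(40)])
        res = choose_k(ward_cluster(df), df, k_max=6)
        assert (res.silhouette < 0.3).all()

    def test_silhouette_and_sse_match_brute_force(self):
        """Internal validity indices equal an explicit pairwise-distance oracle."""
        df = _blobs(n_per=12, sep=4.0, seed=6)
        from ipfnet.subtyping import standardize_features
        X = standardize_features(df).to_numpy().T
        tree = ward_cluster(df)
        res = choose_k(tree, df, k_max=4)
        for k in (2, 3, 4):
            labs = fcluster(tree, t=k, criterion="maxclust")
            # brute-force SSE
            sse = sum(((X[labs == c] - X[labs == c].mean(axis=0)) ** 2).sum()
                      for c in np.unique(labs))
            assert res.sse[k] == pytest.approx(sse, rel=1e-9)
            # brute-force silhouette
            D = np.sqrt(((X[:, None, :] - X[None, :, :]) ** 2).sum(-1))
            svals = []
            for i in range(len(labs)):
                own = labs[i]
                same = [j for j in range(len(labs)) if labs[j] == own and j != i]
                a = D[i, same].mean() if same else 0.0
                bs = [D[i, labs == c].mean() for c in np.unique(labs) if c != own]
                b = min(bs)
                svals.append(0.0 if not same else (b - a) / max(a, b))
            assert res.silhouette[k] == pytest.approx(np.mean(svals), rel=1e-9)

    def test_deterministic(self):
        df = _blobs(n_per=10, seed=7)
        tree = ward_cluster(df)
        r1 = choose_k(tree, df, k_max=5)
        r2 = choose_k(tree, df, k_max=5)
        assert r1.chosen_k == r2.chosen_k
        pd.testing.assert_series_equal(r1.labels, r2.labels)

    def test_k_max_at_least_n_rejected(self):
        df = _blobs(n_per=3, seed=8)
        with pytest.raises(ValueError, match="k_max"):
            choose_k(ward_cluster(df), df, k_max=6)


class TestCompareGroups:
    def test_identical_groups_null(self):
        s = pd.Series([1.0, 2.0, 3.0, 1.0, 2.0, 3.0], index=list("abcdef"))
        labels = pd.Series(["x", "x", "x", "y", "y", "y"], index=list("abcdef"))
        t, p = compare_groups(s, labels)
        assert t == pytest.approx(0.0) and p == pytest.approx(1.0)

    def test_strong_shift_matches_textbook_welch(self):
        rng = np.random.default_rng(9)
        a = rng.normal(0, 1, 50)
        b = rng.normal(2, 1, 50)
        s = pd.Series(np.concatenate([a, b]))
        labels = pd.Series(["a"] * 50 + ["b"] * 50)
        t, p = compare_groups(s, labels)
        va, vb = a.var(ddof=1) / 50, b.var(ddof=1) / 50
        t_ref = (a.mean() - b.mean()) / math.sqrt(va + vb)
        assert t == pytest.approx(t_ref, rel=1e-12)
        assert p < 1e-10

    def test_label_swap_negates_t(self):
        rng = np.random.default_rng(10)
        s = pd.Series(rng.normal(size=20))
        labels = pd.Series(["a"] * 10 + ["b"] * 10)
        swapped = labels.map({"a": "b", "b": "a"})
        t1, p1 = compare_groups(s, labels)
        t2, p2 = compare_groups(s, swapped)
        assert t1 == pytest.approx(-t2) and p1 == pytest.approx(p2)


class TestCompareCategorical:
    def test_extreme_table_enumeration(self):
        """[[5,0],[0,5]]: two-sided p = 2 / C(10,5) by exhaustive counting."""
        _, p = compare_categorical([[5, 0], [0, 5]])
        assert p == pytest.approx(2 / math.comb(10, 5), rel=1e-9)

    def test_balanced_table_no_association(self):
        _, p = compare_categorical([[2, 2], [2, 2]])
        assert p == pytest.approx(1.0)

    def test_transpose_invariance(self):
        tab = [[7, 2], [3, 8]]
        _, p1 = compare_categorical(tab)
        _, p2 = compare_categorical(np.array(tab).T)
        assert p1 == pytest.approx(p2)

    def test_zero_margin_gives_p_one(self):
        _, p = compare_categorical([[0, 0], [3, 4]])
        assert p == 1.0

    def test_haldane_odds_ratio_with_zero_cell(self):
        orr, _ = compare_categorical([[5, 0], [1, 4]])
        assert orr == pytest.approx((5.5 * 4.5) / (0.5 * 1.5))


class TestClinicalCorrelation:
    def test_perfect_anticorrelation(self):
        x = pd.Series(np.arange(10.0), index=[f"s{i}" for i in range(10)])
        scores = pd.DataFrame({"path": x}).T
        cov = pd.DataFrame({"fvc": -x})
        res = clinical_correlation(scores, cov, m_tests=1)
        assert res.loc[0, "r"] == pytest.approx(-1.0)
        assert res.loc[0, "p"] < 1e-12

    def test_bonferroni_arithmetic(self):
        rng = np.random.default_rng(11)
        x = pd.Series(rng.normal(size=30), index=[f"s{i}" for i in range(30)])
        y = x + rng.normal(0, 2, size=30)
        res = clinical_correlation(pd.DataFrame({"p1": x}).T,
                                   pd.DataFrame({"fvc": y}), m_tests=10)
        assert res.loc[0, "adj_p"] == pytest.approx(min(1.0, res.loc[0, "p"] * 10))

    def test_missing_covariates_dropped_per_pair(self):
        x = pd.Series(np.arange(8.0), index=[f"s{i}" for i in range(8)])
        y = -x.copy()
        y.iloc[:2] = np.nan
        res = clinical_correlation(pd.DataFrame({"p1": x}).T, pd.DataFrame({"fvc": y}))
        assert res.loc[0, "n"] == 6 and res.loc[0, "r"] == pytest.approx(-1.0)

    def test_constant_vector_reported_missing(self):
        x = pd.Series(np.ones(6), index=[f"s{i}" for i in range(6)])
        y = pd.Series(np.arange(6.0), index=x.index)
        res = clinical_correlation(pd.DataFrame({"p1": x}).T, pd.DataFrame({"fvc": y}))
        assert np.isnan(res.loc[0, "r"]) and res.loc[0, "note"] == "constant vector"
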