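import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from ipfnet import (
    GeneSetCollection,
    cell_scores,
    eigengene_score,
    enrichment_map,
    enrichment_score,
    generate_compendium,
    gsea,
    gsea_collection,
    ora_test,
    signal_to_noise,
    ssgsea,
)


def brute_force_es(stats_by_gene: dict[str, float], members: set[str], p: float) -> float:
    """Independent running-sum oracle: evaluate the sum at every position."""
    ordered = sorted(stats_by_gene, key=lambda g: (-stats_by_gene[g], g))
    nh = sum(1 for g in ordered if g in members)
    denom = sum(abs(stats_by_gene[g]) ** p for g in ordered if g in members)
    best, run = 0.0, 0.0
    for g in ordered:
        if g in members:
            run += abs(stats_by_gene[g]) ** p / denom
        else:
            run -= 1.0 / (len(ordered) - nh)
        if abs(run) > abs(best):
            best = run
    return best


class TestOra:
    def test_matches_hypergeometric_enumeration(self):
        """Universe 20, set 5, query 5, overlap 4: p = P(X >= 4) computed by
        exhaustive enumeration of the hypergeometric mass."""
        universe = {f"g{i}" for i in range(20)}
        members = {f"g{i}" for i in range(5)}
        query = {"g0", "g1", "g2", "g3", "g10"}
        res = ora_test(query, GeneSetCollection({"S": members}), universe)
        p_enum = sum(
            math.comb(5, k) * math.comb(15, 5 - k) for k in range(4, 6)
        ) / math.comb(20, 5)
        assert res.loc["S", "overlap"] == 4
        assert res.loc["S", "p"] == pytest.approx(p_enum, rel=1e-12)

    def test_disjoint_query_gives_p_one(self):
        universe = {f"g{i}" for i in range(20)}
        res = ora_test({"g10", "g11"}, GeneSetCollection({"S": {"g0", "g1"}}), universe)
        assert res.loc["S", "p"] == pytest.approx(1.0)

    def test_significance_uses_adjusted_p_below_0_05(self):
        universe = {f"g{i}" for i in range(100)}
        sets = GeneSetCollection({
            "hit": {f"g{i}" for i in range(10)},
            "miss": {f"g{i}" for i in range(50, 60)},
        })
        res = ora_test({f"g{i}" for i in range(10)}, sets, universe)
        assert bool(res.loc["hit", "significant"])
        assert not bool(res.loc["miss", "significant"])

    def test_empty_query_rejected(self):
        with pytest.raises(ValueError):
            ora_test(set(), GeneSetCollection({"S": {"a"}}), {"a"})


class TestGseaEs:
    def test_top_ranked_set_reaches_plus_one_unweighted(self):
        stats_by_gene = {f"g{i}": 10.0 - i for i in range(10)}
        es, _ = enrichment_score(pd.Series(stats_by_gene), {"g0", "g1"}, weight_p=0)
        assert es == pytest.approx(1.0)

    def test_bottom_ranked_set_reaches_minus_one_unweighted(self):
        stats_by_gene = {f"g{i}": 10.0 - i for i in range(10)}
        es, _ = enrichment_score(pd.Series(stats_by_gene), {"g8", "g9"}, weight_p=0)
        assert es == pytest.approx(-1.0)

    def test_leading_edge_is_subset_of_the_set(self):
        rng = np.random.default_rng(0)
        s = pd.Series(rng.normal(size=50), index=[f"g{i}" for i in range(50)])
        members = {f"g{i}" for i in range(0, 50, 5)}
        es, leading = enrichment_score(s, members)
        assert set(leading) <= members and abs(es) <= 1.0

    def test_equals_brute_force_oracle_on_random_instances(self):
        rng = np.random.default_rng(1)
        for _ in range(30):
            n = int(rng.integers(10, 200))
            genes = [f"g{i}" for i in range(n)]
            vals = rng.normal(size=n)
            members = set(rng.choice(genes, size=int(rng.integers(2, max(3, n // 4))),
                                     replace=False))
            d = dict(zip(genes, vals))
            es, _ = enrichment_score(pd.Series(d), members)
            assert es == pytest.approx(brute_force_es(d, members, 1.0), abs=1e-12)


class TestGseaPermutation:
    def test_nominal_p_uniform_under_gene_permutation_null(self):
        """Null data: the permutation p of a random set is uniform (KS)."""
        rng = np.random.default_rng(2)
        genes = [f"g{i}" for i in range(100)]
        pvals = []
        for rep in range(200):
            s = pd.Series(rng.normal(size=100), index=genes)
            members = set(rng.choice(genes, size=10, replace=False))
            res = gsea(s, members, n_perm=199, perm_mode="gene", seed=rep)
            pvals.append(res.p)
        _, ks_p = stats.kstest(pvals, "uniform")
        assert ks_p > 0.01

    def test_planted_pathway_found_with_phenotype_permutation(self):
        comp, truth = generate_compendium(
            n_batches=1, cases_per_batch=20, controls_per_batch=20, n_genes=400,
            n_up=0, n_down=0, batch_sd=0.0, subgroup_effect=2.0, pathway_size=25,
            severity_size=0, seed=3,
        )
        sets = GeneSetCollection({
            "planted": truth.pathways["pathway_C1"],
            "random": set(comp.genes[:25]) - truth.pathways["pathway_C1"],
        })
        rank = signal_to_noise(comp.values, comp.condition)
        res = gsea_collection(rank, sets, n_perm=200, perm_mode="phenotype", seed=0,
                              values=comp.values, condition=comp.condition)
        assert res.loc["planted", "es"] > 0
        assert res.loc["planted", "p"] < 0.05
        assert bool(res.loc["planted", "significant"])

    def test_set_absent_from_universe_rejected(self):
        s = pd.Series([1.0, 2.0], index=["a", "b"])
        with pytest.raises(ValueError, match="no members"):
            gsea(s, {"zzz"}, n_perm=100)


class TestSsgsea:
    def test_invariant_to_monotone_transform(self, toy_matrix):
        members = {"g0", "g3"}
        base = ssgsea(toy_matrix, members)
        transformed = ssgsea(np.exp(toy_matrix / 2), members)
        pd.testing.assert_series_equal(base, transformed)

    def test_identical_samples_get_identical_scores(self, toy_matrix):
        dup = toy_matrix.copy()
        dup["s1"] = dup["s0"]
        res = ssgsea(dup, {"g1", "g4"})
        assert res["s0"] == pytest.approx(res["s1"])

    def test_hand_computed_ecdf_difference_alpha_zero(self):
        # 5 genes, one sample, expression ranks g4 > g3 > g2 > g1 > g0
        df = pd.DataFrame({"s": [1.0, 2.0, 3.0, 4.0, 5.0]},
                          index=[f"g{i}" for i in range(5)])
        members = {"g4", "g2"}  # positions 1 and 3 in the descending walk
        # walk: g4 (hit), g3, g2 (hit), g1, g0
        p_in = np.array([0.5, 0.5, 1.0, 1.0, 1.0])
        p_out = np.array([0.0, 1 / 3, 1 / 3, 2 / 3, 1.0])
        expected = float((p_in - p_out).sum())
        assert ssgsea(df, members, alpha=0.0)["s"] == pytest.approx(expected)

    def test_absent_set_rejected(self, toy_matrix):
        with pytest.raises(ValueError, match="absent"):
            ssgsea(toy_matrix, {"zzz"})


class TestEigengene:
    def test_single_gene_set_is_that_gene_standardised(self, toy_matrix):
        score = eigengene_score(toy_matrix, {"g2"})
        g = toy_matrix.loc["g2"]
        expected = (g - g.mean()) / g.std(ddof=0)
        np.testing.assert_allclose(np.abs(np.corrcoef(score, expected)[0, 1]), 1.0)
        np.testing.assert_allclose(score.to_numpy(), expected.to_numpy(), atol=1e-8)

    def test_two_perfectly_correlated_genes(self):
        rng = np.random.default_rng(4)
        base = rng.normal(size=20)
        df = pd.DataFrame({"a": base, "b": 2 * base + 1}).T
        df.columns = [f"s{i}" for i in range(20)]
        score = eigengene_score(df, {"a", "b"})
        for g in ("a", "b"):
            assert abs(np.corrcoef(score, df.loc[g])[0, 1]) == pytest.approx(1.0)

    def test_sign_anchored_to_members(self, small_study):
        comp, truth = small_study
        for name, members in truth.pathways.items():
            score = eigengene_score(comp.values, members)
            z = comp.values.loc[sorted(members & set(comp.genes))]
            z = z.sub(z.mean(axis=1), axis=0).div(z.std(axis=1), axis=0)
            corr = z.mul(score, axis=1).mean(axis=1)
            assert corr.mean() >= 0

    def test_tracks_planted_subgroup_activity(self):
        """The planted pathway's eigengene separates the case subgroups."""
        comp, truth = generate_compendium(
            n_batches=3, cases_per_batch=34, controls_per_batch=5, n_genes=500,
            subgroup_effect=1.5, batch_sd=0.0, seed=5,
        )
        cases = comp.case_samples()
        score = eigengene_score(comp.values[cases], truth.pathways["pathway_C1"])
        activity = (truth.subgroup_labels.loc[cases] == "C1").astype(float)
        assert abs(np.corrcoef(score, activity)[0, 1]) >= 0.9

    def test_constant_members_rejected(self):
        df = pd.DataFrame(np.ones((3, 5)), index=["a", "b", "c"],
                          columns=[f"s{i}" for i in range(5)])
        with pytest.raises(ValueError, match="constant"):
            eigengene_score(df, {"a", "b"})


class TestCellScores:
    def test_spiked_sample_has_maximal_score(self):
        rng = np.random.default_rng(6)
        df = pd.DataFrame(rng.normal(5, 1, size=(60, 10)),
                          index=[f"g{i}" for i in range(60)],
                          columns=[f"s{j}" for j in range(10)])
        markers = GeneSetCollection({"ciliated": {f"g{i}" for i in range(8)}},
                                    {"ciliated": "cell-marker"})
        df.loc[[f"g{i}" for i in range(8)], "s3"] += 2.0
        scores = cell_scores(df, markers)
        assert scores.loc["ciliated"].idxmax() == "s3"

    def test_identical_samples_get_zero_z(self):
        df = pd.DataFrame(np.tile(np.arange(10.0)[:, None], (1, 4)),
                          index=[f"g{i}" for i in range(10)],
                          columns=[f"s{j}" for j in range(4)])
        markers = GeneSetCollection({"m": {"g0", "g5"}})
        scores = cell_scores(df, markers)
        np.testing.assert_allclose(scores.loc["m"], 0.0, atol=1e-12)


class TestEnrichmentMap:
    SETS = GeneSetCollection({
        "S1": {"A", "B", "C"},
        "S2": {"B", "C", "D"},
        "S3": {"X", "Y"},
        "S4": {"A", "B", "C", "D", "E", "F", "G", "H", "I", "J"},
    })

    def test_jaccard_weight_hand_computed(self):
        g = enrichment_map(["S1", "S2"], self.SETS)
        assert g.has_edge("S1", "S2")
        assert g.edges["S1", "S2"]["weight"] == pytest.approx(0.5)

    def test_disjoint_sets_unlinked(self):
        g = enrichment_map(["S1", "S3"], self.SETS)
        assert g.number_of_edges() == 0

    def test_cutoff_is_strict(self):
        # |S3 & S5| / |S3 | S5| chosen to land exactly on 0.10
        sets = GeneSetCollection({"A": {str(i) for i in range(5)},
                                  "B": {"0"} | {f"x{i}" for i in range(6)}})
        # |A & B| = 1, |A | B| = 11 -> not > 0.10; rebuild for exactly 0.10
        sets2 = GeneSetCollection({"A": {str(i) for i in range(4)},
                                   "B": {"0"} | {f"x{i}" for i in range(6)}})
        # 1/10 == 0.10 exactly -> no edge
        g = enrichment_map(["A", "B"], sets2)
        assert g.number_of_edges() == 0

    def test_unknown_set_rejected(self):
        with pytest.raises(ValueError, match="absent"):
            enrichment_map(["nope"], self.SETS)
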