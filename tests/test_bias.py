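import numpy as np
import pandas as pd
import pytest

from allostate.bias import (
    GeneSignalKMeans,
    categorize_bias,
    kmeans_gene_clusters,
    mark_level_compare,
    newgene_cluster_enrichment,
    reciprocal_best_hits,
    summarize_bias_counts,
    wilcoxon_rank_sum,
)

from conftest import wilcoxon_exact_enumeration

COLS = ["query_id", "target_id", "e_value", "coverage", "identity"]


def hits(rows):
    return pd.DataFrame(rows, columns=COLS)


class TestReciprocalBestHits:
    def test_mutual_best_pair(self):
        ad = hits([("A1", "D1", 1e-20, 90, 80)])
        da = hits([("D1", "A1", 1e-20, 90, 80)])
        hom = reciprocal_best_hits(ad, da, ["A1"], ["D1"])
        assert hom.pairs == [("A1", "D1")]
        assert not hom.a_unique and not hom.d_unique

    def test_best_hit_asymmetry_is_not_unique(self):
        # A2's best is D1, but D1's best is A1: A2 unpaired; its passing
        # similarity (cov 60 / id 55) keeps it out of the unique set
        ad = hits([("A1", "D1", 1e-30, 90, 80), ("A2", "D1", 1e-10, 60, 55)])
        da = hits([("D1", "A1", 1e-30, 90, 80)])
        hom = reciprocal_best_hits(ad, da, ["A1", "A2"], ["D1"])
        assert hom.pairs == [("A1", "D1")]
        assert "A2" in hom.a_other
        assert "A2" not in hom.a_unique

    def test_low_coverage_only_hit_is_unique(self):
        ad = hits([("A3", "D1", 1e-8, 30, 80)])
        hom = reciprocal_best_hits(ad, hits([]), ["A3"], ["D1"])
        assert hom.a_unique == {"A3"}
        assert hom.d_unique == {"D1"}  # no hits at all

    def test_no_hit_gene_is_unique(self):
        hom = reciprocal_best_hits(hits([]), hits([]), ["A1"], ["D1"])
        assert hom.a_unique == {"A1"} and hom.d_unique == {"D1"}

    def test_evalue_cut_blocks_pairing(self):
        ad = hits([("A1", "D1", 1e-3, 90, 80)])
        da = hits([("D1", "A1", 1e-3, 90, 80)])
        hom = reciprocal_best_hits(ad, da, ["A1"], ["D1"])
        assert hom.pairs == []
        # the similarity passes cov/id, so neither gene is unique
        assert hom.a_other == {"A1"} and hom.d_other == {"D1"}

    def test_symmetry_under_role_swap(self):
        ad = hits([
            ("A1", "D1", 1e-20, 90, 80), ("A2", "D2", 1e-15, 70, 60),
            ("A3", "D1", 1e-2, 20, 30),
        ])
        da = hits([
            ("D1", "A1", 1e-20, 90, 80), ("D2", "A2", 1e-15, 70, 60),
        ])
        fwd = reciprocal_best_hits(ad, da, ["A1", "A2", "A3"], ["D1", "D2"])
        rev = reciprocal_best_hits(da, ad, ["D1", "D2"], ["A1", "A2", "A3"])
        assert {(a, d) for a, d in fwd.pairs} == {(d, a) for a, d in rev.pairs}
        assert fwd.a_unique == rev.d_unique


class TestCategorizeBias:
    def test_printed_count_arithmetic(self):
        s = summarize_bias_counts(2879, 3114, 26_340)
        assert round(s["biased_percent"], 1) == 22.8
        assert s["A=D"] == 26_340 - 5993

    def test_no_bias_when_balanced(self, rng):
        from allostate.bias import HomoeologSet

        pairs = [(f"A{i}", f"D{i}") for i in range(30)]
        hom = HomoeologSet(pairs)
        counts = pd.DataFrame(
            rng.poisson(200, size=(60, 2)),
            index=[g for p in pairs for g in p][::2] + [p[1] for p in pairs],
            columns=["r1", "r2"],
        )
        counts.index = [p[0] for p in pairs] + [p[1] for p in pairs]
        hom = categorize_bias(hom, counts, ["r1", "r2"], ["r1", "r2"])
        s = (pd.Series(list(hom.bias_category.values())) != "A=D").mean()
        assert s <= 0.2

    def test_planted_tenfold_bias_categorized(self, rng):
        from allostate.bias import HomoeologSet

        # minority of pairs biased 10-fold toward A (normalization must not
        # absorb a minority shift)
        pairs = [(f"A{i}", f"D{i}") for i in range(40)]
        hom = HomoeologSet(pairs)
        a_mu = np.full(40, 200.0)
        a_mu[:5] = 2000.0
        a_counts = rng.poisson(np.repeat(a_mu[:, None], 2, 1))
        d_counts = rng.poisson(200, size=(40, 2))
        counts = pd.DataFrame(
            np.vstack([a_counts, d_counts]),
            index=[p[0] for p in pairs] + [p[1] for p in pairs],
            columns=["r1", "r2"],
        )
        hom = categorize_bias(hom, counts, ["r1", "r2"], ["r1", "r2"])
        assert all(hom.bias_category[p] == "A>D" for p in pairs[:5])
        balanced = [hom.bias_category[p] for p in pairs[5:]]
        assert balanced.count("A=D") >= 30

    def test_missing_expression_defaults_balanced(self):
        from allostate.bias import HomoeologSet

        hom = HomoeologSet([("A1", "D1")])
        counts = pd.DataFrame({"r1": [5], "r2": [7]}, index=["A1"])
        hom = categorize_bias(hom, counts, ["r1", "r2"], ["r1", "r2"])
        assert hom.bias_category[("A1", "D1")] == "A=D"


class TestWilcoxon:
    def test_disjoint_groups_exact_p(self):
        assert wilcoxon_rank_sum([1, 2, 3], [4, 5, 6]) == pytest.approx(0.1)

    @pytest.mark.parametrize("n1,n2", [(3, 3), (4, 5), (6, 6), (2, 10)])
    def test_matches_enumeration_oracle(self, n1, n2, rng):
        for _ in range(10):
            pooled = rng.permutation(np.arange(1.0, n1 + n2 + 1))
            x, y = pooled[:n1], pooled[n1:]
            assert wilcoxon_rank_sum(x, y) == pytest.approx(
                wilcoxon_exact_enumeration(x, y), abs=1e-10
            )

    def test_large_shift_is_significant(self, rng):
        x = rng.normal(0, 1, 50)
        y = rng.normal(0, 1, 50) + 100
        assert wilcoxon_rank_sum(x, y) < 1e-10

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            wilcoxon_rank_sum([], [1.0])


class TestMarkLevelCompare:
    def test_means_and_pvalues_reported(self, rng):
        signal = pd.DataFrame(
            {"H3K4me3": rng.normal(10, 1, 40), "H3K27me3": rng.normal(5, 1, 40)},
            index=[f"g{i}" for i in range(40)],
        )
        groups = {"A": [f"g{i}" for i in range(20)],
                  "B": [f"g{i}" for i in range(20, 40)]}
        out = mark_level_compare(signal, groups)
        assert set(out["mark"]) == {"H3K4me3", "H3K27me3"}
        assert ((out["p_value"] > 0) & (out["p_value"] <= 1)).all()

    def test_empty_group_rejected(self, rng):
        signal = pd.DataFrame({"m": [1.0, 2.0]}, index=["g1", "g2"])
        with pytest.raises(ValueError):
            mark_level_compare(signal, {"A": ["g1"], "B": []})


class TestKMeans:
    def test_planted_blobs_recovered(self, rng):
        a = rng.normal(0, 0.2, size=(30, 3))
        b = rng.normal(5, 0.2, size=(20, 3))
        signal = pd.DataFrame(np.vstack([a, b]),
                              index=[f"g{i}" for i in range(50)])
        labels, _ = kmeans_gene_clusters(signal, k=2, seed=0)
        # cluster 1 is the larger planted blob
        assert (labels[:30] == 1).all()
        assert (labels[30:] == 2).all()

    def test_k1_centroid_is_column_mean(self, rng):
        signal = pd.DataFrame(rng.normal(3, 1, size=(25, 4)))
        _, means = kmeans_gene_clusters(signal, k=1, seed=0)
        np.testing.assert_allclose(means.loc[1], signal.mean(axis=0), rtol=1e-12)

    def test_seed_determinism(self, rng):
        signal = pd.DataFrame(rng.normal(0, 1, size=(60, 5)))
        l1, _ = kmeans_gene_clusters(signal, k=4, seed=11)
        l2, _ = kmeans_gene_clusters(signal, k=4, seed=11)
        assert (l1 == l2).all()

    def test_too_many_clusters_rejected(self, rng):
        signal = pd.DataFrame(rng.normal(0, 1, size=(3, 2)))
        with pytest.raises(ValueError):
            GeneSignalKMeans(n_clusters=5).fit(signal)


class TestNewGeneEnrichment:
    def test_balanced_table_is_null(self):
        labels = pd.Series([1] * 10 + [2] * 10, index=[f"g{i}" for i in range(20)])
        new = {f"g{i}" for i in range(5)} | {f"g{i}" for i in range(10, 15)}
        res = newgene_cluster_enrichment(labels, new)
        for r in res:
            assert r.odds_ratio == pytest.approx(1.0)
            assert r.p_value == pytest.approx(1.0)

    def test_concentrated_new_genes_significant(self):
        labels = pd.Series([1] * 50 + [2] * 50, index=[f"g{i}" for i in range(100)])
        new = {f"g{i}" for i in range(20)}  # all in cluster 1
        res = newgene_cluster_enrichment(labels, new)
        by = {r.label: r for r in res}
        assert by["cluster1 x new"].p_value < 0.01
        assert by["cluster1 x new"].odds_ratio > 1

    def test_empty_new_set_rejected(self):
        labels = pd.Series([1, 2], index=["g1", "g2"])
        with pytest.raises(ValueError):
            newgene_cluster_enrichment(labels, set())
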