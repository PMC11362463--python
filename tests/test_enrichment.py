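"""Gene-set scoring: ranking, preranked GSEA, ssGSEA, and over-representation."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hccdriver.enrichment import (
    GeneSetCollection,
    compare_ssgsea_groups,
    ora_hypergeometric,
    preranked_gsea,
    rank_genes_by_log2fc,
    ssgsea_matrix,
    ssgsea_score,
)


def _naive_es(scores, in_set, weight):
    """Independent re-derivation of the running-sum extremum."""
    hit_w = [abs(s) ** weight if m else 0.0 for s, m in zip(scores, in_set)]
    total = sum(hit_w)
    n_miss = len(scores) - sum(in_set)
    running, best = 0.0, 0.0
    for k in range(len(scores)):
        running += hit_w[k] / total if in_set[k] else -1.0 / n_miss
        if abs(running) > abs(best):
            best = running
    return best


class TestRanking:
    def test_tie_break_lexicographic_and_order_invariant(self):
        table = pd.DataFrame({"gene": ["B", "A", "C"], "log2fc": [1.0, 1.0, 2.0]})
        r1 = rank_genes_by_log2fc(table)
        r2 = rank_genes_by_log2fc(table.iloc[::-1])
        assert list(r1.index) == ["C", "A", "B"]
        assert list(r1.index) == list(r2.index)

    def test_duplicate_genes_rejected(self):
        table = pd.DataFrame({"gene": ["A", "A"], "log2fc": [1.0, 2.0]})
        with pytest.raises(ValueError):
            rank_genes_by_log2fc(table)


class TestPrerankedGsea:
    def test_top_gene_beats_bottom_gene(self):
        ranking = pd.Series([3.0, 2.0, 1.0, 0.5, 0.1], index=list("ABCDE"))
        top = preranked_gsea(ranking, ["A"], n_perm=100, seed=0)
        bottom = preranked_gsea(ranking, ["E"], n_perm=100, seed=0)
        assert top.es > bottom.es

    def test_unweighted_es_matches_hand_enumeration(self):
        """Equal scores, weight 0, 2-of-4 set at the top of the list."""
        ranking = pd.Series([1.0, 1.0, 1.0, 1.0], index=list("ABCD"))
        res = preranked_gsea(ranking, ["A", "B"], weight=0.0, n_perm=100, seed=0)
        # running sum: +1/2, +1, then -1/2 steps twice -> extremum 1.0 at position 2
        assert res.es == pytest.approx(1.0)
        assert res.leading_edge == ("A", "B")

    def test_es_matches_independent_evaluation(self):
        rng = np.random.default_rng(3)
        genes = [f"g{i}" for i in range(12)]
        scores = np.sort(rng.normal(size=12))[::-1]
        ranking = pd.Series(scores, index=genes)
        for members in (["g0", "g5", "g11"], ["g2", "g3"], ["g11"]):
            res = preranked_gsea(ranking, members, weight=1.0, n_perm=100, seed=1)
            in_set = [g in set(members) for g in genes]
            assert res.es == pytest.approx(_naive_es(scores, in_set, 1.0), abs=1e-12)

    def test_permutation_p_uniform_for_random_sets(self):
        from scipy.stats import kstest

        rng = np.random.default_rng(4)
        genes = [f"g{i}" for i in range(50)]
        ranking = pd.Series(np.sort(rng.normal(size=50))[::-1], index=genes)
        ps = []
        for k in range(200):
            members = list(rng.choice(genes, size=8, replace=False))
            ps.append(preranked_gsea(ranking, members, n_perm=200, seed=k).p)
        assert kstest(ps, "uniform").pvalue > 0.005

    def test_reproducible_given_seed(self):
        rng = np.random.default_rng(5)
        ranking = pd.Series(np.sort(rng.normal(size=30))[::-1], index=[f"g{i}" for i in range(30)])
        a = preranked_gsea(ranking, ["g1", "g2", "g3"], n_perm=300, seed=7)
        b = preranked_gsea(ranking, ["g1", "g2", "g3"], n_perm=300, seed=7)
        assert a.p == b.p and a.nes == b.nes

    def test_complement_set_negates_unweighted_es(self):
        """With weight 0 the hit/miss roles swap exactly, so ES flips sign."""
        rng = np.random.default_rng(10)
        genes = [f"g{i}" for i in range(8)]
        ranking = pd.Series(np.sort(rng.normal(size=8))[::-1], index=genes)
        for size in (1, 3, 5, 7):
            members = list(rng.choice(genes, size=size, replace=False))
            complement = [g for g in genes if g not in members]
            es = preranked_gsea(ranking, members, weight=0.0, n_perm=100, seed=0).es
            es_c = preranked_gsea(ranking, complement, weight=0.0, n_perm=100, seed=0).es
            assert es_c == pytest.approx(-es, abs=1e-12)

    def test_es_matches_gseapy_cross_check(self):
        """Our weighted-KS ES agrees with an independent implementation."""
        import gseapy

        rng = np.random.default_rng(11)
        genes = [f"g{i}" for i in range(50)]
        scores = np.sort(rng.normal(size=50))[::-1]
        for k in range(3):
            members = sorted(rng.choice(genes, size=8, replace=False))
            ref = gseapy.prerank(
                rnk=pd.DataFrame({"gene": genes, "score": scores}),
                gene_sets={"S": members},
                permutation_num=10,
                weight=1.0,
                min_size=1,
                max_size=100,
                seed=k,
                outdir=None,
                no_plot=True,
                threads=1,
            ).res2d
            ours = preranked_gsea(
                pd.Series(scores, index=genes), members, weight=1.0, n_perm=100, seed=k
            )
            assert ours.es == pytest.approx(float(ref["ES"].iloc[0]), abs=1e-6)

    def test_empty_or_full_overlap_rejected(self):
        ranking = pd.Series([2.0, 1.0], index=["A", "B"])
        with pytest.raises(ValueError):
            preranked_gsea(ranking, ["Z"], n_perm=100, seed=0)
        with pytest.raises(ValueError):
            preranked_gsea(ranking, ["A", "B"], n_perm=100, seed=0)


class TestSsgsea:
    def test_hand_evaluated_five_gene_profile(self):
        """5 genes, 2-gene set holding the top and third-ranked genes."""
        profile = pd.Series({"A": 9.0, "B": 7.0, "C": 5.0, "D": 3.0, "E": 1.0})
        members = {"A", "C"}
        w = 0.25
        r = [5.0, 4.0, 3.0, 2.0, 1.0]  # descending-rank weights
        hit = [r[0] ** w, 0, r[2] ** w, 0, 0]
        tot = sum(hit)
        ecdf_in = np.cumsum(hit) / tot
        ecdf_out = np.cumsum([0, 1, 0, 1, 1]) / 3
        expected = float(np.sum(ecdf_in - ecdf_out))
        assert ssgsea_score(profile, members) == pytest.approx(expected, abs=1e-12)

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(6)
        profile = pd.Series(rng.normal(size=20), index=[f"g{i}" for i in range(20)])
        members = ["g3", "g7", "g11"]
        base = ssgsea_score(profile, members)
        assert ssgsea_score(np.exp(profile), members) == pytest.approx(base)
        assert ssgsea_score(profile * 10 + 3, members) == pytest.approx(base)

    def test_highest_vs_lowest_expressed_singleton(self):
        rng = np.random.default_rng(7)
        profile = pd.Series(rng.normal(size=15), index=[f"g{i}" for i in range(15)])
        hi, lo = profile.idxmax(), profile.idxmin()
        assert ssgsea_score(profile, [hi]) > ssgsea_score(profile, [lo])

    def test_joint_relabeling_invariance(self):
        profile = pd.Series({"A": 4.0, "B": 3.0, "C": 2.0, "D": 1.0})
        renamed = profile.rename({"A": "W", "B": "X", "C": "Y", "D": "Z"})
        assert ssgsea_score(profile, ["A", "C"]) == pytest.approx(
            ssgsea_score(renamed, ["W", "Y"])
        )

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_rank_based_score_ignores_scale(self, seed):
        rng = np.random.default_rng(seed)
        vals = rng.normal(size=10)
        profile = pd.Series(vals, index=[f"g{i}" for i in range(10)])
        members = [f"g{i}" for i in rng.choice(10, size=3, replace=False)]
        assert ssgsea_score(profile * 7.5, members) == pytest.approx(
            ssgsea_score(profile, members)
        )


class TestOra:
    def test_no_overlap_p_near_one(self):
        res = ora_hypergeometric({"A"}, {"B", "C"}, {"A", "B", "C", "D"})
        assert res.p_value == pytest.approx(1.0)

    def test_full_overlap_combinatorial_value(self):
        universe = {f"u{i}" for i in range(10)}
        members = set(list(universe)[:5])
        res = ora_hypergeometric(members, members, universe)
        assert res.p_value == pytest.approx(1 / 252)

    def test_set_equal_to_universe_always_one(self):
        universe = {f"u{i}" for i in range(8)}
        res = ora_hypergeometric(set(list(universe)[:3]), universe, universe)
        assert res.p_value == pytest.approx(1.0)

    def test_hit_outside_universe_rejected(self):
        with pytest.raises(ValueError):
            ora_hypergeometric({"X"}, {"A"}, {"A", "B"})


class TestCompareSsgseaGroups:
    def _profiles(self, rng, n_genes=60, n_samples=18, planted=None, shift=0.0):
        genes = [f"g{i}" for i in range(n_genes)]
        samples = [f"s{j}" for j in range(n_samples)]
        x = rng.normal(5, 1, size=(n_genes, n_samples))
        strata = pd.Series(
            ["high"] * (n_samples // 3) + ["mid"] * (n_samples // 3) + ["low"] * (n_samples // 3),
            index=samples,
        )
        if planted:
            rows = [genes.index(g) for g in planted]
            cols = [j for j, s in enumerate(samples) if strata[s] == "high"]
            x[np.ix_(rows, cols)] += shift
        return pd.DataFrame(x, index=genes, columns=samples), strata

    def test_identical_scores_not_significant(self):
        scores = pd.DataFrame(
            np.ones((2, 6)), index=["s1", "s2"], columns=[f"x{i}" for i in range(6)]
        )
        strata = pd.Series(["high"] * 3 + ["low"] * 3, index=scores.columns)
        out = compare_ssgsea_groups(scores, strata)
        assert not (out["q"] < 0.9).any()

    def test_planted_upshifted_set_detected(self):
        rng = np.random.default_rng(8)
        planted = [f"g{i}" for i in range(10)]
        collection = GeneSetCollection(
            {"planted": planted, "background": [f"g{i}" for i in range(30, 40)]}
        )
        hits = 0
        for _ in range(20):
            expr, strata = self._profiles(rng, planted=planted, shift=3.0)
            scores = ssgsea_matrix(expr, collection)
            out = compare_ssgsea_groups(scores, strata).set_index("set_name")
            hits += bool(out.loc["planted", "q"] < 0.05)
        assert hits >= 19

    def test_permuted_labels_calibrated(self):
        rng = np.random.default_rng(9)
        planted = [f"g{i}" for i in range(10)]
        collection = GeneSetCollection({"planted": planted})
        rejections = 0
        reps = 200
        for _ in range(reps):
            expr, strata = self._profiles(rng)
            perm = pd.Series(rng.permutation(strata.to_numpy()), index=strata.index)
            scores = ssgsea_matrix(expr, collection)
            out = compare_ssgsea_groups(scores, perm)
            rejections += int((out["p"] < 0.05).any())
        assert 0.01 <= rejections / reps <= 0.10

    def test_missing_group_rejected(self):
        scores = pd.DataFrame(np.ones((1, 4)), index=["s"], columns=list("abcd"))
        strata = pd.Series(["high", "high", "mid", "mid"], index=scores.columns)
        with pytest.raises(ValueError):
            compare_ssgsea_groups(scores, strata)
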