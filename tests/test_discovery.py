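"""Differential expression, JT trend selection, and the consensus cascade."""

import itertools

import numpy as np
import pandas as pd
import pytest

from hccdriver.datasets import StageDataset
from hccdriver.discovery import (
    CascadeConfig,
    compute_de,
    consensus_degs,
    consensus_trend,
    jonckheere_terpstra,
    run_cascade,
    trend_score,
    trend_table,
)
from hccdriver.synthetic import generate_multistage_cohorts


def _two_group_matrix(rng, n_genes=40, n=10, shift_gene=None, shift=0.0):
    genes = [f"G{i:03d}" for i in range(n_genes)]
    cols_a = [f"a{i}" for i in range(n)]
    cols_b = [f"b{i}" for i in range(n)]
    x = rng.normal(5.0, 0.3, size=(n_genes, 2 * n))
    if shift_gene is not None:
        x[genes.index(shift_gene), :n] += shift
    return pd.DataFrame(x, index=genes, columns=cols_a + cols_b), cols_a, cols_b


class TestComputeDE:
    def test_identical_groups_yield_no_degs(self):
        rng = np.random.default_rng(0)
        m, a, b = _two_group_matrix(rng)
        m[b] = m[a].to_numpy()
        table = compute_de(m, a, b)
        assert not table["is_deg"].any()

    def test_planted_gene_detected_with_high_power(self):
        rng = np.random.default_rng(1)
        hits = 0
        for _ in range(100):
            m, a, b = _two_group_matrix(rng, shift_gene="G000", shift=1.0)
            hits += bool(compute_de(m, a, b).loc["G000", "is_deg"])
        assert hits >= 99

    def test_fold_change_gate_blocks_sub_threshold_genes(self):
        """A minute but highly significant shift below log2(1.5) is not a DEG."""
        rng = np.random.default_rng(2)
        m, a, b = _two_group_matrix(rng, n=200, shift_gene="G000", shift=np.log2(1.4))
        table = compute_de(m, a, b, fc_threshold=1.5)
        row = table.loc["G000"]
        assert row["p_adj"] < 1e-6 and not row["is_deg"]
        assert table.loc["G000", "direction"] == "up"

    def test_threshold_monotonicity(self):
        """Loosening alpha or the fold gate never shrinks the DEG set."""
        rng = np.random.default_rng(3)
        m, a, b = _two_group_matrix(rng, shift_gene="G000", shift=1.5)
        strict = compute_de(m, a, b, fc_threshold=2.0, alpha=0.01)
        loose = compute_de(m, a, b, fc_threshold=1.2, alpha=0.10)
        assert set(strict[strict.is_deg].gene) <= set(loose[loose.is_deg].gene)

    def test_small_group_rejected(self):
        rng = np.random.default_rng(4)
        m, a, b = _two_group_matrix(rng)
        with pytest.raises(ValueError):
            compute_de(m, a[:1], b)


class TestConsensusDEGs:
    def _table(self, flags):
        return pd.DataFrame(
            {
                "gene": list(flags),
                "is_deg": [f is not None for f in flags.values()],
                "direction": [f or "up" for f in flags.values()],
            }
        )

    def test_single_cohort_identity(self):
        t = self._table({"A": "up", "B": None, "C": "down"})
        assert consensus_degs([t]) == {"A", "C"}

    def test_disjoint_sets_empty(self):
        t1 = self._table({"A": "up", "B": None})
        t2 = self._table({"A": None, "B": "up"})
        assert consensus_degs([t1, t2]) == set()

    def test_direction_conflict_excluded(self):
        t1 = self._table({"A": "up"})
        t2 = self._table({"A": "down"})
        assert consensus_degs([t1, t2]) == set()


def _brute_force_jt_sf(groups):
    """P(J >= observed) by exhaustive reassignment of the pooled values."""
    pooled = np.concatenate(groups)
    sizes = [len(g) for g in groups]

    def stat(gs):
        j = 0.0
        for i in range(len(gs)):
            for k in range(i + 1, len(gs)):
                diff = gs[k][None, :] - gs[i][:, None]
                j += (diff > 0).sum() + 0.5 * (diff == 0).sum()
        return j

    observed = stat([np.asarray(g, dtype=float) for g in groups])
    n = len(pooled)
    count = total = 0
    idx = set(range(n))
    for first in itertools.combinations(range(n), sizes[0]):
        rest1 = sorted(idx - set(first))
        for second in itertools.combinations(rest1, sizes[1]):
            third = sorted(set(rest1) - set(second))
            arrangement = [pooled[list(first)], pooled[list(second)], pooled[third]]
            total += 1
            if stat(arrangement) >= observed - 1e-9:
                count += 1
    return count / total


class TestJonckheereTerpstra:
    def test_perfect_ladder(self):
        j, z, p = jonckheere_terpstra([[1.0, 2.0], [3.0, 4.0], [5.0, 6.0]])
        assert j == 12.0
        assert p == pytest.approx(1 / 90)  # one arrangement in 6!/(2!2!2!)

    def test_decreasing_profile_has_large_increasing_p(self):
        _, _, p = jonckheere_terpstra([[5.0, 6.0], [3.0, 4.0], [1.0, 2.0]])
        assert p >= 0.5

    @pytest.mark.parametrize("sizes", [(2, 2, 2), (3, 3, 3), (2, 3, 4)])
    def test_exact_p_matches_brute_force_enumeration(self, sizes):
        rng = np.random.default_rng(sum(sizes))
        for _ in range(3):
            groups = [rng.normal(size=s) for s in sizes]
            _, _, p = jonckheere_terpstra(groups)
            assert p == pytest.approx(_brute_force_jt_sf(groups), abs=1e-12)

    def test_null_p_uniform(self):
        """Normal-approximation p-values are uniform under exchangeability."""
        from scipy.stats import kstest

        rng = np.random.default_rng(9)
        genes = 2000
        x = rng.normal(size=(genes, 60))
        samples = [f"s{i}" for i in range(60)]
        stage = pd.Series(np.repeat(["NL", "CH", "LC", "DN", "eHCC", "aHCC"], 10), index=samples)
        ds = StageDataset(
            pd.DataFrame(x, index=[f"G{i}" for i in range(genes)], columns=samples),
            stage,
            "null",
        )
        table = trend_table(ds)
        assert kstest(table["p"], "uniform").pvalue > 0.01


class TestTrendScore:
    def test_rising_gene_passes(self, tiny_stage_dataset):
        res = trend_score(tiny_stage_dataset, "RISE")
        assert res["monotone_pass"] and res["p"] < 0.05

    def test_flat_gene_fails_span_gate(self, tiny_stage_dataset):
        assert not trend_score(tiny_stage_dataset, "FLAT")["monotone_pass"]

    def test_falling_gene_fails_with_large_p(self, tiny_stage_dataset):
        res = trend_score(tiny_stage_dataset, "FALL")
        assert not res["monotone_pass"] and res["p"] >= 0.5

    def test_unknown_gene_raises(self, tiny_stage_dataset):
        with pytest.raises(KeyError):
            trend_score(tiny_stage_dataset, "NOPE")


class TestConsensusTrend:
    def _trend(self, cohort, passes, z):
        return pd.DataFrame(
            {
                "gene": list(passes),
                "cohort_id": cohort,
                "monotone_pass": list(passes.values()),
                "jt_z": [z[g] for g in passes],
            }
        )

    def test_single_cohort_identity(self):
        z = {"A": 3.0, "B": 1.0}
        t = self._trend("c1", {"A": True, "B": False}, z)
        out = consensus_trend({"c1": t})
        assert list(out["gene"]) == ["A"]

    def test_gene_missing_one_cohort_excluded_under_require_all(self):
        z = {"A": 3.0}
        t1 = self._trend("c1", {"A": True}, z)
        t2 = self._trend("c2", {"A": True}, z)
        t3 = self._trend("c3", {"A": False}, z)
        assert len(consensus_trend({"c1": t1, "c2": t2, "c3": t3})) == 0
        assert list(consensus_trend({"c1": t1, "c2": t2, "c3": t3}, require_all=False, quorum=2)["gene"]) == ["A"]

    def test_ordering_by_mean_z_then_gene(self):
        z = {"B": 2.0, "A": 2.0, "C": 5.0}
        t = self._trend("c1", {"B": True, "A": True, "C": True}, z)
        out = consensus_trend({"c1": t})
        assert list(out["gene"]) == ["C", "A", "B"]


class TestCascade:
    def test_null_configuration_empty_final_list(self):
        cohorts, _ = generate_multistage_cohorts(
            n_cohorts=4, genes=300, drivers=0, per_stage_shift=0.0, samples_per_stage=5, seed=5
        )
        result = run_cascade(cohorts[:2], cohorts[2:])
        assert result.final_genes == []

    def test_duplicated_tiers_idempotent(self):
        cohorts, _ = generate_multistage_cohorts(
            n_cohorts=2, genes=200, drivers=20, samples_per_stage=6, seed=6
        )
        result = run_cascade(cohorts, cohorts)
        assert result.final_genes == list(result.trend_consensus_a["gene"])

    def test_invariant_to_row_and_column_order(self):
        cohorts, _ = generate_multistage_cohorts(
            n_cohorts=2, genes=120, drivers=10, samples_per_stage=4, seed=7
        )
        shuffled = []
        rng = np.random.default_rng(0)
        for ds in cohorts:
            gi = rng.permutation(len(ds.genes))
            si = rng.permutation(len(ds.samples))
            shuffled.append(
                StageDataset(
                    ds.expression.iloc[gi, si],
                    ds.sample_stage.iloc[si],
                    ds.cohort_id,
                    ds.stage_order,
                )
            )
        a = run_cascade(cohorts[:1], cohorts[1:])
        b = run_cascade(shuffled[:1], shuffled[1:])
        assert a.final_genes == b.final_genes

    def test_empty_tier_rejected(self):
        cohorts, _ = generate_multistage_cohorts(
            n_cohorts=1, genes=50, drivers=5, samples_per_stage=3, seed=8
        )
        with pytest.raises(ValueError):
            run_cascade(cohorts, [])

    def test_config_validation(self):
        with pytest.raises(ValueError):
            CascadeConfig(alpha=1.5)
        with pytest.raises(ValueError):
            CascadeConfig(fc_threshold=0.5)
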