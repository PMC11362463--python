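"""Shared statistical primitives.

Everything downstream funnels its hypothesis testing through this module:
Benjamini-Hochberg adjustment, correlation, the Wilcoxon rank-sum test with an
exact small-sample branch, and the test-selection policy (Shapiro-Wilk
normality per group deciding between the parametric and rank-based branches).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

__all__ = [
    "TestResult",
    "CorrelationResult",
    "DegenerateInputError",
    "bh_adjust",
    "pearson_corr",
    "spearman_corr",
    "wilcoxon_rank_sum",
    "choose_and_run_group_test",
]


class DegenerateInputError(ValueError):
    """Raised for inputs on which the requested statistic is undefined."""


@dataclass(frozen=True)
class TestResult:
    """Outcome of a single hypothesis test.

    ``n`` records the per-group sample sizes; ``posthoc`` carries a pairwise
    comparison table when an omnibus test was followed by post hoc testing.
    """

    statistic: float
    p_value: float
    method: str
    n: tuple[int, ...]
    posthoc: pd.DataFrame | None = None


@dataclass(frozen=True)
class CorrelationResult:
    r: float
    p_value: float
    n: int
    method: str


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, capped at 1."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any(~np.isfinite(p)) or np.any(p < 0) or np.any(p > 1):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def _as_vector(x, name: str, min_n: int = 1) -> np.ndarray:
    v = np.asarray(x, dtype=float).ravel()
    if v.size < min_n:
        raise ValueError(f"{name} needs at least {min_n} observations, got {v.size}")
    if np.any(~np.isfinite(v)):
        raise ValueError(f"{name} contains non-finite values")
    return v


def _corr(x, y, method: str) -> CorrelationResult:
    xv = _as_vector(x, "x", 3)
    yv = _as_vector(y, "y", 3)
    if xv.size != yv.size:
        raise ValueError("x and y must have equal length")
    for name, v in (("x", xv), ("y", yv)):
        if np.ptp(v) == 0:
            raise DegenerateInputError(f"{name} is constant; correlation undefined")
    if method == "pearson":
        res = sps.pearsonr(xv, yv)
    else:
        res = sps.spearmanr(xv, yv)
    return CorrelationResult(float(res.statistic), float(res.pvalue), xv.size, method)


def pearson_corr(x, y) -> CorrelationResult:
    """Sample Pearson r with a two-sided p-value from the t transformation."""
    return _corr(x, y, "pearson")


def spearman_corr(x, y) -> CorrelationResult:
    return _corr(x, y, "spearman")


def wilcoxon_rank_sum(a, b, exact_below: int = 8, alternative: str = "two-sided") -> TestResult:
    """Wilcoxon rank-sum (Mann-Whitney) test.

    Uses exact enumeration when ``min(n) <= exact_below`` and the pooled sample
    is tie-free, otherwise the tie-corrected normal approximation with
    continuity correction.  The statistic is the Mann-Whitney U of the first
    sample.
    """
    av = _as_vector(a, "a")
    bv = _as_vector(b, "b")
    pooled = np.concatenate([av, bv])
    has_ties = np.unique(pooled).size < pooled.size
    method = "exact" if (min(av.size, bv.size) <= exact_below and not has_ties) else "asymptotic"
    res = sps.mannwhitneyu(av, bv, alternative=alternative, method=method)
    return TestResult(
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
        method=f"wilcoxon-rank-sum-{method}",
        n=(av.size, bv.size),
    )


def _dunn_posthoc(groups: list[np.ndarray], labels: list[str]) -> pd.DataFrame:
    """Dunn's pairwise z-tests on mean ranks after Kruskal-Wallis.

    Midranks throughout; the pooled-variance term carries the standard tie
    correction; pairwise two-sided p-values are BH-adjusted across all pairs.
    """
    pooled = np.concatenate(groups)
    n_tot = pooled.size
    ranks = sps.rankdata(pooled)
    # tie correction sum over tied groups of (t^3 - t)
    _, counts = np.unique(pooled, return_counts=True)
    tie_sum = float(np.sum(counts**3 - counts))
    var_base = n_tot * (n_tot + 1) / 12.0 - tie_sum / (12.0 * (n_tot - 1))
    mean_ranks, sizes = [], []
    pos = 0
    for g in groups:
        mean_ranks.append(ranks[pos : pos + g.size].mean())
        sizes.append(g.size)
        pos += g.size
    rows = []
    for i, j in combinations(range(len(groups)), 2):
        se = np.sqrt(var_base * (1.0 / sizes[i] + 1.0 / sizes[j]))
        z = (mean_ranks[i] - mean_ranks[j]) / se
        rows.append(
            {
                "group_a": labels[i],
                "group_b": labels[j],
                "statistic": float(z),
                "p": float(2.0 * sps.norm.sf(abs(z))),
            }
        )
    table = pd.DataFrame(rows)
    table["p_adj"] = bh_adjust(table["p"].to_numpy())
    return table


def _tukey_posthoc(groups: list[np.ndarray], labels: list[str]) -> pd.DataFrame:
    res = sps.tukey_hsd(*groups)
    rows = []
    for i, j in combinations(range(len(groups)), 2):
        rows.append(
            {
                "group_a": labels[i],
                "group_b": labels[j],
                "statistic": float(res.statistic[i, j]),
                "p": float(res.pvalue[i, j]),
                "p_adj": float(res.pvalue[i, j]),  # Tukey p is already family-wise
            }
        )
    return pd.DataFrame(rows)


def _is_normal(v: np.ndarray, alpha: float) -> bool:
    if np.ptp(v) == 0:  # Shapiro-Wilk is undefined on constant data
        return False
    return sps.shapiro(v).pvalue > alpha


def choose_and_run_group_test(
    groups,
    paired: bool = False,
    alpha_normality: float = 0.05,
    labels: list[str] | None = None,
) -> TestResult:
    """Run the normality-gated test-selection policy on >=2 groups.

    Every group is screened with Shapiro-Wilk at ``alpha_normality``.  If all
    groups look normal: Welch's t (two unpaired groups), the paired t (two
    paired groups), or one-way ANOVA with Tukey's post hoc (>2 groups).  If any
    group fails the screen: Wilcoxon rank-sum (two groups) or Kruskal-Wallis
    with Dunn's post hoc, BH-adjusted (>2 groups).
    """
    gs = [_as_vector(g, f"group {i}", 3) for i, g in enumerate(groups)]
    if len(gs) < 2:
        raise ValueError("need at least two groups")
    if labels is None:
        labels = [f"g{i}" for i in range(len(gs))]
    if paired:
        if len(gs) != 2:
            raise ValueError("paired comparison supports exactly two groups")
        if gs[0].size != gs[1].size:
            raise ValueError("paired groups must have equal sizes")
    sizes = tuple(g.size for g in gs)
    all_normal = all(_is_normal(g, alpha_normality) for g in gs)

    if all_normal:
        if len(gs) == 2:
            if paired:
                res = sps.ttest_rel(gs[0], gs[1])
                return TestResult(float(res.statistic), float(res.pvalue), "paired-t", sizes)
            res = sps.ttest_ind(gs[0], gs[1], equal_var=False)
            return TestResult(float(res.statistic), float(res.pvalue), "welch-t", sizes)
        res = sps.f_oneway(*gs)
        return TestResult(
            float(res.statistic), float(res.pvalue), "anova", sizes, _tukey_posthoc(gs, labels)
        )
    if len(gs) == 2:
        return wilcoxon_rank_sum(gs[0], gs[1])
    res = sps.kruskal(*gs)
    return TestResult(
        float(res.statistic), float(res.pvalue), "kruskal-wallis", sizes, _dunn_posthoc(gs, labels)
    )
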