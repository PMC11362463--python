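"""The staged driver-gene discovery cascade.

The cascade mirrors a multi-cohort integrative screen for genes driving
progression of hepatocellular carcinoma:

1. Per-cohort differential expression, tumor vs non-tumor stages
   (Welch's t on log2 values; BH across genes; a gene is a DEG iff
   adjusted p < alpha and |log2 fold change| >= log2(fold threshold)).
2. Cross-cohort consensus: DEG in every cohort with a consistent direction.
3. Per-cohort ordered-stage trend selection: a one-sided increasing
   Jonckheere-Terpstra test across the cohort's stage ladder, gated on
   BH-adjusted significance, non-decreasing stage means (within a tolerance
   of the pooled within-stage SD), and a minimum first-to-last span.
4. Cross-cohort trend consensus in a discovery tier, then validation of the
   surviving genes in an independent tier of cohorts.

The monotone-trend criterion is this package's deterministic, per-gene
re-statement of "serial pattern" selection: it encodes the selected property
(progressive increase with disease stage) directly rather than through
profile clustering, so every call is reproducible and unit-testable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy import stats as sps

from .datasets import STAGE_LADDER, TUMOR_STAGES, StageDataset
from .stats import bh_adjust

__all__ = [
    "CascadeConfig",
    "CascadeResult",
    "compute_de",
    "consensus_degs",
    "jonckheere_terpstra",
    "trend_score",
    "trend_table",
    "consensus_trend",
    "run_cascade",
]


# ---------------------------------------------------------------------------
# differential expression
# ---------------------------------------------------------------------------

def _resolve_groups(data, group_a, group_b):
    """Return (matrix, columns_a, columns_b) for either input convention.

    ``data`` may be a :class:`StageDataset` with ``group_a``/``group_b`` given
    as stage-label collections, or a plain genes x samples DataFrame with the
    groups given as column-label collections.
    """
    if isinstance(data, StageDataset):
        stages = data.sample_stage.astype(str)
        cols_a = data.samples[stages.isin(list(group_a)).to_numpy()]
        cols_b = data.samples[stages.isin(list(group_b)).to_numpy()]
        return data.expression, cols_a, cols_b
    matrix = data
    return matrix, pd.Index(group_a), pd.Index(group_b)


def compute_de(data, group_a, group_b, fc_threshold: float = 1.5, alpha: float = 0.05) -> pd.DataFrame:
    """Two-group differential expression on log2 values.

    Returns one row per gene with columns ``gene, log2fc, p, p_adj, direction,
    is_deg`` where ``log2fc = mean(group_a) - mean(group_b)`` and
    ``is_deg = (p_adj < alpha) & (|log2fc| >= log2(fc_threshold))``.
    """
    if fc_threshold < 1:
        raise ValueError("fc_threshold is a linear ratio and must be >= 1")
    matrix, cols_a, cols_b = _resolve_groups(data, group_a, group_b)
    if len(cols_a) < 2 or len(cols_b) < 2:
        raise ValueError("each group needs at least 2 samples")
    a = matrix[cols_a].to_numpy(dtype=float)
    b = matrix[cols_b].to_numpy(dtype=float)
    log2fc = a.mean(axis=1) - b.mean(axis=1)
    res = sps.ttest_ind(a, b, axis=1, equal_var=False)
    p = np.asarray(res.pvalue, dtype=float)
    p = np.where(np.isfinite(p), p, 1.0)  # zero-variance genes carry no evidence
    p_adj = bh_adjust(p)
    table = pd.DataFrame(
        {
            "gene": matrix.index,
            "log2fc": log2fc,
            "p": p,
            "p_adj": p_adj,
            "direction": np.where(log2fc > 0, "up", "down"),
            "is_deg": (p_adj < alpha) & (np.abs(log2fc) >= np.log2(fc_threshold)),
        }
    ).set_index("gene", drop=False)
    table.index.name = None
    return table


def consensus_degs(per_cohort: list[pd.DataFrame]) -> set[str]:
    """Genes flagged DEG in every cohort with the same direction everywhere."""
    if not per_cohort:
        raise ValueError("need at least one cohort of DEG results")
    consensus: set[str] | None = None
    for table in per_cohort:
        flagged = set(table.loc[table["is_deg"], "gene"])
        consensus = flagged if consensus is None else consensus & flagged
    assert consensus is not None
    directions = pd.concat(
        [t.loc[t["gene"].isin(consensus), ["gene", "direction"]] for t in per_cohort]
    )
    agree = directions.groupby("gene")["direction"].nunique()
    return set(agree.index[agree == 1])


# ---------------------------------------------------------------------------
# Jonckheere-Terpstra trend test
# ---------------------------------------------------------------------------

@lru_cache(maxsize=None)
def _mwu_counts(m: int, n: int) -> tuple[int, ...]:
    """Number of rank arrangements giving each Mann-Whitney U in 0..m*n."""
    if m == 0 or n == 0:
        return (1,)
    prev = _mwu_counts(m, n - 1)
    counts = np.zeros(m * n + 1, dtype=object)
    counts[: len(prev)] += np.asarray(prev, dtype=object)
    shifted = _mwu_counts(m - 1, n)
    counts[n : n + len(shifted)] += np.asarray(shifted, dtype=object)
    return tuple(int(c) for c in counts)


def _jt_exact_sf(group_sizes: list[int], j_obs: float) -> float:
    """Exact P(J >= j_obs) under exchangeability, tie-free data.

    Uses the classical decomposition of the JT statistic into sequential
    Mann-Whitney counts of each group against the union of its predecessors,
    which are mutually independent under the null; the exact null pmf is their
    convolution and coincides with exhaustive enumeration over arrangements.
    """
    pmf = np.array([1.0])
    m = group_sizes[0]
    for n in group_sizes[1:]:
        counts = np.asarray(_mwu_counts(m, n), dtype=float)
        pmf = np.convolve(pmf, counts / counts.sum())
        m += n
    support = np.arange(pmf.size)
    return float(pmf[support >= j_obs - 1e-9].sum())


def _jt_stat_and_moments(groups: list[np.ndarray]):
    """JT statistic (half-credit for ties) plus tie-corrected null moments."""
    j = 0.0
    for i in range(len(groups)):
        for k in range(i + 1, len(groups)):
            diff = groups[k][None, :] - groups[i][:, None]
            j += float((diff > 0).sum() + 0.5 * (diff == 0).sum())
    sizes = np.array([g.size for g in groups], dtype=float)
    n_tot = sizes.sum()
    pooled = np.concatenate(groups)
    _, ties = np.unique(pooled, return_counts=True)
    t = ties.astype(float)
    mean = (n_tot**2 - np.sum(sizes**2)) / 4.0
    v1 = (
        n_tot * (n_tot - 1) * (2 * n_tot + 5)
        - np.sum(sizes * (sizes - 1) * (2 * sizes + 5))
        - np.sum(t * (t - 1) * (2 * t + 5))
    ) / 72.0
    v2 = (
        np.sum(sizes * (sizes - 1) * (sizes - 2))
        * np.sum(t * (t - 1) * (t - 2))
        / (36.0 * n_tot * (n_tot - 1) * (n_tot - 2))
    )
    v3 = np.sum(sizes * (sizes - 1)) * np.sum(t * (t - 1)) / (8.0 * n_tot * (n_tot - 1))
    return j, float(mean), float(v1 + v2 + v3)


def jonckheere_terpstra(
    groups, alternative: str = "increasing", exact_max_n: int = 12
) -> tuple[float, float, float]:
    """Jonckheere-Terpstra test for an ordered (monotone) alternative.

    Parameters
    ----------
    groups : sequence of 1-D arrays
        Samples per ordered level, lowest level first.
    alternative : {"increasing", "decreasing"}
        Direction of the one-sided ordered alternative.
    exact_max_n : int
        Total-sample cutoff below which the exact tie-free null distribution
        is used; ties or larger samples fall back to the tie-corrected normal
        approximation.

    Returns
    -------
    (statistic, z, p)
    """
    gs = [np.asarray(g, dtype=float).ravel() for g in groups]
    if len(gs) < 3:
        raise ValueError("need at least 3 ordered groups")
    if any(g.size == 0 for g in gs):
        raise ValueError("empty group")
    if alternative == "decreasing":
        gs = gs[::-1]
    elif alternative != "increasing":
        raise ValueError("alternative must be 'increasing' or 'decreasing'")
    j, mean, var = _jt_stat_and_moments(gs)
    z = 0.0 if var <= 0 else (j - mean) / np.sqrt(var)
    n_tot = sum(g.size for g in gs)
    pooled = np.concatenate(gs)
    tie_free = np.unique(pooled).size == pooled.size
    if n_tot <= exact_max_n and tie_free:
        p = _jt_exact_sf([g.size for g in gs], j)
    else:
        p = float(sps.norm.sf(z))
    return j, float(z), p


# ---------------------------------------------------------------------------
# trend scoring
# ---------------------------------------------------------------------------

def _stage_arrays(dataset: StageDataset) -> tuple[list[str], list[np.ndarray]]:
    stages = dataset.stages_present
    if len(stages) < 3:
        raise ValueError(f"cohort {dataset.cohort_id!r} has <3 represented stages")
    return stages, dataset.stage_groups()


def trend_table(
    dataset: StageDataset,
    alpha: float = 0.05,
    span_min: float = float(np.log2(1.5)),
    tolerance: float = 0.1,
    exact_max_n: int = 12,
) -> pd.DataFrame:
    """Monotone-trend statistics for every gene of one cohort.

    Columns: ``gene, cohort_id, jt_statistic, jt_z, p, q, span,
    monotone_pass`` plus one ``mean_<stage>`` column per represented stage.
    ``monotone_pass`` requires BH-adjusted q < alpha, an (approximately)
    non-decreasing stage-mean profile — no adjacent-stage dip larger than
    ``tolerance`` times the observed first-to-last span, strict when the span
    is non-positive — and a span of at least ``span_min`` log2 units.  The
    span-relative dip allowance rejects rise-then-fall shapes while tolerating
    sampling noise on the stage means of a genuinely rising gene.
    """
    stages, cols = _stage_arrays(dataset)
    x = dataset.expression.to_numpy(dtype=float)
    n_genes = x.shape[0]
    n_tot = sum(c.size for c in cols)

    # pairwise greater-than counts, vectorized over genes
    j = np.zeros(n_genes)
    for i in range(len(cols)):
        xi = x[:, cols[i]]
        for k in range(i + 1, len(cols)):
            xk = x[:, cols[k]]
            diff = xk[:, None, :] - xi[:, :, None]
            j += (diff > 0).sum(axis=(1, 2)) + 0.5 * (diff == 0).sum(axis=(1, 2))

    zs = np.empty(n_genes)
    ps = np.empty(n_genes)
    use_exact = n_tot <= exact_max_n
    sizes = [c.size for c in cols]
    for g in range(n_genes):
        groups = [x[g, c] for c in cols]
        _, mean, var = _jt_stat_and_moments(groups)
        zs[g] = 0.0 if var <= 0 else (j[g] - mean) / np.sqrt(var)
        pooled = x[g, np.concatenate(cols)]
        if use_exact and np.unique(pooled).size == pooled.size:
            ps[g] = _jt_exact_sf(sizes, j[g])
        else:
            ps[g] = sps.norm.sf(zs[g])

    means = np.column_stack([x[:, c].mean(axis=1) for c in cols])
    steps = np.diff(means, axis=1)
    span = means[:, -1] - means[:, 0]
    dip_allowance = tolerance * np.maximum(span, 0.0)
    nondecreasing = (steps >= -dip_allowance[:, None]).all(axis=1)
    q = bh_adjust(ps)
    table = pd.DataFrame(
        {
            "gene": dataset.genes,
            "cohort_id": dataset.cohort_id,
            "jt_statistic": j,
            "jt_z": zs,
            "p": ps,
            "q": q,
            "span": span,
            "monotone_pass": (q < alpha) & nondecreasing & (span >= span_min),
        }
    )
    for idx, stage in enumerate(stages):
        table[f"mean_{stage}"] = means[:, idx]
    return table.set_index(pd.Index(table["gene"]))


def trend_score(
    dataset: StageDataset,
    gene: str,
    alpha: float = 0.05,
    span_min: float = float(np.log2(1.5)),
    tolerance: float = 0.1,
) -> pd.Series:
    """Trend statistics for a single gene (q = p, no across-gene adjustment)."""
    if gene not in dataset.genes:
        raise KeyError(f"gene {gene!r} not in cohort {dataset.cohort_id!r}")
    stages, cols = _stage_arrays(dataset)
    x = dataset.expression.loc[gene].to_numpy(dtype=float)
    groups = [x[c] for c in cols]
    j, z, p = jonckheere_terpstra(groups)
    means = np.array([g.mean() for g in groups])
    span = float(means[-1] - means[0])
    nondecr = bool((np.diff(means) >= -tolerance * max(span, 0.0)).all())
    out = {
        "gene": gene,
        "cohort_id": dataset.cohort_id,
        "jt_statistic": j,
        "jt_z": z,
        "p": p,
        "q": p,
        "span": span,
        "monotone_pass": bool(p < alpha and nondecr and span >= span_min),
    }
    for stage, m in zip(stages, means):
        out[f"mean_{stage}"] = float(m)
    return pd.Series(out)


def consensus_trend(
    per_cohort_trends: dict[str, pd.DataFrame],
    require_all: bool = True,
    quorum: int | None = None,
) -> pd.DataFrame:
    """Cross-cohort consensus of monotone-trend calls.

    Keeps genes passing in all cohorts (``require_all``) or in at least
    ``quorum`` cohorts, ordered by mean JT z-score descending with ties broken
    lexicographically by gene identifier.  Returns columns
    ``gene, n_pass, mean_jt_z``.
    """
    if not per_cohort_trends:
        raise ValueError("need at least one cohort of trend results")
    tables = list(per_cohort_trends.values())
    passes = pd.concat(
        [t[["gene", "monotone_pass", "jt_z"]] for t in tables], ignore_index=True
    )
    agg = passes.groupby("gene").agg(
        n_pass=("monotone_pass", "sum"), mean_jt_z=("jt_z", "mean")
    )
    need = len(tables) if require_all else (quorum if quorum is not None else 1)
    kept = agg[agg["n_pass"] >= need].reset_index()
    kept = kept.sort_values(
        ["mean_jt_z", "gene"], ascending=[False, True], kind="stable"
    ).reset_index(drop=True)
    return kept


# ---------------------------------------------------------------------------
# full cascade
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CascadeConfig:
    """Thresholds and gates of the discovery cascade."""

    alpha: float = 0.05
    fc_threshold: float = 1.5
    span_min: float = float(np.log2(1.5))
    tolerance: float = 0.1
    tumor_stages: tuple[str, ...] = TUMOR_STAGES
    stage_order: tuple[str, ...] = STAGE_LADDER

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")
        if self.fc_threshold < 1:
            raise ValueError("fc_threshold must be >= 1")
        if self.tolerance < 0 or self.span_min < 0:
            raise ValueError("tolerance and span_min must be >= 0")


@dataclass
class CascadeResult:
    """Final gene list plus every intermediate table of the cascade."""

    final_genes: list[str]
    deg_tables: dict[str, pd.DataFrame]
    deg_consensus: set[str]
    trend_tables_a: dict[str, pd.DataFrame]
    trend_consensus_a: pd.DataFrame
    trend_tables_b: dict[str, pd.DataFrame]
    final_table: pd.DataFrame
    config: CascadeConfig = field(default_factory=CascadeConfig)


def run_cascade(
    cohorts_tier_a: list[StageDataset],
    cohorts_tier_b: list[StageDataset],
    config: CascadeConfig | None = None,
) -> CascadeResult:
    """Run the full discovery cascade.

    Tier A (discovery): per-cohort DE (tumor vs non-tumor stages) ->
    direction-consistent DEG consensus -> per-cohort monotone trend on the
    consensus genes -> all-cohort trend consensus.  Tier B (validation): the
    surviving genes must pass the trend criterion in every tier-B cohort.
    """
    cfg = config or CascadeConfig()
    if not cohorts_tier_a or not cohorts_tier_b:
        raise ValueError("need at least one cohort in each tier")

    nontumor = tuple(s for s in cfg.stage_order if s not in cfg.tumor_stages)
    deg_tables = {
        ds.cohort_id: compute_de(ds, cfg.tumor_stages, nontumor, cfg.fc_threshold, cfg.alpha)
        for ds in cohorts_tier_a
    }
    deg_set = consensus_degs(list(deg_tables.values()))

    empty_trend = pd.DataFrame(
        columns=["gene", "cohort_id", "jt_statistic", "jt_z", "p", "q", "span", "monotone_pass"]
    )

    def _trend(ds: StageDataset, genes: set[str]) -> pd.DataFrame:
        sub = StageDataset(
            ds.expression.loc[sorted(genes & set(ds.genes))],
            ds.sample_stage,
            ds.cohort_id,
            ds.stage_order,
        )
        return trend_table(sub, cfg.alpha, cfg.span_min, cfg.tolerance)

    if deg_set:
        trend_a = {ds.cohort_id: _trend(ds, deg_set) for ds in cohorts_tier_a}
        cons_a = consensus_trend(trend_a, require_all=True)
    else:
        trend_a = {ds.cohort_id: empty_trend.copy() for ds in cohorts_tier_a}
        cons_a = pd.DataFrame(columns=["gene", "n_pass", "mean_jt_z"])
    genes_a = set(cons_a["gene"]) if len(cons_a) else set()

    if genes_a:
        trend_b = {ds.cohort_id: _trend(ds, genes_a) for ds in cohorts_tier_b}
        cons_b = consensus_trend(trend_b, require_all=True)
        final = cons_b
    else:
        trend_b = {}
        final = pd.DataFrame(columns=["gene", "n_pass", "mean_jt_z"])

    return CascadeResult(
        final_genes=list(final["gene"]),
        deg_tables=deg_tables,
        deg_consensus=deg_set,
        trend_tables_a=trend_a,
        trend_consensus_a=cons_a,
        trend_tables_b=trend_b,
        final_table=final,
        config=cfg,
    )
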