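"""Gene-set scoring: preranked GSEA, single-sample GSEA, and over-representation.

The preranked enrichment score (ES) is the extremum of a weighted
Kolmogorov-Smirnov running sum down a ranked gene list: genes in the set
increment the sum proportionally to ``|score|**weight`` (normalized to sum to
1 over set members), genes outside decrement it by ``1/(N - n_set)``, so the
running sum — and hence |ES| — is bounded by 1.  Significance comes from
seeded gene-label permutations, and NES divides ES by the mean |permuted ES|
of matching sign.

The single-sample score (ssGSEA) ranks the genes of one profile by
expression, weights in-set positions by ``rank**weight``, and sums the
running difference between the weighted in-set ECDF and the uniform
out-of-set ECDF over all positions; it is deterministic and depends on the
profile only through ranks.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .stats import TestResult, bh_adjust, wilcoxon_rank_sum

__all__ = [
    "GeneSetCollection",
    "EnrichmentResult",
    "rank_genes_by_log2fc",
    "preranked_gsea",
    "preranked_gsea_collection",
    "ssgsea_score",
    "ssgsea_matrix",
    "ora_hypergeometric",
    "ora_collection",
    "compare_ssgsea_groups",
]


@dataclass
class GeneSetCollection:
    """Named gene sets (flat lists; duplicates within a set removed upstream)."""

    sets: dict[str, list[str]]
    source: str = ""

    def __post_init__(self) -> None:
        for name, genes in self.sets.items():
            if len(genes) < 1:
                raise ValueError(f"gene set {name!r} is empty")
            if len(set(genes)) != len(genes):
                raise ValueError(f"gene set {name!r} contains duplicate genes")

    def __iter__(self):
        return iter(self.sets.items())

    def __len__(self) -> int:
        return len(self.sets)


@dataclass(frozen=True)
class EnrichmentResult:
    set_name: str
    es: float
    nes: float | None
    p: float
    q: float
    leading_edge: tuple[str, ...]


def rank_genes_by_log2fc(de_table: pd.DataFrame) -> pd.Series:
    """Order a DE table by descending log2 fold change.

    Ties are broken lexicographically by gene identifier, so the ranking is
    invariant to the input row order.  Returns a Series of scores indexed by
    gene, in rank order.
    """
    if de_table["gene"].duplicated().any():
        dup = de_table.loc[de_table["gene"].duplicated(), "gene"].iloc[0]
        raise ValueError(f"duplicate gene entry in DE table: {dup!r}")
    ordered = de_table.sort_values(
        ["log2fc", "gene"], ascending=[False, True], kind="stable"
    )
    return pd.Series(ordered["log2fc"].to_numpy(), index=ordered["gene"].to_numpy(), name="score")


def _running_es(scores: np.ndarray, in_set: np.ndarray, weight: float):
    """(ES, extremum position, running sum) of the weighted KS walk."""
    n = scores.size
    n_hit = int(in_set.sum())
    hit_w = np.abs(scores) ** weight
    hit_w = np.where(in_set, hit_w, 0.0)
    total = hit_w.sum()
    if total == 0:  # all in-set scores are zero: fall back to equal weights
        hit_w = in_set.astype(float)
        total = hit_w.sum()
    steps = hit_w / total - (~in_set) / (n - n_hit)
    running = np.cumsum(steps)
    peak = int(np.argmax(np.abs(running)))
    return float(running[peak]), peak, running


def _validate_ranking(ranking: pd.Series, gene_set) -> tuple[np.ndarray, np.ndarray, list[str]]:
    genes = list(ranking.index)
    if len(set(genes)) != len(genes):
        raise ValueError("ranking contains duplicate genes")
    members = set(gene_set)
    in_set = np.fromiter((g in members for g in genes), dtype=bool, count=len(genes))
    n_hit = int(in_set.sum())
    if n_hit == 0:
        raise ValueError("gene set has no overlap with the ranking")
    if n_hit == len(genes):
        raise ValueError("gene set equals the full ranked universe")
    return np.asarray(ranking.to_numpy(), dtype=float), in_set, genes


def preranked_gsea(
    ranking: pd.Series,
    gene_set,
    weight: float = 1.0,
    n_perm: int = 1000,
    seed: int = 0,
) -> EnrichmentResult:
    """Preranked GSEA of one gene set against an ordered, scored gene list.

    ``ranking`` is a Series of scores indexed by gene, already ordered (use
    :func:`rank_genes_by_log2fc`).  The permutation p-value permutes gene
    labels: each permutation re-draws the set's positions uniformly at
    random.  NES = ES / mean(|permuted ES| of matching sign) and is ``None``
    when fewer than 10 permutations land on that sign.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    scores, in_set, genes = _validate_ranking(ranking, gene_set)
    n = scores.size
    n_hit = int(in_set.sum())
    es, peak, _ = _running_es(scores, in_set, weight)

    rng = np.random.default_rng(np.random.SeedSequence(seed))
    perm_es = np.empty(n_perm)
    for b in range(n_perm):
        mask = np.zeros(n, dtype=bool)
        mask[rng.choice(n, size=n_hit, replace=False)] = True
        perm_es[b] = _running_es(scores, mask, weight)[0]
    same_sign = perm_es >= 0 if es >= 0 else perm_es < 0
    n_same = int(same_sign.sum())
    more_extreme = int((np.abs(perm_es[same_sign]) >= abs(es)).sum())
    p = (1 + more_extreme) / (1 + n_same) if n_same else 1.0
    nes = float(es / np.abs(perm_es[same_sign]).mean()) if n_same >= 10 else None

    if es >= 0:
        leading = [g for k, g in enumerate(genes) if in_set[k] and k <= peak]
    else:
        leading = [g for k, g in enumerate(genes) if in_set[k] and k >= peak]
    return EnrichmentResult(
        set_name="", es=es, nes=nes, p=float(p), q=float(p), leading_edge=tuple(leading)
    )


def preranked_gsea_collection(
    ranking: pd.Series,
    collection: GeneSetCollection,
    weight: float = 1.0,
    n_perm: int = 1000,
    seed: int = 0,
) -> pd.DataFrame:
    """Preranked GSEA over a collection, with BH adjustment across sets."""
    rows = []
    subseeds = np.random.SeedSequence(seed).generate_state(len(collection)) % (2**31)
    for (name, genes), sub in zip(sorted(collection.sets.items()), subseeds):
        res = preranked_gsea(ranking, genes, weight, n_perm, int(sub))
        rows.append(
            {
                "set_name": name,
                "es": res.es,
                "nes": res.nes,
                "p": res.p,
                "leading_edge": ";".join(res.leading_edge),
            }
        )
    table = pd.DataFrame(rows)
    table["q"] = bh_adjust(table["p"].to_numpy())
    return table[["set_name", "es", "nes", "p", "q", "leading_edge"]]


def ssgsea_score(profile: pd.Series, gene_set, weight: float = 0.25) -> float:
    """Single-sample enrichment score of one gene set in one profile.

    Rank-based and deterministic: expression ties are broken lexicographically
    by gene identifier.  No cross-set normalization is applied (the raw
    running-sum total is returned).
    """
    if profile.isna().any():
        raise ValueError("profile contains missing values")
    if profile.index.has_duplicates:
        raise ValueError("profile contains duplicate genes")
    members = set(gene_set)
    order = profile.to_frame("value")
    order["gene"] = order.index
    order = order.sort_values(["value", "gene"], ascending=[False, True], kind="stable")
    genes = list(order.index)
    n = len(genes)
    in_set = np.fromiter((g in members for g in genes), dtype=bool, count=n)
    n_hit = int(in_set.sum())
    if n_hit == 0:
        raise ValueError("gene set has no overlap with the profile")
    if n_hit == n:
        raise ValueError("gene set equals the full profile")
    ranks = np.arange(n, 0, -1, dtype=float)  # highest expression gets rank N
    w = np.where(in_set, ranks**weight, 0.0)
    ecdf_in = np.cumsum(w) / w.sum()
    ecdf_out = np.cumsum((~in_set).astype(float)) / (n - n_hit)
    return float(np.sum(ecdf_in - ecdf_out))


def ssgsea_matrix(
    expression: pd.DataFrame, collection: GeneSetCollection, weight: float = 0.25
) -> pd.DataFrame:
    """ssGSEA scores for every (set, sample): sets in rows, samples in columns."""
    out = {
        name: {
            sample: ssgsea_score(expression[sample], genes, weight)
            for sample in expression.columns
        }
        for name, genes in sorted(collection.sets.items())
    }
    return pd.DataFrame(out).T.loc[sorted(collection.sets), expression.columns]


def ora_hypergeometric(hit_list, gene_set, universe) -> TestResult:
    """Upper-tail hypergeometric over-representation test."""
    hits = set(hit_list)
    uni = set(universe)
    if not hits <= uni:
        outside = sorted(hits - uni)[0]
        raise ValueError(f"hit gene outside the universe: {outside!r}")
    members = set(gene_set) & uni
    if not members:
        raise ValueError("gene set does not intersect the universe")
    k = len(hits & members)
    p = float(sps.hypergeom.sf(k - 1, len(uni), len(members), len(hits)))
    return TestResult(
        statistic=float(k),
        p_value=min(p, 1.0),
        method="hypergeometric",
        n=(len(hits), len(members), len(uni)),
    )


def ora_collection(hit_list, collection: GeneSetCollection, universe) -> pd.DataFrame:
    """Over-representation across a collection with BH adjustment."""
    rows = []
    for name, genes in sorted(collection.sets.items()):
        res = ora_hypergeometric(hit_list, genes, universe)
        rows.append({"set_name": name, "overlap": int(res.statistic), "p": res.p_value})
    table = pd.DataFrame(rows)
    table["q"] = bh_adjust(table["p"].to_numpy())
    return table


def compare_ssgsea_groups(scores: pd.DataFrame, strata: pd.Series) -> pd.DataFrame:
    """Wilcoxon rank-sum of per-sample ssGSEA scores, high vs low stratum.

    ``scores`` is sets x samples (from :func:`ssgsea_matrix`); ``strata`` maps
    sample -> {"high", "mid", "low"}.  BH adjustment across sets.
    """
    strata = strata.reindex(scores.columns)
    high = scores.columns[(strata == "high").to_numpy()]
    low = scores.columns[(strata == "low").to_numpy()]
    if len(high) < 2 or len(low) < 2:
        raise ValueError("both the high and low strata need >= 2 samples")
    rows = []
    for name in scores.index:
        res = wilcoxon_rank_sum(scores.loc[name, high], scores.loc[name, low])
        rows.append(
            {
                "set_name": name,
                "statistic": res.statistic,
                "p": res.p_value,
                "n_high": len(high),
                "n_low": len(low),
            }
        )
    table = pd.DataFrame(rows)
    table["q"] = bh_adjust(table["p"].to_numpy())
    return table[["set_name", "statistic", "p", "q", "n_high", "n_low"]]
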