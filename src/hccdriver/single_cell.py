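"""Pseudo-bulk aggregation and focal-gene stratification of single-cell counts.

"Pseudo-bulk" collapses a cells x genes count matrix into one summed profile
per sample, after which samples are stratified by the aggregated expression of
a focal gene into high (top quartile), mid, and low (bottom quartile) strata.
The positivity proportion is the fraction of cells with at least one count of
the focal gene, per phenotype.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["CellMatrix", "aggregate_expression", "stratify_quartiles", "positivity_proportion"]


@dataclass
class CellMatrix:
    """Non-negative integer counts (cells x genes) with per-cell labels."""

    counts: pd.DataFrame
    cell_sample: pd.Series
    cell_phenotype: pd.Series

    def __post_init__(self) -> None:
        vals = self.counts.to_numpy()
        if not np.issubdtype(vals.dtype, np.integer):
            if not np.all(np.mod(vals, 1) == 0):
                raise ValueError("counts must be integers")
            self.counts = self.counts.astype(np.int64)
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("counts must be >= 0")
        for name, series in (("sample", self.cell_sample), ("phenotype", self.cell_phenotype)):
            if set(series.index) != set(self.counts.index):
                raise ValueError(f"cell {name} labels do not match the count matrix cells")
        self.cell_sample = self.cell_sample.reindex(self.counts.index)
        self.cell_phenotype = self.cell_phenotype.reindex(self.counts.index)

    @property
    def genes(self) -> pd.Index:
        return self.counts.columns

    @property
    def cells(self) -> pd.Index:
        return self.counts.index


def aggregate_expression(cells: CellMatrix, normalize: str | None = None) -> pd.DataFrame:
    """Sum counts over cells per sample, giving a samples x genes matrix.

    ``normalize="cpm"`` rescales each aggregated profile to counts per million
    (the input expected by the single-sample enrichment path); the default is
    the raw-count sum.
    """
    sizes = cells.cell_sample.value_counts()
    if (sizes == 0).any():
        raise ValueError("every sample must have at least one cell")
    agg = cells.counts.groupby(cells.cell_sample, sort=True, observed=True).sum()
    agg.index.name = "sample"
    if normalize is None:
        return agg
    if normalize == "cpm":
        totals = agg.sum(axis=1)
        if (totals == 0).any():
            raise ValueError("cannot CPM-normalize a sample with zero total counts")
        return agg.div(totals, axis=0) * 1e6
    raise ValueError(f"unknown normalization {normalize!r}")


def stratify_quartiles(aggregated: pd.Series) -> pd.DataFrame:
    """Assign each sample to a high/mid/low stratum by focal-gene expression.

    Samples are sorted by value descending; the top ``ceil(n/4)`` samples are
    "high", the bottom ``floor(n/4)`` are "low", and the remainder "mid".
    Ties are broken by the stable input order, so the assignment is a
    deterministic exact partition for any n >= 4.
    """
    values = pd.Series(aggregated, dtype=float)
    n = len(values)
    if n < 4:
        raise ValueError("quartile stratification needs at least 4 samples")
    order = np.argsort(-values.to_numpy(), kind="stable")
    n_high = math.ceil(n / 4)
    n_low = math.floor(n / 4)
    strata = np.empty(n, dtype=object)
    strata[order[:n_high]] = "high"
    strata[order[n_high : n - n_low]] = "mid"
    strata[order[n - n_low :]] = "low"
    return pd.DataFrame(
        {"sample": values.index, "stratum": strata, "aggregated_value": values.to_numpy()}
    )


def positivity_proportion(cells: CellMatrix, gene: str) -> pd.Series:
    """Fraction of cells with count >= 1 for ``gene``, per phenotype."""
    if gene not in cells.genes:
        raise KeyError(f"gene {gene!r} not in the count matrix")
    positive = (cells.counts[gene] >= 1).astype(float)
    out = positive.groupby(cells.cell_phenotype, sort=True, observed=True).mean()
    out.name = f"{gene}_positive_fraction"
    return out
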