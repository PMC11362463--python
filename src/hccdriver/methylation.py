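"""CpG-level methylation biomarker evaluation.

Beta values are the fraction methylated at a CpG, in [0, 1], recorded as
paired tumor (T) / adjacent non-tumor (NT) measurements per patient.  The
module tests per-CpG differential methylation (paired t on T - NT), calls
per-patient hypomethylation, correlates methylation with expression, and
evaluates diagnostic performance by ROC AUC with a DeLong 95% CI.  For a
tumor-hypomethylated marker the tumor class scores *lower*, so the ROC takes
an explicit orientation flag instead of silently reporting 1 - AUC.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .stats import CorrelationResult, TestResult, bh_adjust, pearson_corr

__all__ = [
    "RocResult",
    "differential_methylation",
    "differential_methylation_table",
    "call_hypomethylation",
    "roc_auc",
    "roc_curve_table",
    "methylation_expression_association",
]

_REQUIRED = ("cpg", "patient", "beta_nt", "beta_t")


def _check_records(records: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in _REQUIRED if c not in records.columns]
    if missing:
        raise ValueError(f"beta table is missing columns: {missing}")
    for col in ("beta_nt", "beta_t"):
        v = records[col].to_numpy(dtype=float)
        if np.any(np.isnan(v)):
            raise ValueError(f"{col} contains missing values (unpaired record?)")
        if np.any((v < 0) | (v > 1)):
            raise ValueError(f"{col} outside [0, 1]")
    if records.duplicated(["cpg", "patient"]).any():
        raise ValueError("more than one record per (cpg, patient)")
    return records


def differential_methylation(records: pd.DataFrame, cpg: str) -> tuple[TestResult, float]:
    """Paired t-test of tumor vs non-tumor beta for one CpG.

    Returns the test result and ``delta_beta = mean(beta_t - beta_nt)``
    (negative for tumor hypomethylation).
    """
    records = _check_records(records)
    sub = records[records["cpg"] == cpg]
    if len(sub) < 3:
        raise ValueError(f"CpG {cpg!r} has <3 paired records")
    diff = sub["beta_t"].to_numpy(dtype=float) - sub["beta_nt"].to_numpy(dtype=float)
    if np.ptp(diff) == 0:
        # identical pairs carry no evidence against the null
        return TestResult(0.0, 1.0, "paired-t", (len(sub),)), float(diff.mean())
    res = sps.ttest_rel(sub["beta_t"], sub["beta_nt"])
    return (
        TestResult(float(res.statistic), float(res.pvalue), "paired-t", (len(sub),)),
        float(diff.mean()),
    )


def differential_methylation_table(records: pd.DataFrame) -> pd.DataFrame:
    """Collection-wide paired testing with BH across CpGs.

    Columns: ``cpg, delta_beta, statistic, p, q, n``.
    """
    records = _check_records(records)
    rows = []
    for cpg in sorted(records["cpg"].unique()):
        res, delta = differential_methylation(records, cpg)
        rows.append(
            {"cpg": cpg, "delta_beta": delta, "statistic": res.statistic, "p": res.p_value,
             "n": res.n[0]}
        )
    table = pd.DataFrame(rows)
    table["q"] = bh_adjust(table["p"].to_numpy())
    return table[["cpg", "delta_beta", "statistic", "p", "q", "n"]]


def call_hypomethylation(
    records: pd.DataFrame, cpg: str, margin: float = 0.0
) -> tuple[pd.Series, float]:
    """Flag patients whose tumor beta is below the paired non-tumor beta.

    A patient is hypomethylated iff ``beta_t < beta_nt - margin``.  Returns the
    per-patient boolean flags and the cohort fraction flagged.
    """
    if margin < 0:
        raise ValueError("margin must be >= 0")
    records = _check_records(records)
    sub = records[records["cpg"] == cpg]
    if sub.empty:
        raise KeyError(f"no records for CpG {cpg!r}")
    flags = pd.Series(
        (sub["beta_t"] < sub["beta_nt"] - margin).to_numpy(),
        index=pd.Index(sub["patient"], name="patient"),
        name="hypomethylated",
    )
    return flags, float(flags.mean())


@dataclass(frozen=True)
class RocResult:
    auc: float
    ci_low: float
    ci_high: float
    n_pos: int
    n_neg: int


def roc_auc(
    scores,
    labels,
    positive_label="T",
    lower_is_positive: bool = False,
) -> RocResult:
    """ROC AUC by the Mann-Whitney identity with a DeLong 95% CI.

    AUC is the fraction of (positive, negative) pairs where the positive
    outscores the negative, with half credit for ties.  With
    ``lower_is_positive`` the score sign is flipped first (tumor-hypomethylated
    markers score lower in the positive class).  The CI uses DeLong's
    structural-component variance and is clipped to [0, 1]; with fewer than
    two observations in either class the CI degenerates to [0, 1].
    """
    s = np.asarray(scores, dtype=float)
    lab = np.asarray(labels)
    if s.size != lab.size:
        raise ValueError("scores and labels must have equal length")
    if lower_is_positive:
        s = -s
    pos = s[lab == positive_label]
    neg = s[lab != positive_label]
    if pos.size == 0 or neg.size == 0:
        raise ValueError("both classes must be present")
    psi = (pos[:, None] > neg[None, :]).astype(float) + 0.5 * (pos[:, None] == neg[None, :])
    auc = float(psi.mean())
    v10 = psi.mean(axis=1)  # per-positive placement values
    v01 = psi.mean(axis=0)  # per-negative placement values
    if pos.size > 1 and neg.size > 1:
        var = v10.var(ddof=1) / pos.size + v01.var(ddof=1) / neg.size
        half = 1.959963984540054 * float(np.sqrt(var))
        lo, hi = max(0.0, auc - half), min(1.0, auc + half)
    else:
        lo, hi = 0.0, 1.0
    return RocResult(auc=auc, ci_low=lo, ci_high=hi, n_pos=pos.size, n_neg=neg.size)


def roc_curve_table(scores, labels, positive_label="T", lower_is_positive: bool = False) -> pd.DataFrame:
    """Threshold / sensitivity / specificity table for the ROC curve."""
    from sklearn.metrics import roc_curve

    s = np.asarray(scores, dtype=float)
    if lower_is_positive:
        s = -s
    y = (np.asarray(labels) == positive_label).astype(int)
    fpr, tpr, thr = roc_curve(y, s)
    return pd.DataFrame({"threshold": thr, "sensitivity": tpr, "specificity": 1.0 - fpr})


def methylation_expression_association(beta, expression) -> CorrelationResult:
    """Pearson correlation of beta vs expression; the sign is reported as-is."""
    return pearson_corr(beta, expression)
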