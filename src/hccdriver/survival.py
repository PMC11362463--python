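"""Kaplan-Meier estimation, log-rank testing, and two-group hazard ratios.

Patients are dichotomized into "high" and "low" groups by an expression or
methylation value; the survival contrast is summarized by the product-limit
curves, the log-rank chi-square, and the hazard ratio from a univariate Cox
proportional-hazards fit (Breslow tie handling) with a Wald 95% CI on the
log-hazard scale.  Estimation is delegated to lifelines.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test as _ll_logrank

from .stats import TestResult

__all__ = [
    "SurvivalFitResult",
    "dichotomize",
    "km_estimate",
    "logrank_test",
    "cox_binary_hr",
]


@dataclass(frozen=True)
class SurvivalFitResult:
    """Hazard ratio (high vs low) with Wald CI and the log-rank test."""

    hr: float
    ci_low: float
    ci_high: float
    logrank_chi2: float
    logrank_p: float
    n: tuple[int, int]
    n_events: int


def dichotomize(values: pd.Series, rule: str = "median", threshold: float | None = None) -> pd.Series:
    """Split patients into high/low groups by a scalar marker.

    Rules: ``median`` (ties at the median go to "low"), ``threshold`` ("high"
    iff value > threshold), ``quartile`` (top quartile "high", bottom quartile
    "low", remainder "mid").  The labels are invariant to positive affine
    rescaling of the values.
    """
    v = pd.Series(values, dtype=float)
    if len(v) < 4:
        raise ValueError("dichotomization needs at least 4 patients")
    if rule == "median":
        if v.nunique() == 1:
            raise ValueError("all values identical; median split is undefined")
        cut = float(v.median())
        labels = np.where(v.to_numpy() > cut, "high", "low")
    elif rule == "threshold":
        if threshold is None:
            raise ValueError("threshold rule requires a threshold")
        labels = np.where(v.to_numpy() > threshold, "high", "low")
    elif rule == "quartile":
        lo, hi = v.quantile(0.25), v.quantile(0.75)
        labels = np.where(v.to_numpy() > hi, "high", np.where(v.to_numpy() <= lo, "low", "mid"))
    else:
        raise ValueError(f"unknown rule {rule!r}")
    return pd.Series(labels, index=v.index, name="group")


def _check_records(records: pd.DataFrame) -> pd.DataFrame:
    for col in ("time", "event"):
        if col not in records.columns:
            raise ValueError(f"survival table is missing column {col!r}")
    if (records["time"].to_numpy(dtype=float) < 0).any():
        raise ValueError("negative survival times")
    if not set(records["event"].unique()) <= {0, 1}:
        raise ValueError("event flags must be 0 or 1")
    return records


def km_estimate(records: pd.DataFrame) -> dict[str, pd.DataFrame]:
    """Product-limit survival step function per group.

    Returns, per group label (or "all" when no ``group`` column is present), a
    table with columns ``time`` and ``survival`` — right-continuous, starting
    at S(0) = 1.
    """
    records = _check_records(records)
    groups = (
        {str(g): sub for g, sub in records.groupby("group", sort=True)}
        if "group" in records.columns
        else {"all": records}
    )
    out = {}
    for label, sub in groups.items():
        kmf = KaplanMeierFitter()
        kmf.fit(sub["time"], event_observed=sub["event"])
        sf = kmf.survival_function_
        out[label] = pd.DataFrame(
            {"time": sf.index.to_numpy(dtype=float), "survival": sf.iloc[:, 0].to_numpy()}
        )
    return out


def logrank_test(records: pd.DataFrame) -> TestResult:
    """Two-group log-rank test (O - E with hypergeometric variance, 1 df)."""
    records = _check_records(records)
    if "group" not in records.columns:
        raise ValueError("log-rank test needs a 'group' column")
    labels = sorted(records["group"].unique())
    if len(labels) != 2:
        raise ValueError(f"log-rank test needs exactly two groups, got {labels}")
    if records["event"].sum() < 1:
        raise ValueError("log-rank test needs at least one event")
    a = records[records["group"] == labels[0]]
    b = records[records["group"] == labels[1]]
    res = _ll_logrank(a["time"], b["time"], event_observed_A=a["event"], event_observed_B=b["event"])
    return TestResult(
        statistic=float(res.test_statistic),
        p_value=float(res.p_value),
        method="logrank",
        n=(len(a), len(b)),
    )


def _breslow_tables(time: np.ndarray, event: np.ndarray, x: np.ndarray):
    """Per-event-time risk/death counts by group for the Breslow likelihood."""
    event_times = np.unique(time[event == 1])
    d = np.empty(event_times.size)  # deaths at t
    d1 = np.empty(event_times.size)  # deaths at t in the high group
    r0 = np.empty(event_times.size)  # at risk, low group
    r1 = np.empty(event_times.size)  # at risk, high group
    for k, t in enumerate(event_times):
        at_risk = time >= t
        dying = (time == t) & (event == 1)
        d[k] = dying.sum()
        d1[k] = (dying & (x == 1)).sum()
        r0[k] = (at_risk & (x == 0)).sum()
        r1[k] = (at_risk & (x == 1)).sum()
    return d, d1, r0, r1


def cox_binary_hr(
    records: pd.DataFrame,
    high_label: str = "high",
    tol: float = 1e-8,
    max_iter: int = 50,
) -> SurvivalFitResult:
    """Univariate Cox hazard ratio of the high vs low group.

    Maximizes the Breslow-ties partial likelihood by Newton-Raphson (gradient
    tolerance ``tol``, at most ``max_iter`` iterations) and reports the Wald
    95% CI on the log-hazard scale.  Raises on complete separation (all events
    in one group, where the hazard ratio diverges) and on fewer than two
    events, where the partial likelihood is degenerate.
    """
    records = _check_records(records)
    labels = sorted(records["group"].unique())
    if len(labels) != 2:
        raise ValueError(f"hazard-ratio fit needs exactly two groups, got {labels}")
    if high_label not in labels:
        raise ValueError(f"high label {high_label!r} not among groups {labels}")
    if records["event"].sum() < 2:
        raise ValueError("need at least two events")
    events_per_group = records.groupby("group")["event"].sum()
    if (events_per_group == 0).any():
        empty = events_per_group.idxmin()
        raise ValueError(
            f"complete separation: group {empty!r} has no events; the hazard ratio diverges"
        )
    time = records["time"].to_numpy(dtype=float)
    event = records["event"].to_numpy(dtype=int)
    x = (records["group"] == high_label).astype(int).to_numpy()
    d, d1, r0, r1 = _breslow_tables(time, event, x)

    beta = 0.0
    for _ in range(max_iter):
        eb = np.exp(beta)
        p = r1 * eb / (r0 + r1 * eb)  # expected high-group share per event time
        score = float(np.sum(d1) - np.sum(d * p))
        info = float(np.sum(d * p * (1.0 - p)))
        if info <= 0:
            raise RuntimeError("singular information matrix in the Cox fit")
        beta += score / info
        if abs(score) < tol:
            break
    else:
        raise RuntimeError(f"Cox Newton-Raphson did not converge in {max_iter} iterations")

    eb = np.exp(beta)
    p = r1 * eb / (r0 + r1 * eb)
    se = float(1.0 / np.sqrt(np.sum(d * p * (1.0 - p))))
    z = 1.959963984540054
    lr = logrank_test(records)
    return SurvivalFitResult(
        hr=float(np.exp(beta)),
        ci_low=float(np.exp(beta - z * se)),
        ci_high=float(np.exp(beta + z * se)),
        logrank_chi2=lr.statistic,
        logrank_p=lr.p_value,
        n=(int((x == 0).sum()), int((x == 1).sum())),
        n_events=int(event.sum()),
    )
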