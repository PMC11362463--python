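"""Closed-form assay quantification.

Relative expression from qRT-PCR by the 2^-ddCt method (target cycle
thresholds referenced to a housekeeping gene, then to a reference sample),
relative methylation from qMSP (the Ct difference between methylated- and
unmethylated-specific amplicons, plus the derived two-species fraction), and
the caliper tumor-volume formula 0.52 x length x width^2.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

__all__ = ["ddct_fold_change", "ddct_table", "qmsp_relative_methylation", "tumor_volume"]


def _delta_ct(records: pd.DataFrame, who: str) -> float:
    """Mean target Ct minus mean housekeeping Ct over replicates.

    Accepts either wide records (``target_ct``/``housekeeping_ct`` columns) or
    long records (``assay`` in {"target", "housekeeping"} with a ``ct``
    column).  Replicates are averaged on the Ct (cycle) scale.
    """
    if records.empty:
        raise ValueError(f"{who} record set is empty")
    if {"target_ct", "housekeeping_ct"} <= set(records.columns):
        target = records["target_ct"].to_numpy(dtype=float)
        hk = records["housekeeping_ct"].to_numpy(dtype=float)
    elif {"assay", "ct"} <= set(records.columns):
        target = records.loc[records["assay"] == "target", "ct"].to_numpy(dtype=float)
        hk = records.loc[records["assay"] == "housekeeping", "ct"].to_numpy(dtype=float)
    else:
        raise ValueError(
            f"{who} records need target_ct/housekeeping_ct columns or assay/ct columns"
        )
    if hk.size == 0:
        raise ValueError(f"{who} record set has no housekeeping measurements")
    if target.size == 0:
        raise ValueError(f"{who} record set has no target measurements")
    if not (np.all(np.isfinite(target)) and np.all(np.isfinite(hk))):
        raise ValueError(f"{who} Ct values must be finite")
    return float(target.mean() - hk.mean())


def ddct_fold_change(sample: pd.DataFrame, reference: pd.DataFrame) -> float:
    """Relative expression of a sample vs a reference by 2^-ddCt.

    ``ddCt = dCt(sample) - dCt(reference)`` where each dCt is the
    replicate-averaged target Ct minus housekeeping Ct.
    """
    ddct = _delta_ct(sample, "sample") - _delta_ct(reference, "reference")
    return float(2.0 ** (-ddct))


def ddct_table(ct_table: pd.DataFrame, reference_sample: str) -> pd.DataFrame:
    """Per-sample 2^-ddCt fold changes from a long Ct table.

    Expects columns ``sample, assay, replicate, ct``; returns
    ``sample, delta_ct, ddct, fold_change``.
    """
    for col in ("sample", "assay", "ct"):
        if col not in ct_table.columns:
            raise ValueError(f"Ct table is missing column {col!r}")
    samples = list(dict.fromkeys(ct_table["sample"]))
    if reference_sample not in samples:
        raise KeyError(f"reference sample {reference_sample!r} not in the Ct table")
    dct = {s: _delta_ct(ct_table[ct_table["sample"] == s], s) for s in samples}
    ref = dct[reference_sample]
    return pd.DataFrame(
        {
            "sample": samples,
            "delta_ct": [dct[s] for s in samples],
            "ddct": [dct[s] - ref for s in samples],
            "fold_change": [2.0 ** (-(dct[s] - ref)) for s in samples],
        }
    )


def qmsp_relative_methylation(ct_methylated: float, ct_unmethylated: float) -> tuple[float, float]:
    """qMSP summary: Ct difference and the derived methylated fraction.

    ``delta_ct = Ct(methylated) - Ct(unmethylated)`` is the assay's stated
    readout; the companion two-species fraction
    ``2^-Ct_M / (2^-Ct_M + 2^-Ct_U) = 1 / (1 + 2^delta_ct)`` maps it into
    (0, 1), strictly decreasing in delta_ct with delta 0 -> 0.5.
    """
    if not (np.isfinite(ct_methylated) and np.isfinite(ct_unmethylated)):
        raise ValueError("Ct values must be finite")
    delta = float(ct_methylated - ct_unmethylated)
    fraction = float(np.exp2(-np.logaddexp2(0.0, delta)))  # 1/(1+2^delta), overflow-safe
    return delta, fraction


def tumor_volume(length: float, width: float) -> float:
    """Caliper tumor volume, 0.52 x length x width^2 (mm^3).

    Swapped inputs (width > length) are corrected with a warning rather than
    silently cubing the wrong axis.
    """
    if length < 0 or width < 0:
        raise ValueError("dimensions must be >= 0")
    if width > length:
        warnings.warn("width > length; swapping the axes", stacklevel=2)
        length, width = width, length
    return 0.52 * length * width**2
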