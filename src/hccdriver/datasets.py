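"""Core in-memory containers shared across the pipeline.

A :class:`StageDataset` holds one cohort's normalized log2 expression matrix
together with an ordered disease-stage label per sample.  The default stage
ladder follows the natural history of hepatocellular carcinoma: normal liver
(NL) < chronic hepatitis (CH) < liver cirrhosis (LC) < dysplastic nodule (DN)
< early HCC (eHCC) < advanced HCC (aHCC).  Cohorts may carry any contiguous
or non-contiguous subset of the ladder; trend statistics are computed over the
stages actually present.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Ordered disease-progression ladder used throughout.
STAGE_LADDER: tuple[str, ...] = ("NL", "CH", "LC", "DN", "eHCC", "aHCC")

#: Stages treated as tumor tissue in the two-group differential-expression step.
TUMOR_STAGES: tuple[str, ...] = ("eHCC", "aHCC")


class ValidationError(ValueError):
    """Raised when an input container violates its documented invariants."""


@dataclass
class StageDataset:
    """One cohort: a genes x samples log2 expression matrix with stage labels.

    Parameters
    ----------
    expression : pandas.DataFrame
        Genes in rows (unique identifiers as index), samples in columns.
        Values are normalized log2 intensities/abundances with no missing
        entries.
    sample_stage : pandas.Series
        One stage label per sample, indexed by sample identifier.  Converted
        to an ordered categorical on the declared ladder.
    cohort_id : str
        Cohort label carried through every downstream table.
    stage_order : tuple of str
        The full ordered ladder the labels are drawn from.
    """

    expression: pd.DataFrame
    sample_stage: pd.Series
    cohort_id: str
    stage_order: tuple[str, ...] = STAGE_LADDER

    def __post_init__(self) -> None:
        if self.expression.index.has_duplicates:
            dup = self.expression.index[self.expression.index.duplicated()][0]
            raise ValidationError(f"duplicate gene identifier: {dup!r}")
        if self.expression.isna().any().any():
            raise ValidationError("expression matrix contains missing values")
        if not all(np.issubdtype(dt, np.number) for dt in self.expression.dtypes):
            raise ValidationError("expression matrix contains non-numeric columns")
        missing = set(self.expression.columns) ^ set(self.sample_stage.index)
        if missing:
            raise ValidationError(
                f"samples in matrix and metadata do not match: {sorted(missing)}"
            )
        # align metadata to the matrix column order
        self.sample_stage = self.sample_stage.reindex(self.expression.columns)
        unknown = set(self.sample_stage) - set(self.stage_order)
        if unknown:
            raise ValidationError(f"stage labels outside the ladder: {sorted(unknown)}")
        self.sample_stage = pd.Series(
            pd.Categorical(self.sample_stage, categories=list(self.stage_order), ordered=True),
            index=self.sample_stage.index,
            name="stage",
        )
        counts = self.sample_stage.value_counts()
        thin = counts[(counts > 0) & (counts < 2)]
        if len(thin):
            raise ValidationError(
                f"every represented stage needs >=2 samples; offending: {sorted(thin.index)}"
            )

    @property
    def genes(self) -> pd.Index:
        return self.expression.index

    @property
    def samples(self) -> pd.Index:
        return self.expression.columns

    @property
    def stages_present(self) -> list[str]:
        """Stages with at least one sample, in ladder order."""
        present = set(self.sample_stage.astype(str))
        return [s for s in self.stage_order if s in present]

    def samples_for_stage(self, stage: str) -> pd.Index:
        return self.samples[(self.sample_stage == stage).to_numpy()]

    def stage_groups(self) -> list[np.ndarray]:
        """Column-position arrays per represented stage, in ladder order."""
        stages = self.sample_stage.to_numpy()
        return [np.flatnonzero(stages == s) for s in self.stages_present]


@dataclass(frozen=True)
class GroundTruth:
    """Planted-signal record emitted alongside every synthetic dataset.

    Sufficient to score recovery (sensitivity / specificity) of any downstream
    selection without inspecting generator internals.
    """

    driver_genes: frozenset[str]
    per_stage_shift: float
    cohort_batch_shifts: dict[str, float] = field(default_factory=dict)
    true_hr: float = 1.0
    target_meth_expr_r: float = 0.0

    def __post_init__(self) -> None:
        if self.per_stage_shift < 0:
            raise ValidationError("per_stage_shift must be >= 0")
        if self.true_hr <= 0:
            raise ValidationError("true_hr must be > 0")
        if not -1.0 <= self.target_meth_expr_r <= 0.0:
            raise ValidationError("target_meth_expr_r must lie in [-1, 0]")
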