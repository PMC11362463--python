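"""On-disk formats: TSV matrices and metadata, MTX triplets, GMT gene sets.

All tables are tab-separated with a header and stable column names, written so
the package's own readers round-trip them exactly; generated fixtures and real
data are therefore interchangeable.  Each reader raises a distinct, named
error for each validation failure so a broken input is diagnosed, not
propagated.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .datasets import STAGE_LADDER, StageDataset, ValidationError
from .enrichment import GeneSetCollection
from .single_cell import CellMatrix

logger = logging.getLogger("hccdriver")

__all__ = [
    "SampleMismatchError",
    "DuplicateGeneError",
    "NonNumericError",
    "GmtFormatError",
    "read_expression_matrix",
    "write_stage_dataset",
    "read_gmt",
    "write_gmt",
    "read_cell_matrix",
    "write_cell_matrix",
    "read_survival_table",
    "write_survival_table",
    "read_beta_table",
    "write_beta_table",
    "read_ct_table",
    "write_ct_table",
    "write_tsv",
]


class SampleMismatchError(ValidationError):
    """Samples in the matrix and the metadata do not agree."""


class DuplicateGeneError(ValidationError):
    """A gene identifier appears more than once."""


class NonNumericError(ValidationError):
    """The expression matrix contains non-numeric cells."""


class GmtFormatError(ValidationError):
    """A GMT line does not have name, description, and at least one gene."""


def write_tsv(table: pd.DataFrame, path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    table.to_csv(path, sep="\t", index=False)
    return path


# ---------------------------------------------------------------------------
# stage-labelled expression cohorts
# ---------------------------------------------------------------------------

def read_expression_matrix(
    matrix_path,
    metadata_path,
    cohort_id: str | None = None,
    stage_order: tuple[str, ...] = STAGE_LADDER,
) -> StageDataset:
    """Read a genes x samples TSV plus a sample/stage metadata TSV.

    The matrix's first column holds gene identifiers; the metadata needs
    ``sample`` and ``stage`` columns.  The two sample sets must match exactly.
    """
    matrix_path = Path(matrix_path)
    raw = pd.read_csv(matrix_path, sep="\t", index_col=0)
    raw.index.name = "gene"
    raw.columns.name = "sample"
    if raw.index.has_duplicates:
        dup = raw.index[raw.index.duplicated()][0]
        raise DuplicateGeneError(f"duplicated gene row: {dup!r}")
    bad = [c for c in raw.columns if not np.issubdtype(raw[c].dtype, np.number)]
    if bad:
        raise NonNumericError(f"non-numeric cells in sample columns: {bad}")
    meta = pd.read_csv(metadata_path, sep="\t")
    for col in ("sample", "stage"):
        if col not in meta.columns:
            raise ValidationError(f"metadata is missing column {col!r}")
    matrix_samples = set(raw.columns)
    meta_samples = set(meta["sample"])
    if matrix_samples != meta_samples:
        missing = sorted(matrix_samples ^ meta_samples)
        raise SampleMismatchError(f"samples differ between matrix and metadata: {missing}")
    stage = pd.Series(meta["stage"].to_numpy(), index=meta["sample"].to_numpy(), name="stage")
    return StageDataset(
        expression=raw,
        sample_stage=stage,
        cohort_id=cohort_id or matrix_path.stem,
        stage_order=stage_order,
    )


def write_stage_dataset(dataset: StageDataset, matrix_path, metadata_path) -> None:
    matrix_path, metadata_path = Path(matrix_path), Path(metadata_path)
    matrix_path.parent.mkdir(parents=True, exist_ok=True)
    out = dataset.expression.copy()
    out.index.name = "gene"
    out.to_csv(matrix_path, sep="\t")
    meta = pd.DataFrame(
        {"sample": dataset.samples, "stage": dataset.sample_stage.astype(str).to_numpy()}
    )
    write_tsv(meta, metadata_path)


# ---------------------------------------------------------------------------
# gene sets (GMT)
# ---------------------------------------------------------------------------

def read_gmt(path) -> GeneSetCollection:
    """Read the standard GMT dialect: name <tab> description <tab> genes...

    Duplicate genes within a set are removed (order-preserving) with a logged
    warning; an empty file yields an empty collection.
    """
    path = Path(path)
    sets: dict[str, list[str]] = {}
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise GmtFormatError(f"{path.name}:{lineno}: expected >=3 tab-separated fields")
            name, _desc, *genes = fields
            genes = [g for g in genes if g]
            deduped = list(dict.fromkeys(genes))
            if len(deduped) < len(genes):
                logger.warning("GMT set %r has duplicate genes; keeping first occurrences", name)
            sets[name] = deduped
    return GeneSetCollection(sets=sets, source=str(path)) if sets else GeneSetCollection(
        sets={}, source=str(path)
    )


def write_gmt(collection: GeneSetCollection, path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with path.open("w") as fh:
        for name in sorted(collection.sets):
            fh.write("\t".join([name, "na", *collection.sets[name]]) + "\n")
    return path


# ---------------------------------------------------------------------------
# single-cell counts
# ---------------------------------------------------------------------------

def read_cell_matrix(counts_path, metadata_path, features_path=None, barcodes_path=None) -> CellMatrix:
    """Read cell counts from a dense TSV or an MTX triplet.

    For MTX input, ``counts_path`` is the ``.mtx`` file (genes x cells in the
    conventional orientation) and ``features_path``/``barcodes_path`` list the
    gene and cell identifiers, one per line.  The cell metadata TSV needs
    columns ``cell, sample, phenotype``.
    """
    counts_path = Path(counts_path)
    if counts_path.suffix == ".mtx":
        from scipy.io import mmread

        if features_path is None or barcodes_path is None:
            raise ValidationError("MTX input needs features and barcodes files")
        mat = mmread(counts_path).tocsr()
        genes = [ln.split("\t")[0] for ln in Path(features_path).read_text().splitlines() if ln]
        cells = [ln.strip() for ln in Path(barcodes_path).read_text().splitlines() if ln]
        if mat.shape != (len(genes), len(cells)):
            raise ValidationError(
                f"MTX shape {mat.shape} does not match features x barcodes "
                f"({len(genes)}, {len(cells)})"
            )
        counts = pd.DataFrame(
            mat.toarray().T, index=pd.Index(cells, name="cell"), columns=pd.Index(genes, name="gene")
        )
    else:
        counts = pd.read_csv(counts_path, sep="\t", index_col=0)
        counts.index.name = "cell"
    meta = pd.read_csv(metadata_path, sep="\t")
    for col in ("cell", "sample", "phenotype"):
        if col not in meta.columns:
            raise ValidationError(f"cell metadata is missing column {col!r}")
    if set(meta["cell"]) != set(counts.index):
        missing = sorted(set(meta["cell"]) ^ set(counts.index))
        raise SampleMismatchError(f"cells differ between matrix and metadata: {missing[:5]}")
    meta = meta.set_index("cell")
    return CellMatrix(
        counts=counts,
        cell_sample=meta["sample"],
        cell_phenotype=meta["phenotype"],
    )


def write_cell_matrix(cells: CellMatrix, counts_path, metadata_path, fmt: str = "tsv") -> None:
    """Write counts as dense TSV or MTX triplet plus the cell metadata TSV."""
    counts_path = Path(counts_path)
    counts_path.parent.mkdir(parents=True, exist_ok=True)
    if fmt == "tsv":
        out = cells.counts.copy()
        out.index.name = "cell"
        out.to_csv(counts_path, sep="\t")
    elif fmt == "mtx":
        from scipy.io import mmwrite
        from scipy.sparse import csr_matrix

        mmwrite(counts_path.with_suffix(".mtx"), csr_matrix(cells.counts.to_numpy().T))
        counts_path.with_name("features.tsv").write_text(
            "\n".join(cells.genes) + "\n"
        )
        counts_path.with_name("barcodes.tsv").write_text("\n".join(cells.cells) + "\n")
    else:
        raise ValueError(f"unknown format {fmt!r}")
    meta = pd.DataFrame(
        {
            "cell": cells.cells,
            "sample": cells.cell_sample.to_numpy(),
            "phenotype": cells.cell_phenotype.to_numpy(),
        }
    )
    write_tsv(meta, metadata_path)


# ---------------------------------------------------------------------------
# simple long tables
# ---------------------------------------------------------------------------

def _read_table(path, required: tuple[str, ...], what: str) -> pd.DataFrame:
    table = pd.read_csv(path, sep="\t")
    missing = [c for c in required if c not in table.columns]
    if missing:
        raise ValidationError(f"{what} table is missing columns: {missing}")
    return table


def read_survival_table(path) -> pd.DataFrame:
    """Columns: patient, time, event (+ optional group or value)."""
    return _read_table(path, ("patient", "time", "event"), "survival")


def write_survival_table(table: pd.DataFrame, path) -> Path:
    return write_tsv(table, path)


def read_beta_table(path) -> pd.DataFrame:
    """Columns: cpg, patient, beta_nt, beta_t."""
    return _read_table(path, ("cpg", "patient", "beta_nt", "beta_t"), "beta")


def write_beta_table(table: pd.DataFrame, path) -> Path:
    return write_tsv(table, path)


def read_ct_table(path) -> pd.DataFrame:
    """Columns: sample, assay, replicate, ct."""
    return _read_table(path, ("sample", "assay", "replicate", "ct"), "Ct")


def write_ct_table(table: pd.DataFrame, path) -> Path:
    return write_tsv(table, path)
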