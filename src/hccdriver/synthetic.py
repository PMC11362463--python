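"""Seeded generators for every input the pipeline consumes.

Each generator emulates the statistical structure of the study's real inputs
(multi-stage expression cohorts, overdispersed single-cell counts,
tumor-hypomethylated CpGs inversely coupled to expression, two-group survival
with a known hazard ratio, and qPCR cycle-threshold tables) and emits the
planted ground truth alongside the data, so downstream selections can be
scored for sensitivity and specificity without re-reading generator
internals.  All generators are pure functions of their arguments including
the seed; per-cohort/table sub-streams are derived deterministically with
``numpy.random.SeedSequence``.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .datasets import STAGE_LADDER, GroundTruth, StageDataset
from .single_cell import CellMatrix

__all__ = [
    "generate_multistage_cohorts",
    "generate_sc_counts",
    "generate_methylation_expression",
    "generate_survival",
    "generate_ct_table",
]


def _rngs(seed: int, n: int) -> list[np.random.Generator]:
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n)]


def generate_multistage_cohorts(
    n_cohorts: int = 3,
    stages: tuple[str, ...] = STAGE_LADDER,
    genes: int = 2000,
    drivers: int = 50,
    per_stage_shift: float = 0.5,
    noise_sd: float = 0.5,
    samples_per_stage: int = 10,
    seed: int = 0,
    batch_sd: float = 0.3,
    cohort_prefix: str = "cohort",
) -> tuple[list[StageDataset], GroundTruth]:
    """Stage-labelled log2 expression cohorts with planted monotone drivers.

    Driver genes gain ``per_stage_shift`` log2 units per stage step on top of
    a gene-specific baseline; null genes are stage-constant.  All cohorts
    share the same driver identities and gene baselines, but differ by a
    cohort-wide batch shift (SD ``batch_sd`` log2 units) and by their noise
    realization (Gaussian on the log2 scale, SD ``noise_sd``).
    """
    if n_cohorts <= 0 or genes <= 0 or drivers < 0:
        raise ValueError("counts must be positive")
    if drivers > genes:
        raise ValueError("drivers cannot exceed genes")
    if samples_per_stage < 2:
        raise ValueError("samples_per_stage must be >= 2")
    if len(stages) < 3:
        raise ValueError("need at least 3 stages")
    if noise_sd < 0 or per_stage_shift < 0:
        raise ValueError("noise_sd and per_stage_shift must be >= 0")

    rng_global, *rng_cohorts = _rngs(seed, n_cohorts + 1)
    gene_ids = pd.Index([f"G{i:05d}" for i in range(genes)], name="gene")
    baseline = rng_global.normal(7.0, 1.0, size=genes)
    driver_idx = np.sort(rng_global.choice(genes, size=drivers, replace=False))
    is_driver = np.zeros(genes, dtype=bool)
    is_driver[driver_idx] = True
    batch_shifts = {
        f"{cohort_prefix}{c + 1}": float(rng_global.normal(0.0, batch_sd))
        for c in range(n_cohorts)
    }

    stage_idx = np.repeat(np.arange(len(stages)), samples_per_stage)
    stage_labels = np.repeat(list(stages), samples_per_stage)
    datasets = []
    for c, rng in enumerate(rng_cohorts):
        cohort_id = f"{cohort_prefix}{c + 1}"
        means = baseline[:, None] + batch_shifts[cohort_id]
        means = means + np.where(is_driver[:, None], per_stage_shift * stage_idx[None, :], 0.0)
        x = means + rng.normal(0.0, noise_sd, size=(genes, stage_idx.size))
        samples = pd.Index(
            [f"{cohort_id}_{s}_{k % samples_per_stage:02d}" for k, s in enumerate(stage_labels)],
            name="sample",
        )
        datasets.append(
            StageDataset(
                expression=pd.DataFrame(x, index=gene_ids, columns=samples),
                sample_stage=pd.Series(stage_labels, index=samples, name="stage"),
                cohort_id=cohort_id,
                stage_order=tuple(stages),
            )
        )
    truth = GroundTruth(
        driver_genes=frozenset(gene_ids[driver_idx]),
        per_stage_shift=per_stage_shift,
        cohort_batch_shifts=batch_shifts,
    )
    return datasets, truth


def generate_sc_counts(
    samples: int = 8,
    cells_per_sample: int = 200,
    genes: int = 300,
    focal_gene: str = "G00000",
    phenotype_effect: float = 1.0,
    dispersion: float = 2.0,
    seed: int = 0,
    module_genes: int = 0,
    module_effect: float = 0.0,
    activity_sd: float = 1.0,
    size_factor_sd: float = 0.3,
) -> tuple[CellMatrix, pd.DataFrame]:
    """Overdispersed single-cell counts with a phenotype-coupled focal gene.

    Counts are negative binomial (Gamma-Poisson) with lognormal per-cell
    library-size factors; ``dispersion`` is the Gamma shape (``numpy.inf``
    gives the Poisson limit).  The focal gene's mean is multiplied by
    ``2**phenotype_effect`` in cells of the "malignant" phenotype.  When
    ``module_genes > 0``, a per-sample latent activity drives the focal gene
    and the first ``module_genes`` non-focal genes together
    (``2**(module_effect * activity)``), planting a focal-gene-correlated
    module for the stratified-enrichment pipeline.

    Returns the cell matrix plus the ground-truth module table
    (``gene, in_module``).
    """
    if samples <= 0 or cells_per_sample <= 0 or genes <= 0:
        raise ValueError("counts must be positive")
    if not dispersion > 0:
        raise ValueError("dispersion must be > 0")
    gene_ids = pd.Index([f"G{i:05d}" for i in range(genes)], name="gene")
    if focal_gene not in gene_ids:
        raise KeyError(f"focal gene {focal_gene!r} not in the generated universe")
    rng = np.random.default_rng(np.random.SeedSequence(seed))

    base = 2.0 ** rng.normal(0.0, 1.0, size=genes)  # per-gene mean counts
    focal_col = gene_ids.get_loc(focal_gene)
    module_cols = [i for i in range(genes) if i != focal_col][: int(module_genes)]

    sample_ids = [f"S{j + 1:02d}" for j in range(samples)]
    phenotype_of_sample = {
        s: ("malignant" if j < (samples + 1) // 2 else "non_malignant")
        for j, s in enumerate(sample_ids)
    }
    activity = rng.normal(0.0, activity_sd, size=samples)

    blocks, cell_ids, cell_sample, cell_phen = [], [], [], []
    for j, s in enumerate(sample_ids):
        mu_gene = base.copy()
        mu_gene[focal_col] *= 2.0 ** (activity[j])
        for c in module_cols:
            mu_gene[c] *= 2.0 ** (module_effect * activity[j])
        if phenotype_of_sample[s] == "malignant":
            mu_gene[focal_col] *= 2.0**phenotype_effect
        size = 2.0 ** rng.normal(0.0, size_factor_sd, size=cells_per_sample)
        mu = size[:, None] * mu_gene[None, :]
        if np.isinf(dispersion):
            counts = rng.poisson(mu)
        else:
            counts = rng.poisson(rng.gamma(shape=dispersion, scale=mu / dispersion))
        blocks.append(counts)
        cell_ids.extend(f"{s}_c{k:04d}" for k in range(cells_per_sample))
        cell_sample.extend([s] * cells_per_sample)
        cell_phen.extend([phenotype_of_sample[s]] * cells_per_sample)

    index = pd.Index(cell_ids, name="cell")
    cells = CellMatrix(
        counts=pd.DataFrame(np.vstack(blocks), index=index, columns=gene_ids),
        cell_sample=pd.Series(cell_sample, index=index, name="sample"),
        cell_phenotype=pd.Series(cell_phen, index=index, name="phenotype"),
    )
    truth = pd.DataFrame(
        {"gene": gene_ids, "in_module": [i in set(module_cols) for i in range(genes)]}
    )
    return cells, truth


def generate_methylation_expression(
    n_pairs: int = 300,
    marker_cpgs: int = 4,
    null_cpgs: int = 46,
    tumor_beta_drop: float = 0.2,
    target_r: float = -0.5,
    seed: int = 0,
    beta_noise_sd: float = 0.1,
) -> tuple[pd.DataFrame, pd.Series]:
    """Paired tumor/non-tumor beta values with expression inversely coupled.

    Marker CpGs have tumor beta lower than the paired non-tumor beta by
    ``tumor_beta_drop`` on average; null CpGs are exchangeable between the two
    tissues.  Noise is additive Gaussian on the beta scale (SD
    ``beta_noise_sd``), truncated into (0, 1), so the paired difference for a
    marker CpG is Normal(-drop, sd*sqrt(2)) away from the boundaries.  Marker
    tumor betas share a per-patient component (promoter CpGs of one gene are
    co-methylated within a tumor), and expression is coupled to the
    per-patient mean marker tumor beta so its Pearson correlation with that
    summary — and, nearly, with each single marker CpG — approximates
    ``target_r``.

    Returns the long beta table (``cpg, patient, beta_nt, beta_t``) and the
    per-patient expression vector (log2 units).
    """
    if not 0.0 <= tumor_beta_drop < 1.0:
        raise ValueError("tumor_beta_drop must lie in [0, 1)")
    if not -1.0 <= target_r <= 0.0:
        raise ValueError("target_r must lie in [-1, 0]: the emulated signal is inverse")
    if n_pairs <= 0 or marker_cpgs < 0 or null_cpgs < 0:
        raise ValueError("counts must be positive")
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    eps = 1e-4

    patients = pd.Index([f"P{i + 1:04d}" for i in range(n_pairs)], name="patient")
    cpgs = [f"cgM{i + 1:03d}" for i in range(marker_cpgs)] + [
        f"cgN{i + 1:03d}" for i in range(null_cpgs)
    ]
    # marker tumor noise splits into a shared per-patient component and a
    # per-site residual; total variance stays beta_noise_sd**2
    shared_sd = beta_noise_sd * 0.9
    site_sd = float(np.sqrt(beta_noise_sd**2 - shared_sd**2))
    patient_shared = rng.normal(0.0, shared_sd, n_pairs)
    rows = []
    marker_bt = np.zeros((marker_cpgs, n_pairs))
    for k, cpg in enumerate(cpgs):
        is_marker = cpg.startswith("cgM")
        mu = rng.uniform(0.55, 0.8)
        beta_nt = np.clip(mu + rng.normal(0, beta_noise_sd, n_pairs), eps, 1 - eps)
        if is_marker:
            noise_t = patient_shared + rng.normal(0, site_sd, n_pairs)
            beta_t = np.clip(mu - tumor_beta_drop + noise_t, eps, 1 - eps)
            marker_bt[k] = beta_t
        else:
            beta_t = np.clip(mu + rng.normal(0, beta_noise_sd, n_pairs), eps, 1 - eps)
        rows.append(
            pd.DataFrame(
                {"cpg": cpg, "patient": patients, "beta_nt": beta_nt, "beta_t": beta_t}
            )
        )
    records = pd.concat(rows, ignore_index=True)

    if marker_cpgs > 0 and target_r < 0:
        summary = marker_bt.mean(axis=0)
        z = (summary - summary.mean()) / summary.std()
        c = -target_r
        expr_z = c * (-z) + np.sqrt(1 - c**2) * rng.normal(size=n_pairs)
    else:
        expr_z = rng.normal(size=n_pairs)
    expression = pd.Series(8.0 + expr_z, index=patients, name="expression")
    return records, expression


def generate_survival(
    n_per_group: int = 500,
    true_hr: float = 2.0,
    baseline_hazard: float = 0.1,
    censor_rate: float = 0.05,
    seed: int = 0,
) -> pd.DataFrame:
    """Two-group survival records with a known hazard ratio.

    Event times are exponential with hazard ``baseline_hazard`` in the "low"
    group and ``baseline_hazard * true_hr`` in the "high" group; censoring is
    independent exponential with rate ``censor_rate`` (0 disables censoring).
    Returns columns ``patient, time, event, group``.
    """
    if n_per_group <= 0:
        raise ValueError("n_per_group must be positive")
    if true_hr <= 0 or baseline_hazard <= 0 or censor_rate < 0:
        raise ValueError("hazards must be positive (censor_rate may be 0)")
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    rows = []
    for group, hazard in (("low", baseline_hazard), ("high", baseline_hazard * true_hr)):
        t_event = rng.exponential(1.0 / hazard, size=n_per_group)
        if censor_rate > 0:
            t_cens = rng.exponential(1.0 / censor_rate, size=n_per_group)
        else:
            t_cens = np.full(n_per_group, np.inf)
        time = np.minimum(t_event, t_cens)
        event = (t_event <= t_cens).astype(int)
        for k in range(n_per_group):
            rows.append((f"{group}_{k + 1:04d}", time[k], event[k], group))
    return pd.DataFrame(rows, columns=["patient", "time", "event", "group"])


def generate_ct_table(
    n_samples: int = 4,
    true_fold_changes=None,
    reference_sample: str = "S1",
    ct_noise_sd: float = 0.0,
    seed: int = 0,
    replicates: int = 3,
    housekeeping_ct: float = 20.0,
    reference_target_ct: float = 25.0,
) -> pd.DataFrame:
    """Long-format qPCR Ct table constructed so ddCt inverts exactly.

    Samples are ``S1..Sn``; ``true_fold_changes`` gives each sample's
    expression ratio relative to ``reference_sample`` (defaults to all 1).
    Noiseless target Ct is ``reference_target_ct - log2(fold/fold_ref)`` with
    a constant housekeeping Ct, so the 2^-ddCt pipeline recovers the folds
    exactly; ``ct_noise_sd`` adds independent Gaussian cycles per replicate.
    Returns columns ``sample, assay, replicate, ct`` with assay in
    {"target", "housekeeping"}.
    """
    if n_samples <= 0 or replicates < 1:
        raise ValueError("counts must be positive")
    sample_ids = [f"S{i + 1}" for i in range(n_samples)]
    if reference_sample not in sample_ids:
        raise KeyError(f"reference sample {reference_sample!r} not among {sample_ids}")
    folds = np.ones(n_samples) if true_fold_changes is None else np.asarray(
        true_fold_changes, dtype=float
    )
    if folds.size != n_samples:
        raise ValueError("true_fold_changes must have one entry per sample")
    if np.any(folds <= 0):
        raise ValueError("fold changes must be > 0")
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    ref_fold = folds[sample_ids.index(reference_sample)]
    rows = []
    for s, fold in zip(sample_ids, folds):
        target_ct = reference_target_ct - np.log2(fold / ref_fold)
        for rep in range(1, replicates + 1):
            rows.append((s, "target", rep, target_ct + rng.normal(0, ct_noise_sd)))
            rows.append((s, "housekeeping", rep, housekeeping_ct + rng.normal(0, ct_noise_sd)))
    return pd.DataFrame(rows, columns=["sample", "assay", "replicate", "ct"])
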