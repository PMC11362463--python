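"""End-to-end workflow orchestration.

Four workflows chain the library modules into the study's analyses:

- ``simulate``   — write a complete synthetic input tree with ground truth;
- ``discovery``  — the multi-cohort cascade (DE -> consensus -> trend ->
  validation), optionally scored against a planted ground truth;
- ``stratify-enrich`` — pseudo-bulk aggregation of single-cell counts,
  quartile stratification by a focal gene, high-vs-low DE, preranked GSEA,
  and per-sample ssGSEA with a high/low group comparison;
- ``biomarker``  — paired differential methylation, hypomethylation calling,
  ROC, methylation-expression correlation, and methylation-dichotomized
  survival.

Every run writes its intermediate tables, a provenance file (config echo,
package version, seed — no timestamps), and logs to standard error; an
identical config and seed reproduces the output tree byte for byte.
"""

from __future__ import annotations

import json
import logging
import sys
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd

from . import __version__
from .datasets import STAGE_LADDER
from .discovery import CascadeConfig, compute_de, run_cascade
from .enrichment import (
    compare_ssgsea_groups,
    preranked_gsea_collection,
    rank_genes_by_log2fc,
    ssgsea_matrix,
)
from .io import (
    read_beta_table,
    read_cell_matrix,
    read_expression_matrix,
    read_gmt,
    read_survival_table,
    write_beta_table,
    write_cell_matrix,
    write_ct_table,
    write_gmt,
    write_stage_dataset,
    write_survival_table,
    write_tsv,
)
from .methylation import (
    call_hypomethylation,
    differential_methylation_table,
    methylation_expression_association,
    roc_auc,
    roc_curve_table,
)
from .single_cell import aggregate_expression, stratify_quartiles
from .survival import cox_binary_hr, dichotomize, km_estimate, logrank_test
from .synthetic import (
    generate_ct_table,
    generate_methylation_expression,
    generate_multistage_cohorts,
    generate_sc_counts,
    generate_survival,
)
from .enrichment import GeneSetCollection

logger = logging.getLogger("hccdriver")

__all__ = ["RunConfig", "run_workflow"]

_WORKFLOWS = ("simulate", "discovery", "stratify-enrich", "biomarker")


@dataclass
class RunConfig:
    """Declarative description of one workflow run."""

    workflow: str
    outdir: Path
    seed: int
    inputs: dict[str, Any] = field(default_factory=dict)
    stage_ladder: tuple[str, ...] = STAGE_LADDER
    alpha: float = 0.05
    fc_threshold: float = 1.5
    span_min: float = float(np.log2(1.5))
    tolerance: float = 0.1
    ssgsea_weight: float = 0.25
    gsea_weight: float = 1.0
    n_perm: int = 1000
    margin: float = 0.0

    def __post_init__(self) -> None:
        if self.workflow not in _WORKFLOWS:
            raise ValueError(f"unknown workflow {self.workflow!r}; choose from {_WORKFLOWS}")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")
        if self.fc_threshold < 1:
            raise ValueError("fc_threshold must be >= 1")
        if self.margin < 0 or self.tolerance < 0 or self.span_min < 0:
            raise ValueError("margin, tolerance and span_min must be >= 0")
        if self.n_perm < 100:
            raise ValueError("n_perm must be >= 100")
        if self.workflow == "discovery" and len(set(self.stage_ladder)) < 3:
            raise ValueError("discovery needs a stage ladder with >= 3 unique labels")
        self.outdir = Path(self.outdir)

    def to_dict(self) -> dict[str, Any]:
        # the output directory is omitted so a rerun into a fresh directory
        # reproduces the output tree byte for byte
        d = {k: v for k, v in self.__dict__.items() if k != "outdir"}
        d["stage_ladder"] = list(self.stage_ladder)
        d["inputs"] = {k: (str(v) if isinstance(v, Path) else v) for k, v in self.inputs.items()}
        return d


def _write_provenance(config: RunConfig) -> Path:
    payload = {"config": config.to_dict(), "package": "hccdriver", "version": __version__}
    path = config.outdir / "provenance.json"
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(payload, sort_keys=True, indent=2, default=str) + "\n")
    return path


def run_workflow(config: RunConfig) -> dict[str, Path]:
    """Execute the named workflow; returns a map of artifact name -> path."""
    if not logging.getLogger().handlers and not logger.handlers:
        handler = logging.StreamHandler(sys.stderr)
        handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
        logger.addHandler(handler)
        logger.setLevel(logging.INFO)
    config.outdir.mkdir(parents=True, exist_ok=True)
    logger.info("workflow=%s seed=%d outdir=%s", config.workflow, config.seed, config.outdir)
    runner = {
        "simulate": _run_simulate,
        "discovery": _run_discovery,
        "stratify-enrich": _run_stratify_enrich,
        "biomarker": _run_biomarker,
    }[config.workflow]
    try:
        artifacts = runner(config)
    except Exception:
        logger.exception("workflow %s failed", config.workflow)
        raise
    artifacts["provenance"] = _write_provenance(config)
    return artifacts


# ---------------------------------------------------------------------------
# simulate
# ---------------------------------------------------------------------------

def _run_simulate(config: RunConfig) -> dict[str, Path]:
    out = config.outdir
    ss = np.random.SeedSequence(config.seed)
    sub = [int(s) for s in ss.generate_state(6) % (2**31)]
    inp = config.inputs
    artifacts: dict[str, Path] = {}

    n_a = int(inp.get("n_cohorts_a", 3))
    n_b = int(inp.get("n_cohorts_b", 5))
    # one call so both tiers share driver identities and gene baselines but
    # carry independent batch shifts and noise realizations
    cohorts, truth = generate_multistage_cohorts(
        n_cohorts=n_a + n_b,
        stages=config.stage_ladder,
        genes=int(inp.get("genes", 2000)),
        drivers=int(inp.get("drivers", 50)),
        per_stage_shift=float(inp.get("per_stage_shift", 0.5)),
        noise_sd=float(inp.get("noise_sd", 0.5)),
        samples_per_stage=int(inp.get("samples_per_stage", 10)),
        seed=sub[0],
    )
    tier_a, tier_b = cohorts[:n_a], cohorts[n_a:]
    for ds in tier_a + tier_b:
        write_stage_dataset(ds, out / f"{ds.cohort_id}_matrix.tsv", out / f"{ds.cohort_id}_meta.tsv")
        artifacts[f"{ds.cohort_id}_matrix"] = out / f"{ds.cohort_id}_matrix.tsv"
    (out / "ground_truth.json").write_text(
        json.dumps(
            {
                "driver_genes": sorted(truth.driver_genes),
                "per_stage_shift": truth.per_stage_shift,
                "cohort_batch_shifts": truth.cohort_batch_shifts,
            },
            sort_keys=True,
            indent=2,
        )
        + "\n"
    )
    artifacts["ground_truth"] = out / "ground_truth.json"

    cells, module_truth = generate_sc_counts(
        samples=int(inp.get("sc_samples", 8)),
        cells_per_sample=int(inp.get("cells_per_sample", 200)),
        genes=int(inp.get("sc_genes", 300)),
        focal_gene=str(inp.get("focal_gene", "G00000")),
        phenotype_effect=float(inp.get("phenotype_effect", 1.0)),
        dispersion=float(inp.get("dispersion", 2.0)),
        module_genes=int(inp.get("module_genes", 30)),
        module_effect=float(inp.get("module_effect", 1.0)),
        seed=sub[2],
    )
    write_cell_matrix(cells, out / "sc_counts.tsv", out / "sc_cells.tsv")
    module = module_truth.loc[module_truth["in_module"], "gene"].tolist()
    non_module = module_truth.loc[~module_truth["in_module"], "gene"].tolist()
    collection = GeneSetCollection(
        sets={"planted_module": module, "background_set": non_module[:30]}
        if module
        else {"background_set": non_module[:30]},
        source="synthetic",
    )
    write_gmt(collection, out / "gene_sets.gmt")
    artifacts["sc_counts"] = out / "sc_counts.tsv"
    artifacts["gene_sets"] = out / "gene_sets.gmt"

    records, expression = generate_methylation_expression(
        n_pairs=int(inp.get("n_pairs", 300)),
        tumor_beta_drop=float(inp.get("tumor_beta_drop", 0.2)),
        target_r=float(inp.get("target_meth_expr_r", -0.5)),
        seed=sub[3],
    )
    write_beta_table(records, out / "beta.tsv")
    expr_table = pd.DataFrame({"patient": expression.index, "expression": expression.to_numpy()})
    write_tsv(expr_table, out / "patient_expression.tsv")
    artifacts["beta"] = out / "beta.tsv"
    artifacts["patient_expression"] = out / "patient_expression.tsv"

    surv = generate_survival(
        n_per_group=int(inp.get("n_per_group", 500)),
        true_hr=float(inp.get("true_hr", 2.0)),
        seed=sub[4],
    )
    write_survival_table(surv, out / "survival.tsv")
    artifacts["survival"] = out / "survival.tsv"

    ct = generate_ct_table(
        n_samples=int(inp.get("ct_samples", 4)),
        true_fold_changes=inp.get("true_fold_changes"),
        ct_noise_sd=float(inp.get("ct_noise_sd", 0.0)),
        seed=sub[5],
    )
    write_ct_table(ct, out / "ct.tsv")
    artifacts["ct"] = out / "ct.tsv"
    return artifacts


# ---------------------------------------------------------------------------
# discovery
# ---------------------------------------------------------------------------

def _load_cohorts(pairs, stage_ladder):
    return [
        read_expression_matrix(m, md, stage_order=tuple(stage_ladder)) for m, md in pairs
    ]


def _run_discovery(config: RunConfig) -> dict[str, Path]:
    out = config.outdir
    tier_a = _load_cohorts(config.inputs["tier_a"], config.stage_ladder)
    tier_b = _load_cohorts(config.inputs["tier_b"], config.stage_ladder)
    cascade_cfg = CascadeConfig(
        alpha=config.alpha,
        fc_threshold=config.fc_threshold,
        span_min=config.span_min,
        tolerance=config.tolerance,
        stage_order=tuple(config.stage_ladder),
    )
    result = run_cascade(tier_a, tier_b, cascade_cfg)
    artifacts: dict[str, Path] = {}
    for cid, table in result.deg_tables.items():
        artifacts[f"deg_{cid}"] = write_tsv(table.reset_index(drop=True), out / f"deg_{cid}.tsv")
    artifacts["deg_consensus"] = write_tsv(
        pd.DataFrame({"gene": sorted(result.deg_consensus)}), out / "deg_consensus.tsv"
    )
    for cid, table in result.trend_tables_a.items():
        artifacts[f"trend_{cid}"] = write_tsv(
            table.reset_index(drop=True), out / f"trend_{cid}.tsv"
        )
    for cid, table in result.trend_tables_b.items():
        artifacts[f"trend_{cid}"] = write_tsv(
            table.reset_index(drop=True), out / f"trend_{cid}.tsv"
        )
    artifacts["trend_consensus_a"] = write_tsv(result.trend_consensus_a, out / "trend_consensus_a.tsv")
    artifacts["final_genes"] = write_tsv(result.final_table, out / "final_genes.tsv")
    logger.info(
        "cascade: %d consensus DEGs -> %d tier-A trend genes -> %d final genes",
        len(result.deg_consensus),
        len(result.trend_consensus_a),
        len(result.final_genes),
    )

    truth_path = config.inputs.get("ground_truth")
    if truth_path:
        truth = json.loads(Path(truth_path).read_text())
        drivers = set(truth["driver_genes"])
        universe = set(tier_a[0].genes)
        final = set(result.final_genes)
        tp = len(final & drivers)
        fp = len(final - drivers)
        n_null = len(universe - drivers)
        report = pd.DataFrame(
            [
                {
                    "n_drivers": len(drivers),
                    "n_final": len(final),
                    "true_positives": tp,
                    "false_positives": fp,
                    "sensitivity": tp / len(drivers) if drivers else float("nan"),
                    "null_contamination": fp / n_null if n_null else float("nan"),
                }
            ]
        )
        artifacts["recovery_report"] = write_tsv(report, out / "recovery_report.tsv")
    return artifacts


# ---------------------------------------------------------------------------
# stratify + enrich
# ---------------------------------------------------------------------------

def _run_stratify_enrich(config: RunConfig) -> dict[str, Path]:
    out = config.outdir
    inp = config.inputs
    cells = read_cell_matrix(
        inp["counts"], inp["cell_meta"], inp.get("features"), inp.get("barcodes")
    )
    collection = read_gmt(inp["gene_sets"])
    focal = str(inp["focal_gene"])
    if focal not in cells.genes:
        raise KeyError(f"focal gene {focal!r} not in the count matrix")

    aggregated = aggregate_expression(cells)
    strata = stratify_quartiles(aggregated[focal])
    artifacts = {
        "aggregated": write_tsv(aggregated.reset_index(), out / "aggregated.tsv"),
        "strata": write_tsv(strata, out / "strata.tsv"),
    }

    log_expr = np.log2(aggregate_expression(cells, normalize="cpm") + 1.0).T  # genes x samples
    stratum_of = strata.set_index("sample")["stratum"]
    high = [s for s in log_expr.columns if stratum_of[s] == "high"]
    low = [s for s in log_expr.columns if stratum_of[s] == "low"]
    de = compute_de(log_expr.drop(index=focal), high, low, config.fc_threshold, config.alpha)
    artifacts["de_high_vs_low"] = write_tsv(de.reset_index(drop=True), out / "de_high_vs_low.tsv")

    ranking = rank_genes_by_log2fc(de)
    gsea = preranked_gsea_collection(
        ranking, collection, weight=config.gsea_weight, n_perm=config.n_perm, seed=config.seed
    )
    artifacts["gsea"] = write_tsv(gsea, out / "gsea.tsv")

    scores = ssgsea_matrix(log_expr, collection, weight=config.ssgsea_weight)
    artifacts["ssgsea"] = write_tsv(scores.reset_index(names="set_name"), out / "ssgsea.tsv")
    comparison = compare_ssgsea_groups(scores, stratum_of)
    artifacts["ssgsea_groups"] = write_tsv(comparison, out / "ssgsea_groups.tsv")
    return artifacts


# ---------------------------------------------------------------------------
# biomarker
# ---------------------------------------------------------------------------

def _run_biomarker(config: RunConfig) -> dict[str, Path]:
    out = config.outdir
    inp = config.inputs
    records = read_beta_table(inp["beta"])
    artifacts: dict[str, Path] = {}

    dm = differential_methylation_table(records)
    artifacts["differential_methylation"] = write_tsv(dm, out / "differential_methylation.tsv")
    focal_cpg = str(inp.get("focal_cpg") or dm.sort_values(["q", "cpg"]).iloc[0]["cpg"])

    flags, fraction = call_hypomethylation(records, focal_cpg, margin=config.margin)
    artifacts["hypomethylation"] = write_tsv(
        pd.DataFrame(
            {"patient": flags.index, "hypomethylated": flags.to_numpy().astype(int)}
        ),
        out / "hypomethylation.tsv",
    )

    sub = records[records["cpg"] == focal_cpg]
    scores = np.concatenate([sub["beta_t"].to_numpy(), sub["beta_nt"].to_numpy()])
    labels = np.array(["T"] * len(sub) + ["NT"] * len(sub))
    roc = roc_auc(scores, labels, positive_label="T", lower_is_positive=True)
    curve = roc_curve_table(scores, labels, positive_label="T", lower_is_positive=True)
    artifacts["roc_curve"] = write_tsv(curve, out / "roc_curve.tsv")
    summary_rows = [
        {"quantity": "focal_cpg", "value": focal_cpg},
        {"quantity": "hypomethylated_fraction", "value": fraction},
        {"quantity": "auc", "value": roc.auc},
        {"quantity": "auc_ci_low", "value": roc.ci_low},
        {"quantity": "auc_ci_high", "value": roc.ci_high},
    ]

    expr_path = inp.get("expression")
    if expr_path:
        expr = pd.read_csv(expr_path, sep="\t").set_index("patient")["expression"]
        merged = sub.set_index("patient").join(expr, how="inner")
        corr = methylation_expression_association(merged["beta_t"], merged["expression"])
        summary_rows += [
            {"quantity": "meth_expr_r", "value": corr.r},
            {"quantity": "meth_expr_p", "value": corr.p_value},
        ]

    surv_path = inp.get("survival")
    if surv_path:
        surv = read_survival_table(surv_path)
        if "group" not in surv.columns:
            beta_of = sub.set_index("patient")["beta_t"]
            surv = surv[surv["patient"].isin(beta_of.index)].copy()
            surv["group"] = dichotomize(beta_of.reindex(surv["patient"]).to_numpy(), "median").to_numpy()
        km = km_estimate(surv)
        for label, tab in km.items():
            artifacts[f"km_{label}"] = write_tsv(tab, out / f"km_{label}.tsv")
        fit = cox_binary_hr(surv)
        summary_rows += [
            {"quantity": "hr", "value": fit.hr},
            {"quantity": "hr_ci_low", "value": fit.ci_low},
            {"quantity": "hr_ci_high", "value": fit.ci_high},
            {"quantity": "logrank_chi2", "value": fit.logrank_chi2},
            {"quantity": "logrank_p", "value": fit.logrank_p},
        ]

    artifacts["summary"] = write_tsv(pd.DataFrame(summary_rows), out / "biomarker_summary.tsv")
    return artifacts
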