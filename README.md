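# hccdriver

Multi-cohort staged driver-gene discovery and biomarker evaluation for
hepatocellular carcinoma (HCC), with seeded synthetic-data generators that
plant known signal so every step of the pipeline can be scored against ground
truth.

## Who this is for

Computational biologists running integrative screens for genes that drive
disease progression across several independent expression cohorts, and who
then need the standard downstream characterization: gene-set enrichment,
pseudo-bulk stratification of single-cell data, promoter-methylation
biomarker evaluation (ROC, survival), and qPCR/qMSP quantification.

## The method

**Discovery cascade.** Each cohort is a genes × samples log2 expression
matrix whose samples carry one label from the ordered disease ladder
NL < CH < LC < DN < eHCC < aHCC (normal liver → chronic hepatitis →
cirrhosis → dysplastic nodule → early HCC → advanced HCC). The cascade runs:

1. *Per-cohort differential expression*, tumor (eHCC, aHCC) vs non-tumor
   stages: Welch's *t* on log2 values; Benjamini–Hochberg across genes; a
   gene is a DEG iff `p_adj < 0.05` and `|log2FC| ≥ log2(1.5)`.
2. *Cross-cohort DEG consensus*: significant in every discovery cohort with
   the same direction.
3. *Ordered-stage trend selection* per cohort: the one-sided increasing
   Jonckheere–Terpstra statistic `J = Σ_{i<j} #{x ∈ stage_i, y ∈ stage_j :
   x < y}` (exact null distribution for total n ≤ 12 without ties,
   tie-corrected normal approximation otherwise), gated on BH-adjusted
   `q < 0.05`, an approximately non-decreasing stage-mean profile (no
   adjacent-stage dip larger than 10 % of the first-to-last span), and a
   span of at least log2(1.5).
4. *Trend consensus and validation*: genes passing in all discovery cohorts
   are re-tested in every validation cohort; survivors are ranked by mean JT
   z-score.

**Downstream analyses.** Preranked GSEA (weighted Kolmogorov–Smirnov running
sum, gene-label permutations), single-sample GSEA (rank-weighted running
difference of in-set and out-of-set ECDFs), hypergeometric
over-representation; pseudo-bulk aggregation of single-cell counts with
quartile stratification by a focal gene and a count-≥1 positivity rule;
paired differential methylation of CpG beta values with hypomethylation
calling, ROC AUC (Mann–Whitney identity, DeLong 95 % CI) and
methylation-dichotomized survival (Kaplan–Meier, log-rank, univariate
Breslow Cox hazard ratio); 2^−ΔΔCt relative expression, qMSP ΔCt with its
two-species methylated fraction, and the caliper tumor-volume formula
0.52 × length × width².

## Worked example

Generate the default synthetic study (8 cohorts, 6 stages, 2000 genes, 50
planted drivers rising 0.5 log2 units per stage, noise SD 0.5, 10
samples/stage) and run the cascade with cohorts 1–3 as the discovery tier and
4–8 as the validation tier:

```sh
hccdriver simulate --outdir demo/sim --seed 7
hccdriver discover --outdir demo/disc --seed 7 \
  $(for i in 1 2 3; do echo --tier-a demo/sim/cohort${i}_matrix.tsv demo/sim/cohort${i}_meta.tsv; done) \
  $(for i in 4 5 6 7 8; do echo --tier-b demo/sim/cohort${i}_matrix.tsv demo/sim/cohort${i}_meta.tsv; done) \
  --ground-truth demo/sim/ground_truth.json
```

The run logs `cascade: 50 consensus DEGs -> 50 tier-A trend genes -> 50
final genes` and writes, among other tables, `final_genes.tsv`:

```
  gene  n_pass  mean_jt_z
G01765       5   8.050240
G00964       5   7.985465
G01884       5   7.964737
```

(`n_pass` = validation cohorts passed, `mean_jt_z` = mean trend z-score) and
`recovery_report.tsv` scoring the list against the planted truth:

```
 n_drivers  n_final  true_positives  false_positives  sensitivity  null_contamination
        50       50              50                0          1.0                 0.0
```

i.e. at this seed the cascade recovered all 50 planted drivers with no false
positives among the 1950 null genes. The same library calls are available in
Python (`hccdriver.generate_multistage_cohorts`, `hccdriver.run_cascade`,
…), and the `stratify-enrich` and `biomarker` subcommands run the
single-cell and methylation/survival workflows on the files `simulate`
writes.

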