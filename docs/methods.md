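# Methods

This note documents the statistical models, default parameters, and design
choices behind `hccdriver`, and states what the synthetic study conditions
do and do not establish about behavior on real data.

## Discovery cascade

The cascade looks for genes whose expression rises monotonically along an
ordered disease-stage ladder, consistently across independent cohorts.

**Differential expression.** Inputs are assumed normalized log2
intensities/abundances (no preprocessing or probe collapsing is performed).
The two-group contrast is Welch's *t* per gene, BH-adjusted across all genes
of the cohort; a gene is differentially expressed iff `p_adj < alpha`
(default 0.05) and `|log2FC| ≥ log2(fc_threshold)` (default 1.5, read as a
linear fold-change ratio). Genes with zero variance in both groups are
assigned p = 1 rather than NaN. Cross-cohort consensus requires the flag in
every cohort with the same direction; consensus sets are therefore
intersection-monotone (adding a cohort can only shrink them).

**Trend statistic.** Monotone association with the stage order uses the
Jonckheere–Terpstra statistic, the sum of pairwise Mann–Whitney counts over
all ordered stage pairs, with half credit for ties. For total n ≤ 12 and
tie-free data the p-value is exact: the statistic decomposes into sequential
Mann–Whitney counts of each stage against the union of its predecessors,
which are independent under exchangeability, so the exact null pmf is their
convolution — identical to exhaustive enumeration over arrangements, at a
fraction of the cost. With ties, or for larger samples, the tie-corrected
normal approximation is used (no continuity correction; under the null its
p-values are uniform to within KS tolerance at the sizes used here).
Cohorts carrying only a subset of the ladder are scored over the stages
present, requiring at least three.

**Monotone gate.** A gene passes in a cohort iff (i) its BH-adjusted JT q is
below `alpha` (adjustment across the genes scored in that cohort, i.e. the
consensus-DEG family), (ii) its stage-mean profile is approximately
non-decreasing, and (iii) the first-to-last span is at least `span_min`
(default log2(1.5)). For (ii) the allowed dip between adjacent stage means
is `tolerance × span` (default 0.1, i.e. a dip of at most 10 % of the
gene's total rise; strict when the span is non-positive). The dip allowance
is deliberately scaled by the observed trend magnitude rather than by a
noise SD: stage means at realistic per-stage sample sizes carry sampling
noise comparable to a per-stage shift, and a noise-scaled allowance either
rejects a large fraction of genuinely monotone genes (small multiplier) or
admits non-monotone shapes (large multiplier). Scaling by the span rejects
rise-then-fall profiles — any sizable reversal exceeds 10 % of the net rise
— while tolerating mean-level jitter on a strongly rising gene; flat
profiles get no allowance but are removed by the span gate regardless.
This per-gene deterministic criterion replaces profile clustering with
manual selection of "increasing" clusters: it encodes the selected property
directly and is reproducible and unit-testable.

**Two tiers.** Trend consensus over the discovery tier (pass in all
cohorts) is followed by validation: survivors must pass the same criterion
in every validation cohort. The final list is ordered by mean JT z-score
(descending), ties broken lexicographically by gene identifier, making the
output invariant to gene-row and sample-column order.

## Statistical primitives

- **BH adjustment** via `statsmodels` step-up; all adjusted values capped at 1.
- **Wilcoxon rank-sum**: exact enumeration when min(n) ≤ 8 and the pooled
  sample is tie-free, otherwise midranks with tie-corrected variance and
  continuity correction (scipy). Two-sided by default.
- **Test-selection policy**: Shapiro–Wilk per group at α = 0.05 (the
  normality α is a convention, not prescribed; constant groups are treated
  as non-normal since Shapiro–Wilk is undefined on them). All groups normal
  → Welch's *t* (2 unpaired groups), paired *t* (2 paired groups), or
  one-way ANOVA with Tukey's post hoc (> 2 groups). Any group non-normal →
  Wilcoxon rank-sum (2 groups; pairing is ignored on this branch) or
  Kruskal–Wallis with Dunn's post hoc (> 2 groups). Dunn's pairwise z-tests
  use midranks with the standard tie correction and BH adjustment (Dunn's
  test is named without an adjustment in common usage; BH keeps the policy
  consistent with the DEG step). Paired comparisons with more than two
  groups are rejected explicitly.

## Enrichment scoring

**Preranked GSEA.** Genes are ordered by descending log2FC (ties
lexicographic). The enrichment score is the extremum of the running sum in
which set members add `|score|^weight` (normalized to sum to 1 over
members; weight default 1) and non-members subtract `1/(N − n_set)`, so
|ES| ≤ 1. If all in-set scores are exactly zero the hit weights fall back
to equal. Significance comes from gene-label permutations (the set's
positions are redrawn uniformly; default 1000, seeded);
`p = (1 + #more-extreme-same-sign) / (1 + #same-sign)`. NES divides ES by
the mean |permuted ES| of matching sign and is omitted when fewer than 10
permutations land on that sign. The leading edge is the set members at or
before (after, for negative ES) the extremum.

**ssGSEA.** One sample's genes are ranked by expression (descending; ties
broken lexicographically so the score is deterministic); position weights
are `rank^weight` with rank N for the highest-expressed gene and weight
default 0.25 (the method's canonical exponent). The score is the sum over
all positions of the difference between the weighted in-set ECDF and the
uniform out-of-set ECDF. No cross-set normalization is applied by default;
the score is invariant under any strictly monotone transform of the
profile. Group contrasts of per-sample scores use the Wilcoxon rank-sum
(high vs low stratum) with BH across sets.

**Over-representation** is the upper-tail hypergeometric p of the observed
overlap, hits restricted to the declared universe.

## Single-cell stratification

Pseudo-bulk aggregation sums raw counts over the cells of each sample
(conserving totals); a CPM option serves the enrichment input path.
Quartile stratification sorts samples by the focal gene's aggregated value
descending and assigns the top ⌈n/4⌉ to "high", the bottom ⌊n/4⌋ to "low",
the rest to "mid" — "high" means highest expression, matching the group
names' semantics; nearest-rank boundaries keep the partition exact for any
n ≥ 4, and ties resolve by stable input order. The positivity proportion
counts cells with ≥ 1 read of the gene over all cells, per phenotype.

## Methylation biomarker

Per-CpG differential methylation is the paired *t* on (beta_t − beta_nt),
BH across CpGs; identical pairs yield p = 1 by convention. A patient is
called hypomethylated iff `beta_t < beta_nt − margin` (margin default 0,
i.e. strict inequality; both a paired call and a threshold rule are
available since the dichotomization used for survival is a modeling
choice). ROC AUC is the concordant-pair fraction with half credit for ties
(the Mann–Whitney identity); tumor is the positive class and an explicit
`lower_is_positive` flag handles tumor-hypomethylated markers without
silent 1 − AUC errors. The 95 % CI uses DeLong's structural-component
variance, clipped to [0, 1], degenerating to [0, 1] when a class has fewer
than two observations. Methylation–expression association is the plain
Pearson r, sign reported as-is.

## Survival

Dichotomization: median split (ties at the median to "low"), threshold, or
quartile rules; labels are invariant to positive affine rescaling.
Kaplan–Meier estimation and the two-group log-rank test are delegated to
lifelines. The hazard ratio comes from a univariate Cox partial likelihood
with Breslow tie handling, maximized by Newton–Raphson on the single binary
coefficient (gradient tolerance 1e−8, max 50 iterations) with a Wald 95 %
CI on the log-hazard scale; with continuous simulated times Breslow and
Efron coincide, which the test suite exploits for an independent lifelines
cross-check. Complete separation (all events in one group) and fewer than
two events raise explicit errors.

## Assay quantification

ΔΔCt averages replicate Cts on the cycle scale (standard practice;
replicate-SD propagation is out of scope), then
`fold = 2^−(ΔCt_sample − ΔCt_reference)`. qMSP reports the stated readout
ΔCt = Ct_methylated − Ct_unmethylated plus the derived two-species fraction
`1/(1 + 2^ΔCt)` (a convenience of this package, clearly labelled as such),
computed overflow-safely. Tumor volume is 0.52 × length × width²; swapped
axes are corrected with a warning.

## Synthetic study conditions

The generators define the conditions under which the pipeline is validated;
their defaults are fixed and ground truth is always emitted alongside the
data.

- **Expression cohorts**: Gaussian noise on the log2 scale (log-normal on
  the linear scale, matching microarray-style intensities); gene baselines
  ~ N(7, 1); driver genes gain 0.5 log2 units per stage step; noise SD 0.5;
  10 samples per stage; cohorts share driver identities and baselines but
  differ by a N(0, 0.3) batch shift and independent noise. Defaults: 2000
  genes, 50 drivers, 6 stages, 3 discovery + 5 validation cohorts.
- **Single-cell counts**: negative binomial (Gamma–Poisson, dispersion
  default 2) with log-normal per-cell size factors (SD 0.3 log2), giving
  realistic dropout for the positivity rule; a per-sample latent activity
  can couple a focal gene to a planted module for the stratified-enrichment
  path. The Poisson limit (dispersion → ∞) is exposed for calibration
  checks.
- **Methylation**: per-CpG baselines ~ U(0.55, 0.8); additive Gaussian
  noise (SD 0.1) truncated to (0, 1) rather than Beta draws with logit
  shifts — the additive form gives the paired-difference closed form
  Φ(drop/(sd·√2)) for the expected hypomethylated fraction, which anchors
  the generator's own validation; truncation is negligible at the default
  baselines. Marker tumor betas share 81 % of their noise variance through
  a per-patient component (promoter CpGs of one gene are co-methylated
  within a tumor), and expression is coupled to the per-patient mean marker
  beta so the achieved Pearson r approximates the target (default −0.5);
  the achieved-r contract is defined against that mean, with single-CpG
  correlations slightly attenuated.
- **Survival**: exponential event times with hazard `baseline × HR^group`
  and independent exponential censoring; defaults 500/group, HR 2,
  baseline hazard 0.1, censor rate 0.05.
- **Ct tables**: constructed so the noiseless 2^−ΔΔCt pipeline inverts the
  programmed folds exactly; Gaussian cycle noise optional.

Every generator is a pure function of its arguments including the seed;
sub-streams per cohort/table derive deterministically from one
`SeedSequence`.

**What passing these conditions does not show.** The generators omit
batch-correction challenges, platform artifacts, probe-level effects,
doublets and ambient RNA, array preprocessing for methylation, and any
dependence structure beyond the planted signal. Recovery and calibration
under these conditions demonstrate the pipeline's correctness and its
behavior at known effect sizes — not performance on raw public cohorts,
whose headline gene counts depend on preprocessing choices outside this
package's scope.

## Problem sizes and numerical choices

The test suite and the acceptance script run the cascade at its full default
configuration (8 cohorts × 2000 genes × 60 samples), null calibration at
2000 replicates for the rank-sum and log-rank rates, Cox coverage at 100
replicates of 500 per group, and brute-force oracle comparisons at sizes
where exhaustive enumeration is itself cheap (n ≤ 12 for JT arrangements,
min(n) ≤ 8 for rank assignments, n ≤ 20 per class for ROC pairs) — sizes
chosen so the oracles are exact, not approximations. Tolerances: exact
oracle comparisons at 1e−12; stochastic calibration bands at the binomial
Monte-Carlo width of the replicate count. Degenerate inputs (constant
vectors, single-class labels, complete separation, all-censored tables)
raise named errors rather than returning NaN. Workflow outputs are
deterministic given config + seed: no timestamps in provenance, sorted
iteration everywhere, and pandas' shortest-round-trip float formatting.

## Known limitations

- The trend criterion tests monotone *increase*; decreasing drivers would
  need the mirrored alternative (available in `jonckheere_terpstra` but not
  wired into the cascade, which mirrors a screen for up-regulated drivers).
- The exact JT path requires tie-free data; tied small samples fall back to
  the normal approximation.
- The Cox fit is univariate binary by design; multivariable models,
  time-varying covariates, and competing risks are out of scope.
- ssGSEA offers no cross-set normalization by default; comparing raw scores
  across sets of very different sizes is not meaningful.
- The paired non-normal branch of the test-selection policy ignores
  pairing (it follows the stated policy literally).
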