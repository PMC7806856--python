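# Methods

This note documents the statistical procedures, the conventions chosen where
several were defensible, the synthetic-cohort generator's assumptions, and
the package's known limitations.

## Study design being modelled

A three-group case-control comparison: 40 patients with ESSIC type 2 IC/BPS
(glomerulations at cystoscopic hydrodistention), 40 with
medication-refractory OAB, and 30 women with stress urinary incontinence as
controls. Thirty-one urinary analytes (a 30-plex inflammation
cytokine/chemokine panel plus NGF) were quantified in pg/mL by bead-based
multiplex immunoassay. The packaged fixtures carry the published per-group
marker summaries (mean ± SD with outlier counts), covariate descriptives,
the per-marker diagnostic table for the two contrasts, and the odds-ratio
unit scales. Group sizes, covariate distributions, and marker moments from
these fixtures are the default conditions for every simulation in the test
suite.

## QC rules

**Outlier exclusion.** Within each marker × group cell, values strictly
outside mean ± k·SD (default k = 3) are excluded, with mean and SD computed
once on the full cell (sample SD, n−1 denominator — the convention of
clinical tables). The pass is deliberately single, not iterative: iterative
trimming shrinks the SD each round and would exclude progressively more
values, changing the reported outlier counts. Boundary values are kept, so
a zero-variance cell (interval degenerates to the mean) keeps all its
values. Excluded cells become missing; all downstream analyses delete
missing values pairwise per marker, which is what per-marker outlier counts
in a summary table imply.

A consequence worth knowing: a single aberrant point in a cell of n can
never exceed (n−1)/√n sample SDs, so the 3-SD rule cannot fire at all for
n ≤ 10, and co-occurring extremes partially mask each other at any n (see
*Limitations*).

**Below-LOD flagging.** A marker is flagged when any group's post-exclusion
mean falls below the assay's minimum detectable concentration. Flagged
markers stay in descriptive summaries; whether they are withheld from
diagnostic analyses is a policy switch (`lod_policy`, default `report`),
because the published diagnostic table itself retains some annotated
markers. The manufacturer's LODs are not public, so `default_lod_table()`
is a **synthetic stand-in** constructed from the fixtures such that exactly
the published below-LOD markers flag on moment-matched data (LOD = 1.2× the
smallest group mean for flagged markers, 0.5× for the rest).

## Group comparison

Per marker: classical one-way ANOVA on raw concentrations across the three
groups (matching the original analysis; concentrations are skewed, so a
log-transform switch exists but is off by default), with Welch's
heteroscedasticity-robust variant available. Post hoc pairwise comparisons
default to Tukey's HSD — the standard companion to one-way ANOVA; the
original post hoc procedure is unstated — with Bonferroni-adjusted Welch
t-tests as the alternative. Post hoc tests run regardless of the omnibus
result and are reported significant at adjusted p < 0.05. Under the global
null at the study's group sizes, the measured omnibus type-I error is ~5%
and the Tukey family-wise error ≤ 7% (seeded, 500 replicates).

## ROC diagnostics

* **AUC** by midranks (equivalent to the Mann–Whitney statistic, ties
  counted half); brute-force pair enumeration is the test oracle, and
  scikit-learn is a secondary cross-check.
* **Direction.** Each marker is oriented so AUC ≥ 0.5 (`AUTO`), recording
  whether higher values indicate the positive or the negative class. In the
  packaged table the positive class is always the diseased group (diseased
  vs control) or IC/BPS (IC vs OAB); annotated markers (IL-17A; and IL-10,
  IL-12p70 for IC vs OAB, which are higher in OAB) carry `POS_LOWER`. This
  reading — direction flipped, positive class fixed — is the only one
  consistent with the printed predictive values given the outlier-adjusted
  group sizes.
* **Cutoff.** Youden's J maximized over midpoints between consecutive
  observed values plus all-positive/all-negative sentinels; J-ties break
  toward higher sensitivity, then the lower threshold. The midpoint
  convention matches the half-step cutoffs of the published table (1.385,
  7.805, 9.035, …); positivity is strictly greater-than (less-than under
  `POS_LOWER`), so observed values are never ambiguous at the cutoff.
* **Metrics.** Sens/spec/PPV/NPV as percentages from the confusion counts;
  a metric with an empty denominator is reported missing, never zero.
* **Rate→count identity.** `confusion_from_rates` reconstructs TP/TN from
  printed rates with **half-away-from-zero** rounding (the rounding of
  mainstream statistics software). One published row (IL-6, diseased vs
  control) lands exactly on a .5 count boundary and is only consistent
  under this convention, which fixed the choice. Class denominators are the
  enrolled group sizes minus that marker's published per-group outlier
  counts (e.g. MIP-1β: 80 − 3 = 77 diseased, 30 − 1 = 29 controls). All 22
  rows reproduce their printed PPV/NPV to the printed decimal, including
  the screening stage's 81.6%/68.4% diagnostic rates.

## Adjusted odds ratios

Per marker and contrast, maximum-likelihood logistic regression of case
status on marker + age + sex (F=0/M=1) + BMI + diabetes (0/1), complete
cases only, with Wald 95% CIs. The marker enters as `marker / unit_scale`
so the reported OR is per unit increment (per 100 pg/mL of MCP-1, per
0.01 pg/mL of NGF, …); fitting scaled is identical to rescaling the raw
coefficient (asserted to 1e-8 in log-OR). Because every control is female,
any vs-control contrast quasi-separates on sex (all men are cases) and the
sex coefficient has no finite MLE; a binary nuisance covariate whose level
occurs in only one outcome class is therefore dropped, with a note on the
fit. Separation driven by the marker itself is reported as
`converged=False` with no OR. The published ORs themselves require the
undeposited subject-level data and are not targets; parameter recovery is
instead validated against a known generating model (median log-OR bias
< 5% over 200 replicates at n = 2000).

## Diagnostic cascade

Screen: MIP-1β > 1.385 pg/mL calls a subject diseased; screen-negatives are
labelled CONTROL. Confirmation among screen-positives: eotaxin > 9.035,
CXCL10 > 40.495, RANTES > 9.305 each vote IC/BPS; IL-10 > 1.025 calls OAB.
The source algorithm scores each confirmation marker separately and
specifies no joint rule, so the combined decision here is an explicit
extension: a configurable combiner over the IC votes (default MAJORITY)
with a conflict policy when both or neither branch fires (default
INDETERMINATE). Reported rates: screening PPV/NPV (the fraction of
screen-positives truly diseased and screen-negatives truly control — by
construction identical to the ROC module's confusion metrics at the same
cutoff, asserted exactly), each confirmation rule's correct-call rate among
screen-positive diseased subjects, and 3-class accuracy with INDETERMINATE
counted wrong. The published confirmation rates (73.3/72.7/69.7/60%) depend
on the joint marker distribution of the original subjects and cannot be
recomputed from summaries; they are not asserted.

## Synthetic cohort generator

* **Family.** Lognormal per marker × group, moment-inverted from the
  published mean ± SD (σ² = ln(1+s²/m²), μ = ln m − σ²/2). Chosen because
  concentrations are nonnegative and right-skewed — several cells have
  SD ≈ mean, impossible for a symmetric positive variable. A zero-truncated
  Gaussian family exists for sensitivity analysis; truncation shifts its
  realized moments when CV is large, so it is only approximately
  moment-matched.
* **Independence.** Markers are generated independently within subject; the
  published summaries carry no covariance information, so any imposed
  correlation would be invented. Consequently, joint-distribution
  quantities (cascade confirmation rates, multi-marker accuracy) on
  synthetic cohorts are *not* estimates of the original study's values.
* **Covariates** follow the published per-group descriptives (normal age
  and BMI, Bernoulli sex and diabetes; the control group is all female) and
  do not influence marker levels by default — no published effect sizes
  exist. An optional log-scale linear covariate effect per marker supports
  testing the regression module against a known signal.
* **Outliers.** Each cell value is independently replaced, with probability
  `outlier_rate` (default 0.025, i.e. about one per cell of 40, matching
  the reported 0–2 per cell), by mean + U(magnitude, magnitude+3)·SD
  (default magnitude 5); positions and values are recorded as ground truth.
* **Moment recovery.** At n = 10⁵ per cell, worst-case mean error across
  all 93 cells is under 1%. The SD of the heaviest-tailed cells (CV ≈ 1.7
  gives a lognormal with excess kurtosis in the hundreds) has a relative
  sampling error near 6% even at n = 10⁵, so worst-case SD error hovers
  around 5% and is seed-dependent at that tolerance.

## Problem sizes used in validation

Simulation sizes were chosen to make Monte-Carlo error small relative to
each assertion: 10⁵–10⁶ draws for moment checks, 10⁴ per class for AUC and
screen-rate convergence, 200 replicate cohorts at the study's own 40/40/30
for outlier recovery, 500 replicates for test-size checks, and 200
replicates at n = 2000 for logistic recovery.

## Limitations

* **Masking bounds outlier recall.** With injections at 5–8 target-SDs and
  the 3-SD rule computed on the contaminated cell, a sole injection in a
  cell of 40 is recovered 98.8% of the time, but two co-injected extremes
  inflate the cell SD by ~1.75× and recover at only ~84%, three at ~47%. At
  the calibrated rate (~1 injection per cell) roughly 63% of injections
  share a cell, so pooled recall is ~79–80% — a property of single-pass
  SD-based trimming itself, not an implementation artifact. Every logged
  outlier is still verified to lie genuinely outside the brute-force
  interval (zero rule violations).
* In-sample diagnostic rates on synthetic cohorts reflect the
  moment-matched marginals, not the original subjects; only the printed
  internal-consistency identities are exactly reproducible.
* No assay plate effects, batch drift, urine-creatinine normalization, or
  inter-marker correlation are modelled.
* No confidence intervals on AUC and no smoothed/binormal ROC (not part of
  the modelled analysis); no imputation of excluded or missing cells.
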