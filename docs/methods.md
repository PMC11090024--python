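# Methods

## Problem and model

`isletcal` calibrates per-marker positivity thresholds for islet
autoantibody assays and evaluates single- and multi-marker screening rules.
All computation happens on a common *analysis scale* on which larger values
mean more antibody: log2-transformed concentration units for
radiobinding-style assays (after imputation of nonpositive values), raw
ΔCt-like readouts for agglutination-PCR assays, and negated values for any
platform whose raw orientation is inverted. A sample is called positive for
a marker when its value is at or above the marker's threshold; this ≥
convention is used consistently in fitting and evaluation.

## Threshold rules

**χ²-optimal (chisq).** Candidate cutpoints are the midpoints between
consecutive distinct pooled case/control values plus one sentinel below the
minimum and one above the maximum; this grid realises every achievable 2×2
confusion table exactly once and avoids the ambiguity of placing a
threshold exactly on an observation. The Pearson χ² statistic (no
continuity correction; defined as 0 when a margin is empty) is maximised
over the grid. Ties at the maximum are broken towards the **largest**
threshold: in a screening context the two tied cuts have equal association
strength, and the larger one favours specificity. The tie-break is
configurable (`tie_break="smallest"`). Because the sentinels always score
zero, a degenerate everyone-positive/everyone-negative cut can only be
returned when no cut separates the groups at all.

**Spec98.** With n training controls, the cut is the ⌈0.98·n⌉-th control
order statistic, lifted to the midpoint towards the next distinct control
value (or to the next floating-point value when all remaining controls
tie). This guarantees training specificity ≥ 98% under the ≥ rule. For a
continuous distribution the expected held-out specificity is
m/(n+1) with m = ⌈0.98·n⌉ — about 0.9800 for the default cohort — which is
the transfer property the acceptance check measures. The level (0.98) is a
parameter of every entry point.

## Cross-validation design

Thresholds are fitted inside `n_repeats = 100` independent balanced
`k = 10`-fold partitions. "Balanced" is implemented as stratification by
case/control status (each fold's case fraction matches the cohort's within
one sample); control subgroups are not additionally balanced. Sensitivity
and specificity are computed on the held-out fold only, giving 1000
evaluations per (analyte, assay, method). The summary is the mean and the
empirical 2.5th/97.5th percentiles of the 1000 values (median and IQR are
also reported, and a normal-approximation interval for the mean is
available via `summarize_cv(..., ci="normal")`); the percentile interval
was chosen because the fold values' distribution is visibly skewed for
specificities near 1.

The fold seed for repeat *r* is derived from `(master_seed, r)` only, so
every analysis that partitions the same cohort — per-marker calibration and
multi-marker staging — shares identical partitions, making their fold-level
results directly comparable. Each repeat can be reproduced in isolation.

## Staging

Per fold, the four marker thresholds are fitted independently on the
training folds (no joint optimisation), each held-out sample's 0–4
positive-marker count is computed, and the ≥1 (AAb1) and ≥2 (AAb2) rules
are scored. ZnT8A is treated as a single marker; if triple-variant
radiobinding columns (R/W/Q at residue 325) are supplied they should be
collapsed to one level (e.g. the maximum) upstream. A missing marker
measurement is a negative call with a warning, since real cohorts have
differing n per marker. `control_set="PBC"` restricts fitting and
evaluation to the population-based controls, the alternative reference
population. Per-subgroup 0–4 count distributions are emitted per fold for
boxplot-style summaries.

## ROC and agreement statistics

AUC is the Mann–Whitney statistic with ties half-weighted, identical to the
trapezoidal area of the empirical ROC curve (asserted to 1e-12 in tests).
Variances use DeLong's structural components: per-case placements V10
(fraction of controls below, ties half-weighted) and per-control placements
V01; var(AUC) = S10/m + S01/n with S the sample variances, and the paired
two-marker test uses the placement covariances, z = Δ/√(var₁+var₂−2cov),
two-sided normal p. Confidence intervals are AUC ± 1.96·SE clipped to
[0, 1]; no logit transform is applied. When both markers induce identical
rankings the difference variance is exactly zero and the p-value is
reported as 1. Paired comparisons use pairwise-complete samples (rows with
a missing value in either marker are dropped, with n reported).

Welch's t-test (Satterthwaite df) compares patient and control levels.
Agreement between paired measurement series reports the mean difference
(bias), the sample SD of differences (sddiff), Bland–Altman limits
bias ± 1.96·sddiff, and Pearson r with a Fisher-z 95% interval
(tanh(atanh r ± 1.96/√(n−3))); r is reported as missing with a reason when
either series has zero variance.

## Preprocessing conventions

Concentration values ≤ 0 are imputed to half the **minimum positive**
observed value for that (analyte, assay) — the positive-minimum reading is
deliberate, since an imputation base taken over all values could itself be
nonpositive and break the log2 transform; the report records the count and
the value used. The imputation base is computed once over the full dataset
before any cross-validation split; the induced leakage affects only the
handful of at-floor values and cannot change any rank, hence no AUC or
threshold ordering.

## Synthetic cohort generator

The generator emulates the measurement structure the analysis assumes, not
any particular dataset:

- **Sizes.** 2300 cases and 1504/456/535 PBC/DOC/BDC controls by default,
  matching the study design the package targets.
- **Mixture structure.** Each sample gets a latent per-marker positivity
  flag: cases with the marker's `positive_fraction` (defaults
  GADA 0.90, IA-2A 0.80, IAA 0.75, ZnT8A 0.70 — assumptions chosen to give
  single-marker CV sensitivities in a realistic 0.6–0.9 band, not measured
  facts), controls with a 1% background rate (real control groups contain
  rare single-positives).
- **Levels.** Negative draws come from the marker/platform control
  distribution, N(0, 1) by default; positive draws from N(4, 1.5²). A
  Gaussian mixture is the simplest family reproducing the observed
  near-zero control densities with an elevated positive component; the
  defaults put the Spec98 cut ≈ 2.05, i.e. within-positive sensitivity
  ≈ 0.9, so overall sensitivities land near the positive fractions.
- **Cross-assay correlation.** Positives share a standard-normal latent
  trait: each platform sees √ρ·T + √(1−ρ)·ε with ρ = 0.8 by default, so the
  between-platform correlation among true positives is exactly ρ.
  Latent-negative samples draw independent noise per platform, so controls
  correlate near 0 — reproducing the high-r-in-patients /
  low-r-in-controls pattern real assay comparisons show.
- **Subgroup shifts.** An additive per-control-group offset (default
  PBC −0.5) emulates the lower levels seen in population-based plasma
  controls; specimen type is metadata only (no level effect is modelled).
- **Replicates.** A second run of a sample adds `replicate_bias` (0.05) and
  N(0, `replicate_sddiff` = 0.3) noise, giving duplicate sddiff ≈ 0.3 and
  r ≈ 0.99 on the log2-like scale, typical of a well-behaved automated
  assay.

What the generator does **not** emulate: heavy-tailed or censored level
distributions, assay drift between batches, plate effects beyond the
replicate noise, age structure, and any dependence of levels on specimen
type. Tests passing on this generator therefore demonstrate the
correctness and calibration of the *statistical machinery* (threshold
rules, CV bookkeeping, variance formulas), not the performance any real
assay would achieve.

## Numerical and design choices

- χ² maximisation treats values within 1e-12 relative of the maximum as
  tied before applying the tie-break, to be robust to float summation
  order.
- Per-repeat fold seeds come from `numpy.random.SeedSequence([seed, r])`
  reduced mod 2³¹.
- Problem sizes in the test suite are chosen so each statistical check has
  clear resolution at its tolerance: convergence checks use 3 standard
  errors at n ≥ 5000; the DeLong coverage and type-I-error checks use 2000
  simulations (±3 binomial SE ≈ ±0.015 around 0.05); the
  positive-fraction-recovery check uses 100 cohorts of 600 samples with 20
  CV repeats each.
- Degenerate inputs: empty groups, all-nonpositive imputation input,
  strata too small to fold, unknown labels and mismatched vectors raise
  errors naming the offending field or stratum; zero-variance correlation
  input degrades to a reported missing value rather than an error.

## Known limitations

- The legacy fixed cutoffs (GADA 34 U/mL, IA-2A 5 U/mL, IAA 0.79 relative
  units) are carried as run-manifest metadata only; no unit calibration to
  WHO/in-house standards is performed, so they cannot be applied to the
  analysis-scale values.
- The percentile interval over CV folds reflects fold-to-fold variability
  around one dataset, not sampling variability of the cohort itself.
- No Youden-index or cost-weighted thresholding, no smoothed/binormal ROC,
  no partial AUC, no Deming/Passing–Bablok regression, and no longitudinal
  modelling of autoantibody persistence or reversion.
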