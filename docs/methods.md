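# Methods

## Scientific setting

The package implements the two standard Mendelian randomization designs
for a positive, right-skewed exposure (a blood metabolite concentration,
analyzed as standardized natural-log units) and continuous blood-pressure
outcomes (systolic/diastolic, mm Hg). Genotype at a biallelic SNP is coded
additively as the dosage (0/1/2) of the exposure-increasing allele. The
causal parameter throughout is the change in outcome per 1-SD increase in
log exposure.

## One-sample arm

**Exposure transform.** `standardize_log_exposure` takes natural logs and
z-scores with the sample SD (n−1 denominator). The population-SD choice
would differ by a factor √(n/(n−1)), negligible at cohort scale but fixed
here by convention so the worked three-point example ([1, e, e²] →
[−1, 0, 1]) is exactly reproducible. Grouped standardization (e.g.
sex-specific SD units, the convention of large exposure GWAS) is available
via `grouping`; the pipeline default is overall standardization.

**OLS and 2SLS.** OLS is delegated to statsmodels. 2SLS is implemented
directly (and cross-checked in the test suite against the independent
statsmodels IV2SLS implementation to machine precision): stage one projects
the exposure on instrument + covariates, stage two regresses the outcome on
the projection, and the error variance uses residuals formed with the
*original* exposure. Standard errors are classical homoskedastic IV
sandwich SEs; an HC0 robust option exists behind a flag but is not the
default, matching the convention of reporting conventional CIs. CIs use the
t quantile with residual degrees of freedom (indistinguishable from the
normal quantile at n ≈ 3700, but exact in small samples). First-stage
diagnostics report the instrument's partial F and partial R²; F < 10 logs a
weak-instrument warning rather than failing, since weak-instrument bias is
a property of the design, not an error state.

**DWH endogeneity test.** Implemented as the control-function augmented
regression: the first-stage residual joins the outcome OLS and the squared
t statistic of its coefficient is referred to F(1, n−k). This is
asymptotically equivalent to the classical contrast form
(Δβ)²/(var₂SLS − varOLS) but remains defined and numerically stable when
the variance difference is near zero. When the exposure is an exact affine
function of instrument + covariates the two estimators coincide; the test
short-circuits to statistic 0, p = 1.

**Balance tests.** Genotype class (3-level, collapsing to 2 with a logged
warning when a class is empty) is modeled as a multinomial outcome on the
covariate (dummy-coded when categorical), fitted by statsmodels MNLogit
(Newton, BFGS fallback); the reported p-value is the likelihood-ratio
chi-square for the covariate terms. The ancestry-adjusted p-value includes
the ancestry score(s) in both the null and full models. A constant
covariate returns p = 1 by convention. The direction (genotype as outcome)
follows the usual genotype-distribution-by-covariate presentation of
cohort balance tables.

**Sex-stratified analyses** are produced by subsetting, not interaction
terms, which matches how sex-specific coefficients are conventionally
reported and keeps each stratum's standardization self-contained.

**Missing data** are out of scope: readers reject files with missing
values, reflecting complete-case analysis.

## Two-sample arm

**Harmonization** orients every record to its exposure-increasing allele:
negative exposure betas flip sign on *both* betas and swap the allele
labels; SEs are untouched. Records with a zero exposure beta are dropped
(orientation undefined) with a logged reason. Palindromic A/T and G/C
records are flagged and retained — without allele frequencies strand cannot
be inferred, and no exclusion rule is imposed. IVW is algebraically
invariant to orientation (X·Y and X² are sign-blind); MR-Egger is not,
which is why `egger_regression` refuses unharmonized panels. Both facts are
asserted in the test suite.

**Fixed-effects meta-analysis** uses inverse-variance weights; Q is the
weighted squared deviation from the pool, I² = max(0, (Q−df)/Q)·100 with
df = k−1, and the heterogeneity p-value is the χ²(df) upper tail. The I²
floor at 0 is exact, and a single study pools to itself with Q = 0.

**IVW** ignores the SNP-exposure SEs (the standard first-order summary-data
approximation; the exposure sample is typically much larger and the
estimator is defined that way). A delta-method SE including the exposure
uncertainty is available via `se_method="delta"`. IVW CIs use the 1.96
normal multiplier — these are large-sample summary statistics, not
small-sample regressions.

**MR-Egger** is closed-form weighted least squares with intercept, weights
1/σ_y². Analytic SEs (with multiplicative overdispersion floored at 1) are
reported for reference; the headline 95% CIs are percentile-bootstrap
(default 10,000 iterations, seeded). Two schemes are implemented because
the choice is genuinely open:

- *nonparametric* (default): resample the k SNP records with replacement
  and refit (vectorized closed-form WLS over all replicates). Resamples
  that collapse to a single distinct exposure beta carry no slope
  information and are dropped with a logged count.
- *parametric*: redraw Y_k ~ Normal(fitted_k, σ_y,k) with the SNP set
  fixed.

With k = 18 instruments the nonparametric percentile interval is known to
be slightly narrow: in our null-pleiotropy calibration runs its intercept
CI covers zero ~91% of the time, versus ~95% for the parametric scheme.
The calibration acceptance test therefore checks nominal coverage with the
parametric scheme; the nonparametric default is retained for analysis use
because it is robust to overdispersion beyond the reported σ_y (e.g.
balanced pleiotropy), which the parametric scheme would understate.

Seed-to-seed stability of percentile endpoints scales as n_boot^(−1/2):
the Monte-Carlo SD of a 2.5%/97.5% endpoint is ≈ 0.027·se at 10,000
iterations (normal-quantile asymptotics), so exact two-seed agreement
within 0.02·se is only guaranteed at a few hundred thousand iterations;
the stability test runs at 400,000, where the derived jitter bound holds
with margin.

## Synthetic-data generators

**Cohort.** Genotypes are drawn from per-stratum Hardy–Weinberg
proportions at T-allele frequency 0.306 (the frequency implied by genotype
proportions 47.9/43.0/9.1%). Log exposure is

    log X = log 8.0 + b_g (G − 2q) + b_sx (sex − ½) + b_cx C + ε_x,

with C a latent standard-normal confounder, and the raw exposure is
exp(log X) so the log/standardize transform is exercised downstream.
Outcomes add the causal dose (population-standardized log exposure ×
causal_beta), the confounder loading, any direct (pleiotropic) SNP effect,
sex and stratum offsets, and Normal(0, 12²) noise per outcome.

Default calibration (units: log-exposure components in natural-log units,
outcome components in mm Hg):

| parameter | default | why |
|---|---|---|
| n_individuals | 3701 | complete-case cohort size emulated |
| allele_freq | 0.306 | implied by the emulated genotype table |
| target_r2 | 0.053 | instrument strength; yields first-stage F ≈ 200 at this n |
| causal_beta | 0 | null causal effect as the reference condition |
| confounder_beta_x / _y | 0.135 / 2.5 | together with the sex paths gives a crude slope ≈ +1.0 (SBP) / +0.9 (DBP) mm Hg/SD under the null |
| noise_sd_x | 0.416 | total log-exposure SD ≈ 0.45, i.e. concentrations ~3–20 μmol/L around a geometric mean of 8 |
| noise_sd_y | 12 | outcome residual SD; reproduces OLS CI half-widths ≈ 0.45 and 2SLS ≈ 2 mm Hg |
| sex_beta_x / _sbp / _dbp | 0.045 / 12.2 / 4.4 | male–female differences; the exposure-side difference is kept small so the single latent confounder carries most of the confounding |

`target_r2` solves the per-allele effect analytically from the allele
frequency and the non-genetic variance components, so tests can pin the
first-stage strength exactly; `instrument_beta` is used directly when
`target_r2=None`. Population stratification is modeled as discrete strata
with allele-frequency and outcome offsets plus a noisy observed ancestry
score (`pc1`, stratum indicator + Normal(0, 0.15) noise, standardized)
standing in for genome-wide principal components. A categorical covariate
can be made to track the stratum (`covariate_stratum_assoc`) to build
confounding-by-ancestry scenarios.

**Summary panel.** Exposure betas are uniform on (0.03, 0.16) SD/allele
(the span of effect sizes in large metabolite GWAS, with the functional
variant at the top); outcome betas are causal_beta·X + pleiotropy + noise
with SD `se_outcome` (default 0.10 mm Hg, the scale of consortium
blood-pressure SEs; `se_exposure` defaults to 0.008). The pleiotropy term
has configurable mean (directional pleiotropy), SD, and correlation with
the exposure betas (`inside_violation`; 0 means InSIDE holds). Half the
records are stored on the exposure-*decreasing* allele (`flip_fraction`)
so harmonization is always exercised. Because exposure betas are generated
without measurement noise, the IVW estimator's ignore-σ_x approximation is
exact in simulation, which is what makes the SE-calibration recovery test
sharp.

**What the generators do not emulate:** linkage disequilibrium between
instruments, genotype missingness and imputation, winner's-curse selection
of instruments, sample overlap between the two samples of two-sample MR,
assortative mating or dynastic effects, and effect-measure modification
(e.g. by folate fortification). Passing recovery tests therefore shows the
estimators are correct under their stated assumptions, not that those
assumptions hold in any particular real data set.

## Pipeline

Adjustment sets are named presets — `crude` (none), `pca` (ancestry
score), `sociodemographic` (sex + categorical covariate), `full` — forming
the usual model ladder. Reports are ordered blocks keyed by (outcome,
method, adjustment, stratum) with a config hash and seed recorded;
identical config + seed reproduces byte-identical result files. Figures
are deterministic given the report (fixed ordering, no jitter). The CLI
exits 0 on success, 2 on configuration errors, 3 on data errors, 4 on
estimation errors.

## Problem sizes used in validation

Recovery and calibration runs use 500–1000 replicates: 1000 18-SNP panels
for IVW/Egger recovery and intercept coverage, 500 cohorts of n = 3701 per
causal value for one-sample recovery, 1000 cohorts for the DWH level, and
1000 draws of n = 500 for balance-test uniformity. These sizes put the
Monte-Carlo SE of each checked mean at least threefold below the margin it
is checked against.

## Known limitations

- Exactly-identified single-instrument 2SLS has no finite moments; the
  weak-instrument demonstrations summarize by medians for that reason.
- MNLogit balance tests rely on asymptotic LR p-values; with very sparse
  genotype-by-category cells they can be slightly anticonservative.
- The nonparametric Egger bootstrap undercovers modestly at small k (see
  above); for k well below 18 the parametric scheme or analytic
  t-intervals should be preferred.
- Robust/clustered SEs, LIML, median/mode estimators and multivariable MR
  are out of scope.
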