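# Methods

## Index formulas and unit conventions

All participant data are stored on canonical scales: lengths in m (height)
and cm (waist), weight in kg, analytes (TG, HDL-C, fasting glucose) in
mmol/L, pressures in mmHg, age in years.  Published index formulas mix
unit systems, so each calculator converts internally to the scale its
definition names: the TyG index converts TG and glucose to mg/dL
(factors 88.57 and 18.016 mg/dL per mmol/L; HDL-C uses 38.67), LAP and
CVAI consume TG in mmol/L directly.  CVAI uses log base 10, TyG the
natural log — exactly as each formula is defined.

Two deliberate reporting choices:

* **ABSI ×100.**  The canonical ABSI of a mid-aged adult is ≈ 0.08
  m^(7/6)·kg^(-2/3); we report 100× that, the scale on which the index is
  conventionally tabulated in Chinese cohort studies (values near 8).
  Cut-offs are scale-covariant, so screening conclusions are unchanged.
* **Conicity constant 0.109.**  The standard conicity index is
  WC_m/(0.109·√(weight/height)); published summary values near 1.27 are
  only consistent with 0.109, and that constant is used throughout.

LAP can be negative when the waist is below the sex offset (65/58 cm);
negative scores are retained, not clamped — ROC ranking needs only the
ordering, and truncation would manufacture ties.

BRI is undefined when the waist radius WC/2π exceeds half the height
(radicand negative); such records raise a per-record domain error and a
cohort run reports them without aborting.

## Diagnosis

NCEP ATP III, 3-of-5, with Chinese waist thresholds (≥90 cm men, ≥80 cm
women).  Cut-ins are inclusive (≥), the HDL criterion is strict (<), and
therapy overrides attach only to blood pressure (antihypertensive
medication) and glucose (antidiabetic medication or diabetes history);
lipid-lowering therapy is not modelled.  Thresholds are defined in mg/dL
while storage is mmol/L; comparisons carry a one-part-in-10⁹ relative
guard so a value entered in either unit system flags identically at the
exact threshold (the molar-factor round trip is not bit-exact).

Age bands for stratified prevalence are 45–54, 55–64, 65–74, ≥75,
half-open on the continuous scale (a 54.6-year-old is in 45–54).

## ROC and cut-point conventions

* AUC is the Mann–Whitney concordance probability (ties half-weighted),
  computed from midranks; this equals the trapezoidal area under the
  empirical ROC curve, and the test suite asserts the identity against
  brute-force pair enumeration.
* The SE is Hanley–McNeil's rank-based formula by default (the common
  statistical-package default when no estimator is named); DeLong's
  structural-component estimator is available via `se_method="delong"`.
  The 95% CI is AUC ± 1.96·SE clipped to [0, 1].
* Candidate cut-offs are midpoints between consecutive distinct observed
  values plus ∓∞ sentinels; classification is `score ≥ cutoff → positive`.
  The optimum maximises J = sens + spec − 1; ties on J are broken toward
  higher sensitivity (screening favours catching cases), then toward the
  lower cut-off, making output deterministic.
* Direction is fixed: higher score → disease, for all 13 indices; no
  automatic direction flip.
* Records missing a score are excluded from that index's curve only, with
  the count reported.

## Logistic associations

Exposures are the indices dichotomized at their sex-specific optimal
cut-offs (`≥ cutoff`, the same rule as the ROC classification).  Models
are fit by maximum likelihood (statsmodels Logit, Newton iterations,
observed-information covariance).  Categorical covariates are coded as
reference-level indicators, reference = first category level; sex is
dropped from the adjustment set inside sex strata.  CIs are Wald
exp(β ± 1.96·SE).  Fits with |β| or SE above 50 on the logit scale, or
non-finite covariance, are flagged as separated rather than reported;
non-convergence within 100 iterations is likewise flagged.  Covariate
missingness is handled complete-case with a logged exclusion count.

## Synthetic cohort

The generator emulates the *statistical shape* of a mid-aged/elderly
Chinese cohort: sex ratio 45.9% male; age drawn from sex-specific band
proportions (uniform within band — only band frequencies are published);
a per-sex multivariate-normal latent vector (height, log weight, WC
residual, log TG, HDL-C, log FPG, SBP, DBP) mapped to physical scales
(log-normal weight/TG/FPG, normal HDL and pressures); WC as a linear
regression on weight and height plus the latent residual; categorical
covariates from sex-specific frequency tables; medication/history flags
drawn with probabilities conditional on the generated BP/FPG exceedance.
Latent means and SDs were derived analytically from the published
sex-stratified summary moments (e.g. male TyG 8.62 ± 0.66 fixes the log-TG
location once the FPG distribution is set).  Out-of-range draws are
rejection-resampled and counted.

The latent correlation matrix is **not** published anywhere; defaults are
field-typical magnitudes (weight–height 0.35, TG–HDL −0.40, TG–FPG 0.25,
SBP–DBP 0.70, weaker adiposity–pressure/glucose links), fixed once and
editable through the config.  MetS status is never sampled — it emerges
from the generated components through the diagnostic rule, so the
generator cannot be circularly coupled to the classifier it is used to
test.

What the generator does *not* emulate: survey design, household
clustering, nonresponse, assay error, the real data's deviations from
(log-)normality, and any residual dependence beyond the Gaussian copula
implied by the latent correlations.  Passing calibration tests therefore
show the pipeline behaves correctly on data with the published first and
second moments and a plausible dependence structure — not that the
published AUCs or cut-offs are reproduced numerically; those depend on the
real microdata.  At n = 10 000 the default config yields overall MetS
prevalence ≈ 41–42% (published: 41.87%), index means within 10–15% of the
published sex-stratified anchors, and the published qualitative AUC
ordering (TyG-WC/LAP/CVAI strong, ABSI weakest in both sexes).  VAI's mean
is not used as a calibration anchor: it is an extremely skewed ratio
statistic whose published summary is also internally inconsistent across
strata, so only its ordering behaviour is checked.

## Problem sizes and numerics

Default analyses run at the published cohort size (n = 9457); calibration
tests use n = 10 000 and correlation-recovery checks n = 50 000 (±0.02
absolute).  Parameter-recovery simulations use 200 replicates at n = 5000
with a true adjusted OR of 5.0, requiring the mean estimate within 5% and
Wald CI coverage 0.95 ± 0.03.  ROC oracle checks (brute-force pairwise AUC,
exhaustive Youden scan, trapezoid identity) run on 200 random instances of
n ≤ 50 including heavily tied score sets.  All randomness flows from
explicit integer seeds through `numpy.random.default_rng`; reports are
plain CSV/JSON and byte-identical under identical (input, config, seed).

## Known limitations

* The cut-offs derived on synthetic cohorts are not clinical
  recommendations; they demonstrate the machinery on data with the right
  moments.
* Wald CIs and p-values only; no profile-likelihood or exact small-sample
  intervals (cells are large in the intended regime).
* Complete-case covariate handling; no imputation.
* Cross-sectional associations only — no survey weighting, no causal
  interpretation.
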