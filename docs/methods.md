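# Methods

This note records the statistical models the package implements, the
choices made where the design was genuinely open, and what the
simulation studies do and do not establish.

## The estimand and the two-stage estimator

The target is the average causal hazard ratio of an exposure X (a sleep
trait) on a time-to-event outcome (incident myocardial infarction),
identified through genetic instruments.  With individual-level data the
package uses two-stage predictor substitution (TSPS):

1. **Stage 1** — regress X on the genetic risk score G and covariates
   Z: linear regression when X is continuous, logistic when binary.
   The fit is restricted to participants who never experience the
   event, the standard guard against the outcome contaminating the
   instrument–exposure relation when the outcome is common; the fitted
   coefficients are then applied to *all* rows (restriction applies to
   fitting, not prediction — the only coherent reading when cases need
   fitted values in stage 2).
2. **Stage 2** — Cox proportional hazards of (time, event) on the
   stage-1 fitted values plus the same covariates.  The coefficient on
   the fitted value is the causal log HR.

For binary exposures the stage-1 prediction enters stage 2 on the
linear-predictor (log-odds) scale.  This makes the per-doubling-of-odds
rescaling exact: multiplying the estimate and its SE by ln 2 ≈ 0.693
converts "per unit log-odds" to "per doubling of the odds".  The
predicted-probability scale is available (`binary_fitted_scale=
"probability"`) but is not the default, because the ln 2 rescaling is
then only approximate.

**Bootstrap.**  The plug-in Cox variance treats the fitted exposure as
fixed, which understates uncertainty.  SEs therefore come from a
participant-resampling bootstrap that reruns both stages on each
resample; the SE is the SD of replicate estimates, the canonical CI is
the normal approximation around the full-sample estimate, and a
percentile CI is reported alongside.  Replicate i draws from stream
(seed, i), so increasing the iteration count never reorders earlier
streams.  Replicates that fail to fit (e.g. a resample drops a factor
level or separates the logistic stage) are tallied and tolerated up to
5% of the total; beyond that the run aborts.  Constant covariate
columns inside a replicate are dropped and logged rather than crashing
the refit.

**Cox engines.**  User-facing fits go through lifelines (Efron tie
handling, optional robust sandwich covariance, Schoenfeld residuals).
Bootstrap and replicate loops use an internal vectorized
Newton–Raphson solver for the partial likelihood (`sleepmr._cox`),
written for the untied continuous event times the generator produces —
where Breslow and Efron likelihoods coincide — and cross-checked
against lifelines to 1e-6 in the test suite.  The internal solver is
~30× faster per fit, which is what makes 200-replicate × 100-bootstrap
calibration studies affordable on one CPU.

## Factorial MR and RERI

Two risk scores are median-split (values equal to or below the median
are "low" — ties deliberately go low), and a Cox model with indicator
terms for the three non-reference groups yields HR₁₀, HR₀₁, HR₁₁ with
their log-HR covariance (robust by default).  RERI = HR₁₁ − HR₁₀ −
HR₀₁ + 1.  The CI uses the delta method on the multivariate-normal
log-HRs, gradient (−HR₁₀, −HR₀₁, HR₁₁); a parametric-bootstrap CI over
the same covariance is available as a cross-check (the two agree
closely at the covariance magnitudes seen in practice — the tests
verify this on a 10 000-draw oracle).  RERI is only emitted when all
three HRs are ≥ 1, the usual convention since additive interaction is
not interpretable for preventive directions; `allow_preventive=True`
overrides for methodological work.

The continuous variant z-scores both scores and fits Cox on
(z_A, z_B, z_A·z_B).  RERI is evaluated at +1 SD in both scores,
exp(b₁+b₂+b₃) − exp(b₁) − exp(b₂) + 1 — the natural contrast when
effects are reported per SD — with the same guard and delta-method CI.

## Summary-statistic sensitivity estimators

Per-variant associations are computed in the same cohort: γⱼ from
regressing the exposure on dosage plus covariates (restricted to
non-cases, mirroring stage 1 — the package records this choice in its
output metadata since conventions differ), Γⱼ as the per-dosage log-HR
from Cox with the same covariates.  Applying two-sample machinery in a
one-sample setting is deliberate and mirrors field practice; MR-Egger
in particular can be unreliable in a single dataset, which is why it is
a sensitivity analysis here, not a headline estimator.

- **IVW**: weighted regression of Γ on γ through the origin, weights
  1/se(Γ)².
- **MR-Egger**: the same regression with an intercept, after orienting
  all γⱼ non-negative; the intercept estimates average directional
  pleiotropy under InSIDE.
- Both use the multiplicative random-effects convention: residual
  dispersion scales the SEs but is floored at 1.
- **Weighted median**: ratio estimates bⱼ = Γⱼ/γⱼ sorted, weights
  equal (simple) or γⱼ²/se(Γⱼ)² (weighted); the estimate interpolates
  the weighted CDF at 0.5 using midpoint cumulative sums.  Variants
  with γⱼ = 0 are dropped with a warning.
- **Weighted mode**: Gaussian-kernel density over the bⱼ with inverse-
  variance weights; bandwidth = factor × 0.9·min(SD, MAD/0.6745)·
  n^(−1/5) (a Silverman-type rule on the MAD-consistent sigma, robust
  to outlying ratios); the estimate is the density argmax on a
  2048-point grid.
- Median and mode SEs come from a parametric bootstrap resampling
  (γⱼ, Γⱼ) from their sampling normals — cheaper than case resampling
  and standard for summary-statistic estimators.

**Diagnostics.**  The proportional-hazards check correlates each
term's Schoenfeld residuals with follow-up time (Pearson, two-sided
p).  The confounder scan regresses each covariate on each standardized
GRS (linear for numeric, logistic for binary covariates) and flags
p-values below 0.05/(#GRS × #covariates).

## GRS construction

Harmonization convention: dosages are never modified; when the weight
file's effect allele is the genotype's other allele, the beta is
negated and the EAF reflected (algebraically identical to counting
2−dosage, up to an intercept no downstream regression sees).
Unmatched variant IDs and incompatible allele pairs are dropped and
reported, never silently.  Palindromic (A/T, C/G) variants are flagged
but kept by default; strict mode drops them when EAF ∈ [0.42, 0.58],
where strand cannot be resolved from frequency.

Unweighted scores count trait-increasing alleles: dosages of
negative-beta variants are reflected so weighted and unweighted scores
point the same direction.  (Unweighted scores are the appropriate
choice when the discovery GWAS overlaps the analysis sample, where
external weights would import winner's curse.)  Instrument strength is
the R² / F of a single-regressor least-squares fit of the trait on the
score; for binary traits this is a linear-probability model — the
simplest reproducible convention — with McFadden's pseudo-R² available
as an option.

## The synthetic cohort generator

The generator emulates the data-generating structure the analysis
assumes, not any particular population:

- **Genotypes**: m independent biallelic variants, dosage ~
  Binomial(2, EAF) — Hardy–Weinberg proportions, linkage equilibrium.
  EAFs uniform on a configurable range (default 0.1–0.9), per-allele
  effects Normal (default mean 0.05, SD 0.02, trait units).
- **Exposure**: continuous X = mean + SD·(√v·Z_G + b·U + ε) with Z_G
  the standardized GRS, v the target variance explained, U ~ N(0,1) a
  latent confounder retained in the output for oracle analyses; or a
  binary trait from a logistic liability with the GRS share of
  liability variance (logistic residual π²/3) equal to v and the
  intercept solved numerically so mean predicted probability hits the
  target prevalence in the simulated cohort.
- **Outcome**: event times from hazard λ₀·k·t^(k−1)·exp(β_X·X + β_U·U
  + Σ αⱼgⱼ); the default shape k = 1 (exponential, constant baseline
  hazard) gives closed-form checks (event fraction 1 − exp(−λ₀·c)),
  with Weibull shape as an option.  Direct variant effects αⱼ
  implement pleiotropy: none, balanced (mean 0), or directional
  (nonzero mean).  Censoring is administrative at a fixed horizon
  (default 12 years, of the order of a biobank follow-up) plus
  optional exponential loss-to-follow-up — the real cohorts' censoring
  mechanisms beyond their end-of-follow-up dates are not public, so
  loss-to-follow-up intensity is a free knob, default 0.
- **Prevalent cases** are flagged by an independent Bernoulli draw
  (default 1%) — a deliberate simplification (real prevalence
  correlates with age and risk factors), sufficient because the
  analysis contract is simply that flagged rows are excluded, never
  silently dropped.

Every generator consumes streams derived from the scenario seed, so a
fixed scenario is bit-reproducible.

What the generator does **not** emulate: linkage disequilibrium,
age-varying baseline hazards, competing risks (death from other causes
competes with infarction in real cohorts and can inflate estimates),
assortative mating or population structure, and measurement error in
questionnaire phenotypes.  Passing calibration on these cohorts
therefore shows the estimators are correctly implemented and calibrated
*under the model's own assumptions*; it does not certify behaviour
under LD-correlated instruments or informative censoring.

## Phenotype and outcome rules

Questionnaire classifiers are total functions on their declared
vocabularies (unknown strings raise; quote style and case are
normalized).  The two-question insomnia rule treats a lone
"Often"/"Almost every night" as positive, but a lone negative answer as
missing — excluding rather than risking misclassification.  Sleep
duration outside 3–18 h is treated as implausible and set missing;
short sleepers (≤ 6 h) are excluded from the long-sleep contrast and
vice versa, so `short=yes, long=yes` is impossible by construction.

Outcome derivation matches ICD codes by normalized prefix (dots
stripped): 410 (ICD-9), I21/I22 (ICD-10).  The earliest matching
hospital or death record decides status; a record on the enrolment day
counts as prevalent (conservative tie-break), and a cause-of-death
match with no prior hospital record is the incident event on the death
date.  Follow-up time is days/365.25.

## Simulation-study sizes

The calibration studies (in `sleepmr.calibration`, reported by
`scripts/acceptance.py` and asserted in the test suite) use sizes
chosen to give informative Monte-Carlo error on a single CPU in a few
minutes:

- TSPS recovery/coverage: 200 replicates of n = 2500, 50→40 variants
  explaining 5% of exposure variance (F ≈ 130 — a strong instrument,
  scaled so the instrument's per-sample information matches what a
  biobank-scale cohort achieves with weaker scores), true HR 1.25,
  exponential hazards, 100 bootstrap iterations (the estimator's floor;
  headline analyses would use 2000–5000).
- RERI calibration: 200 replicates of n = 20 000 with group hazards
  built exactly additively (truth 0) or multiplicatively (truth
  (HR₁₀−1)(HR₀₁−1)).
- Egger intercept coverage: 200 summary-level replicates, 30 variants,
  directional pleiotropy mean 0.01.
- Diagnostics: 400 null replicates each for the Schoenfeld test
  (n = 300) and the confounder scan (n = 500, 5 covariates).

## Known limitations

- The TSPS causal HR for a binary exposure inherits the usual
  interpretability caveats of MR with binary exposures (coarsened
  latent exposure, non-collapsibility of the HR).
- MR-Egger in a one-sample setting can be biased toward the
  confounded association; it is included for symmetry with field
  practice and flagged as such above.
- The factorial design is typically underpowered for interaction;
  RERI CIs are honest about this (they are wide at realistic effect
  sizes).
- No competing-risk machinery: events are censored at non-outcome
  death, which overstates cumulative incidence when mortality is
  informative.
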