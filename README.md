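# sleepmr

One-sample and factorial Mendelian randomization (MR) for survival
outcomes, built around the design used to study the causal effects of
sleep traits (insomnia symptoms, sleep duration, chronotype) on
incident acute myocardial infarction in large biobank cohorts.  The
real individual-level data such analyses run on (UK Biobank, HUNT2) are
access-restricted, so the package ships a synthetic-cohort generator
with the same statistical structure — genotypes → exposure → censored
survival outcome, with confounding and pleiotropy — making every stage
of the pipeline testable end to end.

It is aimed at genetic epidemiologists who want a tested, reusable
implementation of:

- **Two-stage predictor substitution (TSPS) with a Cox second stage.**
  Stage 1 regresses the exposure X on the genetic risk score G plus
  covariates Z (linear for continuous X, logistic for binary X),
  fitting on participants who never experience the event but predicting
  X̂ for everyone.  Stage 2 fits the Cox model
  λ(t) = λ₀(t)·exp(β·X̂ + γᵀZ); β estimates the causal log hazard
  ratio.  Standard errors come from a participant-resampling bootstrap
  that reruns both stages, because the plug-in Cox variance ignores
  stage-1 estimation error.  For binary exposures X̂ enters on the
  log-odds scale, so multiplying β by ln 2 = 0.693 gives the risk per
  doubling of the odds of the exposure.
- **2×2 factorial MR with RERI.**  Two genetic risk scores are
  dichotomized at their medians (≤ median = low), crossing participants
  into four genetic-predisposition groups.  A Cox model on the three
  non-reference indicators yields HR₁₀, HR₀₁, HR₁₁, and the relative
  excess risk due to interaction

  RERI = HR₁₁ − HR₁₀ − HR₀₁ + 1

  measures departure from additivity (0 = exact additivity), with a
  delta-method CI from the log-HR covariance.  Following the
  convention for preventive exposures, RERI is reported only when no
  HR is below 1.  A continuous variant uses the two standardized
  scores and their product term, evaluating RERI at +1 SD in both.
- **Pleiotropy-robust sensitivity estimators** computed from per-SNP
  exposure (γⱼ) and outcome (Γⱼ, log-HR) associations in the same
  sample: inverse-variance weighting, MR-Egger (its intercept measures
  directional pleiotropy under the InSIDE assumption), simple/weighted
  median, and the weighted mode — plus a Schoenfeld-residual
  proportional-hazards check and a GRS–confounder association scan with
  Bonferroni flagging.
- **GRS construction**: harmonization of external GWAS weights to
  counted alleles (strand/allele flips, palindromic flagging),
  weighted (Σ βⱼ·dosageⱼ) and unweighted (trait-increasing allele
  count) scores, and instrument strength as R² and
  F = R²(n−2)/(1−R²).
- **Deterministic phenotype rules** for questionnaire-derived sleep
  traits (single- and two-question insomnia rules, short ≤ 6 h / long
  ≥ 9 h sleep contrasts against 7–8 h, morning chronotype) and
  incident-versus-prevalent outcome derivation from ICD-coded
  hospital/death records (prefixes 410, I21, I22).

## Worked example

```python
import numpy as np
from sleepmr import (SimScenario, simulate_cohort, tsps_cox,
                     instrument_strength)

sc = SimScenario(n=20_000, m=50, variance_explained=0.02,
                 true_log_hr=float(np.log(1.25)),
                 baseline_hazard_rate=0.005, prevalent_fraction=0.0,
                 seed=2)
cohort, genotypes, variants = simulate_cohort(sc)
grs = genotypes.dosage @ np.array([v.beta for v in variants])

s = instrument_strength(cohort["exposure"].to_numpy(), grs)
print(f"instrument strength: R2 = {s.r2:.4f}, F = {s.f_stat:.1f}")

est = tsps_cox(cohort, "exposure", grs, covariates=["age", "sex"],
               n_boot=200, seed=2)
print(f"TSPS-Cox: HR = {est.hr:.3f} "
      f"(95% CI {est.ci_low:.3f}, {est.ci_high:.3f})")
```

prints

```
instrument strength: R2 = 0.0174, F = 355.1
TSPS-Cox: HR = 1.159 (95% CI 0.753, 1.786)
```

The cohort of 20 000 carries a true hazard ratio of 1.25 per exposure
unit, an instrument explaining ~2% of exposure variance (F ≈ 355, far
above the weak-instrument rule of thumb of 10), and an unmeasured
confounder acting on both exposure and hazard.  The causal HR estimate
1.16 (bootstrap 95% CI 0.75–1.79) covers the truth; a naive Cox
regression on the observed exposure would be biased by the confounder,
while the genetic instrument is not.

## Pipeline CLI

A configuration-driven runner chains
simulate → grs → onesample → factorial → sensitivity:

```bash
mr all --config config.yaml          # every stage, seeded
mr grs --config config.yaml          # any single stage from cached files
mr phenotypes --pheno pheno.csv --diagnoses dx.csv \
   --end-of-followup 2021-03-23 --out followup.csv
```

with a YAML config such as

```yaml
seed: 7
outdir: mr_out
n: 20000
n_boot: 200
covariates: [age, sex]
trait_a: {name: sleep_duration, kind: continuous, m: 50,
          variance_explained: 0.02, true_log_hr: 0.223}
trait_b: {name: insomnia, kind: binary, m: 30,
          variance_explained: 0.02, prevalence: 0.3,
          scale_doubling: true}
```

Every output table carries the config hash and master seed; reruns with
the same config are byte-identical.

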