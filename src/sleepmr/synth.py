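"""Synthetic cohort generator for instrumental-variable survival analyses.

Emulates the data-generating structure a one-sample Mendelian
randomization study of sleep traits and myocardial infarction assumes:
independent biallelic variants in Hardy-Weinberg proportions, an
exposure driven by a genetic risk score plus an unmeasured confounder
(continuous, or binary via a logistic liability), and censored survival
times from a proportional-hazards model with optional direct
(pleiotropic) variant effects on the hazard.  The latent confounder is
retained in the output so oracle analyses can condition on the truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit

_BASES = np.array(list("ACGT"))

ExposureKind = Literal["binary-liability", "continuous"]
PleiotropyKind = Literal["none", "balanced", "directional"]


@dataclass(frozen=True)
class VariantWeight:
    """One instrument SNP with its external-GWAS weight.

    ``beta`` is the per-effect-allele effect on the exposure (trait units
    for a continuous trait, log-odds for a binary one); ``eaf`` the
    effect-allele frequency in the source population.
    """

    variant_id: str
    effect_allele: str
    other_allele: str
    beta: float
    eaf: float
    pval: float = 5e-9

    def __post_init__(self):
        if self.effect_allele == self.other_allele:
            raise ValueError(
                f"{self.variant_id}: effect and other allele are identical"
            )
        for a in (self.effect_allele, self.other_allele):
            if a not in "ACGT":
                raise ValueError(f"{self.variant_id}: invalid allele {a!r}")
        if not 0.0 < self.eaf < 1.0:
            raise ValueError(f"{self.variant_id}: eaf must be in (0,1)")
        if not 0.0 < self.pval <= 1.0:
            raise ValueError(f"{self.variant_id}: pval must be in (0,1]")


@dataclass
class GenotypeMatrix:
    """Effect-allele dosages, samples x variants."""

    sample_ids: list[str]
    variant_ids: list[str]
    dosage: np.ndarray

    def __post_init__(self):
        self.dosage = np.asarray(self.dosage, dtype=float)
        n, m = self.dosage.shape
        if n != len(self.sample_ids) or m != len(self.variant_ids):
            raise ValueError("dosage shape does not match ID lists")
        if len(set(self.variant_ids)) != m:
            raise ValueError("duplicate variant IDs")
        if len(set(self.sample_ids)) != n:
            raise ValueError("duplicate sample IDs")
        if self.dosage.min() < 0 or self.dosage.max() > 2:
            raise ValueError("dosages must lie in [0, 2]")


@dataclass
class SimScenario:
    """All knobs of one simulated cohort.

    ``variance_explained`` is the fraction of exposure (or liability)
    variance attributable to the standardized GRS — the instrument
    strength, on the scale of the R-squared the analysis reports.
    ``true_log_hr`` is per raw exposure unit for a continuous exposure;
    for a binary exposure it is the log hazard ratio of exposed versus
    unexposed.
    """

    n: int = 20_000
    m: int = 50
    eaf_range: tuple[float, float] = (0.1, 0.9)
    beta_mean: float = 0.05
    beta_sd: float = 0.02
    variance_explained: float = 0.02
    exposure_kind: ExposureKind = "continuous"
    prevalence: float = 0.3
    exposure_mean: float = 7.0
    exposure_sd: float = 1.0
    confounder_effect_on_exposure: float = 0.3
    confounder_effect_on_log_hazard: float = 0.3
    true_log_hr: float = float(np.log(1.25))
    pleiotropy: PleiotropyKind = "none"
    pleiotropy_mean: float = 0.0
    pleiotropy_sd: float = 0.0
    baseline_hazard_rate: float = 0.002
    weibull_shape: float = 1.0
    admin_censor_time: float = 12.0
    ltfu_rate: float = 0.0
    prevalent_fraction: float = 0.01
    seed: int = 0

    def __post_init__(self):
        lo, hi = self.eaf_range
        if not (0 < lo <= hi < 1):
            raise ValueError(f"invalid eaf_range {self.eaf_range}")
        if not 0 <= self.variance_explained < 1:
            raise ValueError("variance_explained must be in [0, 1)")
        if not 0 <= self.prevalent_fraction < 1:
            raise ValueError("prevalent_fraction must be in [0, 1)")
        if self.baseline_hazard_rate <= 0:
            raise ValueError("baseline_hazard_rate must be positive")
        if self.admin_censor_time <= 0:
            raise ValueError("admin_censor_time must be positive")

    def rng(self, salt: int = 0) -> np.random.Generator:
        return np.random.default_rng([self.seed, salt])


def simulate_variants(
    m: int,
    eaf_range: tuple[float, float] = (0.1, 0.9),
    beta_mean: float = 0.05,
    beta_sd: float = 0.02,
    seed: int | np.random.Generator = 0,
) -> list[VariantWeight]:
    """Draw ``m`` instrument SNPs with Uniform EAFs and Normal betas."""
    if m < 1:
        raise ValueError("m must be >= 1")
    lo, hi = eaf_range
    if not (0.01 <= lo <= hi <= 0.99):
        raise ValueError(
            f"eaf_range must lie within [0.01, 0.99], got {eaf_range}"
        )
    rng = np.random.default_rng(seed) if isinstance(seed, int) else seed
    eafs = rng.uniform(lo, hi, size=m)
    betas = rng.normal(beta_mean, beta_sd, size=m)
    pairs = np.array([rng.choice(4, size=2, replace=False) for _ in range(m)])
    return [
        VariantWeight(
            variant_id=f"rs{j + 1:06d}",
            effect_allele=str(_BASES[pairs[j, 0]]),
            other_allele=str(_BASES[pairs[j, 1]]),
            beta=float(betas[j]),
            eaf=float(eafs[j]),
        )
        for j in range(m)
    ]


def simulate_genotypes(
    n: int,
    variants: Sequence[VariantWeight],
    seed: int | np.random.Generator = 0,
) -> GenotypeMatrix:
    """Binomial(2, eaf) dosages per variant: Hardy-Weinberg, no LD."""
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed) if isinstance(seed, int) else seed
    eafs = np.array([v.eaf for v in variants])
    dosage = rng.binomial(2, eafs, size=(n, len(variants))).astype(float)
    return GenotypeMatrix(
        sample_ids=[f"S{i + 1:07d}" for i in range(n)],
        variant_ids=[v.variant_id for v in variants],
        dosage=dosage,
    )


def _standardized_grs(genotypes: GenotypeMatrix,
                      variants: Sequence[VariantWeight]) -> np.ndarray:
    betas = np.array([v.beta for v in variants])
    raw = genotypes.dosage @ betas
    sd = raw.std()
    if sd == 0:
        return np.zeros_like(raw)
    return (raw - raw.mean()) / sd


def simulate_exposure(
    genotypes: GenotypeMatrix,
    variants: Sequence[VariantWeight],
    scenario: SimScenario,
) -> tuple[np.ndarray, np.ndarray]:
    """Exposure vector and the latent confounder U that drove it.

    Continuous: X = mean + sd * (a*Z + b*U + e) with Z the standardized
    weighted GRS and ``a = sqrt(variance_explained)``; b is the
    confounder effect and e takes up the remaining unit variance.

    Binary: logistic liability  logit P = b0 + c*Z + b*U, with c set so
    the GRS share of liability variance (logistic residual pi^2/3)
    equals ``variance_explained``, and b0 solved so the mean predicted
    probability hits the target prevalence in this cohort.
    """
    sc = scenario
    rng = sc.rng(salt=2)
    n = len(genotypes.sample_ids)
    z = _standardized_grs(genotypes, variants)
    u = rng.normal(size=n)
    b = sc.confounder_effect_on_exposure
    v = sc.variance_explained

    if sc.exposure_kind == "continuous":
        a = np.sqrt(v)
        resid_var = 1.0 - v - b * b
        if resid_var < 0:
            raise ValueError(
                "variance_explained + confounder variance exceeds 1"
            )
        e = rng.normal(scale=np.sqrt(resid_var), size=n)
        x = sc.exposure_mean + sc.exposure_sd * (a * z + b * u + e)
        return x, u

    if sc.exposure_kind == "binary-liability":
        if not 0 < sc.prevalence < 1:
            raise ValueError(
                f"target prevalence {sc.prevalence} is unreachable"
            )
        lat_var = b * b + np.pi**2 / 3
        c = np.sqrt(v * lat_var / (1.0 - v)) if v > 0 else 0.0
        eta = c * z + b * u

        def mean_p(b0):
            return expit(b0 + eta).mean() - sc.prevalence

        b0 = brentq(mean_p, -40, 40)
        x = rng.binomial(1, expit(b0 + eta)).astype(float)
        return x, u

    raise ValueError(f"unknown exposure_kind {sc.exposure_kind!r}")


def _direct_effects(scenario: SimScenario, m: int,
                    rng: np.random.Generator) -> np.ndarray:
    if scenario.pleiotropy == "none":
        return np.zeros(m)
    mean = scenario.pleiotropy_mean
    if scenario.pleiotropy == "balanced":
        mean = 0.0
    return rng.normal(mean, scenario.pleiotropy_sd, size=m)


def simulate_survival(
    exposure: np.ndarray,
    u: np.ndarray,
    scenario: SimScenario,
    genotypes: GenotypeMatrix | None = None,
    extra_log_hazard: np.ndarray | None = None,
) -> pd.DataFrame:
    """Event times under proportional hazards with admin censoring.

    Hazard: lambda0 * k * t^(k-1) * exp(bX*X + bU*U + sum_j alpha_j g_j)
    with k = ``weibull_shape`` (1 = exponential).  Administrative
    censoring at ``admin_censor_time`` years, plus optional exponential
    loss-to-follow-up; a ``prevalent_fraction`` of rows is flagged
    prevalent, independent of everything else.
    """
    sc = scenario
    rng = sc.rng(salt=3)
    n = len(exposure)
    x = np.asarray(exposure, dtype=float)
    if sc.exposure_kind == "continuous":
        # effect is per exposure unit on the raw trait scale
        lin = sc.true_log_hr * (x - x.mean())
    else:
        lin = sc.true_log_hr * x
    lin = lin + sc.confounder_effect_on_log_hazard * np.asarray(u)
    if genotypes is not None:
        alpha = _direct_effects(sc, genotypes.dosage.shape[1], sc.rng(salt=4))
        lin = lin + genotypes.dosage @ alpha
    if extra_log_hazard is not None:
        lin = lin + np.asarray(extra_log_hazard, dtype=float)
    rate = sc.baseline_hazard_rate * np.exp(lin)

    k = sc.weibull_shape
    e_std = rng.exponential(size=n)
    # inverse of cumulative hazard lambda*t^k
    t_event = (e_std / rate) ** (1.0 / k)
    censor = np.full(n, sc.admin_censor_time)
    if sc.ltfu_rate > 0:
        censor = np.minimum(censor, rng.exponential(1 / sc.ltfu_rate, size=n))
    time = np.minimum(t_event, censor)
    event = (t_event <= censor).astype(int)
    prevalent = (rng.random(n) < sc.prevalent_fraction).astype(int)
    # avoid zero follow-up on the continuous time scale
    time = np.maximum(time, 1e-9)
    return pd.DataFrame({"time": time, "event": event, "prevalent": prevalent})


def simulate_cohort(
    scenario: SimScenario,
    exposure_name: str = "exposure",
) -> tuple[pd.DataFrame, GenotypeMatrix, list[VariantWeight]]:
    """Full cohort: genotypes -> exposure -> survival, plus covariates.

    Age and sex are independent baseline covariates (they enter the Cox
    adjustment set without confounding the genetic instrument, mirroring
    how covariates behave under random allele assignment).
    """
    sc = scenario
    variants = simulate_variants(
        sc.m, sc.eaf_range, sc.beta_mean, sc.beta_sd, seed=sc.rng(salt=0)
    )
    genotypes = simulate_genotypes(sc.n, variants, seed=sc.rng(salt=1))
    x, u = simulate_exposure(genotypes, variants, sc)
    surv = simulate_survival(x, u, sc, genotypes=genotypes)
    rng = sc.rng(salt=5)
    cohort = pd.DataFrame(
        {
            "sample_id": genotypes.sample_ids,
            exposure_name: x,
            "age": rng.normal(56.0, 8.0, size=sc.n),
            "sex": rng.integers(0, 2, size=sc.n).astype(float),
            "confounder_u": u,
        }
    )
    cohort = pd.concat([cohort, surv], axis=1)
    return cohort, genotypes, variants


# ---------------------------------------------------------------------------
# delimited-text I/O

WEIGHTS_COLUMNS = [
    "variant_id", "effect_allele", "other_allele", "beta", "eaf", "pval",
]


def write_weights_tsv(variants: Sequence[VariantWeight], path) -> None:
    pd.DataFrame([asdict(v) for v in variants])[WEIGHTS_COLUMNS].to_csv(
        path, sep="\t", index=False
    )


def read_weights_tsv(path) -> list[VariantWeight]:
    df = pd.read_csv(path, sep="\t")
    missing = set(WEIGHTS_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"weights file missing columns: {sorted(missing)}")
    return [
        VariantWeight(
            variant_id=str(r.variant_id),
            effect_allele=str(r.effect_allele),
            other_allele=str(r.other_allele),
            beta=float(r.beta),
            eaf=float(r.eaf),
            pval=float(r.pval),
        )
        for r in df.itertuples()
    ]


def write_genotypes_tsv(genotypes: GenotypeMatrix, path) -> None:
    df = pd.DataFrame(
        genotypes.dosage,
        index=pd.Index(genotypes.sample_ids, name="sample_id"),
        columns=genotypes.variant_ids,
    )
    df.to_csv(path, sep="\t")


def read_genotypes_tsv(path) -> GenotypeMatrix:
    df = pd.read_csv(path, sep="\t", index_col="sample_id")
    return GenotypeMatrix(
        sample_ids=[str(s) for s in df.index],
        variant_ids=[str(c) for c in df.columns],
        dosage=df.to_numpy(dtype=float),
    )


def write_cohort_csv(cohort: pd.DataFrame, path) -> None:
    cohort.to_csv(path, index=False)


def read_cohort_csv(path) -> pd.DataFrame:
    return pd.read_csv(path)
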