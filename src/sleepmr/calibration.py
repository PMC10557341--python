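"""Replicate-level simulation studies of the package's own estimators.

Each function runs a small Monte-Carlo design — simulate a cohort under
known truth, analyze it with the package, repeat — and reports the
summary a methodologist checks: bias, CI coverage, type-I error.  These
are the studies behind the package's calibration claims; problem sizes
are arguments so callers can trade precision for run time.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import sensitivity as sens
from .factorial import assign_2x2_groups, factorial_cox
from .onesample import tsps_cox
from .synth import SimScenario, simulate_cohort


def tsps_recovery_study(
    n_rep: int = 200,
    n: int = 2500,
    m: int = 40,
    variance_explained: float = 0.05,
    true_hr: float = 1.25,
    n_boot: int = 100,
    baseline_hazard_rate: float = 0.01,
    seed: int = 0,
) -> dict:
    """Bias and bootstrap-CI coverage of the TSPS-Cox estimator.

    Each replicate simulates a confounded cohort with a valid
    instrument, runs the full two-stage analysis with bootstrap SEs,
    and records whether truth lies within 3 bootstrap SEs of the point
    estimate and inside the 95% CI.
    """
    truth = float(np.log(true_hr))
    betas, ses, cover, within = [], [], 0, 0
    for rep in range(n_rep):
        sc = SimScenario(
            n=n, m=m, variance_explained=variance_explained,
            true_log_hr=truth, baseline_hazard_rate=baseline_hazard_rate,
            prevalent_fraction=0.0,
            seed=int(np.random.default_rng([seed, rep]).integers(2**31)),
        )
        cohort, geno, variants = simulate_cohort(sc)
        grs = geno.dosage @ np.array([v.beta for v in variants])
        est = tsps_cox(
            cohort, "exposure", grs, covariates=["age", "sex"],
            n_boot=n_boot, seed=rep,
        )
        betas.append(est.beta)
        ses.append(est.se)
        if est.ci_low <= true_hr <= est.ci_high:
            cover += 1
        if abs(est.beta - truth) <= 3 * est.se:
            within += 1
    betas = np.array(betas)
    return {
        "true_log_hr": truth,
        "mean_log_hr": float(betas.mean()),
        "sd_log_hr": float(betas.std(ddof=1)),
        "mean_se": float(np.mean(ses)),
        "ci_coverage": cover / n_rep,
        "within_3se": within / n_rep,
        "n_rep": n_rep,
    }


def reri_calibration_study(
    n_rep: int = 200,
    n: int = 20_000,
    joint: str = "additive",
    hr_10: float = 1.3,
    hr_01: float = 1.4,
    lam0: float = 0.01,
    censor: float = 12.0,
    seed: int = 0,
) -> dict:
    """Distribution of the 2x2 RERI estimate under known joint effects.

    "additive" builds the double-exposure hazard as baseline plus both
    excesses (true RERI 0); "multiplicative" multiplies the two hazard
    ratios (true RERI (HR10-1)(HR01-1)).
    """
    if joint == "additive":
        hr_11 = hr_10 + hr_01 - 1.0
        true_reri = 0.0
    elif joint == "multiplicative":
        hr_11 = hr_10 * hr_01
        true_reri = (hr_10 - 1.0) * (hr_01 - 1.0)
    else:
        raise ValueError(f"unknown joint effect {joint!r}")
    hr_map = {"both_low": 1.0, "a_high": hr_10, "b_high": hr_01,
              "both_high": hr_11}
    reris = []
    for rep in range(n_rep):
        rng = np.random.default_rng([seed, rep])
        ga, gb = rng.normal(size=n), rng.normal(size=n)
        groups = assign_2x2_groups(ga, gb)
        rate = lam0 * np.array([hr_map[g] for g in groups])
        t = rng.exponential(1.0 / rate)
        surv = pd.DataFrame(
            {"time": np.minimum(t, censor),
             "event": (t <= censor).astype(int)}
        )
        res = factorial_cox(surv, groups, engine="fast")
        hr = res.hr
        reris.append(
            hr["both_high"] - hr["a_high"] - hr["b_high"] + 1.0
        )
    reris = np.array(reris)
    return {
        "true_reri": true_reri,
        "mean_reri": float(reris.mean()),
        "sd_reri": float(reris.std(ddof=1)),
        "mc_se": float(reris.std(ddof=1) / np.sqrt(n_rep)),
        "n_rep": n_rep,
    }


def egger_pleiotropy_study(
    n_rep: int = 200,
    m: int = 30,
    causal_beta: float = 0.4,
    alpha_mean: float = 0.01,
    alpha_sd: float = 0.005,
    seed: int = 0,
) -> dict:
    """MR-Egger intercept coverage under directional pleiotropy.

    Summary statistics are simulated at the variant level: gamma_j drawn
    with sampling noise, direct effects alpha_j ~ N(alpha_mean,
    alpha_sd) independent of instrument strength (InSIDE holds), and
    Gamma_j = beta gamma_j + alpha_j + noise.
    """
    rng = np.random.default_rng(seed)
    cover = 0
    intercepts = []
    for _ in range(n_rep):
        gamma_true = rng.uniform(0.05, 0.15, size=m)
        se_gamma = np.full(m, 0.005)
        gamma = rng.normal(gamma_true, se_gamma)
        alpha = rng.normal(alpha_mean, alpha_sd, size=m)
        se_Gamma = rng.uniform(0.01, 0.02, size=m)
        Gamma = rng.normal(causal_beta * gamma_true + alpha, se_Gamma)
        assoc = pd.DataFrame(
            {
                "variant_id": [f"rs{j}" for j in range(m)],
                "gamma": gamma,
                "se_gamma": se_gamma,
                "Gamma": Gamma,
                "se_Gamma": se_Gamma,
            }
        )
        out = sens.mr_egger(assoc)
        lo, hi = out["intercept_ci"]
        if lo <= alpha_mean <= hi:
            cover += 1
        intercepts.append(out["intercept"])
    return {
        "true_intercept": alpha_mean,
        "mean_intercept": float(np.mean(intercepts)),
        "intercept_ci_coverage": cover / n_rep,
        "n_rep": n_rep,
    }


def schoenfeld_type1_study(
    n_rep: int = 400,
    n: int = 300,
    beta: float = 0.3,
    lam0: float = 0.05,
    censor: float = 12.0,
    seed: int = 0,
) -> dict:
    """Type-I error of the Schoenfeld PH test under exact PH."""
    rejections = 0
    for rep in range(n_rep):
        rng = np.random.default_rng([seed, rep])
        x = rng.normal(size=n)
        t = rng.exponential(1.0 / (lam0 * np.exp(beta * x)))
        df = pd.DataFrame(
            {
                "x": x,
                "time": np.minimum(t, censor),
                "event": (t <= censor).astype(int),
            }
        )
        out = sens.ph_schoenfeld_test(df, ["x"])
        if out.loc[0, "p_value"] < 0.05:
            rejections += 1
    return {
        "type1_rate": rejections / n_rep,
        "nominal": 0.05,
        "n_rep": n_rep,
    }


def confounder_scan_type1_study(
    n_rep: int = 400,
    n: int = 500,
    n_cov: int = 5,
    seed: int = 0,
) -> dict:
    """Raw p<0.05 rate of the confounder scan on independent data."""
    n_sig = 0
    n_tests = 0
    for rep in range(n_rep):
        rng = np.random.default_rng([seed, rep])
        grs = pd.DataFrame({"g": rng.normal(size=n)})
        covs = pd.DataFrame(
            rng.normal(size=(n, n_cov)),
            columns=[f"c{j}" for j in range(n_cov)],
        )
        out = sens.confounder_scan(grs, covs)
        n_sig += int((out["p_value"] < 0.05).sum())
        n_tests += len(out)
    return {
        "type1_rate": n_sig / n_tests,
        "nominal": 0.05,
        "n_tests": n_tests,
        "n_rep": n_rep,
    }
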