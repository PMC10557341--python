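"""Pleiotropy-robust estimators and model diagnostics.

Computes per-variant SNP-exposure (gamma) and SNP-outcome (Gamma,
log-HR) associations from the same cohort, then applies the standard
summary-statistic MR estimators in a one-sample setting: inverse-
variance weighting, MR-Egger (whose intercept measures directional
pleiotropy under the InSIDE assumption), the simple/weighted median
(valid if at least half the weight is on valid instruments), and the
weighted mode (valid under a plurality of valid instruments).  Also
provides the Schoenfeld-residual proportional-hazards check and a
GRS-confounder association scan with Bonferroni flagging.

Estimator variances use the multiplicative random-effects convention:
the residual dispersion scales standard errors but is floored at 1 so
underdispersion never shrinks them.
"""

from __future__ import annotations

import math
import warnings
from typing import Literal, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from lifelines import CoxPHFitter
from scipy import stats

from ._cox import fit_cox
from .onesample import MRCoxEstimate, design_matrix
from .synth import GenotypeMatrix

ASSOC_COLUMNS = ["variant_id", "gamma", "se_gamma", "Gamma", "se_Gamma"]


def per_snp_associations(
    cohort: pd.DataFrame,
    genotypes: GenotypeMatrix,
    exposure_name: str,
    covariates: Sequence[str] = (),
    exposure_kind: Literal["continuous", "binary"] = "continuous",
    *,
    time_col: str = "time",
    event_col: str = "event",
) -> pd.DataFrame:
    """Per-variant exposure and outcome associations.

    gamma_j: coefficient of dosage_j in a regression of the exposure on
    dosage plus covariates, restricted to non-cases (mirroring the TSPS
    stage-1 restriction).  Gamma_j: log-HR of dosage_j from a Cox model
    with the same covariates on the full analysis set.  Monomorphic
    variants are dropped with a warning.
    """
    covs = design_matrix(cohort, covariates)
    x = cohort[exposure_name].to_numpy(dtype=float)
    time = cohort[time_col].to_numpy(dtype=float)
    event = cohort[event_col].to_numpy(dtype=int)
    noncase = event == 0
    rows = []
    for j, vid in enumerate(genotypes.variant_ids):
        dose = genotypes.dosage[:, j]
        if dose.std() == 0:
            warnings.warn(f"{vid}: monomorphic, dropped from associations")
            continue
        Xg = np.column_stack([np.ones(len(dose)), dose, covs])
        if exposure_kind == "continuous":
            fit = sm.OLS(x[noncase], Xg[noncase]).fit()
        else:
            fit = sm.Logit(x[noncase], Xg[noncase]).fit(disp=0)
        gamma, se_gamma = fit.params[1], fit.bse[1]
        cox = fit_cox(
            np.column_stack([dose, covs]), time, event
        )
        rows.append(
            {
                "variant_id": vid,
                "gamma": float(gamma),
                "se_gamma": float(se_gamma),
                "Gamma": float(cox.beta[0]),
                "se_Gamma": float(cox.se[0]),
            }
        )
    return pd.DataFrame(rows, columns=ASSOC_COLUMNS)


def _validate_assoc(assoc: pd.DataFrame, min_variants: int = 1):
    missing = set(ASSOC_COLUMNS) - set(assoc.columns)
    if missing:
        raise ValueError(f"association table missing columns {missing}")
    if len(assoc) < min_variants:
        raise ValueError(f"need at least {min_variants} variants")
    if (assoc["se_gamma"] <= 0).any() or (assoc["se_Gamma"] <= 0).any():
        raise ValueError("standard errors must be positive")


def ivw(assoc: pd.DataFrame) -> MRCoxEstimate:
    """Inverse-variance-weighted regression of Gamma on gamma (no
    intercept), weights 1 / se(Gamma)^2."""
    _validate_assoc(assoc, 1)
    g = assoc["gamma"].to_numpy(dtype=float)
    G = assoc["Gamma"].to_numpy(dtype=float)
    w = 1.0 / assoc["se_Gamma"].to_numpy(dtype=float) ** 2
    denom = np.sum(w * g * g)
    if denom == 0:
        raise ValueError("all SNP-exposure associations are zero")
    beta = float(np.sum(w * g * G) / denom)
    if len(assoc) > 1:
        resid = G - beta * g
        scale = float(np.sum(w * resid**2) / (len(assoc) - 1))
    else:
        scale = 1.0
    se = math.sqrt(max(scale, 1.0) / denom)
    return MRCoxEstimate(
        beta=beta, se=se,
        ci_low=math.exp(beta - 1.96 * se),
        ci_high=math.exp(beta + 1.96 * se),
        n_used=len(assoc), method="ivw",
    )


def mr_egger(assoc: pd.DataFrame) -> dict:
    """MR-Egger: weighted regression of Gamma on gamma with intercept.

    gammas are oriented non-negative (Gammas sign-flipped with them);
    the intercept estimates average directional pleiotropy, the slope
    the causal effect under InSIDE.
    """
    _validate_assoc(assoc, 3)
    g = assoc["gamma"].to_numpy(dtype=float).copy()
    G = assoc["Gamma"].to_numpy(dtype=float).copy()
    w = 1.0 / assoc["se_Gamma"].to_numpy(dtype=float) ** 2
    flip = g < 0
    g[flip] *= -1
    G[flip] *= -1
    X = np.column_stack([np.ones_like(g), g])
    fit = sm.WLS(G, X, weights=w).fit()
    scale = max(float(fit.scale), 1.0)
    cov = fit.normalized_cov_params * scale
    se = np.sqrt(np.diag(cov))
    intercept, slope = fit.params
    return {
        "slope": float(slope),
        "se_slope": float(se[1]),
        "slope_ci": (slope - 1.96 * se[1], slope + 1.96 * se[1]),
        "intercept": float(intercept),
        "se_intercept": float(se[0]),
        "intercept_ci": (
            intercept - 1.96 * se[0], intercept + 1.96 * se[0]
        ),
        "n_used": len(assoc),
    }


def _ratio_table(assoc: pd.DataFrame) -> pd.DataFrame:
    keep = assoc["gamma"] != 0
    if (~keep).any():
        warnings.warn(
            f"{int((~keep).sum())} variant(s) with gamma = 0 dropped "
            "from ratio-based estimator"
        )
    return assoc.loc[keep].reset_index(drop=True)


def _weighted_median(b: np.ndarray, w: np.ndarray) -> float:
    """Interpolated weighted median at midpoint cumulative weight 0.5."""
    order = np.argsort(b)
    b = b[order]
    w = w[order] / w.sum()
    cum = np.cumsum(w) - w / 2
    return float(np.interp(0.5, cum, b))


def weighted_median(
    assoc: pd.DataFrame,
    mode: Literal["simple", "weighted"] = "weighted",
    n_boot: int = 1000,
    seed: int = 0,
) -> MRCoxEstimate:
    """Median of per-variant ratio estimates Gamma_j / gamma_j.

    "simple" uses equal weights; "weighted" uses inverse-variance
    weights gamma_j^2 / se(Gamma_j)^2 for the ratio.  SE by parametric
    bootstrap of (gamma_j, Gamma_j) from their sampling normals.
    """
    _validate_assoc(assoc, 2)
    tab = _ratio_table(assoc)
    if len(tab) < 2:
        raise ValueError("need at least 2 usable variants")
    g = tab["gamma"].to_numpy(float)
    G = tab["Gamma"].to_numpy(float)
    seg = tab["se_gamma"].to_numpy(float)
    seG = tab["se_Gamma"].to_numpy(float)

    def weights(gam):
        if mode == "simple":
            return np.ones_like(gam)
        return gam**2 / seG**2

    beta = _weighted_median(G / g, weights(g))
    rng = np.random.default_rng(seed)
    reps = np.empty(n_boot)
    for i in range(n_boot):
        gs = rng.normal(g, seg)
        Gs = rng.normal(G, seG)
        ok = gs != 0
        reps[i] = _weighted_median((Gs / gs)[ok], weights(gs)[ok])
    se = float(reps.std(ddof=1))
    return MRCoxEstimate(
        beta=beta, se=se,
        ci_low=math.exp(beta - 1.96 * se),
        ci_high=math.exp(beta + 1.96 * se),
        n_used=len(tab), n_boot=n_boot, seed=seed,
        method=f"{mode}_median",
    )


def _mode_bandwidth(b: np.ndarray, factor: float) -> float:
    """Silverman-style spread rule on the MAD-consistent sigma."""
    n = len(b)
    mad_sigma = stats.median_abs_deviation(b, scale="normal")
    spread = min(np.std(b, ddof=1), mad_sigma) if mad_sigma > 0 else np.std(
        b, ddof=1
    )
    if spread == 0:
        return 0.0
    return factor * 0.9 * spread * n ** (-0.2)


def _weighted_mode_point(
    b: np.ndarray, w: np.ndarray, h: float, grid_size: int = 2048
) -> float:
    grid = np.linspace(b.min() - 3 * h, b.max() + 3 * h, grid_size)
    dens = np.sum(
        w[:, None] * np.exp(-0.5 * ((grid[None, :] - b[:, None]) / h) ** 2),
        axis=0,
    )
    return float(grid[np.argmax(dens)])


def weighted_mode(
    assoc: pd.DataFrame,
    bandwidth_factor: float = 1.0,
    n_boot: int = 1000,
    seed: int = 0,
) -> MRCoxEstimate:
    """Mode of the weighted kernel density of ratio estimates.

    Weights are inverse-variance (gamma^2 / se(Gamma)^2); bandwidth is
    ``bandwidth_factor`` times a Silverman-type rule on the smaller of
    the SD and the MAD-based sigma of the ratios.  SE by parametric
    bootstrap.
    """
    _validate_assoc(assoc, 3)
    tab = _ratio_table(assoc)
    if len(tab) < 3:
        raise ValueError("need at least 3 usable variants")
    g = tab["gamma"].to_numpy(float)
    G = tab["Gamma"].to_numpy(float)
    seg = tab["se_gamma"].to_numpy(float)
    seG = tab["se_Gamma"].to_numpy(float)
    b = G / g
    w = g**2 / seG**2
    if np.all(b == b[0]):
        beta = float(b[0])
        se = 0.0
    else:
        h = _mode_bandwidth(b, bandwidth_factor)
        if h <= 0:
            raise ValueError("zero bandwidth: degenerate ratio spread")
        beta = _weighted_mode_point(b, w / w.sum(), h)
        rng = np.random.default_rng(seed)
        reps = np.empty(n_boot)
        for i in range(n_boot):
            gs = rng.normal(g, seg)
            Gs = rng.normal(G, seG)
            ok = gs != 0
            bs = (Gs / gs)[ok]
            ws = (gs**2 / seG**2)[ok]
            hs = _mode_bandwidth(bs, bandwidth_factor)
            reps[i] = (
                _weighted_mode_point(bs, ws / ws.sum(), hs)
                if hs > 0 else np.median(bs)
            )
        se = float(reps.std(ddof=1))
    return MRCoxEstimate(
        beta=beta, se=se,
        ci_low=math.exp(beta - 1.96 * se),
        ci_high=math.exp(beta + 1.96 * se),
        n_used=len(tab), n_boot=n_boot, seed=seed,
        method="weighted_mode",
    )


# ---------------------------------------------------------------------------
# diagnostics


def ph_schoenfeld_test(
    cohort: pd.DataFrame,
    model_columns: Sequence[str],
    *,
    time_col: str = "time",
    event_col: str = "event",
) -> pd.DataFrame:
    """Proportional-hazards check via Schoenfeld residuals.

    Fits the Cox model on ``model_columns`` and, for each term, reports
    the Pearson correlation of its Schoenfeld residuals (one per event)
    with follow-up time, with a two-sided p-value.
    """
    if int(cohort[event_col].sum()) < 2:
        raise ValueError("Schoenfeld test needs at least 2 events")
    df = cohort[list(model_columns) + [time_col, event_col]].copy()
    cph = CoxPHFitter()
    cph.fit(df, duration_col=time_col, event_col=event_col)
    resid = cph.compute_residuals(df, kind="schoenfeld")
    event_times = df.loc[resid.index, time_col].to_numpy(dtype=float)
    rows = []
    for col in model_columns:
        r, p = stats.pearsonr(event_times, resid[col].to_numpy(dtype=float))
        rows.append({"term": col, "correlation": r, "p_value": p})
    return pd.DataFrame(rows)


def confounder_scan(
    grs_table: pd.DataFrame,
    covariate_table: pd.DataFrame,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Associations of each standardized GRS with each covariate.

    Linear regression for numeric covariates, logistic for binary ones;
    constant covariates are skipped with a warning.  The Bonferroni
    threshold is alpha / (number of GRS x number of covariates tested)
    and rows below it are flagged.
    """
    if grs_table.shape[1] < 1 or covariate_table.shape[1] < 1:
        raise ValueError("need at least one GRS and one covariate")
    usable = []
    for cov in covariate_table.columns:
        v = covariate_table[cov].to_numpy(dtype=float)
        if np.std(v) == 0:
            warnings.warn(f"covariate {cov!r} is constant, skipped")
            continue
        usable.append(cov)
    n_tests = grs_table.shape[1] * len(usable)
    if n_tests == 0:
        raise ValueError("no usable covariates")
    threshold = alpha / n_tests
    rows = []
    for gname in grs_table.columns:
        g = grs_table[gname].to_numpy(dtype=float)
        z = (g - g.mean()) / g.std()
        X = sm.add_constant(z)
        for cov in usable:
            y = covariate_table[cov].to_numpy(dtype=float)
            uniq = np.unique(y)
            if len(uniq) == 2 and set(uniq) <= {0.0, 1.0}:
                fit = sm.Logit(y, X).fit(disp=0)
                kind = "logistic"
            else:
                fit = sm.OLS(y, X).fit()
                kind = "linear"
            rows.append(
                {
                    "grs": gname,
                    "covariate": cov,
                    "model": kind,
                    "beta_per_sd": float(fit.params[1]),
                    "se": float(fit.bse[1]),
                    "p_value": float(fit.pvalues[1]),
                    "bonferroni_threshold": threshold,
                    "flagged": bool(fit.pvalues[1] < threshold),
                }
            )
    return pd.DataFrame(rows)


def write_assoc_tsv(assoc: pd.DataFrame, path) -> None:
    assoc[ASSOC_COLUMNS].to_csv(path, sep="\t", index=False)


def read_assoc_tsv(path) -> pd.DataFrame:
    assoc = pd.read_csv(path, sep="\t")
    _validate_assoc(assoc)
    return assoc
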