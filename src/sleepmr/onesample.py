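"""One-sample Mendelian randomization with a Cox second stage.

Two-stage predictor substitution (TSPS): stage 1 regresses the exposure
on the genetic risk score plus covariates — linear for a continuous
exposure, logistic for a binary one — fitting on participants who never
experience the event (cases would otherwise contaminate the
instrument-exposure fit) but predicting for everyone.  Stage 2 is a Cox
proportional-hazards regression of the survival outcome on the stage-1
fitted values plus the same covariates; its coefficient on the fitted
value is the causal log hazard ratio.  Standard errors come from a
participant-resampling bootstrap that reruns both stages, since the
plug-in Cox variance ignores first-stage estimation error.

For binary exposures the fitted values enter stage 2 on the linear
predictor (log-odds) scale, so multiplying the estimate by ln 2 = 0.693
converts it exactly to risk per doubling of the odds of the exposure.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Callable, Literal, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from statsmodels.tools.sm_exceptions import (
    PerfectSeparationError,
    PerfectSeparationWarning,
)

from ._cox import CoxConvergenceError, fit_cox

logger = logging.getLogger(__name__)

LN2 = math.log(2.0)


@dataclass
class MRCoxEstimate:
    """Causal log-HR with bootstrap uncertainty."""

    beta: float
    se: float
    ci_low: float            # on the HR scale
    ci_high: float
    scaled_doubling: bool = False
    n_boot: int = 0
    seed: int | None = None
    n_used: int = 0
    n_events: int = 0
    ci_low_percentile: float | None = None
    ci_high_percentile: float | None = None
    method: str = "tsps_cox"

    @property
    def hr(self) -> float:
        return math.exp(self.beta)

    def summary_row(self) -> dict:
        return {
            "method": self.method,
            "beta": self.beta,
            "se": self.se,
            "hr": self.hr,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "scaled_doubling": self.scaled_doubling,
            "n": self.n_used,
            "events": self.n_events,
            "n_boot": self.n_boot,
            "seed": self.seed,
        }


def scale_per_doubling(beta: float, se: float) -> tuple[float, float]:
    """Rescale a per-unit-log-odds estimate to per doubling of odds.

    Both the point estimate and its standard error are multiplied by
    ln 2 (0.693 to three decimals).
    """
    if not (np.isfinite(beta) and np.isfinite(se)):
        raise ValueError("beta and se must be finite")
    return beta * LN2, se * LN2


def design_matrix(
    cohort: pd.DataFrame, covariates: Sequence[str]
) -> np.ndarray:
    """Numeric covariate matrix; categorical columns are dummy-coded."""
    if not covariates:
        return np.empty((len(cohort), 0))
    missing = [c for c in covariates if c not in cohort.columns]
    if missing:
        raise ValueError(f"covariates absent from cohort: {missing}")
    block = pd.get_dummies(
        cohort[list(covariates)], drop_first=True, dtype=float
    )
    return block.to_numpy(dtype=float)


def _drop_constant(mat: np.ndarray) -> tuple[np.ndarray, int]:
    if mat.shape[1] == 0:
        return mat, 0
    keep = mat.std(axis=0) > 0
    return mat[:, keep], int((~keep).sum())


def first_stage_fitted(
    exposure: np.ndarray,
    grs: np.ndarray,
    covs: np.ndarray,
    event: np.ndarray,
    kind: Literal["continuous", "binary"],
    binary_scale: Literal["linear_predictor", "probability"] =
        "linear_predictor",
) -> np.ndarray:
    """Stage-1 fitted values for all rows, fit restricted to non-cases."""
    X = np.column_stack([np.ones(len(grs)), grs, covs])
    noncase = np.asarray(event) == 0
    if noncase.sum() < X.shape[1] + 1:
        raise ValueError("too few non-cases for the stage-1 fit")
    if kind == "continuous":
        coef, *_ = np.linalg.lstsq(X[noncase], exposure[noncase], rcond=None)
        return X @ coef
    if kind == "binary":
        import warnings as _warnings

        try:
            with _warnings.catch_warnings():
                _warnings.simplefilter("error", PerfectSeparationWarning)
                fit = sm.Logit(exposure[noncase], X[noncase]).fit(
                    disp=0, maxiter=100
                )
        except (PerfectSeparationError, PerfectSeparationWarning,
                np.linalg.LinAlgError) as exc:
            raise ValueError(
                "stage-1 logistic regression failed (separation or "
                f"singular design): {exc}"
            ) from exc
        if not fit.mle_retvals.get("converged", True):
            raise ValueError(
                "stage-1 logistic regression did not converge "
                "(possible separation)"
            )
        eta = X @ fit.params
        if binary_scale == "linear_predictor":
            return eta
        return 1.0 / (1.0 + np.exp(-eta))
    raise ValueError(f"unknown exposure kind {kind!r}")


def _two_stage_beta(
    exposure: np.ndarray,
    grs: np.ndarray,
    covs: np.ndarray,
    time: np.ndarray,
    event: np.ndarray,
    kind: str,
    binary_scale: str,
) -> float:
    covs, n_dropped = _drop_constant(covs)
    if n_dropped:
        logger.debug("dropped %d constant covariate column(s)", n_dropped)
    fitted = first_stage_fitted(
        exposure, grs, covs, event, kind, binary_scale
    )
    Z = np.column_stack([fitted, covs])
    res = fit_cox(Z, time, event)
    return float(res.beta[0])


def tsps_cox(
    cohort: pd.DataFrame,
    exposure_name: str,
    grs: np.ndarray | str,
    covariates: Sequence[str] = (),
    exposure_kind: Literal["continuous", "binary"] = "continuous",
    scale_doubling: bool = False,
    n_boot: int = 2000,
    seed: int = 0,
    *,
    time_col: str = "time",
    event_col: str = "event",
    binary_fitted_scale: Literal["linear_predictor", "probability"] =
        "linear_predictor",
    max_failure_frac: float = 0.05,
) -> MRCoxEstimate:
    """Two-stage predictor substitution with a Cox second stage.

    Prevalent cases must already be excluded from ``cohort``.  Returns
    the causal log hazard ratio per exposure unit (continuous) or — with
    ``scale_doubling`` — per doubling of the odds of a binary exposure,
    with bootstrap SE, normal-approximation CI and percentile CI.
    """
    if "prevalent" in cohort.columns and cohort["prevalent"].any():
        raise ValueError(
            "cohort contains prevalent rows; exclude them before analysis"
        )
    g = (
        cohort[grs].to_numpy(dtype=float)
        if isinstance(grs, str)
        else np.asarray(grs, dtype=float)
    )
    if g.std() == 0:
        raise ValueError("GRS is constant")
    x = cohort[exposure_name].to_numpy(dtype=float)
    covs = design_matrix(cohort, covariates)
    time = cohort[time_col].to_numpy(dtype=float)
    event = cohort[event_col].to_numpy(dtype=int)
    if event.sum() == 0:
        raise ValueError("no events in cohort")

    beta = _two_stage_beta(
        x, g, covs, time, event, exposure_kind, binary_fitted_scale
    )

    def refit(idx: np.ndarray) -> float:
        return _two_stage_beta(
            x[idx], g[idx], covs[idx], time[idx], event[idx],
            exposure_kind, binary_fitted_scale,
        )

    se, ci_lo_b, ci_hi_b, pct_lo, pct_hi = _bootstrap_indices(
        refit, len(cohort), beta, n_boot, seed, max_failure_frac
    )

    scaled = bool(scale_doubling and exposure_kind == "binary")
    if scaled:
        factor = LN2
        beta, se = beta * factor, se * factor
        ci_lo_b, ci_hi_b = ci_lo_b * factor, ci_hi_b * factor
        pct_lo, pct_hi = pct_lo * factor, pct_hi * factor

    return MRCoxEstimate(
        beta=beta,
        se=se,
        ci_low=math.exp(ci_lo_b),
        ci_high=math.exp(ci_hi_b),
        scaled_doubling=scaled,
        n_boot=n_boot,
        seed=seed,
        n_used=len(cohort),
        n_events=int(event.sum()),
        ci_low_percentile=math.exp(pct_lo),
        ci_high_percentile=math.exp(pct_hi),
    )


def _bootstrap_indices(
    refit: Callable[[np.ndarray], float],
    n: int,
    beta: float,
    n_boot: int,
    seed: int,
    max_failure_frac: float,
) -> tuple[float, float, float, float, float]:
    if n_boot < 100:
        raise ValueError("n_boot must be at least 100")
    betas = []
    failures = 0
    for i in range(n_boot):
        rng = np.random.default_rng([seed, i])  # counter-derived stream
        idx = rng.integers(0, n, size=n)
        try:
            betas.append(refit(idx))
        except (ValueError, CoxConvergenceError) as exc:
            failures += 1
            logger.debug("bootstrap replicate %d failed: %s", i, exc)
    if failures > max_failure_frac * n_boot:
        raise RuntimeError(
            f"{failures}/{n_boot} bootstrap replicates failed to fit"
        )
    bs = np.array(betas)
    se = float(bs.std(ddof=1))
    lo, hi = np.percentile(bs, [2.5, 97.5])
    return se, beta - 1.96 * se, beta + 1.96 * se, float(lo), float(hi)


def bootstrap_se(
    fit_procedure: Callable[[pd.DataFrame], float],
    cohort: pd.DataFrame,
    n_boot: int = 2000,
    seed: int = 0,
    *,
    max_failure_frac: float = 0.05,
) -> dict:
    """Participant-resampling bootstrap of an arbitrary scalar estimator.

    ``fit_procedure`` maps a cohort DataFrame to a point estimate; it is
    rerun on ``n_boot`` with-replacement resamples.  Returns the SE
    (SD of replicate estimates), the normal-approximation 95% CI around
    the full-sample estimate, and the percentile CI.  Replicate streams
    derive from (seed, replicate-index) so changing ``n_boot`` never
    reorders earlier draws.
    """
    point = fit_procedure(cohort)

    def refit(idx: np.ndarray) -> float:
        return fit_procedure(cohort.iloc[idx].reset_index(drop=True))

    se, lo, hi, plo, phi = _bootstrap_indices(
        refit, len(cohort), point, n_boot, seed, max_failure_frac
    )
    return {
        "estimate": point,
        "se": se,
        "ci_low": lo,
        "ci_high": hi,
        "ci_low_percentile": plo,
        "ci_high_percentile": phi,
        "n_boot": n_boot,
        "seed": seed,
    }
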