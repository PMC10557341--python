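"""Factorial Mendelian randomization and additive-interaction statistics.

The 2x2 design crosses two median-split genetic risk scores into four
genetic-predisposition groups and fits a Cox model with indicators for
the three non-reference groups; the relative excess risk due to
interaction (RERI = HR11 - HR10 - HR01 + 1) then measures departure
from additivity of the two excess risks.  RERI = 0 is exact additivity,
RERI > 0 synergism, RERI < 0 antagonism.  Following the convention for
preventive exposures, RERI is only computed when none of the three
hazard ratios is below 1; otherwise it is flagged undefined (an
override exists for methodological work).

A continuous variant treats the two standardized scores and their
product as quantitative Cox terms and evaluates RERI at +1 SD in both.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter

from ._cox import fit_cox

GROUP_LABELS = ("both_low", "a_high", "b_high", "both_high")


def assign_2x2_groups(
    grsA: np.ndarray, grsB: np.ndarray
) -> np.ndarray:
    """Four-group label per sample from the two median splits.

    Scores at or below their median are "low"; ``both_low`` is the
    reference group.
    """
    a = np.asarray(grsA, dtype=float)
    b = np.asarray(grsB, dtype=float)
    if a.shape != b.shape:
        raise ValueError("GRS vectors have different lengths")
    a_high = a > np.median(a)
    b_high = b > np.median(b)
    out = np.where(
        a_high & b_high, "both_high",
        np.where(a_high, "a_high", np.where(b_high, "b_high", "both_low")),
    )
    return out


@dataclass
class FactorialResult:
    """Three group HRs against the double-low reference, plus RERI."""

    group_sizes: dict
    group_events: dict
    log_hr: np.ndarray           # (b10, b01, b11) for a/b/both high
    log_hr_covariance: np.ndarray
    ci: dict = field(default_factory=dict)   # label -> (lo, hi) on HR scale
    reri: float | None = None
    reri_ci: tuple[float, float] | None = None
    reri_undefined_reason: str | None = None

    @property
    def hr(self) -> dict:
        return {
            "a_high": math.exp(self.log_hr[0]),
            "b_high": math.exp(self.log_hr[1]),
            "both_high": math.exp(self.log_hr[2]),
        }

    def summary(self) -> pd.DataFrame:
        rows = [
            {
                "group": "both_low", "n": self.group_sizes["both_low"],
                "events": self.group_events["both_low"],
                "hr": 1.0, "ci_low": np.nan, "ci_high": np.nan,
            }
        ]
        for j, lab in enumerate(("a_high", "b_high", "both_high")):
            lo, hi = self.ci.get(lab, (np.nan, np.nan))
            rows.append(
                {
                    "group": lab, "n": self.group_sizes[lab],
                    "events": self.group_events[lab],
                    "hr": math.exp(self.log_hr[j]),
                    "ci_low": lo, "ci_high": hi,
                }
            )
        df = pd.DataFrame(rows)
        df["reri"] = self.reri
        return df


def factorial_cox(
    cohort: pd.DataFrame,
    groups: np.ndarray,
    covariates: Sequence[str] = (),
    *,
    time_col: str = "time",
    event_col: str = "event",
    engine: Literal["lifelines", "fast"] = "lifelines",
    robust: bool = True,
) -> FactorialResult:
    """Cox model on the three group indicators versus the reference.

    Keeps the covariance of the three log-HRs for RERI.  The lifelines
    engine (default) uses Efron ties and, with ``robust``, a sandwich
    covariance; the fast engine is the internal Newton solver used in
    replicate loops (model-based covariance).
    """
    groups = np.asarray(groups)
    sizes = {lab: int((groups == lab).sum()) for lab in GROUP_LABELS}
    events = {
        lab: int(cohort.loc[groups == lab, event_col].sum())
        for lab in GROUP_LABELS
    }
    for lab in GROUP_LABELS:
        if sizes[lab] == 0:
            raise ValueError(f"empty factorial group {lab!r}")
        if events[lab] == 0:
            raise ValueError(f"no events in factorial group {lab!r}")

    ind = np.column_stack(
        [(groups == lab).astype(float) for lab in
         ("a_high", "b_high", "both_high")]
    )
    covs = _covariate_matrix(cohort, covariates)
    X = np.column_stack([ind, covs])
    time = cohort[time_col].to_numpy(dtype=float)
    event = cohort[event_col].to_numpy(dtype=int)

    if engine == "fast":
        res = fit_cox(X, time, event)
        beta, cov = res.beta[:3], res.cov[:3, :3]
    else:
        names = ["a_high", "b_high", "both_high"] + [
            f"c{j}" for j in range(covs.shape[1])
        ]
        df = pd.DataFrame(X, columns=names)
        df[time_col] = time
        df[event_col] = event
        cph = CoxPHFitter()
        cph.fit(df, duration_col=time_col, event_col=event_col,
                robust=robust)
        beta = cph.params_.loc[["a_high", "b_high", "both_high"]].to_numpy()
        cov = cph.variance_matrix_.loc[
            ["a_high", "b_high", "both_high"],
            ["a_high", "b_high", "both_high"],
        ].to_numpy()

    se = np.sqrt(np.diag(cov))
    ci = {
        lab: (math.exp(beta[j] - 1.96 * se[j]),
              math.exp(beta[j] + 1.96 * se[j]))
        for j, lab in enumerate(("a_high", "b_high", "both_high"))
    }
    return FactorialResult(
        group_sizes=sizes,
        group_events=events,
        log_hr=beta,
        log_hr_covariance=cov,
        ci=ci,
    )


def _covariate_matrix(cohort, covariates):
    from .onesample import design_matrix

    return design_matrix(cohort, covariates)


def reri_from_hrs(
    hr_10: float,
    hr_01: float,
    hr_11: float,
    log_hr_covariance: np.ndarray,
    *,
    allow_preventive: bool = False,
    n_boot: int = 0,
    seed: int = 0,
) -> dict:
    """RERI = HR11 - HR10 - HR01 + 1 with a delta-method CI.

    The variance comes from the multivariate-normal log-HRs with
    gradient (-HR10, -HR01, HR11).  When any HR is below 1 the measure
    is undefined for interaction assessment (preventive direction) and
    no number is emitted unless ``allow_preventive``.  ``n_boot`` > 0
    adds a parametric-bootstrap CI as a cross-check.
    """
    hrs = np.array([hr_10, hr_01, hr_11], dtype=float)
    if np.any(hrs <= 0):
        raise ValueError("hazard ratios must be positive")
    cov = np.asarray(log_hr_covariance, dtype=float)
    if cov.shape != (3, 3):
        raise ValueError("log_hr_covariance must be 3x3")
    if np.any(hrs < 1) and not allow_preventive:
        return {
            "reri": None,
            "ci": None,
            "undefined_reason": "at least one HR < 1 (preventive)",
        }
    reri = float(hr_11 - hr_10 - hr_01 + 1.0)
    grad = np.array([-hr_10, -hr_01, hr_11])
    var = float(grad @ cov @ grad)
    se = math.sqrt(max(var, 0.0))
    out = {
        "reri": reri,
        "ci": (reri - 1.96 * se, reri + 1.96 * se),
        "se": se,
        "undefined_reason": None,
    }
    if n_boot > 0:
        rng = np.random.default_rng(seed)
        draws = rng.multivariate_normal(np.log(hrs), cov, size=n_boot)
        h = np.exp(draws)
        rs = h[:, 2] - h[:, 0] - h[:, 1] + 1.0
        out["ci_bootstrap"] = tuple(np.percentile(rs, [2.5, 97.5]))
    return out


def factorial_mr(
    cohort: pd.DataFrame,
    grsA: np.ndarray,
    grsB: np.ndarray,
    covariates: Sequence[str] = (),
    **cox_kwargs,
) -> FactorialResult:
    """Median-split 2x2 factorial MR with RERI attached."""
    groups = assign_2x2_groups(grsA, grsB)
    res = factorial_cox(cohort, groups, covariates, **cox_kwargs)
    hr = res.hr
    r = reri_from_hrs(
        hr["a_high"], hr["b_high"], hr["both_high"], res.log_hr_covariance
    )
    res.reri = r["reri"]
    res.reri_ci = r["ci"]
    res.reri_undefined_reason = r["undefined_reason"]
    return res


def continuous_factorial_cox(
    cohort: pd.DataFrame,
    grsA: np.ndarray,
    grsB: np.ndarray,
    covariates: Sequence[str] = (),
    *,
    time_col: str = "time",
    event_col: str = "event",
    engine: Literal["lifelines", "fast"] = "lifelines",
    allow_preventive: bool = False,
) -> dict:
    """Cox on two standardized scores and their product term.

    Scores are z-scored so coefficients are per SD; RERI is evaluated at
    +1 SD in both: exp(b1+b2+b3) - exp(b1) - exp(b2) + 1, with the same
    HR >= 1 guard as the 2x2 design and a delta-method CI.
    """
    a = np.asarray(grsA, dtype=float)
    b = np.asarray(grsB, dtype=float)
    if a.std() == 0 or b.std() == 0:
        raise ValueError("constant GRS")
    za = (a - a.mean()) / a.std()
    zb = (b - b.mean()) / b.std()
    covs = _covariate_matrix(cohort, covariates)
    X = np.column_stack([za, zb, za * zb, covs])
    time = cohort[time_col].to_numpy(dtype=float)
    event = cohort[event_col].to_numpy(dtype=int)

    if engine == "fast":
        res = fit_cox(X, time, event)
        beta, cov = res.beta[:3], res.cov[:3, :3]
    else:
        names = ["zA", "zB", "zA_zB"] + [
            f"c{j}" for j in range(covs.shape[1])
        ]
        df = pd.DataFrame(X, columns=names)
        df[time_col] = time
        df[event_col] = event
        cph = CoxPHFitter()
        cph.fit(df, duration_col=time_col, event_col=event_col, robust=True)
        beta = cph.params_.loc[["zA", "zB", "zA_zB"]].to_numpy()
        cov = cph.variance_matrix_.loc[
            ["zA", "zB", "zA_zB"], ["zA", "zB", "zA_zB"]
        ].to_numpy()

    se = np.sqrt(np.diag(cov))
    b1, b2, b3 = beta
    hr1, hr2 = math.exp(b1), math.exp(b2)
    s = b1 + b2 + b3
    out = {
        "beta": dict(zip(("a", "b", "product"), beta)),
        "se": dict(zip(("a", "b", "product"), se)),
        "hr": {
            "a": hr1, "b": hr2, "product": math.exp(b3),
            "both": math.exp(s),
        },
        "ci": {
            k: (math.exp(beta[j] - 1.96 * se[j]),
                math.exp(beta[j] + 1.96 * se[j]))
            for j, k in enumerate(("a", "b", "product"))
        },
        "log_hr_covariance": cov,
    }
    if (hr1 < 1 or hr2 < 1 or math.exp(s) < 1) and not allow_preventive:
        out["reri"] = None
        out["reri_ci"] = None
        out["reri_undefined_reason"] = "at least one HR < 1 (preventive)"
        return out
    reri = math.exp(s) - hr1 - hr2 + 1.0
    # d reri / d (b1, b2, b3)
    grad = np.array(
        [math.exp(s) - hr1, math.exp(s) - hr2, math.exp(s)]
    )
    var = float(grad @ cov @ grad)
    sd = math.sqrt(max(var, 0.0))
    out["reri"] = reri
    out["reri_ci"] = (reri - 1.96 * sd, reri + 1.96 * sd)
    out["reri_undefined_reason"] = None
    return out


def reri_multiplicative_identity(hr_10: float, hr_01: float) -> float:
    """RERI under exactly multiplicative joint effects: (HR10-1)(HR01-1)."""
    return (hr_10 - 1.0) * (hr_01 - 1.0)
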