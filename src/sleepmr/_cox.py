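"""Vectorized Newton solver for the Cox partial likelihood.

Internal engine for bootstrap and replicate loops, where the per-fit
overhead of a full-featured survival package dominates run time.  The
solver assumes continuous event times: with no tied events the Breslow
and Efron partial likelihoods coincide, so the result is identical to
either convention.  Ties are tolerated (Breslow) but user-facing fits
go through lifelines, which applies Efron's correction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass
class CoxResult:
    """Fitted Cox model: coefficients, covariance, and bookkeeping."""

    beta: np.ndarray
    cov: np.ndarray  # inverse observed information
    loglik: float
    n: int
    n_events: int
    converged: bool

    @property
    def se(self) -> np.ndarray:
        return np.sqrt(np.diag(self.cov))


class CoxConvergenceError(RuntimeError):
    pass


def _negloglik_grad_hess(beta, X, order, event_sorted):
    """Partial log-likelihood, gradient and Hessian (Breslow risk sets).

    ``order`` sorts time descending so a cumulative sum walks risk sets.
    """
    Xs = X[order]
    eta = Xs @ beta
    eta = np.clip(eta, -500, 500)
    w = np.exp(eta)
    s0 = np.cumsum(w)  # sum over {j: t_j >= t_i}
    s1 = np.cumsum(w[:, None] * Xs, axis=0)
    # s2 only needed at event rows; p is small so full cumsum is cheap
    outer = np.einsum("ij,ik->ijk", Xs, Xs)
    s2 = np.cumsum(w[:, None, None] * outer, axis=0)

    ev = event_sorted
    s0e = s0[ev]
    s1e = s1[ev]
    xbar = s1e / s0e[:, None]

    loglik = float(np.sum(eta[ev]) - np.sum(np.log(s0e)))
    grad = np.sum(Xs[ev] - xbar, axis=0)
    hess = np.sum(
        s2[ev] / s0e[:, None, None]
        - np.einsum("ij,ik->ijk", xbar, xbar),
        axis=0,
    )
    return loglik, grad, hess


def fit_cox(
    X: np.ndarray,
    time: np.ndarray,
    event: np.ndarray,
    *,
    max_iter: int = 50,
    tol: float = 1e-9,
) -> CoxResult:
    """Fit a Cox proportional-hazards model by Newton-Raphson.

    Parameters
    ----------
    X : (n, p) covariate matrix (no intercept; the baseline absorbs it).
    time, event : follow-up times and 0/1 event indicators.

    Raises
    ------
    ValueError if there are no events or a covariate is constant;
    CoxConvergenceError if Newton fails to converge.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    time = np.asarray(time, dtype=float)
    event = np.asarray(event).astype(bool)
    n, p = X.shape
    n_events = int(event.sum())
    if n_events == 0:
        raise ValueError("Cox model requires at least one event")
    sd = X.std(axis=0)
    if np.any(sd == 0):
        raise ValueError("constant covariate column in Cox design")

    # center/scale for conditioning; back-transform at the end
    mu = X.mean(axis=0)
    Z = (X - mu) / sd
    # stable ordering: descending time, events after censorings at ties so
    # the cumulative risk set includes same-time censored rows
    order = np.lexsort((event, -time))
    ev_sorted = event[order]

    beta = np.zeros(p)
    ll, grad, hess = _negloglik_grad_hess(beta, Z, order, ev_sorted)
    converged = False
    for _ in range(max_iter):
        if np.max(np.abs(grad)) < tol * max(1.0, abs(ll)):
            converged = True
            break
        try:
            step = np.linalg.solve(hess, grad)
        except np.linalg.LinAlgError as exc:
            raise CoxConvergenceError("singular information matrix") from exc
        # step-halving line search; acceptance tolerance is relative to
        # |ll| so floating-point noise never rejects a converged step
        t = 1.0
        slack = 1e-10 * max(1.0, abs(ll))
        for _ in range(30):
            cand = beta + t * step
            ll_new, g_new, h_new = _negloglik_grad_hess(
                cand, Z, order, ev_sorted
            )
            if ll_new >= ll - slack:
                break
            t /= 2
        beta, ll, grad, hess = cand, ll_new, g_new, h_new
    if not converged:
        raise CoxConvergenceError(
            f"Newton did not converge in {max_iter} iterations"
        )
    cov_z = np.linalg.inv(hess)
    beta_x = beta / sd
    cov_x = cov_z / np.outer(sd, sd)
    return CoxResult(
        beta=beta_x,
        cov=cov_x,
        loglik=ll,
        n=n,
        n_events=n_events,
        converged=converged,
    )
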