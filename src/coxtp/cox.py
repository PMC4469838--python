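"""Cox partial-likelihood machinery (Breslow tie convention).

The partial likelihood for coefficients ``beta`` is

    l(beta) = sum_i delta_i [x_i' beta - log sum_{r in R(t_i)} exp(x_r' beta)]

with R(t_i) the risk set of patients still under observation just before
t_i (t_r >= t_i; tied event times share one risk set).  Everything here is
vectorized via cumulative sums over the time-ordered patients; these are
the reference implementations used for KKT certificates, cross-validation
scores and deviances.  The penalized solver has its own compiled kernels
in :mod:`coxtp._solver`.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as _stats

from .data import NoEventsError, SurvivalDataset

__all__ = [
    "cox_partial_loglik",
    "cox_gradient",
    "cox_hessian",
    "compute_lambda0",
    "fit_cox_newton",
    "active_set",
    "CoxFit",
]


def _check(beta: np.ndarray, data: SurvivalDataset) -> np.ndarray:
    beta = np.asarray(beta, dtype=np.float64).ravel()
    if beta.shape[0] != data.p:
        raise ValueError(f"beta has length {beta.shape[0]}, expected p={data.p}")
    if not np.all(np.isfinite(beta)):
        raise ValueError("beta contains non-finite entries")
    if data.n_events == 0:
        raise NoEventsError("no events")
    return beta


def _breslow_terms(eta: np.ndarray, delta: np.ndarray, gfirst: np.ndarray,
                   glast: np.ndarray):
    """Log-likelihood plus per-patient score u and curvature h on the eta scale.

    Returns (loglik, u, h) where u = dl/deta and h is the diagonal of the
    negative Hessian of l with respect to eta (the glmnet-style weights).
    """
    mx = eta.max()
    w = np.exp(eta - mx)
    rc = np.cumsum(w[::-1])[::-1]
    S = rc[gfirst]                       # shifted risk-set denominators
    ca = np.cumsum(delta / S)
    cb = np.cumsum(delta / S**2)
    A = ca[glast]
    B = cb[glast]
    u = delta - w * A
    h = w * A - w * w * B
    ll = float(np.sum(delta * (eta - (np.log(S) + mx))))
    return ll, u, h


def cox_partial_loglik(beta: np.ndarray, data: SurvivalDataset) -> float:
    """Breslow partial log-likelihood l(beta)."""
    beta = _check(beta, data)
    s = data._sorted
    eta = s["X"] @ beta
    ll, _, _ = _breslow_terms(eta, s["delta"], s["gfirst"], s["glast"])
    return ll


def cox_gradient(beta: np.ndarray, data: SurvivalDataset) -> np.ndarray:
    """Gradient dl/dbeta of the Breslow partial log-likelihood."""
    beta = _check(beta, data)
    s = data._sorted
    eta = s["X"] @ beta
    _, u, _ = _breslow_terms(eta, s["delta"], s["gfirst"], s["glast"])
    return u @ s["X"]


def cox_hessian(beta: np.ndarray, data: SurvivalDataset) -> np.ndarray:
    """Exact Hessian d2l/dbeta2 (p x p); intended for small p refits."""
    beta = _check(beta, data)
    if data.p > 200:
        raise ValueError("exact Hessian is only supported for p <= 200")
    s = data._sorted
    X, delta, gfirst = s["X"], s["delta"], s["gfirst"]
    eta = X @ beta
    mx = eta.max()
    w = np.exp(eta - mx)
    rc_w = np.cumsum(w[::-1])[::-1]
    rc_xw = np.cumsum((X * w[:, None])[::-1], axis=0)[::-1]
    xxw = np.einsum("ij,ik->ijk", X, X * w[:, None])
    rc_xxw = np.cumsum(xxw[::-1], axis=0)[::-1]
    S = rc_w[gfirst]
    S1 = rc_xw[gfirst] / S[:, None]
    S2 = rc_xxw[gfirst] / S[:, None, None]
    ev = delta > 0
    H = np.einsum("i,ijk->jk", delta[ev], S2[ev] - np.einsum("ij,ik->ijk", S1[ev], S1[ev]))
    return -H


def compute_lambda0(data: SurvivalDataset) -> float:
    """Smallest penalty at which the lasso solution is exactly zero.

    lambda0 = max_j |dl/dbeta_j| evaluated at beta = 0.
    """
    g = cox_gradient(np.zeros(data.p), data)
    return float(np.max(np.abs(g)))


def active_set(beta: np.ndarray, zero_tol: float = 1e-10) -> np.ndarray:
    """Indices of coefficients whose magnitude exceeds ``zero_tol``."""
    beta = np.asarray(beta, dtype=np.float64).ravel()
    return np.flatnonzero(np.abs(beta) > zero_tol)


@dataclass
class CoxFit:
    """Unpenalized (optionally ridge-stabilized) Cox fit."""

    beta: np.ndarray
    loglik: float          # unpenalized partial log-likelihood at beta
    cov: np.ndarray        # inverse of (-Hessian + ridge I)
    iterations: int
    converged: bool
    ridge: float

    @property
    def se(self) -> np.ndarray:
        return np.sqrt(np.diag(self.cov))

    @property
    def wald_p(self) -> np.ndarray:
        z = self.beta / self.se
        return 2.0 * _stats.norm.sf(np.abs(z))

    def aic(self) -> float:
        return -2.0 * self.loglik + 2.0 * self.beta.shape[0]


def fit_cox_newton(data: SurvivalDataset, ridge: float = 0.0,
                   max_iter: int = 100, tol: float = 1e-9) -> CoxFit:
    """Newton-Raphson maximization of l(beta) - ridge/2 * ||beta||^2.

    Exact Hessian, step-halving line search.  Used for low-dimensional
    refits (prognostic-index models, ranked/random gene subsets); the
    penalized path solver does not go through here.
    """
    if data.n_events == 0:
        raise NoEventsError("no events")
    p = data.p
    beta = np.zeros(p)
    ll = cox_partial_loglik(beta, data)
    pen_ll = ll
    converged = False
    it = 0
    scale = max(1.0, float(data.n_events))
    for it in range(1, max_iter + 1):
        g = cox_gradient(beta, data) - ridge * beta
        if np.max(np.abs(g)) < tol * scale:
            converged = True
            break
        H = cox_hessian(beta, data)
        M = -H + ridge * np.eye(p)
        try:
            step = np.linalg.solve(M, g)
        except np.linalg.LinAlgError:
            step = np.linalg.lstsq(M, g, rcond=None)[0]
        t = 1.0
        for _ in range(40):
            cand = beta + t * step
            ll_c = cox_partial_loglik(cand, data)
            pen_c = ll_c - 0.5 * ridge * float(cand @ cand)
            if pen_c >= pen_ll - 1e-12:
                break
            t *= 0.5
        beta, ll, pen_ll = cand, ll_c, pen_c
    H = cox_hessian(beta, data)
    cov = np.linalg.inv(-H + ridge * np.eye(p))
    return CoxFit(beta=beta, loglik=ll, cov=cov, iterations=it,
                  converged=converged, ridge=ridge)
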