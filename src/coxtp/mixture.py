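"""Laplace + normal mixture on lasso coefficient estimates.

At a penalty lambda the nonzero lasso estimates are modelled as draws
from

    f(b) = (n/p) [ pi0 f_L(b; 0, 1/tau) + sum_c pi_c f_N(b; mu_c, sigma_c^2) ]
           + (1 - n/p) f_L(b; 0, eps)

where the Laplace component (location 0, scale 1/tau) carries the
false-positive genes, the C normal components (mu_c != 0) carry the true
positives, and the near-degenerate Laplace spike (scale eps ~ 1e-8)
accounts for the p - n coefficients that the lasso keeps at exactly zero
when p > n.  Because the likelihood is only ever evaluated on the m
nonzero coefficients, the spike term and the n/p prefactor are constants
with respect to the parameters; fitting therefore maximizes the bracketed
mixture with pi0 + sum_c pi_c = 1 over the selected genes, which makes
pi0_hat = FP_hat / m consistent with the sequential tracking counts.

Tail areas outside a cut-off +-zeta of the fitted Laplace and normal
components give the estimated FP / TP proportions, and scaling by the
number of selected genes m gives the estimated counts with
FP_hat + TP_hat = m exactly.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numba import njit
from scipy import optimize, stats
from scipy.special import logsumexp

__all__ = [
    "MixtureParams", "MixtureFit", "DegenerateFitError",
    "mixture_logpdf", "fit_mixture", "estimate_proportions",
    "estimate_counts", "select_C_by_aic", "CSelection",
]

MU_FLOOR = 1e-4
SIGMA_MIN = 1e-4
B_MIN = 1e-8


class DegenerateFitError(RuntimeError):
    """Mixture maximum-likelihood fit collapsed or is unidentifiable."""


@dataclass
class MixtureParams:
    """Parameters of the coefficient mixture.

    ``tau`` is the Laplace rate (FP scale = 1/tau); ``mu``/``sigma`` hold
    the C normal component locations/scales; ``n_over_p`` is the n/p
    prefactor of the selected-gene part of the density.
    """

    pi0: float
    pi: np.ndarray
    tau: float
    mu: np.ndarray
    sigma: np.ndarray
    C: int
    eps: float = 1e-8
    n_over_p: float = 1.0

    def __post_init__(self) -> None:
        self.pi = np.atleast_1d(np.asarray(self.pi, dtype=float))
        self.mu = np.atleast_1d(np.asarray(self.mu, dtype=float))
        self.sigma = np.atleast_1d(np.asarray(self.sigma, dtype=float))
        if not (len(self.pi) == len(self.mu) == len(self.sigma) == self.C):
            raise ValueError("pi, mu, sigma must all have length C")
        if self.tau <= 0 or np.any(self.sigma <= 0):
            raise ValueError("tau and all sigma_c must be positive")
        if self.pi0 < -1e-12 or np.any(self.pi < -1e-12):
            raise ValueError("mixture proportions must be nonnegative")
        if abs(self.pi0 + self.pi.sum() - 1.0) > 1e-12:
            raise ValueError("pi0 + sum(pi_c) must equal 1")
        if not (0 < self.n_over_p <= 1):
            raise ValueError("n_over_p must lie in (0, 1]")

    @property
    def laplace_scale(self) -> float:
        return 1.0 / self.tau


@dataclass
class MixtureFit:
    params: MixtureParams
    loglik: float
    aic: float
    n_obs: int
    converged: bool
    iterations: int
    free_proportions: bool = True
    n_free_params: int = 0


_LOG_SQRT_2PI = 0.5 * np.log(2.0 * np.pi)


def _laplace_logpdf(x: np.ndarray, scale: float) -> np.ndarray:
    return -np.log(2.0 * scale) - np.abs(x) / scale


def _normal_logpdf(x: np.ndarray, mu: float, sigma: float) -> np.ndarray:
    z = (x - mu) / sigma
    return -0.5 * z * z - np.log(sigma) - _LOG_SQRT_2PI


def _component_logliks(x: np.ndarray, pi0: float, b: float,
                       pi: np.ndarray, mu: np.ndarray, sigma: np.ndarray):
    """Per-point per-component weighted log-densities, shape (m, C + 1)."""
    x = np.asarray(x, dtype=float).ravel()
    cols = [np.full(x.shape, -np.inf) if pi0 <= 0
            else np.log(pi0) + _laplace_logpdf(x, b)]
    for c in range(len(pi)):
        if pi[c] <= 0:
            cols.append(np.full(x.shape, -np.inf))
        else:
            cols.append(np.log(pi[c]) + _normal_logpdf(x, mu[c], sigma[c]))
    return np.column_stack(cols)


def mixture_logpdf(value, params: MixtureParams):
    """Log of the full mixture density, including the (1 - n/p) spike."""
    x = np.asarray(value, dtype=float)
    comp = _component_logliks(x.ravel(), params.pi0, params.laplace_scale,
                              params.pi, params.mu, params.sigma)
    parts = [np.log(params.n_over_p) + logsumexp(comp, axis=1)]
    if params.n_over_p < 1.0:
        parts.append(np.log1p(-params.n_over_p)
                     + _laplace_logpdf(x.ravel(), params.eps))
    out = logsumexp(np.column_stack(parts), axis=1)
    return float(out[0]) if x.ndim == 0 else out.reshape(x.shape)


def _selected_loglik(x, pi0, b, pi, mu, sigma) -> float:
    comp = _component_logliks(x, pi0, b, pi, mu, sigma)
    return float(logsumexp(comp, axis=1).sum())


def _clamp_mu(mu: np.ndarray, mu_floor: float) -> np.ndarray:
    sgn = np.where(mu >= 0, 1.0, -1.0)
    return sgn * np.maximum(np.abs(mu), mu_floor)


@njit(cache=True)
def _em_fixed_c1(x, pi0, pi1, b, mu, sg, max_iter, tol, b_min, sigma_min,
                 mu_floor):
    """Fixed-weight EM for the two-component (Laplace + one normal) case.

    Same algorithm as :func:`_em` with ``free_props=False`` and C = 1,
    compiled for the per-step hypothesis fits of the tracking loop.
    Returns (b, mu, sg, loglik, iterations, converged_flag).
    """
    m = x.shape[0]
    lpi0 = np.log(pi0)
    lpi1 = np.log(pi1)
    ll = -np.inf
    converged = 0
    it = 0
    half_log2pi = 0.5 * np.log(2.0 * np.pi)
    for it in range(1, max_iter + 1):
        new_ll = 0.0
        s0 = 0.0
        sa = 0.0
        s1 = 0.0
        sx = 0.0
        sxx = 0.0
        for i in range(m):
            l0 = lpi0 - np.log(2.0 * b) - abs(x[i]) / b
            z = (x[i] - mu) / sg
            l1 = lpi1 - 0.5 * z * z - np.log(sg) - half_log2pi
            hi = l0 if l0 > l1 else l1
            tot = hi + np.log(np.exp(l0 - hi) + np.exp(l1 - hi))
            new_ll += tot
            r0 = np.exp(l0 - tot)
            r1 = 1.0 - r0
            s0 += r0
            sa += r0 * abs(x[i])
            s1 += r1
            sx += r1 * x[i]
            sxx += r1 * x[i] * x[i]
        if s0 > 1e-12:
            b = sa / s0
            if b < b_min:
                b = b_min
        if s1 > 1e-12:
            mu_new = sx / s1
            var = sxx / s1 - mu_new * mu_new
            mu = mu_new
            sg = np.sqrt(var) if var > sigma_min * sigma_min else sigma_min
        if abs(mu) < mu_floor:
            mu = mu_floor if mu >= 0 else -mu_floor
        if new_ll - ll < tol * (1.0 + abs(new_ll)) and it > 1:
            ll = new_ll
            converged = 1
            break
        ll = new_ll
    # final log-likelihood at the returned parameters
    ll = 0.0
    for i in range(m):
        l0 = lpi0 - np.log(2.0 * b) - abs(x[i]) / b
        z = (x[i] - mu) / sg
        l1 = lpi1 - 0.5 * z * z - np.log(sg) - half_log2pi
        hi = l0 if l0 > l1 else l1
        ll += hi + np.log(np.exp(l0 - hi) + np.exp(l1 - hi))
    return b, mu, sg, ll, it, converged


def _em(x, pi0, pi, b, mu, sigma, *, free_props, max_iter=500, tol=1e-8,
        b_min=B_MIN, sigma_min=SIGMA_MIN, mu_floor=MU_FLOOR):
    """EM iterations; proportions updated only when ``free_props``."""
    x = np.asarray(x, dtype=float).ravel()
    m = x.shape[0]
    ll = -np.inf
    it = 0
    converged = False
    for it in range(1, max_iter + 1):
        comp = _component_logliks(x, pi0, b, pi, mu, sigma)
        tot = logsumexp(comp, axis=1)
        new_ll = float(tot.sum())
        resp = np.exp(comp - tot[:, None])          # (m, C+1)
        if free_props:
            w = resp.mean(axis=0)
            pi0, pi = float(w[0]), w[1:]
        w0 = resp[:, 0].sum()
        if w0 > 1e-12:
            b = max(float(resp[:, 0] @ np.abs(x) / w0), b_min)
        for c in range(len(pi)):
            wc = resp[:, c + 1].sum()
            if wc > 1e-12:
                mu_c = float(resp[:, c + 1] @ x / wc)
                var_c = float(resp[:, c + 1] @ (x - mu_c) ** 2 / wc)
                mu[c] = mu_c
                sigma[c] = max(np.sqrt(var_c), sigma_min)
        mu = _clamp_mu(mu, mu_floor)
        if new_ll - ll < tol * (1.0 + abs(new_ll)) and it > 1:
            ll = new_ll
            converged = True
            break
        ll = new_ll
    ll = _selected_loglik(x, pi0, b, pi, mu, sigma)
    return dict(pi0=pi0, pi=pi, b=b, mu=mu, sigma=sigma, loglik=ll,
                iterations=it, converged=converged, m=m)


def _moment_init(x, C, rng=None):
    """Split small-|b| half to the Laplace, large-|b| half to the normals."""
    x = np.asarray(x, dtype=float).ravel()
    ax = np.abs(x)
    med = np.median(ax)
    small = x[ax <= med]
    large = x[ax > med]
    if large.size == 0:
        large = x
    b = max(float(np.mean(np.abs(small))) if small.size else float(np.mean(ax)),
            B_MIN)
    if C == 1:
        mu = np.array([float(np.mean(large))])
        sigma = np.array([max(float(np.std(large)), SIGMA_MIN)])
    else:
        order = np.argsort(large)
        chunks = np.array_split(large[order], C)
        mu = np.array([float(np.mean(c)) if c.size else 0.0 for c in chunks])
        sigma = np.array([max(float(np.std(c)), SIGMA_MIN) if c.size else 1.0
                          for c in chunks])
    return b, _clamp_mu(mu, MU_FLOOR), sigma


def fit_fixed_weights(x, pi0, pi, *, warm=None, max_iter=500, tol=1e-8,
                      sigma_min=SIGMA_MIN, b_min=B_MIN, mu_floor=MU_FLOOR):
    """Maximum likelihood over (tau, mu_c, sigma_c) with proportions fixed.

    This is the inner fit of the sequential tracking algorithm: the
    hypothesis under test prescribes the proportion vector, and only the
    shape parameters are free.  Closed forms are used when all weight sits
    on a single component; otherwise EM from a moment-based split (and
    from ``warm``, when given) with the better likelihood retained.
    Returns a dict with keys pi0, pi, b, mu, sigma, loglik.
    """
    x = np.asarray(x, dtype=float).ravel()
    pi = np.atleast_1d(np.asarray(pi, dtype=float))
    C = pi.shape[0]
    if x.size == 0:
        raise ValueError("insufficient active set")
    if pi0 >= 1.0 - 1e-12:
        b = max(float(np.mean(np.abs(x))), b_min)
        mu, sigma = (warm["mu"].copy(), warm["sigma"].copy()) if warm else \
            (np.full(C, MU_FLOOR), np.ones(C))
        ll = _selected_loglik(x, 1.0, b, np.zeros(C), mu, sigma)
        return dict(pi0=1.0, pi=np.zeros(C), b=b, mu=mu, sigma=sigma,
                    loglik=ll, iterations=0, converged=True, m=x.size)
    active_c = np.flatnonzero(pi > 0)
    if pi0 <= 1e-12 and active_c.size == 1:
        c = int(active_c[0])
        mu = (warm["mu"].copy() if warm else np.full(C, MU_FLOOR))
        sigma = (warm["sigma"].copy() if warm else np.ones(C))
        mu[c] = float(np.mean(x))
        sigma[c] = max(float(np.std(x)), sigma_min)
        mu = _clamp_mu(mu, mu_floor)
        b = warm["b"] if warm else max(float(np.mean(np.abs(x))), b_min)
        ll = _selected_loglik(x, 0.0, b, pi, mu, sigma)
        return dict(pi0=0.0, pi=pi, b=b, mu=mu, sigma=sigma, loglik=ll,
                    iterations=0, converged=True, m=x.size)
    fits = []
    b0, mu0, sg0 = _moment_init(x, C)
    if C == 1:
        inits = [(b0, float(mu0[0]), float(sg0[0]))]
        if warm is not None:
            inits.append((float(warm["b"]), float(warm["mu"][0]),
                          float(warm["sigma"][0])))
        for bi, mi, si in inits:
            b, mu, sg, ll, it, conv = _em_fixed_c1(
                x, float(pi0), float(pi[0]), bi, mi, si, max_iter, tol,
                b_min, sigma_min, mu_floor)
            fits.append(dict(pi0=float(pi0), pi=pi.copy(), b=b,
                             mu=np.array([mu]), sigma=np.array([sg]),
                             loglik=ll, iterations=it,
                             converged=bool(conv), m=x.size))
    else:
        fits.append(_em(x, pi0, pi.copy(), b0, mu0.copy(), sg0.copy(),
                        free_props=False, max_iter=max_iter, tol=tol,
                        b_min=b_min, sigma_min=sigma_min, mu_floor=mu_floor))
        if warm is not None:
            fits.append(_em(x, pi0, pi.copy(), warm["b"], warm["mu"].copy(),
                            warm["sigma"].copy(), free_props=False,
                            max_iter=max_iter, tol=tol, b_min=b_min,
                            sigma_min=sigma_min, mu_floor=mu_floor))
    return max(fits, key=lambda f: f["loglik"])


def _polish_free(x, fit, C, mu_floor):
    """Quasi-Newton refinement of the free-proportion EM optimum."""
    x = np.asarray(x, dtype=float).ravel()

    def unpack(theta):
        w = np.concatenate([[0.0], theta[:C]])
        w = np.exp(w - logsumexp(w))
        b = np.exp(theta[C])
        mu = theta[C + 1:2 * C + 1]
        sigma = np.exp(theta[2 * C + 1:])
        return float(w[0]), w[1:], b, mu, sigma

    def negll(theta):
        pi0, pi, b, mu, sigma = unpack(theta)
        if b < B_MIN or np.any(sigma < SIGMA_MIN / 10):
            return 1e12
        return -_selected_loglik(x, pi0, b, pi, mu, sigma)

    w = np.maximum(np.concatenate([[fit["pi0"]], fit["pi"]]), 1e-10)
    theta0 = np.concatenate([np.log(w[1:] / w[0]), [np.log(fit["b"])],
                             fit["mu"], np.log(fit["sigma"])])
    res = optimize.minimize(negll, theta0, method="Nelder-Mead",
                            options={"maxiter": 2000, "xatol": 1e-8,
                                     "fatol": 1e-10})
    if np.isfinite(res.fun) and -res.fun > fit["loglik"]:
        pi0, pi, b, mu, sigma = unpack(res.x)
        mu = _clamp_mu(mu, mu_floor)
        fit = dict(fit, pi0=pi0, pi=pi, b=b, mu=mu, sigma=sigma,
                   loglik=_selected_loglik(x, pi0, b, pi, mu, sigma))
    return fit


def fit_mixture(coeffs, C: int, fixed_props=None, *, n_over_p: float = 1.0,
                m_min: int = 5, restarts: int = 10, seed: int = 0,
                polish: bool = True, max_iter: int = 500,
                tol: float = 1e-8) -> MixtureFit:
    """Maximum-likelihood mixture fit to the nonzero lasso coefficients.

    With ``fixed_props`` (length C + 1, summing to 1: pi0 first) only the
    shape parameters tau, mu_c, sigma_c are optimized; otherwise the
    proportions are free and the fit is EM from ``restarts`` random
    initializations plus a moment-based one, followed by a derivative-free
    polish.  AIC counts 3C + 1 free parameters (2C + 1 under fixed
    proportions).
    """
    x = np.asarray(coeffs, dtype=float).ravel()
    if C < 1:
        raise ValueError("C must be a positive integer")
    if x.size < max(m_min, 2 * C + 2):
        raise ValueError(
            f"insufficient active set: {x.size} coefficients for C={C}")
    if np.ptp(x) == 0.0:
        raise DegenerateFitError("all coefficients identical: variance "
                                 "parameters are unidentifiable")
    if fixed_props is not None:
        fp = np.asarray(fixed_props, dtype=float).ravel()
        if fp.shape[0] != C + 1 or abs(fp.sum() - 1.0) > 1e-8 or np.any(fp < 0):
            raise ValueError("fixed_props must be C+1 nonnegative values "
                             "summing to 1 (pi0 first)")
        fit = fit_fixed_weights(x, float(fp[0]), fp[1:], max_iter=max_iter,
                                tol=tol)
        free = False
    else:
        rng = np.random.default_rng(seed)
        b0, mu0, sg0 = _moment_init(x, C)
        w0 = np.full(C + 1, 1.0 / (C + 1))
        fits = [_em(x, w0[0], w0[1:].copy(), b0, mu0.copy(), sg0.copy(),
                    free_props=True, max_iter=max_iter, tol=tol)]
        for _ in range(restarts):
            w = rng.dirichlet(np.ones(C + 1))
            b = max(float(rng.uniform(0.2, 1.5) * np.mean(np.abs(x))), B_MIN)
            mu = _clamp_mu(np.asarray(rng.choice(x, C, replace=False),
                                      dtype=float), MU_FLOOR)
            sigma = np.full(C, max(float(np.std(x)) *
                                   float(rng.uniform(0.2, 1.0)), SIGMA_MIN))
            fits.append(_em(x, float(w[0]), w[1:], b, mu, sigma,
                            free_props=True, max_iter=max_iter, tol=tol))
        fit = max(fits, key=lambda f: f["loglik"])
        if polish:
            fit = _polish_free(x, fit, C, MU_FLOOR)
        free = True
    if np.any(fit["sigma"] <= SIGMA_MIN * (1 + 1e-9)) and x.size >= 2 * C + 2:
        raise DegenerateFitError(
            f"degenerate optimum: sigma collapsed to the floor "
            f"({fit['sigma']}) on {x.size} coefficients")
    n_free = (3 * C + 1) if free else (2 * C + 1)
    params = MixtureParams(pi0=float(fit["pi0"]), pi=fit["pi"],
                           tau=1.0 / fit["b"], mu=fit["mu"],
                           sigma=fit["sigma"], C=C, n_over_p=n_over_p)
    return MixtureFit(params=params, loglik=fit["loglik"],
                      aic=-2.0 * fit["loglik"] + 2.0 * n_free,
                      n_obs=x.size, converged=bool(fit["converged"]),
                      iterations=int(fit["iterations"]),
                      free_proportions=free, n_free_params=n_free)


def estimate_proportions(fit, zeta: float = 0.0):
    """Two-tailed component masses outside +-zeta: (P_FP, P_TP)."""
    if zeta < 0:
        raise ValueError("zeta must be nonnegative")
    params = fit.params if isinstance(fit, MixtureFit) else fit
    p_fp = params.pi0 * float(np.exp(-zeta * params.tau))
    tails = (stats.norm.cdf(-zeta, params.mu, params.sigma)
             + stats.norm.sf(zeta, params.mu, params.sigma))
    p_tp = float(params.pi @ tails)
    return p_fp, p_tp


def estimate_counts(P_FP: float, P_TP: float, m: int):
    """Scale the tail proportions to counts: FP_hat + TP_hat = m exactly."""
    if m < 0:
        raise ValueError("m must be nonnegative")
    if P_FP < 0 or P_TP < 0 or P_FP + P_TP <= 0:
        raise ValueError("P_FP + P_TP must be positive")
    tp = P_TP / (P_TP + P_FP) * m
    return m - tp, tp


@dataclass
class CSelection:
    best_C: int
    table: "object"        # pandas.DataFrame: one row per (step, C)
    per_step_best: dict = field(default_factory=dict)

    def __int__(self) -> int:
        return self.best_C


def select_C_by_aic(path, candidate_Cs=(1, 2, 3), *, m_min: int = 5,
                    n_over_p: float = 1.0, seed: int = 0,
                    restarts: int = 5) -> CSelection:
    """Choose the number of normal components by AIC along the path.

    Every path step with enough active genes is fitted with free
    proportions for each candidate C; the C with the best (lowest) AIC on
    the largest number of steps wins, ties going to the smaller C.
    """
    import pandas as pd

    cands = sorted(set(int(c) for c in candidate_Cs))
    if not cands:
        raise ValueError("candidate_Cs must be nonempty")
    rows = []
    per_step_best = {}
    wins = {c: 0 for c in cands}
    for step in path.steps:
        coeffs = step.beta[np.abs(step.beta) > path.zero_tol]
        aics = {}
        for c in cands:
            if coeffs.size < max(m_min, 2 * c + 2):
                continue
            try:
                f = fit_mixture(coeffs, c, n_over_p=n_over_p, m_min=m_min,
                                restarts=restarts, seed=seed, polish=False)
            except (DegenerateFitError, ValueError):
                continue
            aics[c] = f.aic
            rows.append({"k": step.index, "lam": step.lam, "m": coeffs.size,
                         "C": c, "aic": f.aic, "loglik": f.loglik})
        if aics:
            best = min(aics, key=lambda c: (aics[c], c))
            per_step_best[step.index] = best
            wins[best] += 1
    if not per_step_best:
        raise ValueError("no path step has enough active genes to fit "
                         "any candidate C")
    best_C = max(cands, key=lambda c: (wins[c], -c))
    return CSelection(best_C=best_C, table=pd.DataFrame(rows),
                      per_step_best=per_step_best)
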