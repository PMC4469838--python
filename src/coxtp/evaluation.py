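"""Cross-validated partial likelihood and prediction-accuracy criteria.

The tuning-parameter comparator is the Verweij-van Houwelingen K-fold
cross-validated partial likelihood

    CV(lambda) = sum_k [ l(beta_hat^(-k)(lambda)) - l_(-k)(beta_hat^(-k)(lambda)) ]

where beta_hat^(-k) is the lasso fit with fold k left out, l uses all
patients and l_(-k) excludes fold k.  Validation criteria for a fitted
coefficient vector are the log-rank test between median-split prognostic
groups, the Wald p-value of the prognostic index in a univariate Cox
model, and the validation deviance -2[l_val(beta) - l_val(0)] (lower is
better for all three).
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .cox import cox_partial_loglik, fit_cox_newton
from .data import SurvivalDataset
from .path import LassoPath, fit_lasso_at

__all__ = [
    "cv_folds", "cv_score", "select_lambda_by_cv", "CVSelection",
    "prognostic_index", "PrognosticSplit", "logrank_test", "pi_cox_pvalue",
    "PiCoxResult", "deviance", "rank_vs_random_aic", "km_curves",
    "evaluate_split", "EvalReport",
]


def cv_folds(events: np.ndarray, K: int, seed: int) -> np.ndarray:
    """Fold label per patient, stratified by event status so every fold
    keeps events."""
    events = np.asarray(events)
    if K < 2:
        raise ValueError("K must be at least 2")
    rng = np.random.default_rng(seed)
    fold = np.empty(events.shape[0], dtype=np.int64)
    for status in (0, 1):
        idx = np.flatnonzero(events == status)
        rng.shuffle(idx)
        fold[idx] = np.arange(idx.shape[0]) % K
    return fold


def _check_folds(data: SurvivalDataset, fold: np.ndarray, K: int) -> None:
    for k in range(K):
        held = fold == k
        if data.events[held].sum() == 0 or data.events[~held].sum() == 0:
            raise ValueError(f"degenerate fold {k}: a partition has no events")


def cv_score(lam: float, data: SurvivalDataset, K: int = 5,
             fold_seed: int = 0, folds: np.ndarray | None = None) -> float:
    """Cross-validated partial likelihood CV(lambda), higher is better.

    ``folds`` overrides the seeded stratified assignment with an explicit
    per-patient fold label in {0, ..., K-1}.
    """
    fold = cv_folds(data.events, K, fold_seed) if folds is None \
        else np.asarray(folds)
    _check_folds(data, fold, K)
    total = 0.0
    for k in range(K):
        train = data.subset(np.flatnonzero(fold != k))
        beta = fit_lasso_at(lam, train)
        total += cox_partial_loglik(beta, data) - cox_partial_loglik(beta, train)
    return total


@dataclass
class CVSelection:
    lam_star: float
    scores: np.ndarray
    lambdas: np.ndarray
    K: int

    def __float__(self) -> float:
        return self.lam_star


def _argmax_larger_lambda(lambdas: np.ndarray, scores: np.ndarray) -> int:
    """Index of the maximal score; ties resolved toward the larger penalty."""
    best = np.max(scores)
    tied = np.flatnonzero(scores >= best - 1e-12)
    return int(tied[np.argmax(lambdas[tied])])


def select_lambda_by_cv(data: SurvivalDataset, path: LassoPath, K: int = 5,
                        fold_seed: int = 0) -> CVSelection:
    """Evaluate CV(lambda) on the path's penalty sequence, return the maximizer.

    Each fold's lasso solutions are computed by one warm-started sweep
    down the penalty sequence, which makes the whole curve roughly as
    expensive as K path traversals.
    """
    fold = cv_folds(data.events, K, fold_seed)
    _check_folds(data, fold, K)
    lambdas = path.lambdas
    scores = np.zeros(lambdas.shape[0])
    for k in range(K):
        train = data.subset(np.flatnonzero(fold != k))
        beta = np.zeros(data.p)
        for i, lam in enumerate(lambdas):
            beta = fit_lasso_at(float(lam), train, beta_init=beta)
            scores[i] += (cox_partial_loglik(beta, data)
                          - cox_partial_loglik(beta, train))
    i = _argmax_larger_lambda(lambdas, scores)
    return CVSelection(lam_star=float(lambdas[i]), scores=scores,
                       lambdas=lambdas, K=K)


@dataclass
class PrognosticSplit:
    eta: np.ndarray
    median: float
    better: np.ndarray       # boolean mask, eta <= median
    worse: np.ndarray

    @property
    def group_sizes(self) -> tuple:
        return int(self.better.sum()), int(self.worse.sum())


def prognostic_index(beta: np.ndarray, data: SurvivalDataset) -> PrognosticSplit:
    """Linear risk score eta_i = x_i' beta with the median dichotomy.

    Patients at or below the median risk score form the "better"
    prognostic group (ties at the median go to "better").
    """
    beta = np.asarray(beta, dtype=float).ravel()
    eta = data.expression @ beta
    med = float(np.median(eta))
    better = eta <= med
    return PrognosticSplit(eta=eta, median=med, better=better, worse=~better)


def logrank_test(times, events, groups) -> float:
    """Two-sample log-rank p-value (delegates to lifelines)."""
    from lifelines.statistics import logrank_test as _lr

    times = np.asarray(times, dtype=float)
    events = np.asarray(events)
    groups = np.asarray(groups, dtype=bool)
    if groups.all() or (~groups).all():
        raise ValueError("both groups must be nonempty")
    res = _lr(times[groups], times[~groups],
              event_observed_A=events[groups],
              event_observed_B=events[~groups])
    return float(res.p_value)


@dataclass
class PiCoxResult:
    p_value: float
    alpha: float
    se: float


def pi_cox_pvalue(eta: np.ndarray, data: SurvivalDataset) -> PiCoxResult:
    """Wald test for the prognostic index in h(t|eta) = h0(t) exp(alpha eta)."""
    eta = np.asarray(eta, dtype=float).ravel()
    if np.ptp(eta) == 0:
        raise ValueError("prognostic index is constant")
    uni = SurvivalDataset(times=data.times, events=data.events,
                          expression=eta[:, None], gene_ids=("eta",),
                          patient_ids=data.patient_ids)
    fit = fit_cox_newton(uni)
    return PiCoxResult(p_value=float(fit.wald_p[0]), alpha=float(fit.beta[0]),
                       se=float(fit.se[0]))


def deviance(beta_train: np.ndarray, validation: SurvivalDataset) -> float:
    """Validation deviance -2[l_val(beta_train) - l_val(0)]; lower is better."""
    beta = np.asarray(beta_train, dtype=float).ravel()
    l0 = cox_partial_loglik(np.zeros(validation.p), validation)
    lb = cox_partial_loglik(beta, validation)
    return -2.0 * (lb - l0)


def _subset_aic(data: SurvivalDataset, idx: np.ndarray, ridge: float) -> float:
    sub = SurvivalDataset(times=data.times, events=data.events,
                          expression=data.expression[:, idx],
                          gene_ids=tuple(data.gene_ids[j] for j in idx),
                          patient_ids=data.patient_ids)
    fit = fit_cox_newton(sub, ridge=ridge)
    return -2.0 * fit.loglik + 2.0 * idx.shape[0]


def rank_vs_random_aic(beta: np.ndarray, data: SurvivalDataset,
                       subset_size: int, n_random: int = 10000,
                       seed: int = 0, ridge: float = 1e-4,
                       zero_tol: float = 1e-10) -> float:
    """Fraction of random active-gene subsets beating the ranked subset.

    Refits an (identically ridge-stabilized) Cox model on the top-|beta|
    subset of the active genes and on ``n_random`` uniformly drawn subsets
    of the same size, comparing AIC = -2 l(beta_hat) + 2 * subset_size.
    Small fractions mean the magnitude ranking is hard to beat by chance.
    """
    beta = np.asarray(beta, dtype=float).ravel()
    act = np.flatnonzero(np.abs(beta) > zero_tol)
    m = act.shape[0]
    if subset_size > m:
        raise ValueError(f"subset_size {subset_size} exceeds the active-set "
                         f"size {m}")
    order = act[np.argsort(-np.abs(beta[act]), kind="stable")]
    ranked = np.sort(order[:subset_size])
    aic_ranked = _subset_aic(data, ranked, ridge)
    rng = np.random.default_rng(seed)
    better = 0
    for _ in range(n_random):
        idx = np.sort(rng.choice(act, size=subset_size, replace=False))
        if _subset_aic(data, idx, ridge) < aic_ranked - 1e-9:
            better += 1
    return better / n_random


def km_curves(times, events, groups):
    """Kaplan-Meier curves per group as a tidy frame (for TSV export)."""
    import pandas as pd
    from lifelines import KaplanMeierFitter

    times = np.asarray(times, dtype=float)
    events = np.asarray(events)
    groups = np.asarray(groups, dtype=bool)
    frames = []
    for label, mask in (("better", groups), ("worse", ~groups)):
        if mask.sum() == 0:
            raise ValueError(f"group '{label}' is empty")
        kmf = KaplanMeierFitter()
        kmf.fit(times[mask], events[mask])
        tab = kmf.event_table
        surv = kmf.survival_function_.iloc[:, 0]
        frames.append(pd.DataFrame({
            "group": label,
            "time": tab.index.to_numpy(dtype=float),
            "at_risk": tab["at_risk"].to_numpy(),
            "survival": surv.to_numpy(),
        }))
    return pd.concat(frames, ignore_index=True)


@dataclass
class EvalReport:
    logrank_p: float
    pi_cox_p: float
    deviance: float
    alpha: float
    group_sizes: tuple
    median_eta: float

    def to_dict(self) -> dict:
        return {
            "logrank_p": self.logrank_p,
            "pi_cox_p": self.pi_cox_p,
            "deviance": self.deviance,
            "alpha": self.alpha,
            "group_sizes": list(self.group_sizes),
            "median_prognostic_index": self.median_eta,
        }


def evaluate_split(beta_train: np.ndarray,
                   validation: SurvivalDataset) -> EvalReport:
    """All three validation criteria for a training-data coefficient vector."""
    split = prognostic_index(beta_train, validation)
    lr_p = logrank_test(validation.times, validation.events, split.better)
    pc = pi_cox_pvalue(split.eta, validation)
    dev = deviance(beta_train, validation)
    return EvalReport(logrank_p=lr_p, pi_cox_p=pc.p_value, deviance=dev,
                      alpha=pc.alpha, group_sizes=split.group_sizes,
                      median_eta=split.median)
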