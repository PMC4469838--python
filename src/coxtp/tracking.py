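"""Sequential TP/FP classification along the lasso solution path.

Walking the path from step k to k+1, exactly one gene has entered or
left the active set.  For each hypothesis c in {0, 1, ..., C} ("the
changed gene belongs to the Laplace FP component" for c = 0, "to normal
TP component c" otherwise) the integer count bookkeeping

    pi_0^(k+1) = (FP_hat(k) +- 1) / m(k+1)        (hypothesis 0)
    pi_c^(k+1) = (TP_hat_c(k) +- 1) / m(k+1)      (hypothesis c)

fixes the mixture proportions, the shape parameters are re-fitted to the
nonzero coefficients at lambda_{k+1}, and the hypothesis with the largest
maximized log-likelihood wins (ties conservatively to FP).  The winning
count is incremented (entry) or decremented (exit), so
FP_hat + sum_c TP_hat_c = m holds exactly at every step.

The trace also supports the optimum-penalty rule (the lambda maximizing
the estimated TP count, ties to the sparser model) and the ranking-based
identification of the TP genes by descending coefficient magnitude.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .mixture import fit_fixed_weights
from .path import LassoPath

__all__ = [
    "CountState", "TPTrace", "TrackingConfig", "InfeasibleHypothesisError",
    "hypothesis_proportions", "run_tracking", "select_optimal_lambda",
    "identify_tp_genes", "OptimalLambda", "TPGeneSelection",
]


class InfeasibleHypothesisError(ValueError):
    """A hypothesis would decrement a count that is already zero."""


@dataclass
class CountState:
    """Integer FP / per-component TP bookkeeping after step k."""

    k: int
    FP_hat: int
    TP_hat_c: np.ndarray
    m: int

    def __post_init__(self) -> None:
        self.TP_hat_c = np.asarray(self.TP_hat_c, dtype=np.int64)
        if self.FP_hat < 0 or np.any(self.TP_hat_c < 0):
            raise ValueError("counts cannot be negative")
        if self.FP_hat + int(self.TP_hat_c.sum()) != self.m:
            raise ValueError("FP_hat + sum TP_hat_c must equal m")

    @property
    def TP_hat(self) -> int:
        return int(self.TP_hat_c.sum())


@dataclass
class StepDecision:
    k: int
    feasible: tuple
    logliks: dict
    c_max: int
    flagged: bool = False
    note: str = ""


@dataclass
class TPTrace:
    states: list[CountState]
    decisions: list[StepDecision]
    lambdas: np.ndarray
    C: int

    def tp_hat(self) -> np.ndarray:
        return np.array([s.TP_hat for s in self.states])

    def fp_hat(self) -> np.ndarray:
        return np.array([s.FP_hat for s in self.states])

    def m(self) -> np.ndarray:
        return np.array([s.m for s in self.states])

    def to_frame(self):
        import pandas as pd
        frame = pd.DataFrame({
            "k": [s.k for s in self.states],
            "lambda": self.lambdas,
            "m": self.m(),
            "FP_hat": self.fp_hat(),
            "TP_hat": self.tp_hat(),
            "C_max": [d.c_max for d in self.decisions],
            "flagged": [d.flagged for d in self.decisions],
        })
        for c in range(self.C + 1):
            frame[f"loglik_{c}"] = [d.logliks.get(c, np.nan)
                                    for d in self.decisions]
        return frame


@dataclass
class TrackingConfig:
    """Settings of the sequential classifier.

    ``m_min`` is the smallest active-set size at which the
    likelihood-based decision runs; below it, ``early_rule`` ("tp": count
    the change into normal component 1; "fp": count it as false positive)
    applies.  The default m_min = 1 runs the likelihood machinery from the
    very first selected gene, with one-point component fits guarded by the
    ``sigma_min`` / ``b_min`` scale floors.  ``fallback`` classifies a
    step when every hypothesis fit fails ("fp" fails safe toward fewer
    claimed TP).
    """

    m_min: int = 1
    early_rule: str = "tp"
    fallback: str = "fp"
    sigma_min: float = 1e-4
    b_min: float = 1e-8
    mu_floor: float = 1e-4
    em_max_iter: int = 300
    em_tol: float = 1e-8
    zero_tol: float = 1e-10


def hypothesis_proportions(prev: CountState, m_next: int, hypothesis: int):
    """Proportion vector (pi0, pi_1, ..., pi_C) under one hypothesis.

    The hypothesized component's count is incremented when a gene entered
    (m_next = m + 1) or decremented when one left (m_next = m - 1); all
    counts are then divided by m_next.  Decrementing a zero count raises
    :class:`InfeasibleHypothesisError`.
    """
    C = prev.TP_hat_c.shape[0]
    if not 0 <= hypothesis <= C:
        raise ValueError(f"hypothesis must lie in 0..{C}")
    delta = m_next - prev.m
    if abs(delta) != 1:
        raise ValueError("consecutive steps must differ by exactly one gene")
    counts = np.concatenate([[prev.FP_hat], prev.TP_hat_c]).astype(float)
    counts[hypothesis] += delta
    if counts[hypothesis] < 0:
        raise InfeasibleHypothesisError(
            f"hypothesis {hypothesis}: cannot decrement a zero count")
    if m_next <= 0:
        raise ValueError("m_next must be positive")
    return counts / m_next


def _apply(prev: CountState, k: int, m_next: int, c_max: int) -> CountState:
    delta = m_next - prev.m
    fp = prev.FP_hat
    tp = prev.TP_hat_c.copy()
    if c_max == 0:
        fp += delta
    else:
        tp[c_max - 1] += delta
    return CountState(k=k, FP_hat=fp, TP_hat_c=tp, m=m_next)


def run_tracking(path: LassoPath, C: int = 1,
                 config: TrackingConfig | None = None) -> TPTrace:
    """Classify every active-set change along the path as FP or TP."""
    cfg = config or TrackingConfig()
    if C < 1:
        raise ValueError("C must be at least 1")
    if len(path.steps) < 2:
        raise ValueError("path must contain at least two steps")
    state = CountState(k=path.steps[0].index, FP_hat=0,
                       TP_hat_c=np.zeros(C, dtype=np.int64),
                       m=path.steps[0].m)
    states: list[CountState] = []
    decisions: list[StepDecision] = []
    lambdas = []
    warm = None
    for step in path.steps[1:]:
        m_next = step.m
        coeffs = step.beta[np.abs(step.beta) > cfg.zero_tol]
        if m_next < cfg.m_min:
            c_max = 1 if cfg.early_rule == "tp" else 0
            if m_next < state.m:          # an exit under the early rule
                counts = np.concatenate([[state.FP_hat], state.TP_hat_c])
                if counts[c_max] == 0:
                    c_max = int(np.argmax(counts))
            decision = StepDecision(step.index, (), {}, c_max, flagged=True,
                                    note=f"early rule '{cfg.early_rule}'")
        else:
            logliks = {}
            fits = {}
            feasible = []
            for c in range(C + 1):
                try:
                    props = hypothesis_proportions(state, m_next, c)
                except InfeasibleHypothesisError:
                    continue
                feasible.append(c)
                try:
                    fit = fit_fixed_weights(
                        coeffs, float(props[0]), props[1:], warm=warm,
                        max_iter=cfg.em_max_iter, tol=cfg.em_tol,
                        sigma_min=cfg.sigma_min, b_min=cfg.b_min,
                        mu_floor=cfg.mu_floor)
                except Exception:
                    continue
                logliks[c] = fit["loglik"]
                fits[c] = fit
            if not feasible:
                raise RuntimeError(
                    f"step {step.index}: no feasible hypothesis (counts "
                    f"inconsistent with the path)")
            if logliks:
                best_ll = max(logliks.values())
                c_max = min(c for c, ll in logliks.items()
                            if ll >= best_ll - 1e-12)
                warm = fits[c_max]
                decision = StepDecision(step.index, tuple(feasible), logliks,
                                        c_max)
            else:
                c_max = 0 if cfg.fallback == "fp" else 1
                if c_max not in feasible:
                    c_max = feasible[0]
                decision = StepDecision(step.index, tuple(feasible), {},
                                        c_max, flagged=True,
                                        note="all hypothesis fits failed")
        state = _apply(state, step.index, m_next, c_max)
        states.append(state)
        decisions.append(decision)
        lambdas.append(step.lam)
    return TPTrace(states=states, decisions=decisions,
                   lambdas=np.array(lambdas), C=C)


@dataclass
class OptimalLambda:
    lam_star: float
    k_star: int
    tp_hat: int
    fp_hat: int
    false_positive_rate: float


def select_optimal_lambda(trace: TPTrace) -> OptimalLambda:
    """Penalty maximizing the estimated TP count (ties -> larger lambda)."""
    if not trace.states:
        raise ValueError("empty trace")
    tp = trace.tp_hat()
    i = int(np.argmax(tp))            # argmax returns the first (largest-lam) tie
    s = trace.states[i]
    denom = s.TP_hat + s.FP_hat
    fpr = s.FP_hat / denom if denom > 0 else 0.0
    return OptimalLambda(lam_star=float(trace.lambdas[i]), k_star=s.k,
                         tp_hat=s.TP_hat, fp_hat=s.FP_hat,
                         false_positive_rate=fpr)


@dataclass
class TPGeneSelection:
    genes: list
    indices: np.ndarray
    zeta: float
    tp_hat_raw: float
    n_selected: int


def identify_tp_genes(beta: np.ndarray, TP_hat: float, gene_ids=None,
                      zero_tol: float = 1e-10) -> TPGeneSelection:
    """Top round(TP_hat) active genes by |beta|, with the implied cut-off.

    ``zeta`` is the midpoint between the last included and first excluded
    coefficient magnitude (half the smallest included magnitude when all
    active genes are taken; the largest magnitude when none are).
    TP_hat is rounded half away from zero.
    """
    beta = np.asarray(beta, dtype=float).ravel()
    act = np.flatnonzero(np.abs(beta) > zero_tol)
    m = act.shape[0]
    n_take = int(np.floor(TP_hat + 0.5))
    if n_take > m:
        raise ValueError(f"TP_hat={TP_hat} exceeds the active-set size {m}")
    order = act[np.lexsort((act, -np.abs(beta[act])))]
    chosen = order[:n_take]
    mags = np.abs(beta[order])
    if n_take == 0:
        zeta = float(mags[0]) if m else 0.0
    elif n_take == m:
        zeta = float(mags[-1] / 2.0)
    else:
        zeta = float((mags[n_take - 1] + mags[n_take]) / 2.0)
    if gene_ids is None:
        genes = [int(j) for j in chosen]
    else:
        genes = [gene_ids[j] for j in chosen]
    return TPGeneSelection(genes=genes, indices=chosen, zeta=zeta,
                           tp_hat_raw=float(TP_hat), n_selected=n_take)
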