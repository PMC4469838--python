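"""Survival data container shared by every fitting routine in the package."""
from __future__ import annotations

from dataclasses import dataclass
from functools import cached_property

import numpy as np


class DegenerateDesignError(ValueError):
    """Raised when the expression matrix carries no usable signal."""


class NoEventsError(ValueError):
    """Raised when a partial-likelihood quantity is requested without events."""


@dataclass(eq=False)
class SurvivalDataset:
    """Gene-expression matrix plus right-censored survival outcomes.

    Parameters
    ----------
    times:
        Strictly positive follow-up time per patient (any time unit).
    events:
        Event indicator per patient; 1 if the event was observed, 0 if the
        follow-up time is censored.
    expression:
        Real matrix of shape (n patients, p genes); no missing entries.
    gene_ids, patient_ids:
        Optional identifier sequences; generated as ``g0001`` / ``s0001``
        style labels when omitted.
    """

    times: np.ndarray
    events: np.ndarray
    expression: np.ndarray
    gene_ids: tuple[str, ...] | None = None
    patient_ids: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=np.float64).ravel()
        events = np.asarray(self.events).ravel()
        self.expression = np.ascontiguousarray(self.expression, dtype=np.float64)
        if self.expression.ndim != 2:
            raise ValueError("expression must be a 2-d (patients x genes) matrix")
        n, p = self.expression.shape
        if n < 2 or p < 1:
            raise ValueError(f"need n >= 2 patients and p >= 1 genes, got n={n}, p={p}")
        if self.times.shape[0] != n or events.shape[0] != n:
            raise ValueError("times/events length must match the number of expression rows")
        if not np.all(np.isfinite(self.times)) or np.any(self.times <= 0):
            raise ValueError("all survival times must be finite and strictly positive")
        if not np.isin(events, (0, 1)).all():
            raise ValueError("events must be coded 0 (censored) / 1 (observed)")
        if not np.all(np.isfinite(self.expression)):
            raise ValueError("expression matrix contains non-finite entries")
        self.events = events.astype(np.int8)
        if self.gene_ids is None:
            width = max(4, len(str(p)))
            self.gene_ids = tuple(f"g{j + 1:0{width}d}" for j in range(p))
        else:
            self.gene_ids = tuple(str(g) for g in self.gene_ids)
            if len(self.gene_ids) != p:
                raise ValueError("gene_ids length must equal the number of genes")
            if len(set(self.gene_ids)) != p:
                raise ValueError("gene_ids must be unique")
        if self.patient_ids is None:
            width = max(4, len(str(n)))
            self.patient_ids = tuple(f"s{i + 1:0{width}d}" for i in range(n))
        else:
            self.patient_ids = tuple(str(s) for s in self.patient_ids)
            if len(self.patient_ids) != n:
                raise ValueError("patient_ids length must equal the number of patients")

    @property
    def n(self) -> int:
        return self.expression.shape[0]

    @property
    def p(self) -> int:
        return self.expression.shape[1]

    @property
    def n_events(self) -> int:
        return int(self.events.sum())

    @cached_property
    def _sorted(self) -> dict:
        """Time-ordered views used by the Breslow partial-likelihood kernels.

        Patients are sorted by increasing time; tied times form groups that
        share one risk set (Breslow convention).  ``gfirst[i]``/``glast[i]``
        give the first/last sorted index of the tie group containing sorted
        patient i.
        """
        order = np.argsort(self.times, kind="stable")
        ts = self.times[order]
        n = ts.shape[0]
        new_group = np.empty(n, dtype=bool)
        new_group[0] = True
        new_group[1:] = ts[1:] != ts[:-1]
        gid = np.cumsum(new_group) - 1
        first_of = np.flatnonzero(new_group)
        last_of = np.append(first_of[1:] - 1, n - 1)
        return {
            "order": order,
            "X": np.ascontiguousarray(self.expression[order]),
            "delta": self.events[order].astype(np.float64),
            "gfirst": np.ascontiguousarray(first_of[gid], dtype=np.int64),
            "glast": np.ascontiguousarray(last_of[gid], dtype=np.int64),
        }

    def subset(self, idx: np.ndarray) -> "SurvivalDataset":
        """Return the dataset restricted to the given patient indices."""
        idx = np.asarray(idx)
        return SurvivalDataset(
            times=self.times[idx],
            events=self.events[idx],
            expression=self.expression[idx],
            gene_ids=self.gene_ids,
            patient_ids=tuple(self.patient_ids[i] for i in idx),
        )
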