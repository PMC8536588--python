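"""Nonparametric bootstrap variance and percentile intervals for curves.

Resampling is always at the subject level: a replicate draws ``n`` subjects
with replacement and each drawn subject keeps its complete history.  The
chosen estimator (AJ, LMAJ or HAJ) is recomputed per replicate and pointwise
sample variances and percentile bounds are taken over replicates on a common
evaluation grid (the union of replicate jump times, step evaluation).

For HAJ the non-Markov set is by default the one selected on the original
sample; ``retest=True`` reruns the selection tests inside every replicate,
propagating the selection uncertainty into the intervals.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

import numpy as np

from .core import Histories, landmark_subset, _as_state_set
from .curves import StepCurve
from .estimators import aj_estimate, haj_estimate, lmaj_estimate
from .markov_tests import TestConfig, select_nonmarkov

__all__ = ["EstimatorSpec", "BootstrapResult", "bootstrap_curves"]


@dataclass(frozen=True)
class EstimatorSpec:
    """Which estimator to recompute per replicate, and its arguments."""

    method: str
    s: float
    l: frozenset
    tau: float
    A: frozenset | None = None
    test_configs: tuple = ()
    alpha: float = 0.05

    def __init__(self, method, s, l, tau, A=None, test_configs=(), alpha=0.05):
        method = str(method).lower()
        if method not in ("aj", "lmaj", "haj"):
            raise ValueError("method must be one of 'aj', 'lmaj', 'haj'")
        object.__setattr__(self, "method", method)
        object.__setattr__(self, "s", float(s))
        object.__setattr__(self, "l", _as_state_set(l))
        object.__setattr__(self, "tau", float(tau))
        object.__setattr__(self, "A", None if A is None else frozenset((int(j), int(k)) for j, k in A))
        object.__setattr__(self, "test_configs", tuple(test_configs))
        object.__setattr__(self, "alpha", float(alpha))

    def estimate(self, histories: Histories, A_override=None):
        if self.method == "aj":
            return aj_estimate(histories, self.s, self.l, self.tau)
        if self.method == "lmaj":
            return lmaj_estimate(histories, self.s, self.l, self.tau)
        A = A_override if A_override is not None else (self.A or frozenset())
        return haj_estimate(histories, self.s, self.l, self.tau, A)


@dataclass
class BootstrapResult:
    """Replicate curves with pointwise variance and percentile bounds.

    Percentile bounds need not bracket the point estimate; they are sample
    percentiles of the replicate curves.  ``n_empty_landmark`` counts
    replicates whose landmark set at ``(s, l)`` was empty (their curves stay
    at the initial vector and are kept).
    """

    spec: EstimatorSpec
    grid: np.ndarray
    replicates: np.ndarray  # (B, T, K)
    variance: np.ndarray    # (T, K)
    lower: np.ndarray       # (T, K)
    upper: np.ndarray       # (T, K)
    level: float
    B: int
    seed: int
    retest: bool
    n_empty_landmark: int = 0
    nonmarkov_sets: list = field(default_factory=list)

    def interval_curves(self) -> tuple[StepCurve, StepCurve]:
        lo = StepCurve(self.spec.s, self.grid, self.lower, self.lower[0])
        hi = StepCurve(self.spec.s, self.grid, self.upper, self.upper[0])
        return lo, hi


def bootstrap_curves(
    histories: Histories,
    spec: EstimatorSpec,
    B: int,
    seed: int = 0,
    retest: bool = False,
    level: float = 0.95,
) -> BootstrapResult:
    """Subject-level nonparametric bootstrap of an estimated probability curve."""
    if B < 2:
        raise ValueError("B must be at least 2")
    n = len(histories)
    rng = np.random.default_rng(seed)
    curves = []
    n_empty = 0
    A_sets = []
    for b in range(B):
        idx = rng.integers(0, n, size=n)
        rep = histories.subset(idx)
        if len(landmark_subset(rep, spec.s, spec.l)) == 0:
            n_empty += 1
        A_override = None
        if spec.method == "haj" and retest:
            A_override, _, _ = select_nonmarkov(rep, spec.test_configs, spec.alpha)
            A_sets.append(A_override)
        curves.append(spec.estimate(rep, A_override=A_override))

    grid = np.unique(np.concatenate([c.times for c in curves] + [np.asarray([spec.s])]))
    values = np.stack([c(grid) for c in curves])  # (B, T, K)
    variance = values.var(axis=0, ddof=1)
    q = (1.0 - level) / 2.0
    # probability scale: clip float spill from the product accumulation
    lower = np.clip(np.quantile(values, q, axis=0), 0.0, 1.0)
    upper = np.clip(np.quantile(values, 1.0 - q, axis=0), 0.0, 1.0)
    return BootstrapResult(
        spec=spec,
        grid=grid,
        replicates=values,
        variance=variance,
        lower=lower,
        upper=upper,
        level=level,
        B=B,
        seed=seed,
        retest=retest,
        n_empty_landmark=n_empty,
        nonmarkov_sets=A_sets,
    )
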