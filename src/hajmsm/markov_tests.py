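"""Transition-specific two-sample tests of the Markov property.

For a transition ``j -> k`` and a landmark time ``s``, subjects are split by
the state they occupy at ``s`` into two disjoint groups (``l1`` vs ``l2``);
under the Markov property the conditional intensity of the transition on
``(s, tau]`` does not depend on the group.  A standard two-sample log-rank
statistic compares the groups at one landmark time (the *point test*); the
*grid test* takes the maximum of the point statistics over a grid of landmark
times, with its null distribution approximated by a wild bootstrap that
multiplies each subject's martingale-residual contribution by an i.i.d.
standardized compensated-Poisson multiplier (``Q - 1`` with ``Q ~ Poisson(1)``),
one multiplier per subject per replicate, shared across grid times so the
dependence between the maximized statistics is preserved.

The log-rank variance treats increments as independent across event times,
which recurrent within-subject transitions violate; this is exactly why the
grid test is calibrated by the wild bootstrap rather than by a chi-squared
reference.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy import stats

from .core import Histories, _as_state_set

__all__ = [
    "TestConfig",
    "MarkovTestResult",
    "logrank_point_statistic",
    "point_test",
    "grid_test",
    "select_nonmarkov",
]


@dataclass(frozen=True)
class TestConfig:
    """Configuration of a grid test for one transition.

    ``l1`` and ``l2`` must be disjoint state sets: disjoint landmark groups
    make the two samples independent.  ``variance`` chooses the studentizer of
    the score: ``"robust"`` (default) uses the per-subject sum of squared
    martingale residuals, which is exactly the conditional variance of the
    wild-bootstrap replicate score and stays valid under within-subject
    recurrence; ``"hypergeometric"`` and ``"poisson"`` are the classical
    independent-increment log-rank variances.
    """

    transition: tuple
    grid: tuple
    l1: frozenset
    l2: frozenset
    tau: float
    B: int = 500
    alpha: float = 0.05
    seed: int = 0
    variance: str = "robust"

    def __init__(self, transition, grid, l1, l2, tau, B=500, alpha=0.05, seed=0, variance="robust"):
        object.__setattr__(self, "transition", (int(transition[0]), int(transition[1])))
        grid_arr = tuple(float(g) for g in (grid if np.iterable(grid) else [grid]))
        object.__setattr__(self, "grid", grid_arr)
        object.__setattr__(self, "l1", _as_state_set(l1))
        object.__setattr__(self, "l2", _as_state_set(l2))
        object.__setattr__(self, "tau", float(tau))
        object.__setattr__(self, "B", int(B))
        object.__setattr__(self, "alpha", float(alpha))
        object.__setattr__(self, "seed", int(seed))
        object.__setattr__(self, "variance", str(variance))
        if self.l1 & self.l2:
            raise ValueError("landmark groups l1 and l2 must be disjoint")
        if self.B < 1:
            raise ValueError("B must be at least 1")
        if not (0.0 < self.alpha < 1.0):
            raise ValueError("alpha must lie in (0, 1)")
        if any(g >= self.tau for g in self.grid):
            raise ValueError("every grid time must precede tau")
        if self.variance not in ("robust", "hypergeometric", "poisson"):
            raise ValueError("variance must be 'robust', 'hypergeometric' or 'poisson'")


@dataclass
class MarkovTestResult:
    """Result of a grid test for one transition."""

    config: TestConfig
    statistics: np.ndarray  # per-grid-time chi-squared statistics X_s
    statistic: float        # X = max_i X_{s_i}
    null_sample: np.ndarray  # wild-bootstrap replicates of the max statistic
    p_value: float
    reject: bool
    warnings: tuple = ()

    @property
    def testable(self) -> bool:
        """False when no grid time carried any two-sample information."""
        return bool(np.any(np.asarray(self._variances) > 0))

    _variances: np.ndarray = field(default_factory=lambda: np.zeros(0))


def _logrank_components(histories: Histories, s, transition, l1, l2, tau):
    """Score, variance and per-subject residuals of the two-sample log-rank.

    Returns ``(U, V_hyper, V_poisson, resid, warn)`` where ``resid`` is the
    length-n vector of martingale-residual contributions satisfying
    ``U = resid.sum()`` and ``warn`` flags an empty group at ``s``.
    """
    j, k = transition
    s = float(s)
    st = histories.states_at(s, side="right")
    g1 = np.isin(st, sorted(l1))
    g2 = np.isin(st, sorted(l2))
    pooled = g1 | g2
    n = len(histories)
    resid = np.zeros(n)
    warn = not (np.any(g1) and np.any(g2))

    row_pool = pooled[histories.sid]
    # event rows of the tested transition inside the window, pooled sample
    ev = row_pool & (histories.from_state == j) & (histories.to_state == k) \
        & (histories.exit > s) & (histories.exit <= tau)
    times = np.unique(histories.exit[ev])
    if len(times) == 0:
        return 0.0, 0.0, 0.0, resid, warn

    # at-risk intervals (entry, exit] in state j, clipped to (s, tau]
    occ = row_pool & (histories.from_state == j)
    last = histories._last_row_mask()
    term = row_pool & last & (histories.to_state == j)
    lo_t = np.concatenate([histories.entry[occ], histories.exit[term]])
    hi_t = np.concatenate([histories.exit[occ], np.full(term.sum(), np.inf)])
    own = np.concatenate([histories.sid[occ], histories.sid[term]])
    lo_t = np.maximum(lo_t, s)
    hi_t = np.minimum(hi_t, tau)
    keep = hi_t > lo_t
    lo_t, hi_t, own = lo_t[keep], hi_t[keep], own[keep]
    g_row = g1[own].astype(float)

    # interval -> slice of covered event times: indices in [lo_idx, hi_idx)
    lo_idx = np.searchsorted(times, lo_t, side="right")
    hi_idx = np.searchsorted(times, hi_t, side="right")

    T = len(times)
    ones = np.ones(len(lo_t))
    Ypad = np.zeros(T + 1)
    np.add.at(Ypad, lo_idx, ones)
    np.subtract.at(Ypad, hi_idx, ones)
    Y = np.cumsum(Ypad[:-1])
    Y1pad = np.zeros(T + 1)
    np.add.at(Y1pad, lo_idx, g_row)
    np.subtract.at(Y1pad, hi_idx, g_row)
    Y1 = np.cumsum(Y1pad[:-1])

    ev_sid = histories.sid[ev]
    ev_idx = np.searchsorted(times, histories.exit[ev])
    dN = np.zeros(T)
    dN1 = np.zeros(T)
    np.add.at(dN, ev_idx, 1.0)
    np.add.at(dN1, ev_idx, g1[ev_sid].astype(float))

    with np.errstate(divide="ignore", invalid="ignore"):
        h = np.where(Y > 0, Y1 / np.maximum(Y, 1), 0.0)
        lam = np.where(Y > 0, dN / np.maximum(Y, 1), 0.0)
    U = float(np.sum(dN1 - h * dN))
    good = Y > 1
    V_hyper = float(np.sum(np.where(good, dN * h * (1 - h) * (Y - dN) / np.maximum(Y - 1, 1), 0.0)))
    V_pois = float(np.sum(dN * h * (1 - h)))

    # per-subject residuals: own events minus compensator along at-risk spells
    S1 = np.concatenate([[0.0], np.cumsum(lam)])
    S2 = np.concatenate([[0.0], np.cumsum(h * lam)])
    comp = g_row * (S1[hi_idx] - S1[lo_idx]) - (S2[hi_idx] - S2[lo_idx])
    np.subtract.at(resid, own, comp)
    np.add.at(resid, ev_sid, g1[ev_sid] - h[ev_idx])
    return U, V_hyper, V_pois, resid, warn


def logrank_point_statistic(
    histories: Histories, s: float, transition, l1, l2, tau: float,
    variance: str = "hypergeometric",
) -> float:
    """Chi-squared log-rank statistic ``X_s = U^2 / V`` for one landmark time.

    Returns 0 when the variance is zero (no two-sample information), in
    particular when a landmark group is empty at ``s``.
    """
    l1, l2 = _as_state_set(l1), _as_state_set(l2)
    if l1 & l2:
        raise ValueError("landmark groups l1 and l2 must be disjoint")
    U, Vh, Vp, _, _ = _logrank_components(histories, s, transition, l1, l2, tau)
    V = Vh if variance == "hypergeometric" else Vp
    return float(U * U / V) if V > 0 else 0.0


def point_test(histories, s, transition, l1, l2, tau, variance="hypergeometric"):
    """Point test: the statistic at one landmark time with its chi2(1) p-value."""
    x = logrank_point_statistic(histories, s, transition, l1, l2, tau, variance)
    return x, float(stats.chi2.sf(x, df=1))


def grid_test(histories: Histories, cfg: TestConfig) -> MarkovTestResult:
    """Grid test ``X = max_i X_{s_i}`` with a wild-bootstrap null sample.

    Each bootstrap replicate draws one standardized compensated-Poisson
    multiplier per subject, perturbs every grid time's score with the same
    multipliers, and records the max statistic.  The p-value uses the
    ``(1 + #{X* >= X}) / (B + 1)`` convention.
    """
    m = len(cfg.grid)
    n = len(histories)
    R = np.zeros((m, n))
    U = np.zeros(m)
    V = np.zeros(m)
    warns = []
    for i, s in enumerate(cfg.grid):
        u, vh, vp, resid, warn = _logrank_components(
            histories, s, cfg.transition, cfg.l1, cfg.l2, cfg.tau
        )
        U[i] = u
        if cfg.variance == "robust":
            V[i] = float(np.sum(resid * resid))
        else:
            V[i] = vh if cfg.variance == "hypergeometric" else vp
        R[i] = resid
        if warn:
            warns.append(f"empty landmark group at s={s}")
    with np.errstate(divide="ignore", invalid="ignore"):
        stats_obs = np.where(V > 0, U * U / np.maximum(V, 1e-300), 0.0)
    observed = float(stats_obs.max()) if m else 0.0

    rng = np.random.default_rng(cfg.seed)
    G = rng.poisson(1.0, size=(cfg.B, n)) - 1.0
    U_star = G @ R.T  # (B, m)
    with np.errstate(divide="ignore", invalid="ignore"):
        X_star = np.where(V > 0, U_star**2 / np.maximum(V, 1e-300), 0.0)
    null_sample = X_star.max(axis=1) if m else np.zeros(cfg.B)
    p = float((1 + np.sum(null_sample >= observed)) / (cfg.B + 1))
    res = MarkovTestResult(
        config=cfg,
        statistics=stats_obs,
        statistic=observed,
        null_sample=null_sample,
        p_value=p,
        reject=p < cfg.alpha,
        warnings=tuple(warns),
    )
    res._variances = V
    return res


def select_nonmarkov(
    histories: Histories,
    configs: Iterable[TestConfig],
    alpha: float | None = None,
) -> tuple[frozenset, dict, list]:
    """Run grid tests and collect the non-Markov transition set ``A``.

    Returns ``(A, results, untestable)``: transitions whose grid-test p-value
    falls below the significance level enter ``A``; transitions with no
    two-sample information at any grid time (an origin state never occupied in
    one group) are excluded from ``A`` and listed in ``untestable``.  No
    multiple-testing adjustment is applied.
    """
    results: dict = {}
    A = set()
    untestable = []
    for cfg in configs:
        res = grid_test(histories, cfg)
        results[cfg.transition] = res
        if not res.testable:
            untestable.append(cfg.transition)
            continue
        level = cfg.alpha if alpha is None else alpha
        if res.p_value < level:
            A.add(cfg.transition)
    return frozenset(A), results, untestable
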