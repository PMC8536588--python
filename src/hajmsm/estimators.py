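"""Nelson-Aalen rates and product-integral transition probabilities.

Three estimators of the transition-probability row vector
``P_l(s, t) = (P_l1(s,t), ..., P_lK(s,t))`` are provided, all plug-in product
integrals ``e_l prod_{u in (s,t]} (I + dLambda(u))`` differing only in the
cumulative-hazard increments fed to the product:

* **AJ** - full-sample Nelson-Aalen rates (consistent under the Markov
  assumption);
* **LMAJ** - rates computed on the landmark subsample occupying state(s) ``l``
  at time ``s`` (consistent without the Markov assumption);
* **HAJ** - a per-transition hybrid: landmark rates for the transitions in a
  designated non-Markov set ``A``, full-sample rates otherwise.

``A = {}`` recovers AJ and ``A = E`` recovers LMAJ exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

import numpy as np

from .core import (
    AggregatedProcesses,
    Histories,
    StateSpace,
    _as_state_set,
    aggregate,
    landmark_subset,
)
from .curves import StepCurve, TransitionProbabilityCurve

__all__ = [
    "CumulativeHazard",
    "HybridSpec",
    "nelson_aalen",
    "landmark_nelson_aalen",
    "hybrid_hazard",
    "product_integral",
    "matrix_product_integral",
    "aj_estimate",
    "lmaj_estimate",
    "haj_estimate",
    "occupation_probabilities",
    "greenwood_variance",
]


@dataclass
class CumulativeHazard:
    """Matrix-valued cumulative-hazard increments on ``(origin, tau]``.

    ``delta[t]`` is the K x K increment matrix at the t-th jump time:
    off-diagonal ``(j,k)`` entries are ``dN_jk(u)/Y_j(u)`` (zero when nobody
    is at risk) and each diagonal entry is minus the row's off-diagonal sum,
    so every ``I + delta[t]`` has rows summing to one.

    ``trans_stats`` keeps the raw ``(dN, Y)`` pair per transition (aligned
    with ``times``) for variance computations, and ``source`` records which
    sample each transition's rates came from ("full" or "landmark").
    """

    origin: float
    times: np.ndarray
    delta: np.ndarray
    n_states: int
    trans_stats: dict = field(default_factory=dict)
    source: dict = field(default_factory=dict)

    def cumulative(self, j: int, k: int) -> np.ndarray:
        """Cumulative hazard path ``Lambda_jk`` evaluated at the jump times."""
        return np.cumsum(self.delta[:, j - 1, k - 1])

    def restricted(self, t: float) -> "CumulativeHazard":
        keep = self.times <= t
        return CumulativeHazard(
            self.origin,
            self.times[keep],
            self.delta[keep],
            self.n_states,
            {tr: (dn[keep], y[keep]) for tr, (dn, y) in self.trans_stats.items()},
            dict(self.source),
        )


@dataclass(frozen=True)
class HybridSpec:
    """Which transitions use landmark rates, and from which landmark."""

    nonmarkov: frozenset
    landmark_time: float
    landmark_state: frozenset

    def __init__(self, nonmarkov, landmark_time, landmark_state):
        object.__setattr__(self, "nonmarkov", frozenset((int(j), int(k)) for j, k in nonmarkov))
        object.__setattr__(self, "landmark_time", float(landmark_time))
        object.__setattr__(self, "landmark_state", _as_state_set(landmark_state))


def nelson_aalen(agg: AggregatedProcesses, state_space: StateSpace, source: str = "full") -> CumulativeHazard:
    """Nelson-Aalen increment matrices from aggregated counting processes.

    Increments are ``dN_jk(u) / Y_j(u)`` with the convention that an empty
    risk set contributes zero.
    """
    K = state_space.n_states
    T = len(agg.jump_times)
    delta = np.zeros((T, K, K))
    trans_stats = {}
    src = {}
    for (j, k), dn in agg.increments.items():
        y = agg.at_risk[:, j - 1]
        with np.errstate(divide="ignore", invalid="ignore"):
            inc = np.where(y > 0, dn / np.maximum(y, 1), 0.0)
        delta[:, j - 1, k - 1] = inc
        trans_stats[(j, k)] = (dn.astype(float), y.astype(float))
        src[(j, k)] = source
    for j in range(K):
        delta[:, j, j] = -(delta[:, j, :].sum(axis=1) - delta[:, j, j])
    return CumulativeHazard(agg.window[0], agg.jump_times, delta, K, trans_stats, src)


def landmark_nelson_aalen(
    histories: Histories,
    s: float,
    l: Iterable[int],
    tau: float,
    state_space: StateSpace | None = None,
) -> CumulativeHazard:
    """Nelson-Aalen rates computed on the landmark subsample at ``(s, l)``."""
    space = state_space or histories.state_space
    sub = landmark_subset(histories, s, l)
    return nelson_aalen(aggregate(sub, (s, tau), space), space, source="landmark")


def hybrid_hazard(
    full: CumulativeHazard,
    lm: CumulativeHazard,
    A: Iterable[tuple[int, int]],
    state_space: StateSpace,
) -> CumulativeHazard:
    """Merge full-sample and landmark hazards transition by transition.

    Transitions in the non-Markov set ``A`` take their increments from the
    landmark hazard, all others from the full-sample hazard.  Jump times whose
    merged increment matrix is identically zero are dropped (they would only
    contribute identity factors to the product integral), which makes
    ``A = {}`` coincide with the full hazard and ``A = E`` with the landmark
    hazard exactly.
    """
    A = frozenset((int(j), int(k)) for j, k in A)
    if not A <= state_space.transitions:
        raise ValueError(f"non-Markov set contains transitions outside E: {sorted(A - state_space.transitions)}")
    if full.origin != lm.origin:
        raise ValueError("full and landmark hazards must share the same window origin")
    K = state_space.n_states
    times = np.union1d(full.times, lm.times)
    T = len(times)
    delta = np.zeros((T, K, K))
    trans_stats = {}
    src = {}

    def aligned(h: CumulativeHazard, tr):
        idx = np.searchsorted(times, h.times)
        dn = np.zeros(T)
        y = np.zeros(T)
        dn[idx], y[idx] = h.trans_stats[tr]
        inc = np.zeros(T)
        inc[idx] = h.delta[:, tr[0] - 1, tr[1] - 1]
        return inc, dn, y

    for tr in state_space.sorted_transitions():
        source_h = lm if tr in A else full
        if tr not in source_h.trans_stats:
            continue
        inc, dn, y = aligned(source_h, tr)
        delta[:, tr[0] - 1, tr[1] - 1] = inc
        trans_stats[tr] = (dn, y)
        src[tr] = "landmark" if tr in A else "full"
    for j in range(K):
        delta[:, j, j] = -(delta[:, j, :].sum(axis=1) - delta[:, j, j])

    keep = np.any(delta != 0.0, axis=(1, 2))
    return CumulativeHazard(
        full.origin,
        times[keep],
        delta[keep],
        K,
        {tr: (dn[keep], y[keep]) for tr, (dn, y) in trans_stats.items()},
        src,
    )


# ---------------------------------------------------------------------------
# product integrals
# ---------------------------------------------------------------------------

def product_integral(
    haz: CumulativeHazard,
    init,
    t: float | None = None,
    landmark_state=None,
    method: str = "",
) -> TransitionProbabilityCurve:
    """Row-vector product integral ``init * prod (I + delta(u))`` up to ``t``.

    ``init`` may be a state label (giving the unit vector ``e_l``) or a length
    K probability vector.  The product is accumulated in increasing time
    order; the value at the origin (empty product) is ``init`` itself.
    """
    K = haz.n_states
    scalar_init = isinstance(init, (int, np.integer))
    if scalar_init:
        v = np.eye(K)[int(init) - 1].copy()
    else:
        v = np.asarray(init, dtype=float).copy()
    init_vec = v.copy()
    if t is None:
        t = np.inf
    elif t < haz.origin:
        raise ValueError("evaluation time precedes the hazard origin")
    keep = haz.times <= t
    times = haz.times[keep]
    delta = haz.delta[keep]
    values = np.empty((len(times), K))
    for i in range(len(times)):
        v = v + v @ delta[i]
        values[i] = v
    return TransitionProbabilityCurve(
        haz.origin, times, values, init_vec, landmark_state=landmark_state, method=method
    )


def matrix_product_integral(haz: CumulativeHazard, t: float | None = None) -> np.ndarray:
    """Full K x K product integral ``prod_{u <= t} (I + delta(u))``."""
    K = haz.n_states
    P = np.eye(K)
    if t is None:
        t = np.inf
    for i in range(len(haz.times)):
        if haz.times[i] > t:
            break
        P = P @ (np.eye(K) + haz.delta[i])
    return P


# ---------------------------------------------------------------------------
# the three estimators
# ---------------------------------------------------------------------------

def _initial_distribution(histories: Histories, s: float, l) -> np.ndarray:
    """Empirical distribution over the landmark states at ``s``.

    For a single landmark state this is the unit vector ``e_l``; for a set it
    is the observed occupancy split across the set (uniform over ``l`` when the
    landmark sample is empty, in which case downstream curves stay constant).
    """
    lset = sorted(_as_state_set(l))
    K = histories.state_space.n_states
    st = histories.states_at(s, side="right")
    init = np.zeros(K)
    for state in lset:
        init[state - 1] = np.sum(st == state)
    total = init.sum()
    if total == 0:
        for state in lset:
            init[state - 1] = 1.0 / len(lset)
        return init
    return init / total


def aj_estimate(
    histories: Histories,
    s: float,
    l,
    tau: float,
    state_space: StateSpace | None = None,
    t: float | None = None,
) -> TransitionProbabilityCurve:
    """Aalen-Johansen estimate from ``(s, l)`` using full-sample rates.

    This is the Markov-assuming competitor: it conditions on the landmark
    state only through the initial vector while the rates over ``(s, tau]``
    use every subject under observation.
    """
    space = state_space or histories.state_space
    haz = nelson_aalen(aggregate(histories, (s, tau), space), space)
    init = _initial_distribution(histories, s, l)
    return product_integral(haz, init, t=t, landmark_state=_as_state_set(l), method="aj")


def lmaj_estimate(
    histories: Histories,
    s: float,
    l,
    tau: float,
    state_space: StateSpace | None = None,
    t: float | None = None,
) -> TransitionProbabilityCurve:
    """Landmark Aalen-Johansen estimate: AJ applied to the landmark subsample."""
    space = state_space or histories.state_space
    haz = landmark_nelson_aalen(histories, s, l, tau, space)
    init = _initial_distribution(histories, s, l)
    return product_integral(haz, init, t=t, landmark_state=_as_state_set(l), method="lmaj")


def haj_estimate(
    histories: Histories,
    s: float,
    l,
    tau: float,
    A: Iterable[tuple[int, int]],
    state_space: StateSpace | None = None,
    t: float | None = None,
) -> TransitionProbabilityCurve:
    """Hybrid landmark Aalen-Johansen estimate.

    Rates for the transitions in the non-Markov set ``A`` come from the
    landmark subsample at ``(s, l)``; all remaining transitions use the full
    sample.
    """
    space = state_space or histories.state_space
    full = nelson_aalen(aggregate(histories, (s, tau), space), space)
    lm = landmark_nelson_aalen(histories, s, l, tau, space)
    haz = hybrid_hazard(full, lm, A, space)
    init = _initial_distribution(histories, s, l)
    return product_integral(haz, init, t=t, landmark_state=_as_state_set(l), method="haj")


def _haj_via_riskset_removal(
    histories: Histories,
    s: float,
    l,
    tau: float,
    A: Iterable[tuple[int, int]],
    state_space: StateSpace | None = None,
) -> TransitionProbabilityCurve:
    """Equivalent HAJ construction used as a cross-check.

    Instead of merging two precomputed hazards, the hazard increments are
    recomputed from scratch per transition, removing the subjects outside the
    landmark sample from the risk sets (and event counts) of the transitions
    in ``A`` only.  Must agree bitwise with :func:`haj_estimate`.
    """
    space = state_space or histories.state_space
    A = frozenset((int(j), int(k)) for j, k in A)
    lm_hist = landmark_subset(histories, s, l)
    agg_full = aggregate(histories, (s, tau), space)
    agg_lm = aggregate(lm_hist, (s, tau), space)
    times = np.union1d(agg_full.jump_times, agg_lm.jump_times)
    K = space.n_states
    delta = np.zeros((len(times), K, K))
    for tr in space.sorted_transitions():
        agg = agg_lm if tr in A else agg_full
        idx = np.searchsorted(times, agg.jump_times)
        dn = np.zeros(len(times))
        y = np.zeros(len(times))
        dn[idx] = agg.increments[tr]
        y[idx] = agg.at_risk[:, tr[0] - 1]
        with np.errstate(divide="ignore", invalid="ignore"):
            delta[:, tr[0] - 1, tr[1] - 1] = np.where(y > 0, dn / np.maximum(y, 1), 0.0)
    for j in range(K):
        delta[:, j, j] = -(delta[:, j, :].sum(axis=1) - delta[:, j, j])
    keep = np.any(delta != 0.0, axis=(1, 2))
    haz = CumulativeHazard(s, times[keep], delta[keep], K)
    init = _initial_distribution(histories, s, l)
    return product_integral(haz, init, landmark_state=_as_state_set(l), method="haj")


def occupation_probabilities(
    histories: Histories, t: float, state_space: StateSpace | None = None
) -> np.ndarray:
    """State-occupation probabilities ``pi(0) P_AJ(0, t)``.

    The initial distribution is the empirical occupancy just after time zero;
    the product integral uses full-sample rates.  Occupation probabilities are
    consistently estimated this way with or without the Markov property.
    """
    space = state_space or histories.state_space
    st0 = histories.states_at(0.0, side="right")
    observed = st0 > 0
    if not np.any(observed):
        raise ValueError("no subjects under observation at time 0")
    K = space.n_states
    pi0 = np.bincount(st0[observed], minlength=K + 1)[1:].astype(float)
    pi0 /= pi0.sum()
    if t < 0:
        raise ValueError("t must be nonnegative")
    if t == 0:
        return pi0
    haz = nelson_aalen(aggregate(histories, (0.0, t), space), space)
    return pi0 @ matrix_product_integral(haz)


# ---------------------------------------------------------------------------
# Greenwood-type plug-in variance
# ---------------------------------------------------------------------------

def greenwood_variance(haz: CumulativeHazard, init, t: float | None = None) -> StepCurve:
    """Plug-in pointwise variances for a product-integral row estimate.

    The covariance of the row vector ``v(t) = init * prod (I + delta)`` is
    propagated jump by jump: sandwich the running covariance with
    ``I + delta(u)`` and add, for each origin state, the multinomial plug-in
    covariance of that origin's increment row scaled by the squared occupancy
    ``v_j(u-)^2``.  Binomial-type terms ``dN (Y - dN) / Y^3`` appear on the
    diagonal.  Valid under the Markov assumption; for landmark or hybrid
    hazards it is a plug-in approximation and the bootstrap is the
    recommended check.

    Returns a step curve of the K pointwise variances.
    """
    K = haz.n_states
    if isinstance(init, (int, np.integer)):
        v = np.eye(K)[int(init) - 1].copy()
    else:
        v = np.asarray(init, dtype=float).copy()
    if t is None:
        t = np.inf
    keep = haz.times <= t
    times = haz.times[keep]
    C = np.zeros((K, K))
    out = np.empty((len(times), K))
    by_origin: dict[int, list] = {}
    for (j, k), (dn, y) in haz.trans_stats.items():
        by_origin.setdefault(j, []).append(((j, k), dn, y))
    eye = np.eye(K)
    for i in range(len(times)):
        D = haz.delta[keep][i]
        A = eye + D
        C = A.T @ C @ A
        for j, entries in by_origin.items():
            if v[j - 1] == 0.0:
                continue
            Cj = np.zeros((K, K))
            for (tr1, dn1, y1) in entries:
                if y1[i] <= 0 or dn1[i] <= 0:
                    continue
                p1 = dn1[i] / y1[i]
                k1 = tr1[1] - 1
                Cj[k1, k1] += p1 * (1.0 - p1) / y1[i]
                for (tr2, dn2, y2) in entries:
                    if tr2 == tr1 or y2[i] <= 0 or dn2[i] <= 0:
                        continue
                    # multinomial cross term, only within a common source sample
                    if haz.source.get(tr1) == haz.source.get(tr2):
                        k2 = tr2[1] - 1
                        Cj[k1, k2] -= (dn1[i] / y1[i]) * (dn2[i] / y2[i]) / y1[i]
            if np.any(Cj):
                jj = j - 1
                Cj[jj, :] = -Cj[: , :].sum(axis=0)
                Cj[:, jj] = -Cj[:, :].sum(axis=1)
                C = C + (v[j - 1] ** 2) * Cj
        v = v @ A
        out[i] = np.clip(np.diag(C), 0.0, None)
    return StepCurve(haz.origin, times, out, np.zeros(K))
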