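"""Frailty-driven simulation of multi-state histories and experiment drivers.

The engine simulates subjects on a finite state space whose transition
intensities are ``lambda_jk = V_jk * alpha_jk``: constant baseline rates
``alpha_jk`` scaled by subject-level random frailties ``V_jk`` with mean one.
Conditionally on its frailty vector each subject follows a time-homogeneous
Markov chain (competing exponential sojourns); marginally over a
non-degenerate frailty the process is non-Markov, because a subject's past
trajectory carries information about its frailty and hence about its future
rates.

Two frailty presets mirror the two study designs on the illness-death model
with recovery (states 1 = employed, 2 = sick leave, 3 = disabled):

1. a single gamma frailty with mean 1 and variance ``sigma2`` on the recovery
   transition 2 -> 1 (all other frailties fixed at one), making exactly one
   transition non-Markov;
2. a joint log-normal frailty vector with mean one and a fixed correlated
   covariance across all four transitions, making every transition non-Markov.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable

import numpy as np

from .core import Histories, StateSpace, illness_death_recovery
from .curves import StepCurve
from .estimators import aj_estimate, haj_estimate, lmaj_estimate
from .markov_tests import TestConfig, select_nonmarkov

__all__ = [
    "TRANSITION_ORDER",
    "BASE_RATES",
    "CORRELATED_FRAILTY_COV",
    "FrailtyModel",
    "SimulationDesign",
    "draw_frailties",
    "simulate_histories",
    "true_probability_oracle",
    "run_experiment",
    "ExperimentResult",
    "experiment_design",
    "LANDMARK_GRID_EXP1",
    "LANDMARK_GRID_EXP2",
]

#: frailty-vector component order
TRANSITION_ORDER = ((1, 2), (1, 3), (2, 1), (2, 3))

#: baseline transition rates (alpha_12, alpha_13, alpha_21, alpha_23)
BASE_RATES = (0.12, 0.03, 0.15, 0.1)

#: covariance of the correlated log-normal frailty vector (design 2)
CORRELATED_FRAILTY_COV = np.array(
    [
        [0.80, 0.57, -0.35, 0.37],
        [0.57, 0.42, -0.12, 0.19],
        [-0.35, -0.12, 0.96, -0.63],
        [0.37, 0.19, -0.63, 0.45],
    ]
)

LANDMARK_GRID_EXP1 = (6.0, 9.0, 12.0, 14.0, 17.0, 20.0, 22.0, 25.0, 28.0, 30.0)
LANDMARK_GRID_EXP2 = (1.0, 4.0, 6.0, 8.0, 10.0, 12.0, 14.0, 16.0, 18.0, 20.0, 22.0, 24.0, 26.0, 28.0, 30.0)


@dataclass(frozen=True)
class FrailtyModel:
    """Distribution of the per-subject frailty vector ``(V_12, V_13, V_21, V_23)``.

    Kinds
    -----
    ``none``
        All frailties identically one (Markov model).
    ``gamma_single``
        One component (default the recovery transition 2 -> 1) is gamma with
        mean 1 and variance ``sigma2`` (shape = rate = 1/sigma2); the rest are
        one.  ``sigma2 = 0`` degenerates to ``none``.
    ``lognormal_joint``
        ``V = exp(W)`` with ``W`` multivariate normal chosen so that ``V`` has
        mean one and covariance ``cov``: ``Cov(W_jk) = log(1 + cov_jk)`` and
        ``E[W_j] = -Var(W_j)/2``.  ``repair=True`` projects ``log(1 + cov)``
        to the nearest positive semidefinite matrix with the diagonal
        restored, preserving the marginal moments exactly; otherwise an
        invalid matrix is rejected with its offending eigenvalue.
    """

    kind: str = "none"
    sigma2: float = 0.0
    transition: tuple = (2, 1)
    cov: np.ndarray | None = None
    repair: bool = False

    def __post_init__(self):
        if self.kind not in ("none", "gamma_single", "lognormal_joint"):
            raise ValueError(f"unknown frailty kind {self.kind!r}")
        if self.kind == "gamma_single" and self.sigma2 < 0:
            raise ValueError("sigma2 must be nonnegative")
        if self.kind == "lognormal_joint" and self.cov is None:
            object.__setattr__(self, "cov", CORRELATED_FRAILTY_COV.copy())
            object.__setattr__(self, "repair", True)


def _nearest_psd_preserving_diagonal(M: np.ndarray, eps: float = 1e-10) -> np.ndarray:
    """Clip negative eigenvalues, then rescale to restore the diagonal."""
    w, Q = np.linalg.eigh(M)
    Mp = (Q * np.clip(w, eps, None)) @ Q.T
    d = np.sqrt(np.diag(M) / np.diag(Mp))
    return Mp * np.outer(d, d)


def draw_frailties(model: FrailtyModel, n: int, seed) -> np.ndarray:
    """Draw ``n`` i.i.d. frailty vectors, one row per subject.

    ``seed`` may be an int or a ``numpy.random.SeedSequence``/Generator.
    """
    rng = np.random.default_rng(seed)
    V = np.ones((n, 4))
    if model.kind == "none" or (model.kind == "gamma_single" and model.sigma2 == 0.0):
        return V
    if model.kind == "gamma_single":
        shape = 1.0 / model.sigma2
        col = TRANSITION_ORDER.index(tuple(model.transition))
        V[:, col] = rng.gamma(shape, scale=model.sigma2, size=n)
        return V
    # lognormal_joint
    cov = np.asarray(model.cov, dtype=float)
    M = np.log1p(cov)
    eig = np.linalg.eigvalsh(M)
    if eig[0] < -1e-12:
        if not model.repair:
            raise ValueError(
                f"log(1 + cov) is not positive semidefinite (smallest eigenvalue {eig[0]:.4g}); "
                "pass repair=True to project to the nearest valid matrix"
            )
        M = _nearest_psd_preserving_diagonal(M)
    mean = -0.5 * np.diag(M)
    W = rng.multivariate_normal(mean, M, size=n, method="eigh")
    return np.exp(W)


@dataclass(frozen=True)
class SimulationDesign:
    """Full specification of one simulated dataset."""

    n: int
    rates: dict | tuple = BASE_RATES
    tau: float = 1000.0
    frailty: FrailtyModel = field(default_factory=FrailtyModel)
    initial_state: object = 1
    state_space: StateSpace = field(default_factory=illness_death_recovery)
    seed: int = 0

    def rate_table(self) -> dict:
        if isinstance(self.rates, dict):
            table = {tuple(k): float(v) for k, v in self.rates.items()}
        else:
            table = {tr: float(a) for tr, a in zip(TRANSITION_ORDER, self.rates)}
        if any(a < 0 for a in table.values()):
            raise ValueError("transition rates must be nonnegative")
        return table


def _initial_states(design: SimulationDesign, n: int, rng) -> np.ndarray:
    init = design.initial_state
    if isinstance(init, (int, np.integer)):
        return np.full(n, int(init), dtype=np.int64)
    probs = np.asarray([init.get(s, 0.0) if isinstance(init, dict) else init[s - 1]
                        for s in design.state_space.states], dtype=float)
    probs = probs / probs.sum()
    return rng.choice(np.arange(1, design.state_space.n_states + 1), size=n, p=probs)


def simulate_histories(design: SimulationDesign) -> Histories:
    """Simulate ``n`` subjects by competing exponential sojourns up to ``tau``.

    Each subject gets its own counter-based random stream derived from the
    design seed, so output is reproducible and independent of iteration
    order.  A subject still in a non-absorbing state at ``tau`` is closed with
    a censored sojourn (``to = 0``); entry to an absorbing state ends the
    history.
    """
    space = design.state_space
    table = design.rate_table()
    root = np.random.SeedSequence(design.seed)
    ss_frail, ss_init, ss_path = root.spawn(3)
    V = draw_frailties(design.frailty, design.n, ss_frail)
    frail_col = {tr: i for i, tr in enumerate(TRANSITION_ORDER)}
    init_states = _initial_states(design, design.n, np.random.default_rng(ss_init))

    # per-state outgoing transitions with baseline rates
    out: dict[int, list] = {
        j: [(k, table.get((j, k), 0.0)) for k in space.destinations(j)] for j in space.states
    }

    sid_rows, entry_rows, exit_rows, from_rows, to_rows = [], [], [], [], []
    streams = ss_path.spawn(design.n)
    tau = float(design.tau)
    for i in range(design.n):
        rng = np.random.default_rng(streams[i])
        state = int(init_states[i])
        t = 0.0
        while True:
            dests = out[state]
            rates = np.array(
                [base * V[i, frail_col[(state, k)]] if (state, k) in frail_col else base
                 for k, base in dests]
            ) if dests else np.zeros(0)
            total = rates.sum()
            if total <= 0.0:
                sid_rows.append(i); entry_rows.append(t); exit_rows.append(tau)
                from_rows.append(state); to_rows.append(0)
                break
            # inverse-CDF exponential sojourn and categorical destination
            w = -np.log1p(-rng.random()) / total
            if t + w >= tau:
                sid_rows.append(i); entry_rows.append(t); exit_rows.append(tau)
                from_rows.append(state); to_rows.append(0)
                break
            u = rng.random() * total
            dest = dests[int(np.searchsorted(np.cumsum(rates), u, side="right"))][0]
            sid_rows.append(i); entry_rows.append(t); exit_rows.append(t + w)
            from_rows.append(state); to_rows.append(dest)
            t += w
            state = dest
            if not out[state]:  # absorbing: history ends at first entry
                break
    return Histories(
        np.arange(design.n),
        np.asarray(sid_rows),
        np.asarray(entry_rows),
        np.asarray(exit_rows),
        np.asarray(from_rows),
        np.asarray(to_rows),
        space,
        validate=False,
    )


def experiment_design(
    which: int,
    n: int = 1000,
    sigma2: float = 2.0,
    seed: int = 0,
    tau: float = 1000.0,
    cov: np.ndarray | None = None,
) -> SimulationDesign:
    """Preset designs: 1 = single gamma frailty on 2->1, 2 = joint log-normal."""
    if which == 1:
        frailty = FrailtyModel("gamma_single", sigma2=sigma2) if sigma2 > 0 else FrailtyModel("none")
    elif which == 2:
        frailty = FrailtyModel("lognormal_joint", cov=cov)
    else:
        raise ValueError("experiment must be 1 or 2")
    return SimulationDesign(n=n, tau=tau, frailty=frailty, seed=seed)


def true_probability_oracle(
    design: SimulationDesign,
    s: float,
    l,
    reps: int = 1000,
    n_per_rep: int | None = None,
    seed: int = 0,
    grid: np.ndarray | None = None,
    tau_star: float | None = None,
) -> StepCurve:
    """Simulation-based "true" transition-probability curve from ``(s, l)``.

    The marginal (over frailty) transition probability has no closed form, so
    it is approximated by the mean over ``reps`` fresh simulations of the LMAJ
    estimator, each on an independent sample; the average is taken pointwise
    on a fixed evaluation grid (default 200 equally spaced points on
    ``(s, tau_star]``) with step evaluation, and is constant beyond the grid.
    """
    if reps < 1:
        raise ValueError("reps must be at least 1")
    if grid is None:
        if tau_star is None:
            tau_star = min(design.tau, s + 150.0)
        grid = np.linspace(s, tau_star, 201)[1:]
    grid = np.asarray(grid, dtype=float)
    K = design.state_space.n_states
    acc = np.zeros((len(grid), K))
    acc0 = np.zeros(K)
    children = np.random.SeedSequence(seed).spawn(reps)
    n = design.n if n_per_rep is None else n_per_rep
    for r in range(reps):
        rep_seed = int(children[r].generate_state(1, dtype=np.uint32)[0] % (2**31))
        hist = simulate_histories(replace(design, n=n, seed=rep_seed))
        curve = lmaj_estimate(hist, s, l, design.tau)
        acc += curve(grid)
        acc0 += curve.init
    return StepCurve(s, grid, acc / reps, acc0 / reps)


@dataclass
class ExperimentRepetition:
    """Everything retained from one Monte-Carlo repetition."""

    seed: int
    nonmarkov: frozenset
    p_values: dict
    untestable: list
    curves: dict  # (method, s, frozenset(l)) -> TransitionProbabilityCurve


@dataclass
class ExperimentResult:
    which: int
    landmark_grid: tuple
    alpha: float
    repetitions: list

    def curves(self, method: str, s: float, l) -> list:
        key = (method, float(s), frozenset(l) if np.iterable(l) else frozenset([l]))
        return [rep.curves[key] for rep in self.repetitions]

    def selection_rate(self, transition) -> float:
        tr = tuple(transition)
        return float(np.mean([tr in rep.nonmarkov for rep in self.repetitions]))


def _experiment_test_configs(space, grid, tau, B, alpha, seed):
    """One grid-test config per transition; groups are landmark states 1 vs 2."""
    configs = []
    for i, tr in enumerate(space.sorted_transitions()):
        l1 = frozenset([tr[0]]) if tr[0] in (1, 2) else frozenset([1])
        l2 = frozenset([2]) if l1 == frozenset([1]) else frozenset([1])
        configs.append(TestConfig(tr, grid, l1, l2, tau, B=B, alpha=alpha, seed=seed + i))
    return configs


def run_experiment(
    which: int,
    reps: int,
    n: int = 1000,
    seed: int = 0,
    sigma2: float = 2.0,
    landmark_grid: Iterable[float] | None = None,
    alpha: float = 0.05,
    B: int = 500,
    eval_points: Iterable[tuple] | None = None,
    tau: float = 1000.0,
) -> ExperimentResult:
    """Monte-Carlo driver: simulate, select ``A`` by grid tests, estimate.

    For each repetition the grid test (landmark groups state 1 vs state 2) is
    applied to every transition to build the non-Markov set ``A``; AJ, LMAJ
    and HAJ curves are then computed from each requested evaluation point
    ``(s, l)`` (default: every landmark-grid time from both transient
    states).
    """
    grid = tuple(landmark_grid) if landmark_grid is not None else (
        LANDMARK_GRID_EXP1 if which == 1 else LANDMARK_GRID_EXP2
    )
    base = experiment_design(which, n=n, sigma2=sigma2, tau=tau)
    space = base.state_space
    if eval_points is None:
        eval_points = [(s, frozenset([l])) for s in grid for l in (1, 2)]
    eval_points = [(float(s), frozenset(l)) for s, l in eval_points]

    children = np.random.SeedSequence(seed).spawn(reps)
    repetitions = []
    for r in range(reps):
        rep_seed = int(children[r].generate_state(1, dtype=np.uint32)[0] % (2**31))
        hist = simulate_histories(replace(base, n=n, seed=rep_seed))
        configs = _experiment_test_configs(space, grid, tau, B, alpha, rep_seed)
        A, results, untestable = select_nonmarkov(hist, configs)
        curves = {}
        for s, l in eval_points:
            curves[("aj", s, l)] = aj_estimate(hist, s, l, tau, space)
            curves[("lmaj", s, l)] = lmaj_estimate(hist, s, l, tau, space)
            curves[("haj", s, l)] = haj_estimate(hist, s, l, tau, A, space)
        repetitions.append(
            ExperimentRepetition(
                seed=rep_seed,
                nonmarkov=A,
                p_values={tr: res.p_value for tr, res in results.items()},
                untestable=untestable,
                curves=curves,
            )
        )
    return ExperimentResult(which, grid, alpha, repetitions)
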