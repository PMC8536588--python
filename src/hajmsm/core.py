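"""Event-history containers, long-format I/O and counting-process aggregation.

Multi-state event histories are stored in "long" sojourn format: one record per
visit to a state, carrying the entry time, the exit time and the destination
state of the jump that ended the visit (``to = 0`` when observation ended
without a jump, i.e. censoring or administrative study end).  Every estimator
in this package consumes histories through the aggregated at-risk processes
``Ybar_j(t-)`` and transition-counting increments ``dNbar_jk(t)`` computed
here.

Conventions
-----------
* Sample paths are right-continuous: the state *at* time ``t`` is the state
  jumped into at ``t``.  At-risk sets use left limits, so a subject counts as
  at risk in ``j`` at time ``u`` when it occupied ``j`` strictly before ``u``.
* A subject whose final sojourn ends with a real transition (``to != 0``)
  occupies the destination state from that time onward; this is the natural
  encoding for absorbing states.
* Ties across subjects are aggregated into a single jump time; simultaneous
  events within a subject are excluded by the strict ``entry < exit``
  requirement.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Iterator, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "CENSORED",
    "StateSpace",
    "EventHistory",
    "Histories",
    "AggregatedProcesses",
    "illness_death_recovery",
    "read_histories",
    "write_histories",
    "fixture_histories",
    "aggregate",
    "landmark_subset",
]

#: destination code marking "observation ends here without a transition"
CENSORED = 0

_COLUMNS = ("id", "entry", "exit", "from", "to")


@dataclass(frozen=True, init=False)
class StateSpace:
    """A finite state space ``{1, ..., K}`` with permitted direct transitions.

    Parameters
    ----------
    n_states
        Number of states ``K``.
    transitions
        Iterable of ordered pairs ``(j, k)``, ``j != k``, the transitions the
        process may make directly.  States that appear as origin of no pair
        are absorbing.
    """

    n_states: int
    transitions: frozenset

    def __init__(self, n_states: int, transitions: Iterable[tuple[int, int]]):
        object.__setattr__(self, "n_states", int(n_states))
        trans = frozenset((int(j), int(k)) for j, k in transitions)
        object.__setattr__(self, "transitions", trans)
        if self.n_states < 1:
            raise ValueError("n_states must be a positive integer")
        for j, k in trans:
            if j == k or not (1 <= j <= self.n_states) or not (1 <= k <= self.n_states):
                raise ValueError(f"invalid transition ({j}, {k}) for K={self.n_states}")

    @property
    def states(self) -> range:
        return range(1, self.n_states + 1)

    @property
    def absorbing(self) -> frozenset:
        origins = {j for j, _ in self.transitions}
        return frozenset(s for s in self.states if s not in origins)

    def destinations(self, j: int) -> list[int]:
        """Sorted direct destinations reachable from state ``j``."""
        return sorted(k for a, k in self.transitions if a == j)

    def sorted_transitions(self) -> list[tuple[int, int]]:
        return sorted(self.transitions)


def illness_death_recovery() -> StateSpace:
    """Three-state illness-death model with recovery.

    States: 1 = healthy/employed, 2 = ill/on sick leave, 3 = dead/disabled
    (absorbing).  Transitions 1->2, 1->3, 2->1 and 2->3 are permitted.
    """
    return StateSpace(3, [(1, 2), (1, 3), (2, 1), (2, 3)])


@dataclass(frozen=True)
class EventHistory:
    """One subject's observed path as an ordered tuple of sojourns.

    Each sojourn is ``(entry_time, exit_time, from_state, to_state)`` with
    ``to_state = 0`` encoding end of observation.
    """

    subject_id: object
    sojourns: tuple

    def __post_init__(self):
        object.__setattr__(
            self,
            "sojourns",
            tuple((float(a), float(b), int(f), int(t)) for a, b, f, t in self.sojourns),
        )

    @property
    def n_transitions(self) -> int:
        return sum(1 for _, _, _, t in self.sojourns if t != CENSORED)

    def state_at(self, t: float, side: str = "right") -> int:
        """State occupied at ``t`` (0 when not under observation).

        ``side='right'`` evaluates the right-continuous path ``X(t)``;
        ``side='left'`` evaluates the left limit ``X(t-)``.
        """
        if side not in ("right", "left"):
            raise ValueError("side must be 'right' or 'left'")
        for entry, exit_, from_, _ in self.sojourns:
            if (entry <= t < exit_) if side == "right" else (entry < t <= exit_):
                return from_
        last = self.sojourns[-1]
        beyond = (t >= last[1]) if side == "right" else (t > last[1])
        if beyond and last[3] != CENSORED:
            return last[3]
        return 0


class Histories(Sequence):
    """A collection of :class:`EventHistory`, stored columnar for speed.

    The public constructor accepts parallel row arrays; most users build
    instances through :func:`read_histories`, :meth:`from_event_histories`,
    :meth:`from_frame` or the simulator.
    """

    def __init__(
        self,
        ids: np.ndarray,
        sid: np.ndarray,
        entry: np.ndarray,
        exit: np.ndarray,
        from_state: np.ndarray,
        to_state: np.ndarray,
        state_space: StateSpace,
        validate: bool = True,
    ):
        order = np.lexsort((np.asarray(entry, dtype=float), np.asarray(sid, dtype=np.int64)))
        self.ids = np.asarray(ids)
        self.sid = np.asarray(sid, dtype=np.int64)[order]
        self.entry = np.asarray(entry, dtype=float)[order]
        self.exit = np.asarray(exit, dtype=float)[order]
        self.from_state = np.asarray(from_state, dtype=np.int64)[order]
        self.to_state = np.asarray(to_state, dtype=np.int64)[order]
        self.state_space = state_space
        n = len(self.ids)
        self._starts = np.searchsorted(self.sid, np.arange(n), side="left")
        self._stops = np.searchsorted(self.sid, np.arange(n), side="right")
        if validate:
            self._validate()

    # -- construction ----------------------------------------------------
    @classmethod
    def from_event_histories(
        cls, histories: Iterable[EventHistory], state_space: StateSpace, validate: bool = True
    ) -> "Histories":
        histories = list(histories)
        ids, sid, entry, exit_, fr, to = [], [], [], [], [], []
        for i, h in enumerate(histories):
            ids.append(h.subject_id)
            for a, b, f, t in h.sojourns:
                sid.append(i)
                entry.append(a)
                exit_.append(b)
                fr.append(f)
                to.append(t)
        return cls(
            np.asarray(ids, dtype=object),
            np.asarray(sid),
            np.asarray(entry),
            np.asarray(exit_),
            np.asarray(fr),
            np.asarray(to),
            state_space,
            validate=validate,
        )

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, state_space: StateSpace, validate: bool = True) -> "Histories":
        """Build from a long-format frame with columns ``id,entry,exit,from,to``."""
        missing = [c for c in _COLUMNS if c not in frame.columns]
        if missing:
            raise ValueError(f"long-format frame is missing columns {missing}")
        df = frame.sort_values(["id", "entry"], kind="mergesort")
        sid, uniq = pd.factorize(df["id"])
        return cls(
            np.asarray(uniq),
            sid,
            df["entry"].to_numpy(dtype=float),
            df["exit"].to_numpy(dtype=float),
            df["from"].to_numpy(dtype=np.int64),
            df["to"].to_numpy(dtype=np.int64),
            state_space,
            validate=validate,
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "id": self.ids[self.sid],
                "entry": self.entry,
                "exit": self.exit,
                "from": self.from_state,
                "to": self.to_state,
            }
        )

    # -- validation ------------------------------------------------------
    def _validate(self) -> None:
        bad: list[str] = []
        E = self.state_space.transitions
        K = self.state_space.n_states
        if np.any(self.entry < 0):
            rows = np.flatnonzero(self.entry < 0)[:5]
            bad.append(f"negative entry times at rows {rows.tolist()}")
        nonpos = self.exit <= self.entry
        if np.any(nonpos):
            rows = np.flatnonzero(nonpos)[:5]
            bad.append(f"entry >= exit at rows {rows.tolist()}")
        same = self.sid[1:] == self.sid[:-1]
        dup = same & (self.entry[1:] == self.entry[:-1])
        if np.any(dup):
            rows = (np.flatnonzero(dup) + 1)[:5]
            bad.append(f"duplicate (id, entry) rows at {rows.tolist()}")
        gap = same & (self.entry[1:] != self.exit[:-1])
        if np.any(gap):
            rows = (np.flatnonzero(gap) + 1)[:5]
            bad.append(f"non-contiguous sojourns at rows {rows.tolist()}")
        mism = same & (self.from_state[1:] != self.to_state[:-1])
        if np.any(mism):
            rows = (np.flatnonzero(mism) + 1)[:5]
            bad.append(f"from_state does not continue previous to_state at rows {rows.tolist()}")
        last = np.zeros(len(self.sid), dtype=bool)
        if len(self.sid):
            last[self._stops[self.sid] - 1] = True
        early_censor = (self.to_state == CENSORED) & ~last
        if np.any(early_censor):
            rows = np.flatnonzero(early_censor)[:5]
            bad.append(f"censoring before the final sojourn at rows {rows.tolist()}")
        real = self.to_state != CENSORED
        ok_state = (self.from_state >= 1) & (self.from_state <= K)
        if np.any(~ok_state):
            rows = np.flatnonzero(~ok_state)[:5]
            bad.append(f"from_state outside 1..{K} at rows {rows.tolist()}")
        pairs = set(zip(self.from_state[real].tolist(), self.to_state[real].tolist()))
        illegal = pairs - set(E)
        if illegal:
            bad.append(f"transitions not in E: {sorted(illegal)}")
        if bad:
            raise ValueError("invalid event histories: " + "; ".join(bad))

    # -- sequence protocol ----------------------------------------------
    def __len__(self) -> int:
        return len(self.ids)

    def __getitem__(self, i):
        if isinstance(i, slice):
            return [self[j] for j in range(*i.indices(len(self)))]
        lo, hi = self._starts[i], self._stops[i]
        soj = tuple(
            (self.entry[r], self.exit[r], self.from_state[r], self.to_state[r])
            for r in range(lo, hi)
        )
        return EventHistory(self.ids[i], soj)

    def __iter__(self) -> Iterator[EventHistory]:
        for i in range(len(self)):
            yield self[i]

    # -- queries ---------------------------------------------------------
    @property
    def n_transitions(self) -> int:
        return int(np.sum(self.to_state != CENSORED))

    def _last_row_mask(self) -> np.ndarray:
        last = np.zeros(len(self.sid), dtype=bool)
        if len(self.sid):
            last[self._stops[self.sid] - 1] = True
        return last

    def states_at(self, t: float, side: str = "right") -> np.ndarray:
        """Vector of occupied states at ``t`` per subject (0 = not observed)."""
        out = np.zeros(len(self), dtype=np.int64)
        if side == "right":
            occ = (self.entry <= t) & (t < self.exit)
        elif side == "left":
            occ = (self.entry < t) & (t <= self.exit)
        else:
            raise ValueError("side must be 'right' or 'left'")
        out[self.sid[occ]] = self.from_state[occ]
        last = self._last_row_mask()
        if side == "right":
            term = last & (self.to_state != CENSORED) & (t >= self.exit)
        else:
            term = last & (self.to_state != CENSORED) & (t > self.exit)
        out[self.sid[term]] = self.to_state[term]
        return out

    def subset(self, indices: Iterable[int]) -> "Histories":
        """New collection holding (copies of) the selected subjects.

        Subjects are relabelled ``0..m-1`` so the same original subject may be
        included several times (as needed by bootstrap resampling with
        replacement).
        """
        indices = np.asarray(list(indices), dtype=np.int64)
        lo, hi = self._starts[indices], self._stops[indices]
        counts = hi - lo
        rows = np.concatenate([np.arange(a, b) for a, b in zip(lo, hi)]) if len(indices) else np.empty(0, dtype=np.int64)
        sid = np.repeat(np.arange(len(indices)), counts)
        return Histories(
            np.arange(len(indices)),
            sid,
            self.entry[rows],
            self.exit[rows],
            self.from_state[rows],
            self.to_state[rows],
            self.state_space,
            validate=False,
        )


# ---------------------------------------------------------------------------
# long-format file I/O
# ---------------------------------------------------------------------------

def read_histories(path, state_space: StateSpace) -> Histories:
    """Read a long-format CSV (header ``id,entry,exit,from,to``).

    Rows are validated against the state space; malformed files raise
    ``ValueError`` with row-level diagnostics.
    """
    df = pd.read_csv(path)
    if list(df.columns) != list(_COLUMNS):
        raise ValueError(f"expected header {','.join(_COLUMNS)}, found {','.join(map(str, df.columns))}")
    return Histories.from_frame(df, state_space)


def write_histories(histories: Histories, path) -> None:
    """Write a collection as long-format CSV, rows sorted by (id, entry)."""
    histories.to_frame().to_csv(path, index=False)


def fixture_histories() -> Histories:
    """A hand-checkable 3-subject dataset on the illness-death-with-recovery model.

    Subject 1 is healthy, falls ill at t=1, recovers at t=3 and is censored at
    t=5; subject 2 is absorbed from health at t=2; subject 3 starts ill and is
    absorbed at t=4.
    """
    frame = pd.DataFrame(
        {
            "id": [1, 1, 1, 2, 3],
            "entry": [0.0, 1.0, 3.0, 0.0, 0.0],
            "exit": [1.0, 3.0, 5.0, 2.0, 4.0],
            "from": [1, 2, 1, 1, 2],
            "to": [2, 1, 0, 3, 3],
        }
    )
    return Histories.from_frame(frame, illness_death_recovery())


# ---------------------------------------------------------------------------
# counting-process aggregation
# ---------------------------------------------------------------------------

@dataclass
class AggregatedProcesses:
    """Aggregated at-risk counts and transition-count increments on a window.

    ``at_risk[t, j-1]`` is ``Ybar_j(u_t-)`` (left limit) and
    ``increments[(j,k)][t]`` the number of direct j->k transitions at the t-th
    jump time.
    """

    window: tuple
    jump_times: np.ndarray
    at_risk: np.ndarray
    increments: dict
    n_subjects: int

    def total_transitions(self) -> int:
        return int(sum(arr.sum() for arr in self.increments.values()))


def aggregate(histories: Histories, window: tuple, state_space: StateSpace | None = None) -> AggregatedProcesses:
    """Aggregate counting processes over the half-open window ``(s, tau]``.

    Jump times are the distinct transition times in the window; an empty
    window yields an empty jump set.
    """
    space = state_space or histories.state_space
    s, tau = float(window[0]), float(window[1])
    if s >= tau:
        raise ValueError(f"window requires s < tau, got ({s}, {tau})")
    K = space.n_states
    real = histories.to_state != CENSORED
    ev = real & (histories.exit > s) & (histories.exit <= tau)
    jump_times = np.unique(histories.exit[ev])
    T = len(jump_times)

    increments: dict = {}
    for j, k in space.sorted_transitions():
        arr = np.zeros(T, dtype=np.int64)
        mask = ev & (histories.from_state == j) & (histories.to_state == k)
        if np.any(mask):
            idx = np.searchsorted(jump_times, histories.exit[mask])
            np.add.at(arr, idx, 1)
        increments[(j, k)] = arr

    at_risk = np.zeros((T, K), dtype=np.int64)
    last = histories._last_row_mask()
    for j in space.states:
        occ = histories.from_state == j
        entries = np.sort(histories.entry[occ])
        exits = np.sort(histories.exit[occ])
        # sojourn occupancy: in state j on (entry, exit] as seen by left limits
        y = np.searchsorted(entries, jump_times, side="left") - np.searchsorted(
            exits, jump_times, side="left"
        )
        # terminal occupancy: a final real jump into j occupies j from then on
        term = last & (histories.to_state == j)
        y = y + np.searchsorted(np.sort(histories.exit[term]), jump_times, side="left")
        at_risk[:, j - 1] = y

    return AggregatedProcesses((s, tau), jump_times, at_risk, increments, len(histories))


def landmark_subset(histories: Histories, s: float, l: Iterable[int]) -> Histories:
    """Subjects occupying one of the landmark states ``l`` at time ``s``.

    Evaluation is right-continuous (the state *at* ``s``); subjects whose
    observation ended at or before ``s`` are excluded.  The returned subjects
    keep their complete histories.
    """
    lset = _as_state_set(l)
    st = histories.states_at(float(s), side="right")
    keep = np.flatnonzero(np.isin(st, sorted(lset)))
    return histories.subset(keep)


def _as_state_set(l) -> frozenset:
    if isinstance(l, (int, np.integer)):
        return frozenset([int(l)])
    return frozenset(int(x) for x in l)
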