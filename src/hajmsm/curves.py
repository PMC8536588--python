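"""Right-continuous vector-valued step curves.

Transition-probability estimates, truth curves and variance curves are all
step functions that jump at event times; this module gives them a common
container with step evaluation and CSV export.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = ["StepCurve", "TransitionProbabilityCurve"]


class StepCurve:
    """A right-continuous step function ``t -> R^K`` starting at ``start``.

    ``values[i]`` is the value on ``[times[i], times[i+1])``; before the first
    jump the curve equals ``init``.  Evaluation at arbitrary times returns the
    value at the largest jump time ``<= t``.
    """

    def __init__(self, start: float, times: np.ndarray, values: np.ndarray, init: np.ndarray):
        self.start = float(start)
        self.times = np.asarray(times, dtype=float)
        init = np.atleast_1d(np.asarray(init, dtype=float))
        self.values = np.asarray(values, dtype=float).reshape(len(self.times), len(init))
        self.init = init

    @property
    def n_states(self) -> int:
        return len(self.init)

    def __call__(self, t) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        idx = np.searchsorted(self.times, t, side="right") - 1
        stacked = np.concatenate([self.init[None, :], self.values], axis=0)
        return stacked[idx + 1]

    @property
    def final(self) -> np.ndarray:
        return self.values[-1] if len(self.times) else self.init

    def restricted(self, t: float) -> "StepCurve":
        """The same curve truncated to jump times ``<= t``."""
        keep = self.times <= t
        return StepCurve(self.start, self.times[keep], self.values[keep], self.init)

    def to_frame(self, prefix: str = "p") -> pd.DataFrame:
        cols = {f"{prefix}{k}": np.concatenate([[self.init[k - 1]], self.values[:, k - 1]])
                for k in range(1, self.n_states + 1)}
        return pd.DataFrame({"time": np.concatenate([[self.start], self.times]), **cols})

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "StepCurve":
        times = frame["time"].to_numpy(dtype=float)
        vals = frame.drop(columns="time").to_numpy(dtype=float)
        return cls(times[0], times[1:], vals[1:], vals[0])


class TransitionProbabilityCurve(StepCurve):
    """Estimated transition-probability row ``t -> (P_l1(s,t), ..., P_lK(s,t))``.

    Carries the landmark time/state and the estimating method.  Values are row
    vectors of a product-integral estimate; they sum to one by construction
    and are kept unclipped (use :meth:`clipped` for reporting).
    """

    def __init__(self, start, times, values, init, landmark_state=None, method: str = ""):
        super().__init__(start, times, values, init)
        self.landmark_state = frozenset(landmark_state) if landmark_state is not None else None
        self.method = method

    def clipped(self) -> StepCurve:
        return StepCurve(self.start, self.times, np.clip(self.values, 0.0, 1.0), np.clip(self.init, 0.0, 1.0))
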