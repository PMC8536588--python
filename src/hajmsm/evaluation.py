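"""Performance metrics for estimated transition-probability curves.

The headline metric is the mean residual squared error (MRSE): the squared
L2 distance ``int_s^tau (f(t) - g(t))^2 dt`` between an estimated curve and
the (simulated) truth, computed as a left-endpoint Riemann sum over the union
of the two curves' jump times -- exact for step functions.  Pointwise bias,
variance and interval coverage across Monte-Carlo replicates are also
provided.
"""

from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .curves import StepCurve

__all__ = ["mrse", "pointwise_bias_variance", "coverage", "mrse_table", "plot_mrse_panel"]


def mrse(f: StepCurve, g: StepCurve, window: tuple, component: int | None = None):
    """Squared L2 distance between two step curves over ``(s, tau]``.

    ``component`` selects a state (1-based) and returns a scalar; otherwise a
    length-K vector of componentwise integrals is returned.
    """
    s, tau = float(window[0]), float(window[1])
    if tau <= s:
        raise ValueError("window requires s < tau")
    cuts = np.unique(np.concatenate([
        [s], f.times[(f.times > s) & (f.times < tau)], g.times[(g.times > s) & (g.times < tau)], [tau]
    ]))
    left = cuts[:-1]
    widths = np.diff(cuts)
    diff = f(left) - g(left)
    out = np.sum(diff * diff * widths[:, None], axis=0)
    if component is not None:
        return float(out[component - 1])
    return out


def pointwise_bias_variance(
    curves: Sequence[StepCurve], truth: StepCurve, grid: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Empirical bias and sample variance of replicate curves on a grid.

    Returns ``(bias, variance)``, each of shape ``(len(grid), K)``: bias is
    the replicate mean minus the truth, variance the ddof=1 sample variance.
    """
    if len(curves) < 2:
        raise ValueError("need at least two replicate curves")
    grid = np.asarray(grid, dtype=float)
    values = np.stack([c(grid) for c in curves])
    bias = values.mean(axis=0) - truth(grid)
    variance = values.var(axis=0, ddof=1)
    return bias, variance


def coverage(
    bounds: Iterable[tuple], truth: StepCurve, grid: np.ndarray
) -> np.ndarray:
    """Proportion of replicate intervals containing the truth, per grid time.

    ``bounds`` is an iterable of ``(lower, upper)`` pairs; each may be a
    :class:`StepCurve` or an array of shape ``(len(grid), K)``.
    """
    grid = np.asarray(grid, dtype=float)
    tv = truth(grid)
    hits = []
    for lo, hi in bounds:
        lov = lo(grid) if callable(lo) else np.asarray(lo, dtype=float)
        hiv = hi(grid) if callable(hi) else np.asarray(hi, dtype=float)
        hits.append((lov <= tv) & (tv <= hiv))
    if not hits:
        raise ValueError("no interval bounds supplied")
    return np.mean(np.stack(hits), axis=0)


def mrse_table(
    curves_by_method: dict,
    truth: StepCurve,
    window: tuple,
) -> pd.DataFrame:
    """Mean (over replicates) componentwise MRSE per estimator.

    ``curves_by_method`` maps a method label to its list of replicate curves.
    """
    rows = []
    for method, curves in curves_by_method.items():
        vals = np.stack([mrse(c, truth, window) for c in curves])
        for k in range(vals.shape[1]):
            rows.append({"method": method, "state": k + 1,
                         "mrse_mean": vals[:, k].mean(), "mrse_sd": vals[:, k].std(ddof=1)})
    return pd.DataFrame(rows)


def plot_mrse_panel(table: pd.DataFrame, ax=None, title: str = ""):
    """Bar panel of mean MRSE by estimator and destination state."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    pivot = table.pivot(index="state", columns="method", values="mrse_mean")
    pivot.plot.bar(ax=ax)
    ax.set_xlabel("destination state")
    ax.set_ylabel("mean MRSE")
    if title:
        ax.set_title(title)
    return ax
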