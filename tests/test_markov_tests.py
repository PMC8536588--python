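"""Log-rank point test, wild-bootstrap grid test, non-Markov selection."""

import numpy as np
import pandas as pd
import pytest

from hajmsm import Histories, TestConfig, grid_test, logrank_point_statistic, select_nonmarkov
from hajmsm.core import illness_death_recovery
from hajmsm.markov_tests import _logrank_components, point_test
from hajmsm.simulator import LANDMARK_GRID_EXP1, experiment_design, simulate_histories


def _hist(rows):
    frame = pd.DataFrame(rows, columns=["id", "entry", "exit", "from", "to"])
    return Histories.from_frame(frame, illness_death_recovery())


def test_single_event_hand_computation():
    """One jump, one subject at risk per group, event in group 1: X = 1."""
    hist = _hist(
        [
            (1, 0.0, 2.0, 2, 1),  # group l1={2}: in state 2 at s=0
            (1, 2.0, 10.0, 1, 0),
            (2, 0.0, 1.0, 1, 2),  # group l2={1}: enters state 2 at t=1
            (2, 1.0, 10.0, 2, 0),
        ]
    )
    x = logrank_point_statistic(hist, 0.0, (2, 1), {2}, {1}, 10.0)
    assert x == pytest.approx(1.0, abs=1e-14)


def test_balanced_groups_give_zero_statistic():
    """Identical risk/event patterns in both groups: U = 0."""
    hist = _hist(
        [
            (1, 0.0, 2.0, 2, 1),   # group 1, event at t=2
            (1, 2.0, 10.0, 1, 0),
            (2, 0.0, 0.5, 1, 2),   # group 2, same event time t=2
            (2, 0.5, 2.0, 2, 1),
            (2, 2.0, 10.0, 1, 0),
        ]
    )
    assert logrank_point_statistic(hist, 0.0, (2, 1), {2}, {1}, 10.0) == 0.0


def test_no_events_in_window_gives_zero(fx):
    assert logrank_point_statistic(fx, 4.0, (2, 1), {2}, {1}, 5.0) == 0.0


def test_disjoint_group_requirement(fx):
    with pytest.raises(ValueError, match="disjoint"):
        logrank_point_statistic(fx, 0.0, (2, 1), {1, 2}, {1}, 5.0)


def _naive_logrank(hist, s, transition, l1, l2, tau):
    """Brute-force per-subject oracle for the two-sample log-rank pieces."""
    j, k = transition
    groups = {}
    for h in hist:
        st = h.state_at(s)
        if st in l1:
            groups[h.subject_id] = 1
        elif st in l2:
            groups[h.subject_id] = 2
    times = sorted(
        {
            b
            for h in hist
            if h.subject_id in groups
            for (_, b, f, t) in h.sojourns
            if f == j and t == k and s < b <= tau
        }
    )
    U = V = 0.0
    for u in times:
        y = y1 = dn = dn1 = 0
        for h in hist:
            g = groups.get(h.subject_id)
            if g is None:
                continue
            at_risk = h.state_at(u, side="left") == j
            y += at_risk
            y1 += at_risk and g == 1
            event = any(b == u and f == j and t == k for (_, b, f, t) in h.sojourns)
            dn += event
            dn1 += event and g == 1
        U += dn1 - y1 * dn / y
        if y > 1:
            V += dn * (y1 / y) * (1 - y1 / y) * (y - dn) / (y - 1)
    return U, V


@pytest.mark.parametrize("s", [6.0, 14.0])
def test_vectorized_logrank_matches_naive_oracle(frail_hist, s):
    sub = frail_hist.subset(range(80))
    U, Vh, _, resid, _ = _logrank_components(sub, s, (2, 1), {2}, {1}, 1000.0)
    U0, V0 = _naive_logrank(sub, s, (2, 1), {2}, {1}, 1000.0)
    assert U == pytest.approx(U0, abs=1e-10)
    assert Vh == pytest.approx(V0, abs=1e-10)
    # martingale residuals reconstruct the score
    assert resid.sum() == pytest.approx(U, abs=1e-10)


def test_point_test_chi2_reference(frail_hist):
    x, p = point_test(frail_hist, 9.0, (2, 1), {2}, {1}, 1000.0)
    from scipy.stats import chi2

    assert p == pytest.approx(chi2.sf(x, 1))


def test_statistic_invariant_to_time_shift_and_relabeling(frail_hist):
    x = logrank_point_statistic(frail_hist, 9.0, (2, 1), {2}, {1}, 1000.0)
    df = frail_hist.to_frame()
    df["entry"] += 7.5
    df["exit"] += 7.5
    shifted = Histories.from_frame(df, frail_hist.state_space)
    assert logrank_point_statistic(shifted, 16.5, (2, 1), {2}, {1}, 1007.5) == pytest.approx(x, rel=1e-12)
    df2 = frail_hist.to_frame()
    df2["id"] = df2["id"].map(lambda i: f"subj-{i}")
    relabeled = Histories.from_frame(df2, frail_hist.state_space)
    assert logrank_point_statistic(relabeled, 9.0, (2, 1), {2}, {1}, 1000.0) == pytest.approx(x, rel=1e-12)


def test_grid_test_max_and_determinism(frail_hist):
    cfg = TestConfig((2, 1), LANDMARK_GRID_EXP1, {2}, {1}, 1000.0, B=150, seed=99)
    res = grid_test(frail_hist, cfg)
    assert res.statistic == res.statistics.max()
    assert np.all(res.statistic >= res.statistics)
    assert 0.0 < res.p_value <= 1.0
    res2 = grid_test(frail_hist, cfg)
    assert res2.p_value == res.p_value
    assert np.array_equal(res2.null_sample, res.null_sample)


def test_single_grid_time_reduces_to_point_statistic(frail_hist):
    cfg = TestConfig((2, 1), [9.0], {2}, {1}, 1000.0, B=100, seed=5,
                     variance="hypergeometric")
    res = grid_test(frail_hist, cfg)
    x = logrank_point_statistic(frail_hist, 9.0, (2, 1), {2}, {1}, 1000.0)
    assert res.statistic == pytest.approx(x)
    assert res.statistics.tolist() == [res.statistic]


def test_robust_studentizer_is_sum_of_squared_residuals(frail_hist):
    """Default grid statistic is U^2 over the iid-subject residual variance."""
    cfg = TestConfig((2, 1), [9.0], {2}, {1}, 1000.0, B=50, seed=5)
    res = grid_test(frail_hist, cfg)
    U, _, _, resid, _ = _logrank_components(frail_hist, 9.0, (2, 1), {2}, {1}, 1000.0)
    assert res.statistic == pytest.approx(U**2 / np.sum(resid**2))


def test_all_zero_statistics_give_p_value_one(fx):
    cfg = TestConfig((2, 3), [4.5], {2}, {1}, 5.0, B=50, seed=1)
    res = grid_test(fx, cfg)
    assert res.statistic == 0.0
    assert res.p_value == 1.0
    assert not res.testable


def test_wild_multiplier_moments():
    rng = np.random.default_rng(0)
    G = rng.poisson(1.0, size=200000) - 1.0
    assert G.mean() == pytest.approx(0.0, abs=0.01)
    assert G.var() == pytest.approx(1.0, rel=0.01)


def test_select_nonmarkov_finds_the_frailty_transition():
    """With a large 2->1 frailty, the 2->1 transition is selected in most runs."""
    hits, others = 0, 0
    reps = 8
    for r in range(reps):
        hist = simulate_histories(experiment_design(1, n=1000, sigma2=2.0, seed=1000 + r))
        configs = [
            TestConfig(tr, LANDMARK_GRID_EXP1, {tr[0]}, {1 if tr[0] == 2 else 2}, 1000.0, B=200, seed=r)
            for tr in hist.state_space.sorted_transitions()
        ]
        A, results, untestable = select_nonmarkov(hist, configs)
        hits += (2, 1) in A
        others += len(A - {(2, 1)})
        assert untestable == []
    assert hits >= 7
    assert others <= reps  # Markov transitions rejected at roughly the nominal rate
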