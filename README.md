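# hajmsm

Hybrid landmark Aalen–Johansen estimation of transition probabilities in
partially non-Markov multi-state models.

## The problem

In a multi-state model `X(t)` on states `{1, …, K}`, the quantities of applied
interest are usually transition probabilities
`P_lk(s,t) = P(X(t) = k | X(s) = l)` — for instance, the probability that a
worker on sick leave at month `s` is back at work at month `t`.  The classical
**Aalen–Johansen (AJ)** estimator plugs Nelson–Aalen rate estimates into a
product integral,

    P̂(s,t) = ∏_{u ∈ (s,t]} (I + ΔΛ̂(u)),      ΔΛ̂_jk(u) = ΔN̄_jk(u) / Ȳ_j(u),

and is consistent only under the Markov assumption.  The **landmark AJ
(LMAJ)** estimator restores consistency without the Markov property by
restricting estimation to the landmark subsample `{i : X_i(s) = l}` — at the
price of a much smaller risk set, hence higher variance.

Many real processes are only *partially* non-Markov: a subset `A ⊆ E` of
transitions violates the Markov condition while the rest satisfy it.  The
**hybrid (HAJ)** estimator exploits this: it uses landmark rates for the
transitions in `A` and full-sample rates for all others,

    Λ̂ʰ_jk = Λ̂_jk      if (j,k) ∉ A,
    Λ̂ʰ_jk = Λ̂ᴸᴹ_jk    if (j,k) ∈ A,

then product-integrates as usual.  `A = ∅` recovers AJ, `A = E` recovers LMAJ;
in between the HAJ trades a little bias for a substantial variance reduction
relative to LMAJ.  The set `A` is selected by transition-specific two-sample
log-rank tests comparing intensities between disjoint landmark groups, either
at one landmark time (*point test*) or maximized over a grid of landmark times
(*grid test*), with the grid test's null distribution approximated by a wild
bootstrap with standardized compensated-Poisson multipliers.

The package provides all three estimators, the Markov tests and non-Markov
selection, nonparametric bootstrap variance/percentile intervals, a
Greenwood-type plug-in variance, a frailty-driven simulator of the
illness-death-with-recovery model whose transition intensities are
`λ_jk = V_jk α_jk` with subject-level random frailties `V_jk`, and evaluation
metrics (MRSE, pointwise bias/variance, interval coverage).  See
`docs/methods.md` for the modelling details and numerical conventions.

## Worked example

Simulate 1000 subjects from the illness-death model with recovery
(states 1 = employed, 2 = sick leave, 3 = disabled; baseline rates
`α = (0.12, 0.03, 0.15, 0.1)`) with a gamma frailty of variance 2 on the
recovery transition 2→1 — so exactly that transition is non-Markov — then
select `A` with grid tests and compare the three estimators:

```python
from hajmsm import (aj_estimate, lmaj_estimate, haj_estimate,
                    select_nonmarkov, TestConfig)
from hajmsm.simulator import (LANDMARK_GRID_EXP1, experiment_design,
                              simulate_histories)

hist = simulate_histories(experiment_design(1, n=1000, sigma2=2.0, seed=7))
configs = [
    TestConfig(tr, LANDMARK_GRID_EXP1, {tr[0]}, {1 if tr[0] == 2 else 2},
               tau=1000.0, B=500, seed=i)
    for i, tr in enumerate(hist.state_space.sorted_transitions())
]
A, results, untestable = select_nonmarkov(hist, configs)
print("non-Markov set A:", sorted(A))
for tr, res in sorted(results.items()):
    print(f"  {tr[0]}->{tr[1]}: max statistic {res.statistic:6.2f}, p = {res.p_value:.3f}")

s, l, tau = 17.0, {2}, 1000.0
for name, curve in [("AJ  ", aj_estimate(hist, s, l, tau)),
                    ("LMAJ", lmaj_estimate(hist, s, l, tau)),
                    ("HAJ ", haj_estimate(hist, s, l, tau, A))]:
    p = curve(40.0)
    print(f"{name} P_2k(17, 40) = ({p[0]:.3f}, {p[1]:.3f}, {p[2]:.3f})")
```

Output:

```
non-Markov set A: [(2, 1)]
  1->2: max statistic   1.33, p = 0.888
  1->3: max statistic   1.80, p = 0.798
  2->1: max statistic  26.65, p = 0.002
  2->3: max statistic   1.71, p = 0.719
AJ   P_2k(17, 40) = (0.114, 0.097, 0.789)
LMAJ P_2k(17, 40) = (0.089, 0.089, 0.821)
HAJ  P_2k(17, 40) = (0.086, 0.099, 0.815)
```

The tests single out exactly the frailty-carrying transition 2→1
(p = 0.002; the three Markov transitions are far from significance), so
`A = {(2,1)}`.  The AJ estimate of the return-to-work probability
`P_21(17, 40)` is visibly higher than the landmark-based estimates: subjects
still on sick leave at `s = 17` are frailty-selected slow recoverers, which
full-sample rates ignore.  HAJ agrees closely with LMAJ while borrowing the
full sample for the three Markov transitions, which is where its variance
advantage over LMAJ comes from.

A command-line interface mirrors the library
(`hajmsm simulate|estimate|test|bootstrap|oracle|evaluate`); run
`hajmsm --help` for the options.  Histories are exchanged as long-format CSV
with header `id,entry,exit,from,to` (`to = 0` marks end of observation), and
curves as CSV with header `time,p1,…,pK`.

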