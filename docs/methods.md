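# Methods

This note documents the statistical model, the estimators, the tests and the
numerical conventions implemented in `hajmsm`, together with the design
choices that were genuinely open and the limitations a user should know
about.

## Data model and counting processes

A subject's path is a right-continuous step function on states `1..K`, stored
as contiguous sojourn records `(entry, exit, from, to)` with `to = 0`
encoding end of observation (censoring or administrative end).  The state
*at* `t` is the state jumped into at `t`; at-risk sets use left limits
(`X(u−) = j` iff the subject occupied `j` on some `(entry, exit]` containing
`u`).  A final record with `to = k ≠ 0` means the subject occupies `k` from
then on — the natural encoding for absorbing states.  Event times are exact
reals; ties across subjects are aggregated into a single jump time with an
integer increment, and within-subject simultaneous events are excluded by the
strict `entry < exit` requirement.  Aggregation over a window `(s, τ]`
produces the at-risk counts `Ȳ_j(u−)` and transition-count increments
`ΔN̄_jk(u)` at the distinct event times, which is all the estimators consume.

Landmark membership at `(s, l)`: subjects with `X(s) ∈ l`, evaluated
right-continuously.  Subjects whose observation ended at or before `s` cannot
be observed in `l` and are excluded.  `l` may be a set of states (needed by
the two-sample tests, whose second group is typically "all other occupied
states").

## Estimators

All three estimators are product integrals
`v(t) = v(s) ∏_{u ∈ (s,t]} (I + ΔΛ̂(u))`, accumulated in increasing time
order; they differ only in the hazard increments:

* **AJ**: full-sample Nelson–Aalen increments `ΔN̄_jk/Ȳ_j` (zero when the
  risk set is empty).  The AJ curve from a landmark `(s, l)` conditions on
  `l` only through the initial vector; it is the Markov-assuming comparator.
* **LMAJ**: the same increments computed on the landmark subsample.
* **HAJ**: per-transition merge — landmark increments for transitions in the
  designated non-Markov set `A`, full-sample increments otherwise, with the
  diagonal recomputed as the negative off-diagonal row sum.

The initial vector is `e_l` for a single landmark state, and the empirical
occupancy split across `l` for a set (uniform over `l` in the degenerate
empty-landmark case, in which the curve stays constant).

Two exact algebraic identities hold on uncensored data and are enforced in
the tests to 1e−12: the LMAJ curve equals the landmark occupancy fraction
`Ȳᴸᴹ(t+)/Ȳᴸᴹ_•(s)` at every time (bookkeeping identity), and the plug-in
occupation probabilities `π̂(0)P̂(0,t)` equal the empirical occupancy
fractions.  `A = ∅` and `A = E` reproduce AJ and LMAJ bitwise; for this the
hybrid merge drops jump times whose merged increment matrix is identically
zero (they would contribute identity factors only).  The equivalent
construction that removes non-landmark subjects from the risk sets of the
transitions in `A` is implemented as an independent code path and must agree
bitwise.

Each factor `I + ΔΛ̂(u)` of the AJ/LMAJ product is a stochastic matrix, so
curve values are probability vectors; rows always sum to one.  For hybrid
hazards a row's off-diagonal sum can in principle exceed one when landmark
and full-sample events coincide at one time, which with continuous simulated
times has probability zero; values are kept unclipped internally (tolerance
1e−12 in checks) with a `clipped()` accessor for reporting.  Step curves are
right-continuous; evaluation at a non-jump time returns the value at the
largest jump time below it.

## Greenwood-type plug-in variance

The pointwise variance of a product-integral row `v(t)` is propagated jump by
jump: at each event time the running covariance is sandwiched with
`I + ΔΛ̂(u)` and, for every origin state `j`, the multinomial plug-in
covariance of that origin's increment row (binomial terms
`ΔN̄(Ȳ−ΔN̄)/Ȳ³` on the diagonal, `−p_k p_k'/Ȳ` across destinations from a
common source sample) is added, scaled by the squared occupancy `v_j(u−)²`.
This is the standard Markov plug-in recursion; applied to landmark or hybrid
hazards it ignores the extra variation induced by non-Markov rates and the
cross-covariance between full-sample and landmark increments of one row, so
the bootstrap is the recommended inferential tool.  On the 3-subject worked
fixture the recursion gives `Var(P̂_13(0,2)) = 1/8` exactly, while the exact
multinomial enumeration of the subject bootstrap gives `211/1458 ≈ 0.1447`
— a genuine small-sample (n = 3) gap; on simulated Markov data with n = 300
the two agree closely, which is the regime the plug-in is meant for.

## Markov tests and selection of A

For transition `j→k` and landmark time `s`, subjects are grouped by
`X(s) ∈ l1` versus `X(s) ∈ l2` (disjoint, so the samples are independent).
The two-sample log-rank score over the pooled groups' event times in `(s,τ]`
is `U(s) = Σ_u [ΔN¹_jk(u) − Ȳ¹_j(u) ΔN_jk(u)/Ȳ_j(u)]`.

* **Point test**: `𝔛_s = U²/V` with the hypergeometric variance `V`,
  referred to χ²(1).
* **Grid test**: `𝔛 = max_i 𝔛_{s_i}` over a landmark grid, calibrated by a
  wild bootstrap: each subject's martingale-residual contribution
  `ξ_i(s) = Σ_u (g_i − Ȳ¹/Ȳ)(ΔN_i − Y_i ΔΛ̂)` (which reconstructs
  `U = Σ_i ξ_i`) is multiplied by one standardized compensated-Poisson
  multiplier `G_i = Q_i − 1`, `Q_i ~ Poisson(1)`, per subject per replicate,
  *shared across grid times* so the joint dependence of the maximized
  statistics is preserved.  The p-value uses `(1 + #{𝔛* ≥ 𝔛})/(B + 1)`.

Studentization of the grid statistics is configurable.  The default is the
robust per-subject variance `W(s) = Σ_i ξ_i(s)²`, applied identically to the
observed and replicate scores: `W` is by construction the conditional
variance of the replicate score, so observed and null statistics live on the
same scale, and it remains valid under within-subject recurrence, which the
independent-increment log-rank variances ignore.  In a dedicated null
calibration (n = 500, B = 200, 1000 Monte-Carlo repetitions on seed streams
separate from the test suite's) the robust form had empirical size 5.2% at
the nominal 5% level versus 6.1% for hypergeometric studentization; both
options (`"hypergeometric"`, `"poisson"`) remain selectable.

`select_nonmarkov` runs one grid test per transition and collects
`A = {transitions with p < α}`.  Transitions with no two-sample information
at any grid time (an origin state never occupied in one group) are reported
as untestable and never enter `A`.  No multiple-testing adjustment is
applied; `α` is a per-transition tuning knob of the selection mechanism, with
5% as the conventional default.

## Bootstrap inference

Nonparametric bootstrap at the subject level only: each replicate resamples
`n` subjects with replacement, keeping complete histories, and recomputes the
chosen estimator.  Pointwise sample variances and percentile bounds
(percentile method, default 95%) are taken on the union of the replicate jump
times with step evaluation.  For HAJ the non-Markov set is fixed from the
original sample by default; `retest=True` reruns the selection inside every
replicate, exposing the selection uncertainty the default conditions away.
Replicates with an empty landmark set are kept as constant-`e_l` curves and
counted in `n_empty_landmark` rather than dropped, so the reported intervals
reflect the same estimator the user would have computed on such a sample.

## Simulator

The engine simulates any state space with a constant baseline rate table
`α_jk`, per-subject frailty multipliers, and truncation at `τ` (default
1000): given its frailty vector, a subject follows competing exponential
sojourns (inverse-CDF sampling from its own counter-based random stream, so
`(n, seed)` fully determine the output independent of iteration order).
Conditionally on the frailty the path is time-homogeneous Markov; marginally
it is non-Markov whenever a frailty is non-degenerate.  Censoring is not
simulated — only the administrative cut at `τ` — matching the uncensored
setting the exact identities require.

Preset: the illness-death model with recovery, baseline rates
`(α_12, α_13, α_21, α_23) = (0.12, 0.03, 0.15, 0.1)`, with two frailty
designs: (1) a single gamma frailty (mean 1, variance σ² ∈ [0, 2],
moment-matched shape = rate = 1/σ²) on the recovery transition 2→1; (2) a
joint log-normal vector `V = exp(W)` with mean one and a fixed correlated
covariance Σ across all four transitions via `Cov(W) = log(1 + Σ)`,
`E[W_j] = −Var(W_j)/2` (the mapping that makes `E[V] = 1` and `Cov(V) = Σ`
exact).  The preset Σ, taken at two-decimal precision, does not map to a
valid `Cov(W)` as printed (the (3,4) entry alone would force
`corr(W_3, W_4) < −1`), so the preset projects `log(1+Σ)` to the nearest
positive semidefinite matrix and restores the diagonal by symmetric scaling:
marginal means and variances are preserved exactly while off-diagonal
correlations shrink toward feasibility.  User-supplied matrices are rejected
with the offending eigenvalue unless repair is requested.

All subjects start in state 1 at time 0 by default (cohort entry in the
"employed" state); the initial state is configurable as a fixed state or a
distribution.  Note that with this default the landmark state 2 is sparsely
occupied at very early landmark times (e.g. `s = 1`), which inflates
landmark-estimator variance there.

**Truth oracle.**  The marginal transition probability under frailty has no
closed form; the "true" curve is the pointwise mean of the LMAJ estimator
over many fresh simulations (default 1000 × n = 1000), averaged on a fixed
grid of 200 points on `(s, s + 150]` and constant beyond — by `s + 150`
virtually all mass is absorbed (mean absorption time ≈ 19 from state 1), so
the truncation loses nothing visible.  The oracle's own Monte-Carlo error is
that of a mean of ~1000 curves and is negligible against estimator noise at
the scales used here.  With σ² = 0 the oracle agrees with the matrix
exponential `e_l exp((t−s)Q)` of the baseline generator, which the tests
check.

**Experiment driver.**  `run_experiment` repeats: simulate → grid-test all
transitions (landmark groups state 1 vs state 2, the experiment's landmark
grid, B = 500 by default) → build `A` → compute AJ/LMAJ/HAJ curves from the
requested landmark points.  Landmark grids: `{6, 9, …, 30}` for the gamma
design and `{1, 4, …, 30}` for the log-normal design.

## Evaluation metrics

MRSE is the squared L2 distance `∫_s^τ (f − g)² dt` computed as a
left-endpoint Riemann sum over the union of the two curves' jump times —
exact for step functions, no quadrature error.  Pointwise bias and variance
across replicates use the replicate mean minus the oracle and the ddof = 1
sample variance; coverage is the fraction of replicate intervals containing
the oracle per grid time.  Repetitions with empty landmark sets are included
(their curves are constant) and counted, not silently dropped.

## Problem sizes used in the checks

The packaged checks run at deliberately compact sizes chosen to keep
Monte-Carlo error well inside the asserted tolerances: exact identities on
100 random small datasets; the Markov limit and rate recovery on one
n = 20 000 simulation; null calibration of the grid test at 200 repetitions
× n = 500 × B = 200 (binomial ±3 percentage points around 5%); generator
moments from 200 000 draws; and the bias/variance ordering under σ² = 2 at
200 repetitions of n = 1000 with a 200-repetition oracle.  Re-running the
drivers at the full 1000 × 1000 scale only tightens these comparisons.

## Known limitations

* Censoring is representable and handled through risk-set exit, but all
  estimators assume independent censoring; no IPCW weighting is provided, so
  dependent censoring (which also distorts landmark selection) is out of
  scope.
* No covariate-adjusted (Cox/additive) transition rates.
* The Greenwood-type recursion is a Markov plug-in; for LMAJ/HAJ under
  non-Markov data it can understate variance — use the bootstrap.
* The grid test's power is tied to the chosen landmark grid and groups;
  untestable transitions (empty groups throughout) silently default to
  "Markov" apart from being reported.
* Interval-censored / panel-observed data are not supported; sojourn records
  must be exact.
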