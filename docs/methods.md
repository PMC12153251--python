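# Methods

## The monitoring model

All computations live on the canonical Brownian-motion scale.  For a
two-arm comparison with effect estimator `δ̂` and information
`I = 1/var(δ̂)`, the information fraction is `t = I/I_end`, the z-score is
`Z(t) = δ̂/se(δ̂)`, and the B-value is `B(t) = √t·Z(t)`.  Under standard
large-sample conditions B is a drifted Brownian motion observed at the look
times: increments `B(t₂) − B(t₁)` are independent `N(θ(t₂−t₁), t₂−t₁)`,
where the drift `θ = E[Z(1)]` is the expected final z-score.  The package
never touches patient-level likelihoods; endpoint detail enters only through
the map from an endpoint summary to a drift (`design_tools.drift_from_endpoint`):
`δ·√I_end` for continuous/binary endpoints and the log-hazard-ratio
approximations `|θ| = |ln HR|·√(D/4)` (1:1 allocation) or `√(2D/9)` (2:1)
for survival with `D` target events.  For survival settings the information
fraction is approximated by the event-count ratio `d/D`.

Sign convention everywhere: positive z favors treatment; for survival this
means `θ = −ln(HR)·√(D/4)`, so a benefit (HR < 1) has positive drift; for a
binary harm-reduction endpoint the reported effect `p_i − p_c` is negative
under benefit while the drift `(p_c − p_i)/se` is positive.

Closed forms built on this representation (all exact normal-CDF algebra,
no numerics): conditional power, the current-trend drift `b/t`, reverse
conditional power, the normal-prior predictive probability of success, and
the continuous-curtailment type II bound `β/(1−Γ)`.  Conditional power at
`t = 1` is deliberately an error rather than 0/1: the final analysis is a
comparison of `Z(1)` with `z_crit`, and silently dividing by `√(1−t)` = 0
would hide caller bugs.

## First-crossing probabilities

`gs_engine.crossing_probabilities` uses the classical recursive numerical
integration for group-sequential designs.  The sub-density of
not-yet-stopped paths is represented by its values at Gauss-Legendre nodes
on the continuation interval (B-value scale) and propagated look-to-look
through the normal increment kernel; first-crossing probabilities below the
lower and above the upper boundary are integrals of that sub-density against
normal tail probabilities.

Numerical choices:

- 301 Gauss-Legendre nodes per look interval, integration ranges truncated
  at ±8 standard deviations of the reachable support intersected with the
  continuation interval.  Boundary values are invariant to raising the node
  count to 1001 at the 1e-6 level, far inside any reporting precision.
- Boundaries are stated and solved on the z-score scale (the field's
  convention) but propagated on the B scale, where the Markov kernel is a
  plain normal density.
- Root finding (boundary values, calibrated drift) uses Brent's method with
  1e-12 tolerance on boundaries and 1e-8 on the drift; everything is
  deterministic.
- `±inf` boundaries are sentinels for "no boundary on that side"; a
  zero spending increment yields an infinite boundary at that look.

Efficacy (upper) boundaries from alpha spending are derived under the null
drift **ignoring** any futility boundary — the non-binding convention.
Recovering the type I error "lost" to futility stopping would control alpha
only if the futility guideline were strictly followed, which futility
guidelines never are; non-binding derivation is also what reproduces the
standard published O'Brien-Fleming-like boundary values.  Futility (lower)
boundaries are then derived **respecting** the upper boundaries: a type II
error requires crossing the lower boundary without a prior efficacy
crossing.

## Beta-spending boundary and drift calibration

For a spending function `β*(t)` with total `β`, candidate drift θ, and given
upper boundaries: lower boundaries `l₁..l_{k−1}` are solved sequentially so
the first-lower-crossing probability at look j equals
`β*(t_j) − β*(t_{j−1})`; the final lower boundary is pinned to the final
upper boundary (`l_k = u_k`) so the last analysis has an unambiguous
verdict.  The total type II error — interim lower crossings plus failing the
final test with no prior efficacy stop — is strictly decreasing in θ, and θ
is found by root bracketing so the total equals β.  The calibrated drift
always exceeds the no-monitoring drift for the same β: its squared ratio is
the sample-size inflation the futility plan costs.

Infeasible spending (an increment exceeding the probability mass still in
play) raises a dedicated error; a solved lower boundary exceeding the upper
boundary is clamped to it and reported, signalling overly aggressive
spending.  The Hwang-Shih-DeCani family at γ = 0 is defined by its analytic
limit, linear spending `β·t`.

Reproduction precision: the solver, converged in node count, agrees with the
standard published 4-look boundary/drift values within 1.5 units in the 4th
decimal.  Re-solving the lower boundaries with the drift fixed at the
published values reproduces those tables' boundary entries exactly to
4 decimals, so the residual is attributable to the finite grid search used
to produce the reference values ("search over a grid of values of the drift
parameter"), not to this integration.  Tests therefore assert 4-decimal
agreement with a one-to-one-and-a-half-ulp allowance.

## Operating characteristics of futility rules

A curtailment rule is converted per interim look to the largest z-score at
which it triggers (closed-form inversions; stopping uses ≤, so boundary
equality stops).  "K looks" means K total analyses at `t = j/K` including
the final one, with futility assessed at the K − 1 interims — the reading
forced by the single-look column of the operating-characteristic tables
equalling β exactly.  Type II error is then a first-crossing computation
under the design drift with the final lower boundary at `z_crit` and, by
default, no interim efficacy boundary (pure futility monitoring; finite
upper bounds can be supplied for combined designs).

## Predicted intervals

Binary endpoint: future events are Binomial(N − n, π) per arm under the
stated assumption (null, alternative, observed trend), pooled with observed
events, and the Wald interval for the difference of proportions at the full
target size is computed.  Survival endpoint: instead of simulating event
times, the final statistic is drawn directly from
`B(1) = b + θ(1−t) + N(0, √(1−t))` and the z-scale interval `B(1) ± z_{α/2}`
is back-transformed to hazard ratios through the allocation-specific drift
relation.  This deliberately avoids assumptions about the event-time
distribution and censoring pattern; it inherits the B-value approximation's
large-sample character.

The predicted interval plot runs M replicates (default 500; the acceptance
checks use 10⁴) and brightness-codes them.  Percentile grouping uses four
central shells at the 50/80/95/100 percentiles of distance from the median
estimate, with the innermost shell brightest and the replicate closest to
the median as the summary row; the band count is a presentation choice the
underlying procedure leaves open.  CPDF grouping ranks replicates by
Gaussian-kernel density height (Silverman bandwidth — the reference-rule
choice, as the procedure specifies only "kernel density estimation"), with
the mode replicate as the summary.  Given a seed, replicates, groups and
summaries are fully deterministic.

A printed-reference caveat: the published half-information worked example
lists an observed estimate of −0.059 alongside event counts (123/606 vs
90/606) that give −0.0545.  All four printed rows are midpoints of their own
symmetric intervals, so the tabulated interval machinery is internally
consistent and the discrepancy lies in the stated counts; the observed row
is therefore validated on its width (0.085), which the counts do reproduce.
The published predicted-interval medians come from an M = 500 simulation
with unstated seed, so median comparisons use combined Monte-Carlo error
(reference at M = 500, ours at M = 10⁴) plus printing precision.

## Inefficacy monitoring and other design tools

The single-look rule at half the target events (stop the discussion if more
deaths on treatment than control, z < 0) and the inefficacy strategies that
start monitoring at `t₀ = (z_{0.025}/(z_{α/2}+z_β))²` are implemented as
stated: strategy 1 stops on any wrong-way z after t₀; strategy 2 stops when
the nominal 95% CI for the drift, `z/√t ± z_{0.025}/√t`, lies entirely below
the design drift (at t₀ this coincides exactly with z < 0 — the numerator of
t₀ uses the exact 97.5% quantile rather than its 1.96 rounding so the
tangency is exact).  Strategy 3's "sliding scale that makes late stopping
more difficult" is under-specified in the literature; here the CI must clear
the design drift by a margin growing linearly from zero at t₀ to one full
interval half-width at t = 1.  This is one documented reading, recorded in
the decision output, not a canonical definition.

## The simulator and what passing tests show

`simulate.simulate_paths` draws B-value increments directly from their
defining normal law — it is a Monte-Carlo restatement of the model, not an
independent data-generating process.  Agreement between the integration
engine and the simulator (within 3 Monte-Carlo standard errors at 2×10⁵
paths, the scale at which the checks run in seconds) validates the numerics
of both, and the binomial trial generator exercises the predicted-interval
machinery end to end.  None of this tests the adequacy of the Brownian
approximation for a given real endpoint: small trials, non-proportional
hazards, information fractions estimated with error, or staggered-entry
survival data can all make `Z(t)` deviate from the idealized joint normal
law, and the operating characteristics computed here are exact only for
that law.

## Known limitations

- Everything is on the canonical normal scale; no exact binomial or
  survival-specific group-sequential computations.
- No inference-after-stopping machinery (repeated confidence intervals,
  stage-wise ordering).
- Predicted intervals are implemented for binary endpoints and the
  survival B-value approximation; continuous endpoints follow the same
  pattern but are not wired up.
- Type I error of futility rules (which futility monitoring can only
  decrease) is not reported.
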