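# futilitykit

Futility monitoring for group-sequential clinical trials.

A data monitoring committee looking at interim results of a randomized trial
faces two questions: *is a null result likely?* and *would a null result
still be meaningful?*  `futilitykit` implements the standard quantitative
toolkit for the first question — conditional power, reverse conditional
power, predictive probability of success, stochastic-curtailment operating
characteristics, beta-spending futility boundaries — and the revised-power
calculation for the second, together with predicted interval plots for an
estimation-side view.  It is aimed at trial statisticians preparing interim
reports and at methodologists studying the operating characteristics of
futility guidelines.

## The model

Interim test statistics are monitored on the Brownian-motion **B-value**
scale.  At information fraction `t = I / I_end` (sample-size ratio for
continuous/binary endpoints, event-count ratio for survival), the z-score
`Z(t)` and the B-value `B(t) = √t·Z(t)` satisfy

- `B(t) ~ N(θt, t)` with independent increments,
- `Z(t) ~ N(θ√t, 1)`, `cov(Z(t₁), Z(t₂)) = √(t₁/t₂)`,

where the **drift parameter** `θ = E[Z(1)]` is the expected final z-score
(`θ = z_α + z_power`; e.g. 3.24 for 90% power at one-sided α = 0.025).
Positive z-scores favor treatment.  On this scale:

- **Conditional power**  `CP = Φ((b + θ(1−t) − z_α)/√(1−t))` — probability
  of final significance given the interim data, under a drift assumption
  (design hypothesis, current trend `b/t`, or anything in between).
- **Reverse conditional power**
  `RCP = Φ((z√t − z_α·t)/√(t(1−t)))` — probability, given a barely
  significant final result, of interim data at least this disappointing;
  it needs no treatment-effect assumption at all.
- **Predictive probability of success** — conditional power averaged over
  the posterior of θ under a normal prior.
- **Beta-spending boundaries** — lower z-boundaries placed so the cumulative
  type II error spent by each look follows a chosen spending function
  (O'Brien-Fleming-like or Hwang-Shih-DeCani γ family), with the drift
  calibrated so the total type II error hits its nominal value.

First-crossing probabilities through arbitrary boundaries are computed by
the classical recursive Gauss-Legendre integration over the B-value Markov
chain, and every such number is cross-checked against a Monte-Carlo path
simulator in the test suite.

## Worked example

An 85%-power trial (one-sided α = 0.025) reaches its halfway interim
analysis with z = 0.3:

```
$ futilitykit cp --t 0.5 --z 0.3 --power 0.85
{
  "conditional_power": 0.3620311958414828,
  "theta": 2.996397374033844,
  "assumption": "original_hypothesis",
  ...
}
$ futilitykit cp --t 0.5 --z 0.3 --current-trend
{
  "conditional_power": 0.0149350872628252,
  "theta": 0.4242640687119285,
  ...
}
```

Under the originally hypothesized effect the trial still has 36% conditional
power — no cause for alarm — but under the (noisy) current trend only ~1%.
The gap is why curtailment on the current trend loses so much power: with
six equally spaced looks and a 0.20 threshold, the type II error of a
90%-power trial inflates from 0.10 to 0.306, whereas the drift-free reverse
conditional power rule at 0.025 only inflates it to 0.112:

```python
from futilitykit import table_sweep
print(table_sweep("cp_current_trend", 0.20, [0.80, 0.85, 0.90], range(1, 7)).round(3))
# looks     1      2      3      4      5      6
# power
# 0.80   0.20  0.259  0.312  0.356  0.392  0.422
# 0.85   0.15  0.204  0.256  0.300  0.337  0.368
# 0.90   0.10  0.147  0.196  0.238  0.275  0.306
```

Futility boundaries from beta spending, with the drift calibrated to keep
total type II error at 0.15:

```
$ futilitykit boundaries --looks 4 --beta 0.15 --gamma -4
{
  "drift": 3.0572689709685985,
  ...
  "table": [
    {"look": 1, "t": 0.25, "lower_z": -1.0606492601801003, "upper_z": 4.332633646049566, ...},
    ...
  ]
}
```

Conservative spending (γ = −4) needs a drift of 3.057, barely above the
3.00 required with no monitoring; aggressive spending (γ = +2) pushes it to
3.535, a (3.535/3.057)² ≈ 1.34-fold larger sample size.

Predicted interval plot for a binary-endpoint trial at half information
(1212 per arm targeted, 123 vs 90 events observed in 606 per arm), with
future data simulated under the null:

```
$ futilitykit pip --n-target 1212 --n-observed 606 --x-control 123 \
    --x-intervention 90 --pi-control 0.2 --pi-intervention 0.2 \
    --m 500 --seed 3 --plot pip.png
{
  "summary_estimate": -0.026402640264026417,
  "summary_lower": -0.057447624434061845,
  "summary_upper": 0.0046423439060090076,
  "mean_width": 0.062126699222271535,
  ...
}
```

Even if the true effect were null from here on, the predicted final interval
(width ≈ 0.062, versus 0.085 at the interim — a ~27% narrowing) sits mostly
left of zero: the data so far carry real evidence of benefit.

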