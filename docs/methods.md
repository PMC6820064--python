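# Methods

## Decision problem and model structure

The model compares two strategies for a patient whose anaphylaxis has been
treated and has fully resolved: discharge after a 1-hour symptom-free
observation, or an extended stay of 6–24 hours. A biphasic recurrence can
occur, by definition, any time after the first symptom-free hour and up to a
78-hour horizon; the only consequence modelled for catching it under
observation is (a) the episode is managed under medical care and (b) a
large assumed reduction (10- to 1000-fold) in the risk that it is fatal.
The tree is deliberately simple: costs accrue only from the scheduled
observation time, treatment costs of the biphasic event itself are excluded
in both locations (they would be incurred either way), there is no
discounting (78-hour horizon), no quality-of-life weighting, and no
background mortality.

Expected values per strategy *s*:

* `Cost(s) = hours(s) × rate`, where `rate` is the direct hourly cost
  ($286.92 at base case) plus, under the societal perspective only, indirect
  job-opportunity costs ($27.77/h).
* `P(postdischarge biphasic | s)`: 5.0% for the 1-hour arm, 2.7% for ≥6
  hours — the complements of the pooled negative predictive values 95% and
  97.3%.
* `Deaths(s) = P(postdischarge | s) × CF × r(s)`, with case fatality
  CF = 0.33% and `r = 1/fold` applied to the extended arm only.

Two ICERs follow: dollars per additional biphasic episode observed under
medical care (willingness-to-pay reference $10,000) and dollars per death
prevented (reference $10 million, the value-of-a-statistical-life
benchmark).

### The fatality algebra

The arm-level form `Deaths(ext) = p(ext) × CF × r` is a modelling choice
with a non-obvious wrinkle: a verbal reading of "risk reduction for events
identified under observation" would instead attach `r` to the *observed*
events and leave the extended arm's postdischarge events at full CF. That
reading, however, is inconsistent with the tree's own per-death outputs and
break-even relative risks (which this package reproduces to the dollar),
so the arm-level form is used throughout — including in the
microsimulation, whose aggregates are required to converge to the tree.
The divergence is documented here rather than resolved: with the available
inputs the two readings cannot both hold.

## Parameters

| input | base case | sampled range | units |
|---|---|---|---|
| direct cost of observation | 286.92 | Tri(100, 286.92, 500) | $/h, 2019 USD |
| indirect (opportunity) cost | 27.77 | Tri(0, 27.77, 50) | $/h (societal only) |
| extended observation time | 6 | Tri(6, 6, 24) | h |
| short observation time | 1 | fixed | h |
| postdischarge risk, 1-h arm | 0.05 | Tri(0.01, 0.05, 0.05) | probability |
| postdischarge risk, ≥6-h arm | 0.027 | Tri(0.01, 0.027, 0.027) | probability |
| case fatality | 0.0033 | Tri(0.0025, 0.0033, 0.0033) | probability |
| fatality risk reduction | 10-fold | scenario: 10–1000-fold | — |

The extended-arm risk is specified on the risk scale (range 1%–2.7%) rather
than the NPV scale (97.3%–99%); the config loader accepts either convention
(`postdischarge_biphasic_prob` or `npv`) per strategy. The fold reduction
is a scenario parameter, not a sampled quantity. Currency is handled as
plain floating point in 2019 USD; rounding (cents for costs, one decimal
for percentages, whole dollars for ICERs) is applied exactly once, in the
reporting layer.

## Deterministic sensitivity analysis

One-way sweeps re-run the cohort tree over a grid of a single input. The
three break-even thresholds have closed forms obtained by inverting the
ICER:

* risk: `p* = p(ext) + ΔCost / WTP` (above ⇒ extending is cost-effective);
* hourly cost: `c* = WTP × Δp / extra hours` (below), computed on the
  direct-cost scale by default so the printed value excludes indirect costs;
* relative risk of death:
  `r* = (p(short)·CF − ΔCost/WTP_death) / (p(ext)·CF)` (below), capped at 1
  and reported unattainable when nonpositive.

Every closed form is cross-checked by an independent bisection
(`solve_threshold_numeric`, Brent's method, parameter-scale tolerance
1e-12) of the corresponding one-dimensional ICER curve; the package's own
tests require agreement to 1e-9. Tornado rows evaluate the ICER at both
ends of each input's sampled range with all others at base case, sorted by
span with an alphabetical tie-break so output order is deterministic.

## Probabilistic sensitivity analysis

Each iteration draws all six inputs independently by inverse-CDF transform
of a single seeded `numpy` Generator stream, in a fixed documented column
order (direct, indirect, extended hours, p_short, p_extended, case
fatality). The indirect draw is consumed under both perspectives so a seed
yields identical sampled columns either way. Two conventions matter:

* **Ratio of means, not mean of ratios.** The reported ICER is
  `mean(ΔCost) / mean(Δeffect)`. Per-iteration ratios have no finite
  moments when the effect difference can approach zero, and the ratio of
  means is the estimator consistent with the cohort ICER.
* **Independent arms.** `p_short` and `p_extended` are drawn without an
  ordering constraint; draws with `p_ext > p_short` (possible since the
  supports overlap at 1%–2.7%) are retained. The published per-arm
  means/SDs are the unconstrained triangular moments, which fixes this
  convention.

Default sizes mirror the two stages of the analysis: 10,000 iterations for
summary statistics and 1,000 for the acceptability curve. At WTP $10,000
the acceptability of extended observation is exactly zero — provably, not
just empirically: the largest possible incremental benefit is
$10,000 × (0.05 − 0.01) = $400 while the smallest possible incremental cost
is 5 h × $100/h = $500.

An alternate-distribution variant replaces triangulars with beta
(probabilities, fatality) and gamma (costs) draws, moment-matched with the
mean at the cohort base-case value and the variance equal to the
corresponding triangular's, with the extended stay fixed at 6 or 24 hours.
The source analysis does not state its beta/gamma parameters, so only this
mean-matched reconstruction is defensible; because ratio-of-means ICERs
depend on the means alone, its results sit within a few percent of the
cohort values and of the published alternate-distribution figures, and the
package's checks hold them to a loose 10% stochastic tolerance.

## Microsimulation (synthetic patients)

The generator realises the cohort model at the individual level. Event
times follow a three-part mixture on the 78-hour horizon: no event
(probability 1 − p_total); an early event uniform on (1, 6] hours
(probability p_total − p_late); a late event uniform on (6, 78] hours
(probability p_late). The two masses are the only constraints the evidence
supplies — exceedance 5.0% at the 1-hour mark and 2.7% at the 6-hour mark —
and the uniform pieces deliberately add no hazard shape beyond them
(a piecewise-exponential law was rejected as implying unobserved
structure). Consequences:

* No events occur in the first symptom-free hour, matching the definition
  of a biphasic reaction; both arms observe nothing in (0, 1].
* For discharge times strictly between 1 and 6 hours the mixture implies
  intermediate postdischarge risks. The deterministic 4-hour scenario does
  **not** use them — it reuses the extended arm's 2.7% (there are no data
  on risk reduction between 1 and 5 hours) — and this divergence is a
  documented convenience, not an empirical claim.
* An event at exactly the discharge time counts as observed.

Deaths mirror the tree (arm-level fatality, postdischarge events only);
costs depend only on scheduled duration. `oracle_check` simulates both arms
(the per-arm seeds are derived from one integer), tabulates postdischarge
and death rates, mean costs and the Monte Carlo ICER against the cohort
closed forms, and flags each at a 3-standard-error criterion; the test
suite runs it at n = 10⁶ patients per arm (a few seconds, vectorised), a
size at which 3 SE of the rate estimates is ≈ 0.07 percentage points.

### What the generator does and does not emulate

It reproduces exactly the probabilistic structure the cohort model assumes:
calibrated discharge-time-conditional event probabilities, Bernoulli
fatality, deterministic costs. It does not model protracted or refractory
anaphylaxis, re-exposure events, treatment costs or duration-extending
consequences of an observed event, patient heterogeneity, or any event
dynamics beyond 78 hours. Passing oracle tests therefore demonstrate
internal consistency of the implementation — that the tree's closed forms
are the correct expectations of the stated patient-level process — not
external validity of the 5.0%/2.7%/0.33% inputs themselves.

## Numerical choices and degenerate inputs

* Triangular sampling uses the two-branch inverse CDF; the three pinned
  quantiles (u = 0, u = (mode−min)/(max−min), u = 1) are tested exactly.
  Edge-degenerate shapes (mode at an endpoint) are first-class; the fully
  degenerate point mass min = mode = max is admitted so that a
  probabilistic run collapses onto the cohort analysis exactly, which the
  tests exploit as an algebraic identity check.
* Zero incremental effect (or non-positive averted deaths) yields a NaN
  ICER plus an explicit dominance label (`extended_dominant`,
  `extended_dominated`, `equivalent`) instead of a signed ratio.
* Thresholds are reported at full precision together with the printed
  granularity (whole percent, dollars); ICER tables round to the nearest
  dollar only at rendering.
* Per-death cohort ratios are checked against their published values within
  $100 (≤0.001% relative), absorbing sub-dollar rounding upstream of the
  published figures; all other cohort quantities are exact to the printed
  precision.

## Problem sizes

Defaults used throughout the package and its tests: 10,000 PSA iterations,
1,000 acceptability-curve simulations, 10⁶ microsimulated patients per arm
for oracle comparisons (3 SE below one part in a thousand of the rate
scale), and 10⁵-sample checks of the sampler's moments. All run in seconds
on one CPU.

## Known limitations

The package reproduces a stylised model: two discharge times, cohort-level
probabilities, no cost of the biphasic event itself, a fatality reduction
entered as a scenario assumption rather than an estimate, and inputs from a
single meta-analysis of observational studies. The 17%/$46/24% break-even
results inherit all of those assumptions. The alternate-distribution
comparison is necessarily approximate (unstated source parameterisation),
and values read off the source's figures are out of scope entirely.
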