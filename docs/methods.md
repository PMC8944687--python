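# Methods

## The discrete Gompertz disposal model

A herd registration table gives cohort counts `N_t` at consecutive
lactation numbers `t = 1, 2, …` (the "transverse" reading: successive
lactation groups in one herd stand in for a birth cohort followed through
time, valid when herd renewal is stationary). The per-lactation relative
disposal rate

    y_t = (N_t − N_{t+1}) / N_t

pools culling for all involuntary reasons with death, and is modelled as a
discrete-time Gompertz hazard `y(t) = B·e^{ct}`: `c` is the aging rate,
`B` the baseline level at `t = 0`. Cows offer few age points (rarely more
than ~11 lactations), so a two-parameter law is the deliberate ceiling of
model complexity: Gompertz–Makeham, logistic or Weibull hazards and
continuous-time maximum-likelihood survival fitting are out of scope, and
the estimator is unweighted OLS of `ln y_t` on `t` — the estimate a
spreadsheet exponential trendline produces, chosen so that the method
remains reproducible by livestock specialists without statistical
tooling. The default fit window drops points with `y_t ≥ 1` or `y_t ≤ 0`
(outside the log domain) and trailing points where the destination count
has fallen below one cow.

Exits are taken positive (`ΔN_t = N_t − N_{t+1} ≥ 0`); the exit fraction
`Δn_t = ΔN_t / N_1` satisfies `Σ Δn_t + remnant = 1` exactly.

## Integration conventions (and why "destination" is the default)

To forecast a cohort the recursion multiplies the current count by a
retention factor. Two indexings are possible for which hazard drives the
transition `t → t+1`:

- **destination** (default): `N_{t+1} = N_t · (1 − y(t+1))`
- **origin**: `N_{t+1} = N_t · (1 − y(t))`

Published worked integrations of the Tosnensky life table are reproduced
integer-for-integer (1500 → 1213 → 899 → … → 10) only by the destination
convention; the origin convention gives 1500 → 1134 at the first step. The
package therefore defaults to destination and keeps origin behind a flag,
and the test suite contains the discriminating comparison.

The choice has one subtle consequence: the observed rate labelled `t`
(origin labelling, as in registration tables) equals the *generating*
hazard at `t + 1`. A log-linear fit on origin labels recovers `c` exactly
but its `exp(intercept)` estimates `B·e^c` rather than `B`. Mixture
results therefore expose both `B = exp(intercept)` (which matches the
published mixture-level baselines) and the destination-referred baseline
`exp(intercept − c)` (which recovers the generating `B` exactly for a
homogeneous population). Stop rules: integration ends at the horizon
(default 20 lactations), when the driving hazard reaches 1, or when the
next count would fall below one cow; counts stay real-valued internally
and are rounded half-away-from-zero for display only.

`T = Σ Δn_t · t` counts observed exits only; the remnant fraction is
reported alongside rather than folded in (for the Tosnensky table the two
readings give 3.46 and 3.52, both printing as 3.5).

## Heterogeneity and the Strehler–Mildvan artifact

A model population is a finite mixture of Gompertz subcohorts `(B_j, c_j,
N1_j)`; each is integrated independently (destination convention,
real-valued, deliberately *not* floored at one cow — flooring subcohorts
distorts the pooled hazard; the one-cow stop applies to the pooled series
only), then summed per lactation. Subcohorts are summed in a canonical
order so permuting the specification leaves results bit-identical.
Continuous frailty distributions are out of scope; finite mixtures are the
object of study.

Refitting the Gompertz law to the pooled disposal series over a fixed
window (default lactations 1–8, a parameter — the window covers the range
where herd tables retain meaningful counts) yields *apparent* parameters.
For mixtures sharing `c` with unequal `B`, apparent `c` is strictly below
the true `c` (frail subcohorts deplete first and flatten the pooled
hazard), and across a family of increasingly heterogeneous populations
apparent `B` rises while apparent `c` falls — a negative correlation of
exactly the Strehler–Mildvan shape, generated with no underlying
parameter trade-off. The four built-in reference populations (common
`c = 0.15`, baselines 0.10 | 0.15/0.09 | 0.22/0.15/0.10 | 0.26/0.20/0.11)
reproduce the published apparent aging rates 0.15, 0.13, 0.11, ~0.085 at
two decimals under this window.

## Unbinning composition tables

Age-composition reports pool older lactations (scheme 1, 2, 3, 4–5, 6–7,
8–9, 10+). Reconstruction of per-lactation counts proceeds by constrained
trend projection: (i) the three leading single-lactation bins anchor an
initial log-linear hazard fit; (ii) the fitted hazard defines a relative
depletion trajectory; (iii) each pooled bin is split proportionally to
that trajectory (bin sums preserved exactly, splits strictly decreasing);
(iv) the hazard is refitted to the full reconstructed series and the
scheme iterates until split fractions move by less than 1e−6 (cap 100
iterations, warning on non-convergence). The open-ended 10+ bin is closed
at two lactations by default (configurable). When the binned data are
exactly Gompertz-generated the proportional split is a fixed point of the
iteration and recovery is exact to machine precision; the acceptance-level
requirement is property-based — exact bin-sum conservation, strict
monotonicity, and ≤ 2 % per-lactation error on synthetic round trips — not
reproduction of any particular published split, because the published
tables are internally inconsistent at the 4–5 bin (the pooled mean 4483
versus 2637 + 1716 = 4353 in the worked life table; likewise the printed
mean percentage 21.7 versus the arithmetic mean 21.4 of its own rows).
No correction is made for herd growth between years.

## Milk-yield degradation

Group-mean 305-d yields across lactations follow

    y_m(t) = A · exp(−exp(−b·t)) · D^t

with potential yield `A` (kg), maturation rate `b` (per lactation, prior
range 0.4–0.5), and degradation base `D ∈ (0, 1]`. The estimator divides
out the maturation factor with an assumed `b` (default 0.45, the midpoint
of the prior range), fits `ln` of the corrected yields on `t` over
lactations 4–10, and reads `D = exp(slope)`, `A = exp(intercept)` — the
back-extrapolation to first lactation is then literally `D¹ = D`. Under
the model with matching `b` this is exactly unbiased. Mis-specifying `b`
anywhere in [0.4, 0.5] against the assumed 0.45 biases `D` by at most
~0.0046 (worst case at `b = 0.40`; the residual maturation trend over
lactations 4–10 contributes ≤ 0.005 to the log-slope), which the property
suite bounds at 0.005. A linear-scale fit (`A·D^t` by nonlinear least
squares on the corrected yields) is provided for sensitivity analysis.
Within-lactation (daily) curve models are out of scope.

Across last-lactation groups, `D` regresses linearly on `t_max`; the
inversion `t_max = (D − intercept)/slope` turns a fitted relation (e.g.
the published `D = 0.88 + 0.008·t_max`, giving `t_max = 125·D − 110`) into
a longevity predictor.

## Synthetic data

Generators mirror the estimators' assumptions exactly:

- **Cohorts**: expected-value mode reproduces the deterministic integrator
  bit-for-bit; binomial mode draws integer exits `~ Binomial(N_t, min(1,
  rate))` per transition, with the rate indexed by the same convention as
  the integrator (destination by default, origin by flag). Empirical
  hazards converge to the specified Gompertz values as `N1` grows (checked
  at `N1 = 10⁵` within 3 standard errors).
- **Yields**: model values times `exp(ε)`, `ε ~ N(0, sd)` — multiplicative
  lognormal noise, default sd 5 % in simulation studies, matching the
  scale of group-mean yield variation.
- **Composition tables**: exact forward binning of a cohort series, the
  inverse test partner of the reconstruction.

Every stochastic call uses one `numpy` generator seeded per run; nothing
touches global state, so fixed seeds reproduce bit-identically. What the
generators deliberately do not emulate: calendar-time effects (seasonal
calving, herd growth), individual-cow event histories, and
reason-specific culling — passing tests demonstrate correctness of the
estimators under the stated model, not robustness to those features of
real registration data.

## Numerical choices and edge cases

- OLS via `scipy.stats.linregress`; a zero-variance response yields
  slope 0 with Pearson `r` reported as 0 plus a warning (flat lines are
  legitimate); zero-variance predictors raise a singular-fit error.
- Rates of exactly 0 or ≥ 1 are excluded from log-domain fits; an explicit
  window containing them raises rather than silently dropping.
- Display rounding is half-away-from-zero to whole cows; all arithmetic is
  unrounded.
- The worked-table fixtures keep the published values authoritative even
  where they disagree with recomputation in the third decimal (printed
  exits 97/57 versus count differences 98/56): the published retention
  factors are the canonical input for reproducing the published
  integration, and recomputed rates are compared to the printed rate
  column within 0.007.
- Problem sizes in tests and the acceptance script are the worked-example
  sizes themselves (cohorts of 10³–10⁵ cows, ≤ 20 lactations, 500-replicate
  simulation studies); everything is closed-form or small-matrix, so the
  full suite runs in seconds.

## Known limitations

- The transverse method assumes stationary herd renewal; trends in herd
  size or management bias the fitted parameters.
- The viability-index predictor of `T` was established on one large
  regional population; its coefficients ship as a dataset, not as a
  universal law, and small herds will show large sampling spread in
  `1/y₁`.
- Apparent-parameter values for mixtures depend on the fit window; the
  default (1–8) is a convention, and the strongest built-in mixture's
  apparent baseline is reproduced only as a range (0.19–0.24).
- The unbinning reconstruction presumes the underlying series is
  Gompertz-like; it cannot recover features the trend does not encode
  (e.g. a one-year culling shock inside a pooled bin).
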