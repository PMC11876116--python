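# Methods

## Model

The projection rests on the illness-death (three-state) model without
remission: healthy → ill with incidence *i*(*a*, *t*), healthy → dead with
*m*₀(*a*, *t*), ill → dead with *m*₁(*a*, *t*).  The age-specific prevalence
*p*(*a*, *t*) of the ill state satisfies

    (∂t + ∂a) p = (1 − p) [ i − p (m₁ − m₀) ].

Since *m*₀ is not observed in routine data, the implementation never
materialises *m*₀ or *m*₁: the excess-mortality term is always evaluated
through the algebraically equivalent substitution
p (MRR − 1) m / (p (MRR − 1) + 1), where *m* is the general-population
mortality and MRR = *m*₁/*m*₀.  (Only the validation oracle inverts the
identity, recovering *m*₀ = *m* / (p (MRR − 1) + 1) from the same inputs.)

Assumptions inherited from the model: no remission, no migration, no
distinction between diagnosed and undiagnosed disease beyond what the input
rates encode, and deterministic dynamics (no parameter uncertainty is
propagated; the upstream study reports none).

## Numerical integration

Along a characteristic (*a*₀ + *s*, *t*₀ + *s*) the PDE is an ODE in *s*,
integrated with classical 4th-order Runge–Kutta.  Default step 0.1 years;
the right-hand side is smooth and cheap, and RK4 at this step is at the
rounding floor for the constant-coefficient closed form
p(s) = 1 − (1 − p₀)e^(−is) (measured error ≈ 4 × 10⁻¹⁴ over 30 years).
Prevalence is clipped to [0, 1] after every stage and step, which guards
against overshoot at coarse steps without affecting converged runs.

The projection grid is 18–100 years of age and base-year–horizon in
calendar time, both in unit steps (defaults 2010–2040).  Because grid
spacing is one year in both directions, every grid node lies exactly on a
characteristic launched from the base-year column or from the minimum-age
boundary; the surface is filled by advancing the whole base column
diagonally (one RK4 sub-year at a time), which avoids any cross-diagonal
resampling.  Rates between grid nodes are evaluated by bilinear
interpolation; outside the grid hull coordinates clamp to the nearest edge,
so cohorts older than the top age node reuse the top-node rates.

Boundary conditions: the base-year column is the supplied starting
prevalence; cohorts entering at the minimum adult age carry the base-year
minimum-age prevalence (near zero for adult-onset disease).  Results at the
horizon are insensitive to this choice because entering cohorts accumulate
their own incidence history almost immediately.

The MRR enters as a schedule: a piecewise-linear base profile in age times
an annual factor (default 0.98 per year, i.e. a 2 %/year decline in the rate
ratio), floored at 1.0.  The floor expresses that the disease is never
protective; without it the geometric decline would eventually push the
ratio below 1.

## Incidence trend model

Grouped estimates (sex × age group × year) are mapped to continuous age at
the arithmetic group midpoints; the open-ended top group (80+) is assigned a
representative age of 85.  The regression is OLS of log rate on the tensor
product of a natural cubic spline in age (4 knots: boundary at the extreme
midpoints, interior at the midpoint terciles), a natural cubic spline in
calendar year (3 knots: boundary 2015/2021, interior at the median year) and
sex, including all interactions up to the three-way product — 24 columns for
the default 70 observations.  The spline bases come from patsy's `cr`
(natural cubic regression splines); the factorial expansion is assembled
explicitly because formula algebra does not produce a full-rank factorial
for multi-column numeric factors.  Natural splines are linear beyond their
boundary knots on the log scale, so extrapolation beyond the last observed
year continues the boundary slope log-linearly — this is what the trend
scenarios extrapolate.  The fit is unweighted: the published estimates carry
no usable uncertainty information.

Fitted models serialise to a plain-text document (knots plus named
coefficients) that reproduces predictions bit-for-bit when reloaded.

## Scenarios

Each projection scenario maps calendar year *y* to an effective prediction
year clip(*y*, 2015, trend_end_year): years before the first fitted year
reuse the first fitted year's prediction, years beyond the scenario's end
year freeze the (sex, age)-specific value of the end year.  "Constant
incidence" is the special case trend_end_year = 2021 (the last observed
year).  The "constant prevalence" counterfactual takes the projected
prevalence profile of the first reporting year — identical across the
PDE-based scenarios, which only diverge after 2021 — and holds it fixed, so
its case counts move only through the population projection.

Counts are prevalence × population per (sex, age, year); crude adult
prevalence is the population-weighted mean over ages ≥ 18; the pooled
"total" block pools counts and population over the sexes rather than
averaging the sex-specific prevalences.  Relative changes in the summary
table are computed from unrounded start/end values and rounded last (half
away from zero, integer percent; prevalence to 0.1 %, counts to 0.1
million).

## Synthetic data and what it does (not) show

The generator emulates the structure, not the values, of the study inputs:

* log incidence = α(sex) + β(sex)·s(age) + γ(sex)·(year − 2015), with s a
  logistic in age (centre 55, scale 12) rising to a plateau near age 70.
  Defaults α = −6.65 (men) / −6.85 (women), β = 3.6, γ = +1.0 %/yr (men) /
  +1.2 %/yr (women): a ~35-fold rise in incidence over the adult age span
  and a mild upward calendar trend in every stratum.
* mortality: Gompertz *m* = a·e^(0.10·age) with a 0.5 %/year improvement,
  a = 1.2 × 10⁻⁵ (men) / 0.8 × 10⁻⁵ (women).
* MRR: 3.0 below age 30 declining linearly to 1.3 at age 90, 2 %/year
  calendar decline, floor 1.
* population: Gaussian age pyramid (sd 18 years) whose mean age drifts from
  45 upward by 0.2 years per calendar year — a stylised ageing population.
* baseline prevalence: generated by the cohort oracle itself (every cohort
  simulated from age 18 at entry prevalence 0.005 under the same laws), so
  the baseline is exactly consistent with the generating rates and a correct
  projector stays on the ground-truth surface.  The magnitudes put adult
  prevalence near 10 % in 2015, a realistic regime for type 2 diabetes.

Grouped estimates are person-time-weighted means of the true rate over each
group's ages (weights from the synthetic population), with optional
log-normal noise (default sd 0.05) and an optional multiplicative 2020 dip
emulating pandemic under-ascertainment.

The oracle is an explicit-Euler recursion on healthy/ill occupancies
(default dt 0.001 years), structurally independent of the prevalence-ODE
code path; the two agree within 10⁻⁴ absolute prevalence at default steps.

What passing tests show: the integrator solves the stated model correctly
(closed forms, oracle agreement, monotonicity and range invariants), the
regression reproduces in-span data exactly and extrapolates log-linearly,
and the scenario/reporting arithmetic is internally consistent.  What they
do not show: anything about real claims data (diagnosis-code behaviour,
insurance churn, ascertainment), and the pipeline does *not* recover a
curved generating incidence law to within 1 % at every age.  The measured
end-to-end discrepancy (max ≈ 7 % per age, ≈ 1.3 % on the crude 2040
prevalence) is dominated by the grouped-data design itself: a
person-time-weighted group mean of an exponentially rising rate differs
from the rate at the group midpoint by several percent per group
(Jensen-type distortion, here partially offset by declining person-time
weights within groups), and a 4-knot spline through five midpoints cannot
remove it.  This is a property of fitting grouped published estimates, not
of the implementation, and applies equally to any study built on such
estimates.  For the same reason the Monte-Carlo mean of the fitted surface
carries a small deterministic offset (up to ≈ 2 % on the log scale) from the
generating group rates; the estimator is exactly unbiased (and tested as
such) for the projected surface on the log scale.

## Problem sizes and defaults

Default runs integrate 83 age nodes × 31 years per sex and scenario at step
0.1 (about 10⁴ RK4 stages per surface); validation uses 20 random parameter
draws for oracle agreement and 200 replicates for estimator calibration.
These sizes make the full suite and the acceptance script complete in a few
minutes on a single core while leaving all measured errors far from their
tolerances (except the grouped-data recovery limits discussed above).

## Known limitations

* No uncertainty intervals: the projection is deterministic in its inputs.
* No remission, no migration, no distinction of diagnosed vs. true
  prevalence.
* The top age group is represented by a single configurable age (85), and
  ages above the top grid node reuse top-node rates.
* Scenario freezing is per (sex, age) cell; no scenarios for mortality or
  MRR beyond the fixed annual decline are provided.
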