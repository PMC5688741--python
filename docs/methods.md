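# Methods

This note documents the statistical model behind `worklife`, the numerical
choices, what the synthetic-data generator does and does not emulate, and the
design decisions taken where more than one reading was defensible.

## The multi-state model

Labor-market affiliation is modeled as a continuous-time multi-state process
on the age scale. The default state space has five primary states — work
(W), sickness absence (S), unemployment (U), disability pension (D),
voluntary early-retirement pension (E) — plus auxiliary temporary-out (TO)
and Death states. W, S, U (and TO) are *transdurable*: they can be entered
and left repeatedly. D, E and Death are absorbing. Worklife expectancy (WLE)
counts occupancy of W, S and U. Everyone is administratively censored at the
pension age (default 65) and at the end of follow-up.

Data enter in counting-process (long) format: one row per subject-episode
with a half-open age interval `[entry, exit)`, origin state, destination
state or a censoring marker, episode-constant covariate values and an
optional weight. An event happens *at* `exit`; a subject is at risk in state
`h` at age `t` iff `entry < t <= exit`. Episodes within a subject must chain
(each episode starts in the state the previous one reached), which the
validator enforces with subject-and-row-naming errors. Time-varying
covariates are represented purely by episode splitting: a dynamic indicator
(e.g. "has had long-term sickness absence") flips no→yes at most once and is
carried forward.

Because D- and E-events are sparse relative to origin, their hazards are
estimated as **combined transitions** on the pooled {W,S,U} risk set:
`alpha_c(t) = d_c(t) / (n_W + n_S + n_U)(t)`.

## Intensities, occupation probabilities, expectancies

The nonparametric (MSLT) route sets `alpha_hj(t) = d_hj(t)/n_h(t)` at every
distinct event age; the Cox-MSLT route sets `alpha_hj(t)` to the Breslow
baseline-hazard increment of the transition times `exp(beta_hj' Z)` for the
covariate profile `Z` of interest. Either way the increments are assembled
into matrices `A(t)` with diagonal `-sum_j alpha_hj(t)` and zero absorbing
rows, stored sparsely at event ages only (the product integral changes
nowhere else).

Occupation probabilities are the Aalen–Johansen product integral
`P(s,t) = prod (I + A(u))`; each factor is row-stochastic whenever
off-diagonal row sums are at most 1, so `P` is a proper transition matrix
and Chapman–Kolmogorov holds exactly by construction. Expected state
durations integrate the piecewise-constant occupancy curve; the step-function
integral is exact for the estimator and is the primary quadrature. A
trapezium rule on a configurable grid (default: whole ages) is provided as
the conventional life-table alternative; on event-dense data the two agree
closely, and the step integral additionally satisfies occupancy conservation
(`sum_h E(h)` equals the horizon) to machine precision.

### Combined-transition redistribution

A pooled hazard must be written back into the origin rows of `A(t)`. Two
modes are provided because the redistribution is genuinely underdetermined:

* `equal` (default): each origin row receives the pooled value `d_c/n_c`
  unchanged. This is the canonical matrix form and is exactly right when the
  true hazard to the absorbing state is the same from every origin.
* `crude_frequency`: origin row `h` receives
  `(d_c/n_c) * f_h * n_c(t)/n_h(t)`, with `f_h` the whole-follow-up share of
  pooled events that originated in `h`. This preserves the total expected
  event flow `sum_h n_h(t) * entry_h(t) = d_c(t)` at every age and
  concentrates hazard where the events actually came from. With no observed
  origin events it falls back to `equal` with a warning.

## The Cox engine

One proportional-hazards model per transition,
`lambda_hj(t|Z,u_i) = u_i * lambda_hj0(t) * exp(beta_hj' Z)`, fitted by
Newton–Raphson on the weighted partial likelihood with the **Breslow** tie
convention. Breslow was chosen because it keeps the exact `d/n` identities:
with no covariates the baseline increments reduce to the Nelson–Aalen
estimator, so the covariate-free Cox-MSLT coincides with the MSLT to
machine precision (a tested identity). Convergence: relative change in
partial log-likelihood below 1e-9, at most 100 iterations with step-halving;
diverging coefficients or a singular information matrix raise a separation
error naming the transition.

Fitting each transition separately is identical to one fit on stacked
long-format data stratified by transition with transition-specific covariate
interactions — the stratified partial likelihood factorizes. Both
arrangements are exposed, and the test suite additionally cross-checks the
coefficients against an independent Cox implementation (lifelines) on both
arrangements.

Weights enter the score, the information and the Breslow denominator
(weighted Breslow), as required for inverse-propensity-weighted fits; a
constant weight cancels exactly.

**Frailty.** An optional shared per-subject gamma frailty (mean 1, variance
theta) is estimated by EM: the E-step replaces each subject's frailty by its
posterior mean `(1/theta + N_i)/(1/theta + H_i)` given the subject's event
count and accumulated hazard, the M-step refits with `log u_i` offsets, and
theta is chosen by maximizing the marginal (gamma-integrated) likelihood on
a bounded search. Frailty is off by default: it is not needed for the
headline pipelines, and population-level intensities use the frailty at its
mean of 1 regardless.

## Variance and confidence bounds

The covariance of the Aalen–Johansen estimator follows the standard
recursion: with `G_k = I + dA(t_k)` and row-major vectorization,

    V_k = (I ⊗ G_k') V_{k-1} (I ⊗ G_k')' + (P_{k-1} ⊗ I) C_k (P_{k-1} ⊗ I)',

where `C_k` is the Greenwood-type multinomial covariance of the increment
entries (within origin row `h`: variance `d(n-d)/n^3`, cross-destination
covariance `-d d'/n^3`, diagonal by linearity). In the pure-survival case
this reproduces the classical Greenwood variance of the Kaplan–Meier
estimator *exactly*, which the tests verify against the closed form; in a
three-state model the recursion variance is validated against a
nonparametric bootstrap. Cross-destination covariances within a row are
carried in full; rows are treated as independent — in `equal` combined mode
the origin rows share the pooled increment, so a small cross-row covariance
is ignored, consistent with the row-wise published recursion. Increment
covariances for combined transitions use effective counts `a_hj * n_h`,
which reduces to the exact counts for plain transitions.

Pointwise limits are plain Wald intervals on the probability scale, clipped
to [0,1] — no log-log transform, the simplest choice where none is
prescribed. WLE bounds are areas under the pointwise limits computed with
the same quadrature as the point estimate; because the pointwise limits are
dependent across ages these bounds are approximate and are labeled as such.
Only the variability of the (baseline) hazard is propagated: the sampling
variability of the Cox coefficients is deliberately not included, keeping
the two routes' uncertainty statements comparable.

## Stabilized inverse-propensity weights

To read a covariate effect marginally, per-record stabilized weights
`(p0/p(Z)) * (c0/c(Z))` combine an exposure component (conditional
probability of the observed exposure level given the adjusters, stabilized
by the marginal level probability) with a censoring component (conditional
vs marginal probability of remaining uncensored). Both are ordinary logistic
regressions on records (statsmodels GLM). Administrative censoring — at
pension age or end of follow-up — is *not* modeled, being
covariate-independent by design; with no loss to follow-up the censoring
component is exactly 1. The default adjuster set is every covariate except
the exposure. Optional percentile truncation (off by default, 0.5/99.5 when
enabled) guards small strata against extreme weights; truncated records are
flagged in the output. Under correct specification the mean stabilized
weight is close to 1, which is asserted on simulations.

Note the non-collapsibility caveat: with heterogeneous baselines the true
*marginal* hazard ratio is attenuated relative to the conditional one, so
the IPW tests benchmark the weighted fit against a randomized-exposure
simulation of the same structural model rather than against the conditional
coefficient.

## The cohort simulator

`simulate_cohort` draws register-style histories from piecewise-constant
baseline intensities with multiplicative covariate effects, optional shared
gamma frailty, covariate-dependent loss to follow-up and dynamic covariate
flips (an indicator switches on after a configurable dwell time in a trigger
state, splitting the episode at the flip age). Sojourns are sampled by exact
inversion of the piecewise-constant cumulative hazard of the summed outgoing
intensities; the destination is drawn from the relative intensities at the
event age. Output is deterministic given the seed.

For the Markov case (no frailty, fixed profile) the implied occupancy
probabilities and expectancies have closed forms: products of matrix
exponentials over the constant pieces (`scipy.linalg.expm`), with the
integral obtained from the augmented-matrix identity
`expm([[G, I], [0, 0]] dt)`, exact even for singular generators. These are
the oracles the estimators are tested against (entrywise occupancy agreement
and 2% expectancy agreement on large simulated cohorts).

The shipped `default_scenario` is **illustrative, not calibrated**: rates
are loosely shaped so the qualitative orderings seen in real register
cohorts emerge (members of the early-retirement scheme with poor self-rated
health have the lowest expected work duration; the retirement channel opens
at age 60; poor health raises entry into sickness absence, unemployment,
disability and early retirement and slows return to work). Default cohort
size is 5212 subjects aged 55–65 starting in work, with 10% poor self-rated
health. What the generator does *not* emulate: seasonal and calendar-time
effects, benefit-rule changes during follow-up, clustered employers,
measurement error in state classification, and delayed study entry
(everyone starts at the window's lower age). Passing tests therefore
demonstrate correctness of the estimators under the model's assumptions,
not fidelity of any particular rate to a real register.

Problem sizes used in the test suite and the acceptance script — 5 000
subjects for hazard-ratio recovery, 10 000 for life-table consistency,
20 000 for occupancy convergence, 200 bootstrap replicates on 500 subjects
for the variance recursion — were chosen as the smallest cohorts at which
the Monte-Carlo noise floor sits comfortably below the tolerance being
asserted. Expectancy consistency is asserted at 2% relative for states
carrying at least ~0.4 years of occupancy; the rare disability state (a few
hundred events at these sizes) has a Monte-Carlo noise floor above 2% and is
asserted within 3 Monte-Carlo standard deviations instead.

## Degenerate inputs and numerical conventions

* Ages with no events are simply absent from the intensity series; an empty
  series yields the identity occupation matrix and straight-line
  expectancies.
* An off-diagonal increment above 1 (possible only with pathological
  weights) makes a product-integral factor negative and raises an error
  rather than silently producing a non-stochastic matrix.
* A transition with no events has a zero baseline and no coefficients; a
  covariate constant within a transition's risk set is dropped from that
  transition's fit (coefficient 0, SE NaN) and recorded.
* Months are years × 12 rounded half-up.
* Tied event ages aggregate (Breslow downstream); event-age grids are exact
  float comparisons, never binned.

## Known limitations

* The Markov assumption is violated once dynamic history indicators (prior
  long-term sickness absence / unemployment) enter the model; estimates are
  then interpretable as predictions for the covariate path held fixed, and
  the simulator's exact oracles cover only the Markov case.
* WLE bounds are areas under dependent pointwise limits — approximate by
  construction.
* Cox coefficient variability is not propagated into the occupancy or
  expectancy uncertainty.
* The frailty profile-likelihood search is bounded (theta in [1e-4, 4]) and
  is the slowest path in the package; it is not run by the headline
  pipelines.
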