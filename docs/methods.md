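# Methods

## Indirect estimation of the male TFR

Male fertility is not directly observed in most vital-statistics systems,
so the package estimates it from two quantities that are: the female TFR
and the sex composition of the reproductive-age population. The model is a
pooled, unweighted OLS regression on natural logarithms,

    log TFRm = α + β₁ log TFRw + β₂ log SR + ε,

so β₁ and β₂ are elasticities. The rationale is mechanical: births are
shared between the sexes, so the male rate must track the female rate
(β₁ ≈ 1), and when the male population at risk grows relative to the
female population the same births produce a lower per-man rate (β₂ < 0).

Three model variants differ only in the age windows defining the sex ratio
SR: `baseline` 20–39/20–39, `postponement` 25–44/25–44, and `age_gap`
men 25–44 / women 20–39. The age-gap variant encodes the typical 3–5-year
seniority of fathers over mothers and is the default. All age ranges in
the package are closed and inclusive in completed years.

No fixed effects, weights, or clustered standard errors are used: the
estimator targets a single global coefficient set, and the shipped
reference coefficients (`DEFAULT_COEFFICIENTS`) come from a published
global fit of exactly this pooled specification on ~4,000 country-years.
Users with their own harmonized male-TFR compilations can refit via
`maletfr fit`; how overlapping source estimates are harmonized is left to
the user — any valid `fertility.csv` with a `tfr_male` column is accepted.

### Prediction intervals

Intervals are standard OLS prediction intervals on the log scale,
exponentiated: with x = (1, log TFRw, log SR), the prediction variance is
x'Vx + s² (parameter covariance V plus residual variance s², denominator
n − 3) and the interval uses the t distribution with n − 3 degrees of
freedom. Default level 0.90. As n grows the parameter term vanishes and
the log-scale half-width approaches z₀.₉₅·s from above. When only point
coefficients are supplied (no covariance), `predict` honestly returns the
point alone rather than fabricating an interval; published interval
endpoints are therefore not reproducible from the shipped coefficient set,
which carries no residual scale.

## Standardization

`TFR_std = Σ_{x=15}^{55} B_x / P_x^male` applies observed births by
maternal age to the male population. It answers: what would the male TFR
be if men had children at exactly the ages mothers do? Comparing with
`Σ B_x / P_x^female` (which reproduces the female TFR) isolates the pure
population-composition effect. The identical-schedule assumption is a
deliberate simplification — real male schedules are older and broader — so
`ratio_std` should be read as a bound on the composition effect, not an
alternative male-TFR estimate. Births must be by single maternal age;
`split_grouped_births` uniformly splits 5-year groups when needed. The
range 15–55 is the reproductive span conventionally used for both sexes in
this construction; it is a function argument, not a constant.

## Sex-ratio decomposition

The synthetic-cohort sex ratio at age x under year-t rates is

    SR_t(x) = 100 · (B_m/B_w) · Π_{i=0}^{x−1} p_m(i) / p_w(i).

Two conventions matter and are deliberate:

* **Product bounds.** The survivorship product runs from birth to *exact*
  age x (upper index x − 1, empty product at x = 0). This is forced by the
  radix convention: the male radix is the sex ratio at birth, so SR_t(0)
  must equal 100·B_m/B_w with no mortality applied. Including p(x) in the
  factor for age x would double-count the final interval.
* **Period interpretation.** All p(i) come from year t's life table (a
  synthetic cohort). Cohort life tables are not supported. Migration is
  excluded by construction, which is the point: the decomposition isolates
  births and mortality.

The identity `sr_total = birth_contribution × mortality_contribution` holds
to machine precision because the total is computed as that product; the
informative tests are the closed forms (constant survival gap gives
100·SRB·(p_m/p_w)^x) and the cross-module stationarity check below. The
output also carries the per-age increments p_m(x)/p_w(x) so either the
cumulative factor or its increments can be plotted. Ratios are men per 100
women by default; `scale=1` gives men per woman.

## Crossover analytics

Percent difference is 100·(TFRm − TFRw)/TFRw; the crossover year is the
first year TFRm < TFRw *strictly* (ties do not cross, parity being the
equilibrium); the "substantially lower" threshold is pct_diff < −5
strictly ("more than 5 % lower"). Country shares count current sign, not
ever-crossed status. The population-weighted share weights by total
population, all ages and sexes. A PI-aware helper flags years where the
male-TFR prediction interval straddles the female TFR, where the sign of
the gap is not distinguishable from zero.

The counterfactual decomposition of TFR-ratio change uses the model
identity log(TFRm/TFRw) = α + (β₁−1) log TFRw + β₂ log SR, splitting the
change between two states into (β₁−1)Δlog TFRw and β₂Δlog SR. In logs this
split is exact, additive, and order-independent — a deliberately simple
design chosen over stepwise counterfactuals, whose components depend on the
order in which factors are switched.

## Synthetic data generator

The generator emulates WPP-style inputs with a deterministic, migration-free
cohort-component projection. What it reproduces: single-age population
counts by sex, births by sex and maternal age, period survival
probabilities, and female TFR, all exactly consistent under the balancing
equation P(x+1, t+1) = P(x, t)·p(x, t). What it does not: migration,
marriage/union dynamics, stochastic (Poisson) counts, cohort fertility
feedbacks, and data-quality artifacts (undercounts, heaping). Passing tests
on generated data therefore demonstrate correctness of the demographic
accounting and estimators, not robustness to real-data measurement error —
in particular, the known failure mode of the regression under migration-
driven sex imbalances (e.g. Gulf-state labor migration) is out of the
generator's reach by design.

Parameter choices (defaults, set once):

* **Mortality**: female hazard h(x) = a·e^{bx} + c·e^{−dx} with Gompertz
  level a = 5·10⁻⁵ and slope b = 0.1 (female life expectancy ≈ 80),
  infant component c = 0.015, d = 1.2, and an optional young-adult Gaussian
  hump (off by default). The male hazard is 1.4× the female hazard — a
  typical modern sex gap. p(x) = exp(−h(x)).
* **Fertility schedule**: beta density over ages 15–55 parameterized by
  mean age 28 and sd 6 via method of moments, evaluated at age midpoints
  and normalized to sum to 1, scaled by the year's TFR (default 2.1). Any
  smooth unimodal schedule suffices for the estimators under test.
* **Sex ratio at birth**: 105 male per 100 female births, the center of
  the natural 103–107 range; scenario knobs allow per-year paths (ramps
  emulating sex-selective abortion) and shocks allow transient hazard
  multipliers by sex, age range, and year range (conflict, maternal
  mortality).
* **Initial population**: stationary-shape, P(x, 0) = radix·l(x) per sex
  with the male radix scaled by SRB/100, using year-0 survivorship l(x).
  Every cohort — seeded or simulated — then carries the sex ratio
  (SRB/100)·l_m(x)/l_f(x) of its birth regime, which makes the
  stationarity equivalence (period population sex ratio = synthetic-cohort
  decomposition at every age) exact from year 0 under constant rates. This
  is the package's key cross-module oracle. Note the *level* of the birth
  series is not stationary unless the rates imply replacement; only the
  sex composition is, which is what the equivalence needs.
* **Top age**: closed at 100, p(100) = 0, so cohorts are extinguished
  rather than pooled into an open interval and the balancing identity is
  exact at every emitted age.

Counts are expected values; the only stochastic component in the package is
`generate_regression_panel`, which draws log TFRw ~ Uniform(log 0.8, log 8)
and log SR ~ Normal(0, 0.15) and adds Gaussian log-scale noise to the model
surface, all from a single seeded generator for bit-reproducibility.

## Numerical and I/O conventions

All logarithms are natural. CSV is the interchange format (UTF-8, one table
kind per file, stable column order); floats are written at full repr
precision and read back with correctly-rounded parsing, so write→read
round-trips are exact. "All"-marginal birth rows must agree with single-age
sums to a relative 10⁻⁹. Validation is strict and names the offending rows
and rule; region-years that cannot be processed downstream are skipped with
an explicit report, never dropped silently. Degenerate inputs (zero female
population, births at ages with zero male population, empty holdouts,
collinear regressors) raise typed errors rather than propagating NaNs.

## Problem sizes

Default test and pipeline scales — 21–41 year scenarios of one region,
training panels of 400–4,000 observations, 100-replication Monte-Carlo
recovery checks — were chosen as the smallest sizes at which the identities
are exercised across cohort turnover and the stochastic checks have
comfortable margins (e.g. the Monte-Carlo standard error of a recovered
elasticity at n = 4,000, sd 0.05 is ~0.001–0.005, far inside the asserted
bands).

## Known limitations

* The regression transfers the female age-fertility relationship to men
  through a single global elasticity pair; populations whose sex imbalance
  is migration-driven violate its premise.
* The standardization's identical-schedule assumption understates male
  fertility where parental age gaps are large; the shifted-schedule
  refinement (using observed male fertility schedules) is not implemented.
* The decomposition is period-based; it describes the composition a regime
  implies, not the history any real cohort lived.
* The generator's stationary-shape seed means level trends in cohort size
  only appear once simulated cohorts age in; analyses of age-structure
  *levels* near the start year reflect the seed, not dynamics.
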