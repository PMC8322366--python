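# Methods

`sensormiss` quantifies *sensor non-collection* in duty-cycled
smartphone digital-phenotyping studies: data the study design expected
but that never arrived, because a phone was off, a sensor was disabled,
or the operating system suppressed collection. This note documents the
models, algorithms and numerical choices; it is the place to look
before changing a default.

## From raw timestamps to the analysis panel

**Design-expected volume.** A sensor schedule alternates an on-cycle of
`on` seconds with an off-cycle of `off` seconds. The expected number of
measurement groupings per day is the known, fixed quantity

    E = floor(86400 / (on + off)),

and the design coverage is `on / (on + off)` (for the canonical 1 min
on / 9 min off GPS design: 10%, i.e. 2.4 h of data per 24 h, E = 144).
A partial trailing cycle is not counted as an expected grouping — a
conservative choice that keeps `E` an integer and slightly lowers the
missingness denominator.

**Measurement groupings.** Raw per-measurement timestamps are segmented
into *measurement groupings*: maximal runs separated from the next run
by a gap of **at least half the off-cycle**. A gap of exactly `off/2`
starts a new grouping; duplicate timestamps never split (they are
distinct measurements delivered in the same instant). The segmentation
is a single left-to-right pass and is tested against a brute-force gap
scan on random streams.

**The participant-day panel.** Each grouping is assigned to the
calendar day (configurable timezone, default UTC) containing its
*start* time, so no grouping counts twice. For each participant, days
span the calendar day of their first event through their last, or — 
when enrollment windows are supplied — the configured window, which is
the only way a fully missing first or last day can be counted. The
response is

    y = max(0, E - observed groupings that day),

clipped at zero on the rare days a device delivers more groupings than
the design expects (clock drift, OS bursts); such days are logged.
Partial first/last days are kept as full days by default
(`drop_partial_edge_days` exists for sensitivity).

**Covariates and complete cases.** The covariate table carries phone
OS, gender, educational attainment, race/ethnicity and age. Modeling
uses dummies with reference levels Android, female, less than a 4-year
degree, and non-Hispanic White; age enters in decades, time-in-study in
weeks (`day_index / 7`), uncentered, so the exponentiated intercept is
the conditional non-collection rate at each participant's first day.
Participants missing any modeled covariate are dropped whole
(complete-case analysis, no imputation); the exclusion report lists who
and why.

## The hierarchical negative-binomial model

For participant *i* in study *j* on day *d*:

    y_ijd ~ NegBin(mu_ijd, omega)            Var(y) = mu + mu^2/omega
    log mu_ijd = log E + alpha0 + beta' x_ijd + gamma_ij + delta_j
    gamma_ij ~ Normal(0, sigma_gamma^2)
    delta_j  ~ Normal(0, sigma_delta^2)

`omega` is the inverse-overdispersion (shape): small values mean heavy
day-to-day overdispersion; `omega -> inf` recovers the Poisson.
Priors follow the diffuse defaults of mainstream Bayesian regression
software: improper flat on the coefficients, Student-t(3, 6.7, 2.5) on
the (centered) intercept — the location is configurable and may be set
to `"auto"` (median of log1p(y)) — half-Student-t(3, 0, 2.5) on both
random-effect SDs, and Gamma(0.01, 0.01) on `omega`.

Reported rate ratios are summaries of `exp(draws)` (posterior median
and central 95% interval; the posterior mean of `exp(beta)` is reported
separately as `mean_exp` because it is *not* `exp` of the mean). The
weekly time coefficient is also rendered as a percent change per week,
`(exp(beta) - 1) * 100`.

## Posterior computation

No probabilistic-programming backend is used: the joint log posterior
and its analytic gradient are implemented directly (vectorized numpy;
the `gammaln`/`digamma` likelihood pieces reduce over the distinct
values of the bounded count, so an evaluation is a handful of passes
over the panel), and sampling is a self-contained No-U-Turn sampler:
multinomial trajectory sampling, generalized U-turn criterion,
dual-averaging step size (default target acceptance 0.9) and diagonal
mass-matrix adaptation in Stan-style expanding windows. Chains start
from a jittered data-informed point (crude log rate, method-of-moments
shape).

The sampling parameterization was chosen for this model's geometry and
is an exact reparameterization of the model above:

* **Participant level, hierarchically centered.** The state holds each
  participant's total intercept `b_i ~ Normal(a_j + x_i' beta_c,
  sigma_gamma^2)`; with 30–90 observations per participant the
  likelihood pins `b_i`, and the non-centered form (a funnel between
  the standardized effects and `sigma_gamma`) mixes an order of
  magnitude worse.
* **Study level, non-centered.** `a_j = alpha0 + sigma_delta * u_j`,
  `u_j ~ Normal(0,1)`. With only six studies the `sigma_delta`
  posterior can reach its funnel near zero, where the centered form
  produces divergences or stuck chains.
* **Covariates.** Time-varying columns (the week term) stay in the
  likelihood, centered and thin-QR orthogonalized; participant-constant
  columns move into the prior regression for `b_i`, where they form a
  well-conditioned 180-point Gaussian regression instead of riding a
  ridge against 180 participant intercepts. Coefficient draws are
  mapped back to the natural scale before any reporting. The one
  model-visible consequence: the diffuse intercept prior applies to the
  centered intercept (the convention of the reference software).

Degenerate inputs: a design column with no variation in the fitted
panel (e.g. a race dummy with no members) has an improper flat-prior
posterior and is dropped with a warning; overflow states probed during
step-size search return `-inf` and read as divergences; a constant
parameter reports R-hat = +inf.

**Convergence gate.** A fit is `converged` only when every parameter's
rank-normalized split R-hat *and* rank-normalized folded split R-hat
are <= 1.01 and bulk and tail ESS reach 100 per chain. Report builders
refuse to run on an unconverged fit unless overridden. Diagnostics are
computed by arviz and cross-checked in the test suite against a direct
transcription of the rank-normalization recipe.

**Model comparison.** WAIC is computed from its defining formula
(deviance scale, pointwise variance with the `S-1` divisor), PSIS-LOO
through arviz (Pareto k > 0.7 observations are counted and reported,
not fatal), and Bayes R² per draw as

    R^2 = var_n(mu) / (var_n(mu) + mean_n(mu + mu^2/omega)),

the fitted-value variance against the modeled NB residual variance.

## The synthetic-data generator

Real duty-cycled clinical sensor logs cannot be redistributed, so
validation is simulation-based throughout. The generator emulates a
six-study cohort with the published demographic margins: 23% iOS, 33%
male, 25% with a 4-year degree or higher, race distribution
(0.579, 0.153, 0.183, 0.010, 0.075) over (non-Hispanic White,
non-Hispanic Black, Asian, American Indian/Alaska Native,
Other/Hispanic), age Normal(25.4, 10.8) years. Categorical draws are
independent Bernoulli/multinomial per participant; ages are untruncated
normals (the model uses age linearly, so support realism is
immaterial). The RNG is split hierarchically per study/participant/day:
enlarging one study never perturbs another's draws.

Counts are drawn from the hierarchical NB model itself, then **clipped
at E** — the bounded reality the unbounded NB cannot express. The clip
rate is recorded in the ground truth and surfaced in pipeline
manifests because it is the one systematic gap between generator and
model: at the published GPS/accelerometer estimates roughly 9–11% of
participant-days clip, which attenuates recovered coefficients and
random-effect SDs slightly (measured on proxy regressions: about +0.11
log units on the iOS coefficient, about one posterior SD). Recovery
tests use 3-posterior-SD bands that absorb this together with the
finite-cohort imbalance of realized random effects.

Raw event streams are realized by dropping `y` of the `E` cycles per
day uniformly at random and emitting events at 1 Hz (configurable)
within retained on-cycles; segmentation plus panel rebuilding
round-trips to the simulated counts *exactly* provided within-cycle
spacing stays below `off/2` — a property the acceptance suite checks on
random configurations. A deterministic 211-participant reference
cohort reproduces the published per-study demographic margins for
summarizer checks (its within-study joint distribution is synthetic;
only margins are faithful — it is not real data).

What passing these tests does **not** show about real data: the
generator has no battery/OS mechanism (drops are exchangeable within a
day), no autocorrelated within-participant missingness runs, no
attrition process, and covariates are drawn independently rather than
with the real cohort's study-level confounding.

## Problem sizes and defaults

Library defaults mirror the reference workflow (8 chains, 1000+1000
iterations). The built-in recovery studies and the acceptance script
use the desk-scale design of 6 studies x 30 participants x 90 days
(16,200 rows, 199 parameters) with 4 chains and 500 warmup / 750–1000
kept draws, which passes the convergence gate with min ESS in the
high hundreds and runs in about a minute per fit; the replicate
coverage harness (`sensormiss recovery`) defaults to 20 replicates at
the same scale for overnight use and is exercised at reduced scale in
the test suite.

## Known limitations

* The ceiling effect is acknowledged, recorded, and deliberately not
  modeled (a bounded-count likelihood is out of scope); estimates from
  heavily clipped regimes are mildly attenuated.
* The NB shape prior is a convention (Gamma(0.01, 0.01)), not a
  published value; it is configurable.
* Segmentation trusts device timestamps; clock jumps larger than
  `off/2` fabricate grouping boundaries.
* The sampler is single-threaded and chains run sequentially; wall
  time scales linearly in chains.
* `E` is schedule-derived and constant per sensor; studies mixing
  schedules mid-stream need per-period configs.
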