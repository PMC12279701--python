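# Methods

This note documents the model, its assumptions, the tunable parameters, the
synthetic data-generating process, and the numerical choices made where the
design was genuinely open.  Nothing here states an empirical result that the
test suite or `scripts/acceptance.py` does not itself compute.

## Model overview and assumptions

The estimand is the global full-time-equivalent (FTE) workforce required to
provide assistive products in five domains at a high level of access.  The
core assumption is **transportability of workforce productivity**: the
reference country's staff-per-person-in-need ratio, per product domain, is
taken as the requirement everywhere.  Violations (different case mixes,
organisation, task-sharing, prefabrication) are handled not by modelling but
by a deterministic ±50% productivity sensitivity band, following standard
deterministic scenario analysis in health-workforce planning.

Three further structural assumptions:

* **Regional representativeness.** The three regions' pooled workforce
  density equals the national density.  Regions are pooled (summed FTE over
  summed population) before scaling rather than averaging per-region
  densities; this keeps small regions from dominating and makes the
  estimator a single ratio `W_S = W_R · P_S / P_R`.
* **Survey validity.** The design-weighted household-survey prevalence of
  need is treated, after rounding, as an exact binomial observation.  Design
  effects on the interval width are ignored (a conservative exact interval
  compensates in part); this is a known limitation.
* **Prevalence model.** On the fourth-root scale the prevalence of need is
  linear in median age and the Human Development Index with domain-specific
  slopes, exchangeable domain intercepts and Gaussian residuals.  The
  fourth root maps the strongly right-skewed prevalences (roughly 0.2%–6%)
  to an approximately normal scale; it also guarantees a positive back
  transform.

## Workforce extrapolation

Staffing tables carry, per region × domain, clinical/non-clinical FTE and
administrative FTE.  A pool of administrative staff shared between two
domains' centres is allocated proportionally to the domains' total workforce
in that region and resolved to whole FTE by the largest-remainder method
(ties broken toward the larger weight, then by domain name); the printed
source tables carry integer allocations, and largest remainder is the
smallest-total-deviation integer split.  Reported FTE are rounded to one
decimal at output; internal arithmetic keeps full precision.

Prescribers are head counts, not FTE — prescription is a minor part of their
duties — so they are carried in a separate type and scaled by the same
population (and later need) ratios, reported to the nearest thousand.

## Survey needs

Weighted need counts and totals are rounded **half-to-even** to integers
independently, then `p̂ = k/n` with a 95% Clopper–Pearson interval
(`scipy`/`statsmodels` beta inversion).  The exact interval is conservative
(coverage ≥ 95% by construction) and well defined at k = 0 and k = n;
Wilson and normal intervals are available behind a config switch.  Needs are
`p̂ ×` population with CI bounds mapped by the same linear function.  Where
a survey enrolled adults only, the under-18 prevalence is a per-country
**child factor** times the adult prevalence (defaults 0.30 for the reference
country and 0.40 for the other adult-only survey; both configurable), so

`n = p_adult · (pop_18+ + child_factor · pop_<18)`.

## Prevalence model and MCMC

The mixed model is

`y_cd = α_d + β1_d · medAge_c + β2_d · HDI_c + ε_cd`,  `y = pN^(1/4)`,
`α_d ~ N(μ, τ²)`, `ε ~ N(0, σ²)`.

*Screening.* A preliminary OLS fit with the same fixed-effect structure
(domain intercepts + domain-interacted slopes) computes Cook's distance per
observation; observations with distance > 0.5 are flagged, keeping at most
the 2 largest (both knobs in config).  The cap mirrors the intended use —
removing isolated gross errors, not trimming the sample.  Cook's distance is
known to *mask* when several outliers are present (each inflates the
residual variance that standardises the others), so the planted-outlier
tests place gross errors (20× the residual sd) at high-leverage design
points of distinct countries.

*Priors.* Weakly informative: N(0, 10²) on μ and on slopes of the
internally centred-and-scaled covariates, half-Cauchy(1) on τ and σ.  With
only five domains τ is weakly identified; its prior scale is a config
parameter of `PriorConfig`.

*Sampler.* An affine-invariant ensemble sampler (`emcee`, 40 walkers,
differential-evolution moves) on the **marginal** posterior: given τ and σ
the model is linear-Gaussian, so the domain intercepts are integrated out in
closed form (Sherman–Morrison on the per-domain compound-symmetric
covariance), reducing the target to 13 well-behaved dimensions and removing
the usual funnel geometry.  Intercepts are recovered afterwards from their
exact Gaussian conditional, one draw per retained sample.  Defaults: 13,000
steps, 3,000 burn-in, thinned to ≤500 steps per walker (≥1,000 retained
draws; in practice 20,000).  Split-chain R-hat (walkers as chains, via
`arviz`) and effective sample sizes are recorded per parameter; R-hat above
the 1.05 cutoff sets `converged = False` and records a warning rather than
raising, and the pipeline surfaces it in the run log.  Everything is exactly
reproducible given the seed.

*Prediction.* For each unsurveyed country × domain the posterior draws of
the linear predictor — plus residual noise by default, since the resulting
intervals feed per-country need CIs (a mean-only mode exists) — are
summarised by median and 2.5/97.5 percentiles on the transformed scale.
Each summary is verified non-negative (negative values would arise only from
extreme covariate combinations; they are truncated to zero and counted in
the run log) and raised to the fourth power.  Residual noise is seeded per
country–domain identifier, so predictions are invariant to input order.
Back-transformed values above 1 are clipped and counted likewise.

## Global scaling

Per-domain global needs are the sum of country point estimates; CI bounds
are summed likewise (**bound summation**).  This treats country errors as
perfectly correlated and is therefore conservative; a Monte-Carlo mode
(sampling each country's need from the normal its interval implies,
truncated at zero) gives the independent-error alternative and is never
wider.  The published aggregation method is not stated; bound summation is
the default because it reproduces the published cognition-row interval
exactly.

The workforce ratio uses **opposite-bound propagation**: the lower bound of
`N_G/N_S` divides the numerator's lower bound by the denominator's upper
bound, and conversely.  All-domain figures are sums over domains before any
display rounding.  Sensitivity bounds multiply point estimates by 0.5 and
1.5.  Prescribers scale by the summed needs of the two domains they cover.

## Synthetic world

The generator emulates the study conditions: 28 surveyed and 161 unsurveyed
countries, five domains, true prevalence from the model's own regression
structure (fourth-root scale, Gaussian noise sd 0.02, transformed values
clamped to [0, 1] before back-transforming).  Default coefficients are
chosen so prevalences span the realistic 0.2%–6% range over the covariate
space.  Covariates are uniform over plausible ranges (median age 15–48
years, HDI 0.35–0.97, population log-uniform 10⁵–1.4×10⁹) to cover the
predictor space for recovery tests — deliberately *not* the real joint
distribution (real median age and HDI are strongly correlated).  Surveys
draw Bernoulli need indicators per respondent with lognormal design weights
(dispersion 0.3, unit expected mean), default 9,000 respondents per country
(the order of the real surveys' average), emitting non-integer weighted
counts so the downstream rounding step is exercised.  Two surveyed countries
are adult-only with child factors drawn from [0.2, 0.5], bracketing the
real 0.30/0.40.  Regional staffing tables are exact population shares of a
ground-truth national workforce (8.9% coverage over 3 regions by default),
so extrapolation recovers the truth to machine precision; an optional
shared administrative pool spans hearing and vision in one region.

What passing synthetic tests do **not** show about real data: the weight
model is a stand-in (the real survey weighting scheme is not described),
there is no nonresponse or clustering, covariates are independent, and the
prevalence model is exactly true in the generator — real-world model
misspecification is unquantified.

## Problem sizes and tolerances in the test suite

The arithmetic pipeline runs from published inputs in well under a second.
Simulation-based tests use the study-scale panel (140 observations, 10
fixed-effect slopes) with 8,000-step chains, and scale replicate studies
down (10 replicate null fits, 500–2,000 survey replicates) — sizes chosen
as the smallest at which the checked properties are stable, and stated in
each test.  Printed-input tolerances are ±0.2–1% because the published
tables round to 1 decimal / 2 significant figures and their hidden decimals
propagate through the ratios.

## Known limitations

* The reference country's productivity is high-resource and specialist:
  requirement estimates are likely conservative for other provision models.
* Credible intervals for slopes show slight frequentist under-coverage
  (~92% at nominal 95% in the null simulation) due to intercept shrinkage
  with only five domains; this is inherent to the exchangeable-intercept
  hierarchy.
* Bound-summed global CIs overstate interval width if country errors are
  independent; the Monte-Carlo mode brackets that case.
* The binomial CIs ignore survey design effects.
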