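# atworkforce

Needs-based estimation of the global workforce required to provide
**assistive technology** — hearing aids, wheelchairs, prostheses,
communication aids and other assistive products — at a high level of access.

More than 2.5 billion people need assistive products, yet in most countries
access is low, and workforce shortage is one of the main barriers.  This
package implements a three-stage planning model that answers: *how many
full-time equivalents (FTE) of provision staff would the world need if every
country provided assistive technology at the level of the best-performing
reference country (Sweden)?*  It is aimed at health-workforce planners and
researchers in rehabilitation and disability epidemiology.

## The model

Work is disaggregated over five **product domains**: cognition &
communication, hearing, mobility & self-care, orthotics & prosthetics, and
vision (excluding ordinary spectacles).

1. **Reference workforce** — staffing tables from three healthcare regions
   (combined population P_R) are pooled and scaled to the national
   population P_S per domain and workforce class (clinical/non-clinical vs
   administrative):

   `W_S = W_R · P_S / P_R`

   Administrative staff shared between two domains' centres are allocated
   proportionally to the domains' workforce with largest-remainder rounding.

2. **Needs** — for surveyed countries, the prevalence of need pN comes from
   design-weighted household surveys (WHO rapid assistive technology
   assessment); weighted counts are rounded and given exact Clopper–Pearson
   95% CIs, then multiplied by the population (with a reduced child
   prevalence where the survey covered adults only).  For the remaining
   countries, prevalence is predicted from a Bayesian linear mixed model on
   the fourth-root scale,

   `pN^(1/4) ~ medAge:domain + HDI:domain + (1 | domain)`,

   fitted by MCMC after removing high-influence observations (Cook's
   distance screen).  Posterior predictive summaries are verified
   non-negative and raised to the fourth power.

3. **Global scaling** — per-country needs are aggregated to global totals
   N_G and the reference workforce is scaled by the need ratio,

   `W_G = W_S · N_G / N_S`,

   with opposite-bound interval propagation, a ±50% deterministic
   productivity sensitivity analysis (`W_G,low = 0.5·W_G`,
   `W_G,high = 1.5·W_G`), and an analogous extrapolation of prescriber head
   counts.

Because the survey microdata are not public, a **synthetic world** module
generates country panels, surveys and staffing tables from the same
regression structure with known ground truth, so the whole pipeline is
testable end to end.

## Worked example

```sh
python analysis/01_reference_workforce.py
python analysis/02_global_workforce.py
python analysis/03_synthetic_validation.py
```

The second script runs the published-input pipeline and prints:

```
Required global workforce for a high level of access:

  total:    4.37 M FTE (95% CI 2.93-6.93), 540 FTE per million population
  clinical: 3.41 M FTE (95% CI 2.27-5.47)
  +/-50% productivity band (total): 2.2-6.6 M FTE
  prescribers: 16.1 M (95% CI 12.2-21.4)
```

i.e. roughly 4.4 million FTE of dedicated provision staff — of which 3.4
million are clinical and non-clinical — plus about 16 million prescribers
for whom prescription is part of broader duties, would be needed globally.
The first script prints the reference-country table it scales from (~5,300
FTE, 502 FTE per million population), and the third validates the
statistical pipeline against synthetic ground truth (per-domain global needs
recovered to within a few percent, intervals covering the truth).

The same pipeline is scriptable via the CLI (`atworkforce run`,
`atworkforce simulate`, `atworkforce fit`, ...) or the library API
(`atworkforce.pipeline.run_pipeline`).

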