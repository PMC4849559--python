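# Methods

This note records the model, its conventions, the synthetic data it is
tested on, and the choices made where the design was genuinely open.

## Model structure

Six states: stable-CAD, post-MI, post-ischaemic-stroke,
post-haemorrhagic-stroke, CVD death, non-CVD death (deaths absorbing).
Cycle length is 90 days; one convention — 90/365.25 years — is used
everywhere (`CYCLE_LENGTH_YEARS`). Only first occurrences of the
non-fatal events are modelled explicitly; the time-varying post-event
cost and utility profiles carry the burden of later morbidity. The
horizon runs until live occupancy falls below 1e-9, capped at 60 years
or attained age 110, whichever binds first; residual live mass at the
cap is logged as a warning.

## Risk equations

All survival models are accelerated-failure-time (AFT) with location
μ = x′β:

* exponential S(t) = exp(−t·e^{−μ})
* Weibull S(t) = exp(−(t·e^{−μ})^{1/σ})
* lognormal S(t) = 1 − Φ((ln t − μ)/σ)
* generalised gamma (Prentice μ, σ, Q), nesting Weibull at Q = 1 and
  lognormal as Q → 0.

Fitting maximises the right-censored log-likelihood (mean per
observation, covariates standardised internally) by BFGS, multi-start
from the exponential solution (the generalised gamma additionally from
the fitted Weibull and lognormal). Convergence requires a max-gradient
below 1e-4 (1e-3 for the generalised gamma, whose likelihood ridge
between its nested families is genuinely flat). The covariance matrix
is the inverse observed information on the (β, log σ, Q) scale,
eigenvalue-floored so that saturated designs on rare endpoints yield
large-but-finite rather than indefinite uncertainty. Family choice is
minimum AIC per endpoint; exact ties go to fewer parameters.

Covariate encoding: one-hot with reference levels sex = male,
subtype = stable angina, smoking = never, deprivation quintile 1;
biomarkers enter linearly. Primary equations use analysis time since
cohort entry with baseline age as a covariate; ageing beyond the data
enters through the life-table splice, the utility age bands and the
cost model's current-age term. Post-event equations reset the clock at
the event and use sex and age-at-event only. Non-CVD mortality beyond
the splice time (default 10 years of follow-up, also for post-event
states via total follow-up time) uses the life-table rate
−ln(1 − qₓ) at the current integer age; a terminal-row qₓ = 1 becomes
an effectively infinite rate (clamped at 1e12/yr, which zeroes survival
exactly in floating point). For group-mean profiles with fractional
`sex_female`, life-table and utility lookups blend the male and female
values by that fraction.

Sparse-data fallback: a post-event endpoint observing fewer than five
deaths is refitted on the pool of all three non-fatal event types for
that cause (logged). This only engages at small cohort sizes —
haemorrhagic stroke is rare — and never at the default analysis scale.

## Transition engine

Hazards are treated as piecewise constant on a sub-cycle grid (midpoint
evaluation, 16 sub-steps per cycle for primary transitions, 8 for
post-event; halving the step moves no CIF by more than 1e-7 on the
tested hazard shapes). Under that approximation the CIF increments,
survival updates and within-cycle person-time integrals are exact and
mutually consistent, so S + Σ F_k = 1 holds to machine precision and
constant-hazard cases reproduce their closed forms to ~1e-14.
Within-cycle competing events need no ordering assumption: each cycle's
mass is split across causes by the hazard-proportional CIF increments.

## Accrual and discounting conventions

* Life years and QALYs accrue the *expected within-cycle person-time*
  of each live state (the exact integral of occupancy over the cycle,
  available from the same sub-cycle grid). This is not a half-cycle
  correction — it is the limit a half-cycle correction approximates —
  and it is what lets 90-day cycles hit exponential life expectancy to
  0.1% rather than the ~2% bias of full-cycle accrual.
* Costs accrue as a full 90-day amount to the state occupied at cycle
  start, matching the convention of the cost panel (a patient dying
  mid-cycle still generates that cycle's row).
* Discounting multiplies each cycle's accruals by
  (1 + r)^{−t_j} at the cycle-start time t_j (mid-cycle optional),
  r = 3.5%/year by default.
* A transition during cycle j enters its post-event tunnel at the start
  of cycle j+1; that first tunnel cycle carries the acute cost uplift
  and acute utility decrement, and the post-event clock starts there.
  Relative to the event's true mid-cycle timing this shifts post-event
  profiles by up to half a cycle (~45 days), a documented bias well
  inside every tolerance used.
* The final cycle is weighted by the fraction lying inside the horizon,
  so a 60-year cap yields exactly 60 zero-hazard life years.

Because post-event mortality, costs and utilities depend on time since
the event, the model is semi-Markov: post-event occupancy is tracked in
tunnels indexed by entry cycle. The microsimulation oracle samples
individual trajectories from *exactly* the per-cycle probabilities and
person-time factors the cohort engine integrates, so cohort outputs
must equal microsimulation means up to Monte Carlo error — the
package's central internal-validity check (all 17 outputs within 3 SEs
across 10 random parameter draws at n = 100,000).

## Costs and utilities

The per-cycle cost model is a log-link mean model estimated by Poisson
quasi-likelihood — the standard consistent estimator for non-negative,
right-skewed cost data under any noise distribution — with
cluster-robust (by patient) covariance; dispersion is the Pearson X²
scale. It is solved by a damped Newton routine (panels reach ~10⁶
rows; verified coefficient- and SE-identical to the statsmodels GLM on
the same data). Two components, CVD-attributable and other, are fitted
separately and sum to the total, giving both total and CVD-specific
lifetime costs. Features: a parsimonious baseline covariate set,
current age (baseline age is deliberately excluded to avoid
collinearity), post-event state indicators, an acute (event-cycle)
indicator and an early band (cycles 1–4 after the event).

Utilities multiply an age/sex base score by a condition multiplier, a
post-event state multiplier and, in the event cycle only, an acute
multiplier; the multiplicative composition is a modelling choice (the
catalogue format supplies levels, not a composition rule). All values
are constrained to the EQ-5D UK value-set range [−0.594, 1].

## Synthetic data

The generator emulates the *marginal* structure of a large English
stable-CAD cohort: covariate means and proportions follow the published
overall patient-characteristics column (44% female, mean age 67/72
male/female, hypertension 76%, heart failure 26%, …); continuous
covariates pass through a Gaussian copula (default correlations zero,
configurable) with lognormal moment-matched biomarker marginals so
configured means are exact. Event histories are drawn as latent
cause-specific AFT times (minimum = first event), independent
exponential administrative censoring with median follow-up 4.2 years;
post-event outcomes are redrawn with the clock reset. Ground-truth
hazards are Weibull, calibrated once so that the 5-year cause-specific
cumulative hazards at the mean covariate vector are MI 0.065, ischaemic
stroke 0.048, haemorrhagic stroke 0.006, CVD death 0.055, non-CVD death
0.16 — jointly implying a mean 5-year composite CVD risk of ~16% —
with age, sex, comorbidity and smoking coefficients of conventional
sign and magnitude. Cost truth: stable total ≈ £800/cycle split
CVD/other, acute event cycle ≈ ×5 on the CVD component, gamma
multiplicative noise.

What the generator does **not** emulate: covariate correlations beyond
the copula knobs, missingness and imputation, practice-level entry and
exit, repeat non-fatal events, secular trends, or real national
life-table / EQ-5D values (the packaged life table and utility
catalogue are synthetic stand-ins with Gompertz mortality and
population-norm-shaped utilities, marked as such in their filenames).
Passing tests therefore demonstrate internal validity — correct
estimation and propagation given the assumed data-generating law — not
calibration to any real population.

## Stratification, PSA, pricing

The 5-year composite risk score integrates the four CVD CIFs under
competing non-CVD death on a 128-step grid (512 for single profiles).
Deciles are contiguous equal splits of the stable risk ranking (ties by
patient id); group-level runs use the decile's mean covariate vector
with categoricals as level proportions; the representative patient is
the median-risk member (lower of two at even sizes).

PSA draws survival coefficients from multivariate normals on the
estimation scale (β, log σ, Q), cost coefficients likewise, and
utilities from beta distributions with the catalogue value as mean
(concentration 200) rescaled over the EQ-5D range; non-positive-definite
covariances are eigenvalue-clipped with a warning. Intervals are
percentile-based. At smoke scale the Wald covariances of very rare
endpoints are honest but enormous, so lower interval bounds can reach
zero; this reflects genuine small-sample uncertainty, not instability
of the engine.

Pricing: the treatment multiplies the MI, stroke (both types — a
config switch excludes haemorrhagic) and CVD-death hazards, including
post-event CVD death (also switchable), by (1 − ρ), with no effect on
non-CVD mortality and no side-effects. The maximum annual price divides
net monetary headroom by the treated arm's *discounted* life years —
the treatment is taken while alive in any state and paid for like any
other cost; negative headroom floors at £0. Annualising over discounted
rather than undiscounted exposure is a documented convention.

## Problem sizes and defaults

Default analysis scale in the numbered scripts and the acceptance
script is 2,000 patients with 50 PSA iterations (minutes on one CPU);
recovery and convergence checks in the test suite use cohorts up to
50,000 and microsimulations of 100,000 individuals. The PSA iteration
count for a production run is 1,000 (`RunConfig.psa_iterations`).

## Known limitations

* Baseline covariates are frozen at entry; only age advances (via the
  splice, costs and utilities). Risk-factor drift is out of scope.
* First non-fatal events only; recurrent events enter solely through
  post-event cost/utility/mortality profiles.
* The acute cost uplift is charged one cycle after the transition (see
  accrual conventions).
* Group-level results evaluate the model at mean covariates; because
  risk is convex in the linear predictors this understates the mean of
  per-patient risks — visible in every decile summary — which is why
  both quantities are reported.
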