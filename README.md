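# scadmodel

A lifetime cost-effectiveness model for **stable coronary artery disease
(stable-CAD)**: patients who are event-free at least six months after an
acute coronary syndrome, or who have stable angina or another chronic
coronary diagnosis. The package is aimed at health economists and
methodologists who want a fully testable, end-to-end implementation of a
multi-state decision model of this class — from cohort data to
value-based treatment prices — without access-restricted EHR data:
every input is synthetic, drawn from known ground truth, so each stage
can be validated against that truth.

## The model

Patients enter a six-state Markov cohort model in the **stable** state
and progress in 90-day cycles through first occurrences of non-fatal
**MI**, **ischaemic stroke** and **haemorrhagic stroke** into the
absorbing **CVD death** and **non-CVD death** states. Disease
progression is driven by 11 parametric survival equations in
accelerated-failure-time form (exponential, Weibull, lognormal,
generalised gamma; minimum-AIC family per endpoint):

* five *primary* cause-specific equations on time since cohort entry,
  with the full baseline covariate vector x (demographics, CAD subtype
  and severity, risk factors, comorbidities, psychosocial factors,
  biomarkers);
* six *post-event* mortality equations (CVD and non-CVD death after
  each non-fatal event), clock reset at the event, covariates sex and
  age at event only;
* non-CVD mortality beyond 10 years of follow-up spliced to national
  life-table rates −ln(1 − qₓ).

Cause-specific hazards h_k(t) are composed, in the standard
competing-risks fashion, into event-free survival
S(t) = exp(−Σ_k H_k(t)) and cumulative incidence functions
F_k(t) = ∫₀ᵗ h_k(u) S(u) du, from which per-cycle transition
probabilities follow:

    P(→ k in cycle j) = (F_k(t_{j+1}) − F_k(t_j)) / S(t_j).

Per-cycle costs come from a two-component (CVD-attributable + other)
log-link panel regression; utilities from an EQ-5D-style age/sex
catalogue with condition and event multipliers. Lifetime (discounted at
3.5%/year) life years, QALYs and costs are accrued to cohort
extinction; an individual-level microsimulation provides an independent
Monte Carlo oracle for every output.

Patients are ranked by 5-year composite CVD risk
(F_MI + F_IS + F_HS + F_CVDdeath at 5 years) and split into tenths; the
model runs at each decile's mean covariate vector. A hypothetical
treatment multiplies CVD hazards by (1 − ρ); its **maximum annual
price** at willingness-to-pay λ (GBP/QALY) is the value-based price

    p* = max(0, (λ·ΔQALY − ΔCost_disease) / exposure),

with exposure the treated arm's discounted life years. Parameter
uncertainty is propagated by Monte Carlo (multivariate-normal
coefficient draws, beta-perturbed utilities).

## Worked example

The numbered scripts under `analysis/` run the whole study at smoke
scale (2,000 patients, 50 PSA iterations, seed 1), writing artefacts to
`results/run/`:

```bash
python analysis/01_simulate_cohort.py
python analysis/02_fit_risk_equations.py
python analysis/03_stratify_risk_deciles.py
python analysis/04_run_lifetime_model.py
python analysis/05_probabilistic_sensitivity.py
python analysis/06_price_treatments.py
```

`04_run_lifetime_model.py` prints the per-decile lifetime summary; at
seed 1 the first and last rows are

```
 risk_group  life_years  discounted_qalys  discounted_total_costs  cvd_mortality_pct
          1       24.22              9.96                53472.34               7.90
         10        5.30              3.04                27875.78              38.24
```

i.e. the lowest-risk tenth (5-year composite risk 3.5%) lives 24.2 more
years on average, accrues 9.96 discounted QALYs and £53.5k discounted
lifetime healthcare costs, and mostly dies of non-CVD causes; the
highest-risk tenth (41%) has 5.3 remaining life years and loses far
more of them to CVD. `06_price_treatments.py` prints the value-based
price grid; at a £20,000/QALY threshold a treatment cutting CVD hazards
by 10/20/30/40% is worth at most £37/£73/£109/£145 per year in the
lowest-risk decile but £227/£457/£688/£922 in the highest — the
risk-stratified pricing gradient the model exists to quantify.

The same pipeline is available as a CLI
(`scadmodel all --seed 1 --out results/run`, with per-stage subcommands
`simulate | fit | stratify | run | psa | price`).

## Layout

```
src/scadmodel/    library: synthetic data, survival fitting, CIF/transition
                  engine, cost & utility models, Markov engine + microsim
                  oracle, stratification/PSA, pricing, config/IO/CLI
analysis/         numbered narrative drivers (the study, start to finish)
tests/            pytest suite incl. end-to-end acceptance properties
docs/methods.md   modelling assumptions, conventions and limitations
```
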