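# medhaz

Causal mediation of group inequalities in all-cause mortality on the
**additive hazard scale**: how much of an exposure group's excess (or
deficit) mortality runs through lifestyle mediators, split into
*differential exposure* (groups have different mediator distributions)
and *differential vulnerability* (the same mediator level harms groups
differently)?

The package is written for epidemiologists and biostatisticians who want
to run — and, on synthetic cohorts with known truth, *validate* — this
decomposition for a cohort shaped like the pooled 1997–2014 US national
health-interview survey linked to mortality follow-up through 2015:
race/ethnicity as the exposure, four categorized lifestyle factors
(alcohol use, smoking, BMI, physical activity) as mediators, and
sex-stratified models adjusted for education, marital status and survey
year, with **age as the timescale** (delayed entry at the age of survey).

## The model

Mortality follows a semiparametric additive hazards model with constant
coefficients (Lin–Ying form) and age `a` as the timescale. For the
counterfactual natural-effects (marginal structural) model, each subject
is replicated over all assignments of *auxiliary exposures*
`R*_1..R*_4` (one per mediator) and weighted by

    W(r*) = prod_k  P_k(M_k | R = r*_k, C) / P_k(M_k | R, C),

where each `P_k` is a baseline-category multinomial logit of mediator
`k` on exposure and covariates. The weighted additive-hazards fit

    lambda(a) = lambda_0(a) + beta R + sum_k eta_k R*_k
                + sum_k psi_k (R x R*_k) + gamma' C

identifies, per contrast (e.g. Black vs White, within sex):

| coefficient | component |
|---|---|
| `beta`  | (pure) direct effect |
| `eta_k` | differential exposure through mediator k (pure indirect effect) |
| `psi_k` | differential vulnerability to mediator k (mediated interaction) |

with `total = beta + sum_k (eta_k + psi_k)` holding exactly, all in
**additional deaths per 10,000 person-years**. The estimating equation
is solved in closed form with exact interval decomposition (no
discretization), left truncation honored on `(entry, exit]`, weights and
subject-level clustering throughout. Confidence intervals come from a
subject-level bootstrap that reruns the entire pipeline per replicate
(primary), or from a cluster sandwich (fast approximation).

A first-class synthetic-cohort generator (`medhaz.simulate`) draws
covariates, mediators and event ages from a fully specified additive
hazard with known coefficients and computes the implied true
decomposition in closed form, which is what the test suite and the
acceptance script measure recovery against.

## Worked example

```python
import medhaz as mh
from medhaz.decompose import DecompositionConfig, report_table

params = mh.default_params(n=30_000)            # NHIS-like defaults, binary contrast
cohort = mh.generate_cohort(params, seed=11)
result = mh.run_decomposition(cohort, DecompositionConfig(exposure_levels=["white", "black"]))
print(report_table(result)[1])
```

prints (men's column shown; values are deaths per 10,000 person-years):

```
                                                             black men
Effect of race/ethnicity (ref = White)               15.5 (-2.9, 34.0)
'Direct' effect of race/ethnicity (ref = White)      8.4 (-11.8, 28.5)
Net indirect effect of race/ethnicity (ref = White)   7.1 (-1.2, 15.4)
Alcohol use: differential exposure                    -0.9 (-3.6, 1.9)
Alcohol use: differential vulnerability                2.7 (-3.1, 8.4)
Smoking: differential exposure                        -0.6 (-3.0, 1.7)
Smoking: differential vulnerability                    4.0 (-1.7, 9.7)
BMI: differential exposure                             0.9 (-0.2, 2.0)
BMI: differential vulnerability                        0.7 (-1.8, 3.2)
Physical inactivity: differential exposure             0.8 (-0.7, 2.3)
Physical inactivity: differential vulnerability       -0.5 (-3.9, 3.0)
```

Reading: in this simulated cohort Black men experience 15.5 additional
deaths per 10,000 person-years relative to White men after covariate
adjustment; 8.4 of those are a direct effect and 7.1 run through the
lifestyle mediators; e.g. the positive smoking-vulnerability entry says
the same smoking categories carry a higher additive mortality rate for
Black men here. The generator's closed-form truth for this parameter set
(`mh.true_decomposition(params)`) is total 20.0, direct 18.0, net
indirect 2.1 — inside all the intervals above.

The `examples/` directory holds one short narrative script per
capability (generation, additive-hazards fitting, decomposition,
descriptive survival), and the `medhaz` CLI exposes the same pipeline as
`simulate`, `decompose`, `recover` and `describe` subcommands driven by
a YAML config.

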