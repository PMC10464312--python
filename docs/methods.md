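# Methods

## Problem and estimands

`medhaz` decomposes the total effect of a group exposure R
(race/ethnicity, reference = non-Hispanic White) on all-cause mortality
into natural-effect components on the additive hazard scale, with four
categorized lifestyle mediators M_1..M_4 (alcohol use, smoking, BMI,
leisure-time physical activity) and covariates C (education, marital
status, survey year), sex-stratified, with age as the timescale. All
effects are constant hazard differences reported as additional deaths
per 10,000 person-years.

The decomposition follows the counterfactual natural-effects convention
in which, per contrast:

- **direct effect** = pure direct effect: the effect of changing R with
  every mediator held at its distribution under the reference exposure.
  This term absorbs the exposure–mediator interaction evaluated at the
  reference mediator distribution — an unavoidable convention choice;
  the alternative (folding that remainder into the vulnerability
  components) changes the direct/vulnerability split but not the total.
  We use the pure-direct convention because it is exactly what the
  coefficient of R in the weighted natural-effect model estimates, so
  estimator and estimand coincide term by term.
- **differential exposure_k** = pure indirect effect through M_k: the
  hazard change from giving the exposed group the reference group's
  distribution of M_k, evaluated at reference-group vulnerability
  (coefficient of the auxiliary exposure R*_k).
- **differential vulnerability_k** = mediated interaction: the
  additional change because the same mediator level carries a different
  additive effect in the exposed group (coefficient of R x R*_k).
- **net indirect** = sum over mediators of the previous two;
  **total** = direct + net indirect, an exact identity of the
  coefficient mapping, never a separately fitted number. (An
  independent unweighted, unexpanded "race + covariates" fit is
  reported in the metadata as a diagnostic for the total.)

Natural effects marginalize over covariates. The package fixes the
marginalization population to the covariate distribution of the whole
analytic sample (both exposure groups), and uses the same convention in
the generator's closed-form truth, so oracle and estimator target the
same quantity.

Identification needs the usual assumptions: no unmeasured confounding of
the exposure–outcome, exposure–mediator and mediator–outcome relations;
no mediator–outcome confounder affected by exposure; mediators without
causal effects on each other (they are modeled, and generated,
conditionally independent given R and C); and positivity of the
mediator models under every counterfactual exposure.

## Estimation pipeline

Per sex stratum:

1. **Mediator models.** One baseline-category multinomial logit per
   mediator: predictors are the exposure dummies, age ((age-50)/10,
   linear), education (two dummies; dropped in the sensitivity
   configuration), married, and survey year ((year-2005.5)/10, linear).
   Centering/scaling only conditions the Newton iterations. Fitting is
   Newton–Raphson with step-halving to a gradient sup-norm below 1e-8;
   on suspected separation a tiny ridge (1e-6) is applied once and
   logged. Reference categories: consumption category I, never smoker,
   normal weight, physically active.
2. **Expansion.** Each subject is replicated over all L^K assignments of
   auxiliary exposures (16 for a binary contrast, 81 for the three-level
   joint model); survival fields are copied unchanged.
3. **Weights.** Unstabilized likelihood ratios
   prod_k P_k(m|r*_k,C)/P_k(m|r,C); the identity replicate has weight
   exactly 1 by construction (the ratio is computed as x/x). Weights are
   truncated at the 99.5th percentile per stratum by default (variance
   control; count and clipped mass are reported); an optional
   normalization by mean weight per replicate pattern is available.
   Denominator probabilities below 1e-12 raise a positivity error naming
   subject and mediator.
4. **Outcome model.** Weighted Lin–Ying additive hazards fit with
   delayed entry: the estimating equation is evaluated *exactly* by
   decomposing time into intervals between consecutive distinct
   entry/exit ages (risk interval convention (entry, exit]; ties among
   event ages aggregated; a subject exiting at an event age is at risk
   at that age, one entering at it is not; no jitter). Coefficients are
   events per person-year; the 10,000 person-year scale is applied only
   at reporting. Singular integrated designs raise a rank error naming
   the degenerate or collinear columns. Nonnegativity of fitted hazards
   is not enforced (additive models may cross zero); the baseline
   estimator reports the Breslow-type cumulative hazard, which reduces
   to Nelson–Aalen at beta = 0.

Uncertainty: the primary intervals are percentile bootstrap over
subjects, rerunning the *entire* pipeline (mediator fits, expansion,
weights, truncation, outcome fit) per replicate, deterministic given the
seed; B >= 50 enforced, failures above 10% of replicates abort. A
cluster sandwich (martingale-residual scores summed within subject
before the outer product) is the fast alternative; it treats the weights
as known and is therefore mildly conservative/anticonservative depending
on the component, which is why the bootstrap is primary.

The bootstrap loop runs through a vectorized engine that computes the
same estimating equation from subject-level aggregates without
materializing the expanded design; the test suite pins engine and
public path to ~1e-15 agreement, for binary and three-level contrasts
and for every configuration switch (covariate set, truncation,
normalization).

## Synthetic generator

`GeneratorParams` fully specifies: race marginals; sex mix; age at
survey ~ 18 + 67·Beta(1.3, 1.8) (mean ≈ 46 y, SD ≈ 16 y); survey year
uniform on 1997–2014; education and marriage probabilities per race;
per-sex mediator laws (multinomial logits whose intercepts and race
shifts are placed to loosely match published unweighted prevalences of
the emulated survey — illustrative realism, not estimates); and the
additive hazard: a Gompertz-like piecewise-constant baseline per 1-year
age bin, 9e-4 + 2e-3·exp(0.085·(age−40)) per person-year with a 0.6
multiplicative factor for women (sex-stratified fitting makes a per-sex
baseline innocuous), race offsets (+20 per 10,000 py for Black, −3 for
Hispanic), mediator-level offsets gamma (e.g. +42 per 10,000 py for
everyday smoking), race×mediator interactions delta of a few per 10,000
py matching the sign pattern of the published decomposition, and small
negative covariate effects. Event ages come from exact inverse-transform
sampling through the piecewise-constant cumulative hazard from the
subject's entry age; administrative censoring at age-at-survey +
(2016 − survey year), hard cap at age 100. Assembled rates are clipped
at zero; the clipped fraction is recorded and must stay below 1% (it is
0 at the defaults — the default magnitudes were chosen so the additive
model never goes negative on the supported range).

What the generator does *not* emulate: complex survey design (strata,
clusters, oversampling, weights — explicitly out of scope), probabilistic
death-record linkage error, time-varying mediators or covariates,
reporting error in the lifestyle measures, and non-constant (age-varying)
exposure effects. Passing recovery tests therefore demonstrate that the
pipeline estimates what it claims under a correctly specified additive
data-generating law of realistic magnitude — not that the published
substantive estimates are correct.

Two known, deliberately accepted approximation gaps between estimator
and closed-form truth: survivors are selected toward low-risk mediator
levels over follow-up, and the covariate-dependence of the mediator laws
makes the constant-coefficient natural-effect model a (person-time
weighted) average. Both effects are second order at realistic effect
sizes (a few per 10,000 py over ≤ 19 years of follow-up) and are covered
by the Monte-Carlo tolerance of the recovery studies.

## Study sizes used by the suite and acceptance script

Chosen to exercise each property at the smallest informative scale:
oracle equivalence on 100 random ≤ 20-row designs (tolerance 1e-10);
parameter recovery on one 50,000-subject single-sex cohort against a
400,000-draw closed-form truth (3 SE); null calibration over 100
replications at n = 5,000 with B = 100 bootstrap; bootstrap coverage
over 150 replications at n = 5,000 with B = 100 (band 0.90–0.99);
hazard-difference sanity at n = 100,000. Single-sex cohorts are used for
the replication studies (the pipeline is sex-stratified, so the second
stratum only duplicates compute); the two-sex path is exercised by the
structural tests and examples.

## Numerical and degenerate-input choices

- Percentiles (weight truncation, bootstrap CIs) use numpy's linear
  interpolation.
- Table rendering rounds half away from zero to one decimal.
- The integrated information matrix is declared singular when a
  diagonal entry vanishes (a column with no variation on any risk set)
  or its scaled condition number exceeds 1e10.
- A single subject, a single cluster, mediators with one observed
  level, or a mediator level unobserved in an exposure group are
  rejected with named errors rather than silently extrapolated.
- All randomness flows through named substreams of one master seed
  (generator, truth, bootstrap per stratum, simulation studies), so
  adding a stage never perturbs another stage's draws.

## Limitations

Constant hazard differences are an approximation over a 60+ year age
range; the diagnostic time-varying story is limited to the baseline
(fully time-varying coefficient fits are out of scope). The sandwich
variance ignores weight estimation. The three-level joint model (81-fold
expansion) is provided but the replication studies run the binary
contrast for compute reasons. Real-data concerns — missingness beyond
complete-case validation, survey design, linkage error — are out of
scope by design.
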