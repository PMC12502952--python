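# Methods

This note documents the statistical model, the numerical choices, and what
the synthetic-data experiments do and do not demonstrate.

## Density standardization

Percent mammographic density (area-based PMD or volumetric PVD, both in
[0, 100]) depends strongly on age and BMI. To treat density as a *fixed*
covariate in an age-indexed hazard model, the package works with
standardized residuals:

1. Ordinary least squares of percent density on age at entry and,
   when available, BMI (no interaction). Two covariate sets are fitted —
   `age_only` and `age_bmi` — per density tool, four parameter blocks in
   total, because BMI is often unavailable at the point of care. A scoring
   request with missing BMI dispatches to the age-only block.
2. A two-parameter Box-Cox transform of the residuals,
   `((r + c)^λ − 1)/λ` (natural log at λ = 0). The shift *c* is set so the
   smallest shifted training residual equals a configurable positive
   offset (default 1 percentage point). The exponent λ maximizes the
   Gaussian profile log-likelihood over the grid λ ∈ [−3, 3] in steps of
   0.01; grid maximum likelihood was chosen because a closed-form
   criterion does not exist and the grid makes the estimate reproducible
   to a stated resolution.
3. Standardization by the mean and SD (ddof = 1) of the transformed
   training values, so the training sample is exactly mean 0, SD 1.

Degenerate inputs: fewer than 3 complete regression rows, constant
covariates, fewer than 10 or all-equal residuals raise errors. New
observations whose shifted residual is not strictly positive lie below the
transformable range; the default policy clamps them to the training
minimum with a warning (a `raise` policy is available). For fixed age and
BMI the mapping from raw density to *z* is strictly increasing wherever
defined.

## Hazard estimation

Cox proportional-hazards fits use **age as the time scale** with left
truncation at the age at entry — chosen for coherence with the
age-indexed risk engine — and Efron tie handling. Partial-likelihood
maximization is delegated to `lifelines.CoxPHFitter` (Newton iterations,
convergence precision 1e-9, up to 500 steps); the test suite checks the
maximizer against an independent brute-force grid search of the Efron
partial likelihood on small datasets (tolerance 1e-4).

The density effect is per SD of *z*, with a binary menopausal-status
interaction (status main effect included). Because the simulated hazard
switches from the pre- to the postmenopausal effect at the age at
menopause, follow-up is episode-split at the first whole follow-up year
starting at or after that age, so the interaction column tracks *current*
status and the estimator is consistent for both stratum effects. The
unknown-status hazard ratio comes from a separate no-interaction fit on
all women rather than from combining the pre/post pair.

Adjustment covariates are the questionnaire risk factors and family
history as a categorical variable (0/1/2+ affected first-degree
relatives, two dummies). BMI is never an adjustment covariate when density
was residualized on BMI — the residualization already removes it.

The genotyped-subcohort design samples cases and non-cases with different
probabilities; sampled women are weighted by the inverse of their
inclusion probability and the weighted fit uses robust variance. The
attenuation line is an ordinary least-squares fit through
(log-HR unadjusted, log-HR adjusted for the polygenic score) pairs and is
used to project PGS-adjusted effect sizes onto a cohort without complete
genotype data; it requires at least two pairs with distinct abscissae.

## Absolute-risk engine

The model is multiplicative on the annual hazard scale. The linear
predictor adds, for the factors in the configured input combination:

- continuous density: `β(t)·z`, where `β(t)` is the pre- or
  postmenopausal log-HR according to the woman's (known or expected) age
  at menopause at the projection age, or the unknown-status value when
  status is unknown; exactly one density representation (BIRADS or one
  continuous tool) is active per prediction, and the PGS-adjusted HR set
  is selected automatically when the PGS is among the inputs;
- BIRADS: the category log-RR (categories 1–4);
- questionnaire factors: per-SD log-RRs for z-scored continuous factors,
  per-category log-RRs for categorical ones;
- family history and PGS: categorical and per-SD log-RRs respectively.

**Baseline constraint.** For every age and calendar period the baseline
is the registry rate divided by the population-mean relative risk
`E[exp(LP)]`, computed under independence of the factor components:
continuous standard-normal factors contribute the lognormal mean
`e^{β²/2}` — for density, a mixture over menopausal status with
`P(post | age)` from a truncated-normal age-at-menopause distribution
(default mean 51, SD 4, truncated to 40–60) — and categorical factors
contribute `Σ p_k·RR_k`, with BIRADS probabilities specific to attained
age below/at-or-above 50. Independence is justified by the
residualization (which removes the density–age/BMI dependence); remaining
factors are modelled multiplicatively. By construction the
population-averaged model incidence reproduces the input rates; the test
suite verifies this by simulation to within Monte-Carlo error.

**Projection.** Discrete annual recursion on half-open one-year age
intervals: `risk = Σ_t λ_i(t)·S_bc(t)·S_mort(t)` with survival factors
`S(t) = Π_{s<t}(1 − rate(s))`; annual rates are treated as probabilities
(the registry rates involved are ≤ ~0.03/yr, so the distinction is below
other model error). Competing all-cause mortality is toggleable and
ignores the double counting of breast-cancer deaths. Projections are
capped at age 80. The calendar period of a projection year is birth year
plus attained age, clamping to the nearest available period column at the
table edges. Cohort predictions start one landmark year after the age at
entry, excluding prevalent disease. The recursion is verified against an
independent per-year Bernoulli Monte-Carlo simulation (10⁶ replicates, 3
SE agreement).

Where the data do not determine a choice, the engine takes the simplest
deterministic option: a premenopausal woman transitions at her individual
age at menopause when known, otherwise at the configured expected age
(default 51); the BIRADS age band is evaluated at attained age during
projection.

Reference parameter values shipped as defaults: per-SD density hazard
ratios (pre/post/unknown) of 1.48/1.41/1.44 for area-based and
1.27/1.38/1.32 for volumetric density, with a slightly attenuated set
(1.45/1.38/1.41 and 1.26/1.37/1.31) used when a polygenic score is also
in the model; BIRADS category relative risks 0.55/1.00/1.45/2.05 with
band-specific category distributions (0.08, 0.37, 0.43, 0.12) below 50
and (0.13, 0.45, 0.34, 0.08) at 50+. The BIRADS values are
literature-typical settings, not estimates produced by this package, and
are configurable.

## Validation battery

The observed 5-year status treats women developing invasive cancer after
the prediction window as unaffected; women censored before the window
closes keep their observed status by default (a `drop` rule is
available) — the choice matters little in the synthetic cohorts, where
censoring within the window is rare. The calibration slope regresses the
binary outcome on the log-odds of predicted risk (Wald CI). Quantile
calibration uses equal-count bins with stable tie-breaking and exact
Poisson intervals on bin case counts (`χ²` quantile form; a zero count
gives a lower bound of 0). The AUC is the Mann-Whitney estimator with
ties counted 1/2 and a DeLong interval, computed on the binary 5-year
outcome (not a survival concordance). Risk categories use half-open
[lo, hi) intervals at 1%, 1.67% and 3%, optionally splitting the lowest
category at 0.35%; the NRI is
`[P(up|case) − P(down|case)] + [P(down|non-case) − P(up|non-case)]`.

## Synthetic cohort generator

The generator emulates the structure the pipeline assumes, not any real
registry's marginals:

- entry ages on 40–74 with a Beta(1.2, 2.0) shape (screening enrolment
  skews younger; this also provides adequate premenopausal person-time);
- log-normal BMI (median 25, log-SD 0.15);
- density on a latent Gaussian scale, linear in age and BMI with negative
  slopes, mapped through an inverse shifted-power transform (shape 0.35)
  and clipped to [0, 100] — guaranteeing the downstream Box-Cox fit has
  real signal and a right-skewed bounded marginal;
- menopause age truncated-normal (51, 4) on 40–60; the simulated age is
  kept for *all* women (real data would carry it only for postmenopausal
  women) so that time-varying-status analyses and projection transitions
  can use the individual value;
- questionnaire factors (two z-scored continuous, one binary), family
  history with probabilities (0.88, 0.105, 0.015) and log-RRs
  (0, ln 1.8, ln 2.9), and a standard-normal PGS sharing a configurable
  correlation (default 0.1) with the density noise so the correlation
  survives residualization;
- invasive-cancer times from a piecewise-constant annual hazard
  `base · exp(β(t)·z + covariate terms)` with the per-SD effect switching
  at the personal annual grid point at or after menopause; the baseline
  0.002/yr together with 8 years of administrative follow-up and
  competing rates (other cancer 0.004, in-situ 0.0005, mastectomy 0.0002,
  death 0.004 per year) yields a crude incidence near 2.5 per 1,000
  woman-years and roughly 780 invasive events per 40,000 women — the
  scale of the motivating cohort. Event times are drawn by
  inverse-transform sampling of the piecewise-constant hazard, so exit
  times are continuous; the earliest simulated event censors, with
  administrative censoring coded as reaching age 80 or end of follow-up.
- BIRADS categories are assigned by quantile-cutting the percent density
  at configurable cumulative probabilities (0.10, 0.51, 0.90).

`generate_outcomes_from_model` draws independent Bernoulli horizon
outcomes from a model's own predicted risks, the basis of the
self-calibration experiments.

For the hazard-recovery experiments the configured pre/post log-HRs are
interpreted as the *total* (PGS-unadjusted) density effect, so the PGS is
excluded from the simulated hazard there to avoid double counting its
correlated share; elsewhere the PGS contributes ln(1.6) per SD.

What passing these experiments shows: the standardization, fitting and
projection machinery are mutually consistent and unbiased under the
model's own assumptions. What they do not show: performance on real
mammography data, where density–covariate relationships are nonlinear,
covariates are missing not at random, menopause status is misreported,
and proportional hazards is an approximation.

## Problem sizes and numerical tolerances

Recovery experiments use 40,000-woman cohorts (~780 events), matching the
scale at which the reference hazard ratios were estimated; the
per-stratum log-HR standard error is then ≈ 0.05–0.07, so the test suite
averages three replicate cohorts when checking recovery against the
reference intervals while the acceptance script reports single-cohort
estimates. Self-calibration uses 200,000 Bernoulli draws (slope SE ≈
0.025). Oracle equivalences: Cox slope vs exhaustive grid 1e-4; AUC vs
all-pairs counting 1e-12; risk recursion vs 10⁶-replicate simulation
within 3 binomial SEs; baseline constraint within 1% by simulation.
Exact identities (closed-form normalizing constants, constant-hazard
risks, serialization round-trips) are asserted at 1e-12 relative.

## Known limitations

- Linear age/BMI effects on density only; no longitudinal (repeat
  mammogram) modelling.
- No pedigree likelihood, pathogenic-variant carrier modelling, ovarian
  or contralateral risks; the polygenic score is a single standard-normal
  summand.
- The population-mean relative risk assumes independent factor
  components; a cohort aging across the 50-year BIRADS band boundary with
  frozen categories departs slightly from the constraint's cross-sectional
  assumption.
- Missing covariates are handled by parameter-set dispatch (BMI) or row
  errors, not imputation; the synthetic cohorts are complete by
  construction.
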