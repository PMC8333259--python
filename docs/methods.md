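# Methods

## Model

For subject *i* with visit times *t_ij* (months) and survival data
*(T_i, δ_i)* under right censoring:

- **Longitudinal sub-model.** sqrt-SBP follows a linear mixed model
  `y_ij = x_ij'β + u_i + ε_ij` with `u_i ~ N(0, σ_u²)` and independent
  `ε_ij ~ N(0, σ_e²)`. The square-root scale is adopted after a normality
  panel (Shapiro–Wilk and Kolmogorov–Smirnov against the fitted Gaussian, on
  the raw, sqrt and log transforms); for right-skewed SBP readings the sqrt
  transform is the first to pass.
- **Survival sub-model.** A Weibull proportional-hazards model
  `h_i(t|u_i) = λ ρ t^{ρ−1} exp(x_i'α + γ·link_i(t))`. The package reports
  both the PH and the AFT parameterization of any Weibull fit; the exact
  conversion is `β_PH = −β_AFT·ρ`, `μ_AFT = −log λ / ρ`, `σ_AFT = 1/ρ`.
  The association link is `u_i` (`shared_intercept`, default) or the current
  latent trajectory value `m_i(t) = x_i(t)'β + u_i` (`current_value`).
  The field's convention reads exp(α) > 1 as higher death risk; the PH scale
  is therefore the primary reporting scale even though the same model can be
  written as an AFT with a latent term.
- **Joint likelihood.** Conditional on `u_i` the sub-models are independent,
  so each subject contributes
  `∫ f(T_i, δ_i | u) · Π_j f(y_ij | u) · φ(u; 0, σ_u²) du`,
  with the survival factor `h(T|u)^δ · exp(−Λ(T|u))`.

## Estimation

- **Quadrature.** Adaptive Gauss–Hermite with 15 nodes by default: nodes are
  centered at each subject's posterior mode (found by a safeguarded,
  vectorized Newton iteration — the log-integrand is strictly concave in `u`
  for both links) and scaled by the curvature there. A plain prior-centered
  Gauss–Hermite rule is kept for oracle comparisons. Doubling the node count
  changes the fitted log-likelihood by far less than 1e-4 and γ̂ by < 1e-3 at
  the default cohort size.
- **EM.** Initialization from the separate fits (random-intercept LMM by ML;
  Weibull PH by Newton–Raphson) with γ = 0 — by conditional independence this
  initialization is exactly the γ=0 constrained MLE, which the likelihood-
  ratio test in the test-suite exploits. E-step: posterior moments of `u_i`
  from the quadrature weights. M-step (shared-intercept link): closed-form
  updates for β (GLS on `y − E[u]`), σ_e² and σ_u²; the survival block
  (log λ, log ρ, α, γ) is updated by a short L-BFGS run on the expected
  complete-data log-likelihood with analytic gradient. Convergence: relative
  log-likelihood change < 1e-8 and maximum parameter change < 1e-6, at most
  200 iterations; a direct BFGS polish of the observed log-likelihood (on
  log-transformed positive parameters) follows in every case, and ascent
  relative to the initialization is asserted on every fit. Under the
  `current_value` link the β-update is no longer closed-form, so the fit goes
  straight from the separate-fit initialization to the quasi-Newton stage.
- **Standard errors.** Numerically differentiated observed information at the
  optimum (central differences, relative step 1e-5, on the natural parameter
  scale); a singular information matrix raises rather than silently
  pseudo-inverting.
- **LMM machinery.** The marginal likelihood `Y_i ~ N(X_iβ, Z_iDZ_i' + Σ_i)`
  is profiled over β (GLS) and maximized by L-BFGS-B over transformed
  variance parameters (log standard deviations; Fisher-z for the AR1
  coefficient; logistic for exchangeable correlations), with up to 3
  restarts from perturbed starts on failure. Residual structures: IND, CS
  (parameterized as between+within variance, so the exchangeable correlation
  is restricted to [0, 1) — negative exchangeable correlation is not
  meaningful for repeated measures of this kind), AR1 by within-subject visit
  index, heterogeneous CS (accepted under both of its conventional names,
  HCS and CSH) with per-occasion standard deviations on a binned visit grid,
  and UN. The UN structure is fitted by a closed-form EM for the multivariate
  normal with arbitrary missingness; the REML variant integrates β against a
  flat prior inside the E-step, and on complete data with saturated occasion
  means both variants reduce to the sample covariance (divisor N for ML,
  N−1 for REML), which the tests verify. Random effects are allowed only with
  IND or AR1 residuals: CS/HCS/UN residual correlation is aliased with a
  random intercept, and the model refuses the combination instead of
  returning a ridge of equivalent solutions. Covariance-structure selection
  is therefore run on marginal (no-random-effect) models, and the final
  subject-specific fit maps an exchangeable winner (CS/HCS/UN) to IND
  residuals alongside the selected random effects, logging the mapping.
- **Cox / log-rank / KM.** Kaplan–Meier curves and the log-rank test go
  through lifelines. Cox regression is an in-package Newton–Raphson on the
  Breslow partial likelihood (score-norm tolerance 1e-8, step-halving,
  divergence of a coefficient reported as probable separation), because the
  proportional-hazards diagnostic needs risk-set internals: the PH check is a
  score test of adding `x·log(t)` per covariate (joint over dummy columns;
  the GLOBAL row tests all interactions at once), which only requires the
  Schoenfeld residuals and risk-set covariances of the base fit.
- **Fixed-effect inference.** LMM t-statistics use residual degrees of
  freedom (total observations − fixed parameters); no Satterthwaite or
  Kenward-Roger correction is attempted. AIC = −2ℓ + 2k and
  BIC = −2ℓ + k·log(n_obs) with k = fixed parameters + variance parameters.

## Synthetic cohorts

The generator emulates the hypertension follow-up registry the package is
calibrated against, and is the basis of all simulation tests:

- 318 subjects, administrative censoring at 65 months, independent
  exponential censoring at rate 0.016/month; visits scheduled every 6 months
  with ±0.5-month uniform jitter (baseline fixed at t=0) and truncated at the
  observed survival time, giving ≈6.5 visits/subject (≈2100 measurements) and
  an observed follow-up distribution with mean ≈ 37.6 and median ≈ 37 months.
  The 6-month spacing was chosen so the total observation count matches the
  magnitude implied by the study's information criteria; it is configurable.
- Covariates: 15 subject-level predictors (plus visit time). Prevalences
  printed in the study (gender 54.4% female, residence 64.78% urban, age>50
  51.13%, hypertension-stage distribution, family history 64.46% positive,
  diabetes 61.32%) are used verbatim; the rest were back-computed once from
  the published per-category death proportions and the 11% overall mortality
  where possible (alcohol 0.44, khat 0.31) and otherwise set to plausible
  values (smoking 0.20, stress 0.35, raised cholesterol 0.30, poor adherence
  0.40, related-disease mix 0.55/0.13/0.19/0.13, lifestyle change 0.55).
  Fasting blood sugar is log-normal (median 100, log-sd 0.25).
- Trajectory coefficients default to the study's multivariable estimates
  (intercept 11.71 sqrt-mmHg, time slope −0.001/month, stage and lifestyle
  effects); survival coefficients default to the study's Weibull estimates;
  γ defaults to 0.03. σ_u = σ_e = 0.65 sqrt-mmHg were fixed once: the total
  marginal variance (≈0.85) reproduces the per-observation log-likelihood
  magnitude of the study's covariance-selection table, and the implied
  between-patient SBP spread (~15 mmHg) is clinically realistic.
- The Weibull baseline scale (5.7e-4; 8.5e-4 for the reduced design below)
  was calibrated by simulation so ≈11% of subjects die during follow-up —
  the study's observed mortality — with ≈89% censored. Event times are drawn
  by inverse-transform sampling of the cumulative hazard (closed form for the
  shared-intercept link, vectorized bisection for the current-value link).
  Negative sqrt-SBP draws, impossible under realistic settings, are resampled
  and logged rather than truncated, keeping the Gaussian residual model exact.
- `recovery_config()` is the reduced design used for replicated simulation
  studies: identical size, follow-up, variance components, event fraction and
  association, but two survival covariates and one longitudinal covariate, so
  hundreds of joint fits stay inside a few minutes.

What the generator does **not** emulate: missing visits or measurement
dropout other than death/censoring, measurement rounding, informative visit
schedules, covariate correlation (predictors are sampled independently), or
secular trends. Passing tests therefore demonstrate correctness of the
estimators under the stated model, not robustness to those real-data
complications.

## Design choices in genuinely open territory

- The study's association could be read as a shared random effect or as a
  current-value link; both are implemented, with `shared_intercept` the
  default (closed-form hazards, and the plainest reading of a "shared
  parameter model"). Every report names the link used.
- The survival model is implemented on the Weibull proportional-hazards
  scale, which matches the hazard/survivor notation of the joint likelihood
  and the published interpretation of exp(coefficients) as hazard ratios; the
  AFT equivalent is always reported alongside.
- The univariable screens for the longitudinal and survival halves retain two
  independent covariate sets (no union); the multivariable LMM uses exactly
  the longitudinal-screen survivors, the Weibull and joint survival half
  exactly the Cox-screen survivors.
- When the global PH test rejects, the pipeline proceeds to the Weibull
  parametric model and records the evidence that triggered the switch.

## Numerical notes and limitations

- Wald z ratios with tiny standard errors and the p-values printed alongside
  them in the source study are arithmetically inconsistent in places (e.g. a
  z of 7.895 next to p = 0.034); this package always reports the p-value
  implied by its own statistic.
- With ~35 deaths among 318 subjects and σ_u ≈ 0.65, the Fisher information
  for γ is approximately (number of events)·σ_u² ≈ 15, i.e. SE(γ̂) ≈ 0.26 per
  cohort. A γ of 0.03 is therefore not individually significant at this
  sample size — estimates of γ from single synthetic cohorts scatter widely
  around the truth even though Wald coverage is correct, and averages over a
  few hundred replicates still carry Monte-Carlo noise of ≈ 0.02. Simulation
  checks of γ should be read with that yardstick in mind.
- The unstructured covariance on an 11-bin grid estimates 66 parameters from
  318 subjects; it fits (the EM is exact), but its AIC penalty makes it a
  rare winner at this size, and it cannot be combined with random effects.
- No left/interval censoring or truncation, no competing risks, no Bayesian
  estimation, no log-logistic/log-normal AFT alternatives, no missing-data
  imputation, and no plotting: curve and profile data are emitted as CSV.

## Problem sizes used by the test-suite

Simulation tests run at the calibrated study size (n = 318) where the claim
being tested concerns that size (parameter recovery: 200 replicates;
selection consistency: 100 replicates per comparison), and at n = 150–200
with 800–2500 replicates for type-I-error calibration of the screen and the
log-rank test, sizes at which the Monte-Carlo standard error is comfortably
inside the asserted bands.
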