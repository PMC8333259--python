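# sbpjoint

Joint modeling of longitudinal systolic blood pressure (SBP) and survival time
in hypertension follow-up cohorts.

## The problem

In a hypertension registry each patient contributes two linked outcomes: a
series of SBP measurements taken at follow-up visits, and a right-censored
time to death. Analyzing them separately wastes information and biases both
answers — patients with high latent blood pressure die sooner, which truncates
their SBP series, and the SBP trajectory itself carries prognostic
information. `sbpjoint` implements the standard shared-random-effects joint
model for this situation, together with all the machinery a full analysis
needs around it, and a calibrated synthetic-cohort generator so every stage is
testable without patient data.

## The model

SBP is modeled on the square-root scale (which a Shapiro–Wilk /
Kolmogorov–Smirnov panel typically selects for right-skewed SBP readings).
For subject *i* at visit time *t<sub>ij</sub>*:

```
longitudinal:  y_ij = x_ij' β + u_i + ε_ij,     u_i ~ N(0, σ_u²),  ε_ij ~ N(0, σ_e²)
survival:      h_i(t | u_i) = λ ρ t^(ρ−1) · exp( x_i' α + γ · u_i )
```

The random intercept *u<sub>i</sub>* is shared by both sub-models; the
association parameter γ measures how strongly a patient's latent
blood-pressure level drives the death hazard (a `current_value` link,
γ·m<sub>i</sub>(t), is also available). Conditional on *u<sub>i</sub>* the two
processes are independent, so the marginal likelihood is a one-dimensional
integral per subject, evaluated by adaptive Gauss–Hermite quadrature and
maximized by EM with a quasi-Newton polish. Standard errors come from the
numerically differentiated observed information.

Around the joint model the package provides, as separate estimators:

- `LinearMixedModel` — Gaussian LMM for sqrt-SBP with selectable residual
  covariance structures (IND, CS, AR1, heterogeneous CS, unstructured) fitted
  by ML/REML, plus AIC-based covariance-structure and random-effect selection
  and a 25%-level univariable screen;
- `KMCurve` / `logrank_test` — Kaplan–Meier estimation and the log-rank test
  (via lifelines);
- `CoxPHModel` — Cox regression (Breslow ties) with a covariate-by-log(time)
  score test of the proportional-hazards assumption;
- `WeibullRegressionModel` — parametric Weibull survival regression reported
  in both the proportional-hazards and accelerated-failure-time
  parameterizations (βPH = −βAFT·ρ exactly);
- `generate_cohort` — synthetic cohorts with the calibrated study conditions:
  318 subjects, visits every ~6 months up to 65 months, ~11% deaths, printed
  covariate prevalences and sub-model coefficients;
- `run_full_analysis` — the full pipeline (descriptives → normality →
  screening → selection → LMM → KM/log-rank → PH check → Weibull → joint
  model), writing every table analog as CSV.

All estimators are scikit-learn style (`fit`, fitted attributes with a
trailing underscore, `get_params`); `fit_lmm`, `weibull_fit`, `fit_joint`,
... are functional wrappers.

## Worked example

```python
from sbpjoint import SyntheticConfig, generate_cohort, JointModel

cohort = generate_cohort(SyntheticConfig(seed=11))
fit = JointModel(
    longitudinal_terms=("time", "family_history", "adherence"),
    survival_terms=("family_history", "smoking"),
).fit(cohort)
print(fit.summary())
```

prints

```
Joint longitudinal-survival model (association: shared_intercept)

Longitudinal sub-model (sqrt-SBP)
                          estimate      se         t       p
intercept                  13.5995  0.1321  102.9665  0.0000
time                       -0.0027  0.0009   -3.0380  0.0024
family_history[Positive]    0.4551  0.1477    3.0816  0.0021
adherence[Poor]             0.7715  0.1436    5.3714  0.0000
  sigma_u = 1.1949 (SE 0.0516)   sigma_e = 0.6397 (SE 0.0109)

Survival sub-model (Weibull PH)
                          estimate      se       z       p  hazard_ratio
family_history[Positive]     0.155  0.3477  0.4457  0.6558        1.1676
smoking[Yes]                -0.628  0.4802 -1.3078  0.1909        0.5337

  shape rho = 1.3256 (SE 0.1779)   scale lambda = 9.855e-04

Association gamma = 0.1864 (SE 0.1469, z = 1.269, p = 0.205)
  positive association: higher latent sqrt-SBP level, higher death hazard
log-likelihood = -2719.9077
```

Reading the output: the longitudinal panel says patients with a positive
family history run about 0.46 sqrt-mmHg higher SBP (on the square-root scale)
and poor adherence adds another 0.77; `sigma_u` is the between-patient spread
of latent blood-pressure levels. The survival panel gives Weibull log-hazard
ratios (`hazard_ratio = exp(estimate)`), and the association row is the Wald
test of γ = 0. With only ~35 deaths among 318 patients a single cohort
estimates γ with substantial uncertainty (SE ≈ 0.15–0.3 here), so
non-significance in one replicate is expected; the omitted longitudinal
covariates are absorbed into the random intercept, which is why `sigma_u`
exceeds its generating value in this reduced fit.

The same workflow is available from the shell:

```bash
sbpjoint simulate --seed 1 --out cohort/
sbpjoint analyze --simulate --seed 1 --out results/
sbpjoint report --in results/
```

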