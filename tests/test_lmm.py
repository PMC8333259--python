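"""Linear mixed model: closed-form oracles, invariants, selection, screening."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from sbpjoint import (LinearMixedModel, SyntheticConfig, check_normality,
                      compare_cov_structures, compare_random_effects,
                      fit_lmm, generate_cohort, information_criteria,
                      random_intercept_loglik, univariable_screen)
from sbpjoint.cohort import recovery_config


def balanced_frame(k, m, sigma_u=2.0, sigma_e=1.0, mean=3.0, seed=1):
    rng = np.random.default_rng(seed)
    u = rng.normal(0, sigma_u, k)
    y = mean + u[:, None] + rng.normal(0, sigma_e, (k, m))
    return pd.DataFrame({
        "subject_id": np.repeat(np.arange(k), m),
        "visit_time": np.tile(np.arange(m, dtype=float), k),
        "sqrt_sbp": y.ravel(),
    })


def test_reml_matches_anova_estimators_on_balanced_design():
    """On a balanced 10x5 one-way layout the REML variance components equal the
    closed-form ANOVA estimators MSE and (MSB - MSE)/m."""
    k, m = 10, 5
    df = balanced_frame(k, m)
    fit = LinearMixedModel(fixed_terms=(), random_terms="intercept",
                           cov_structure="IND", method="REML").fit(df)
    y = df["sqrt_sbp"].to_numpy().reshape(k, m)
    ybar_i, ybar = y.mean(axis=1), y.mean()
    msb = m * ((ybar_i - ybar) ** 2).sum() / (k - 1)
    mse = ((y - ybar_i[:, None]) ** 2).sum() / (k * (m - 1))
    assert fit.sigma_params_["sigma_e"] ** 2 == pytest.approx(mse, rel=1e-6)
    assert fit.D_[0, 0] == pytest.approx((msb - mse) / m, rel=1e-6)


def test_ml_and_reml_intercept_equal_grand_mean_on_balanced_data():
    df = balanced_frame(20, 4, seed=3)
    grand = df["sqrt_sbp"].mean()
    for method in ("ML", "REML"):
        fit = LinearMixedModel(fixed_terms=(), random_terms="intercept",
                               method=method).fit(df)
        assert fit.beta_values_[0] == pytest.approx(grand, abs=1e-9)


def test_single_observation_per_subject_refused():
    df = balanced_frame(30, 1)
    with pytest.raises(ValueError, match="identifiable"):
        LinearMixedModel(fixed_terms=(), random_terms="intercept").fit(df)


def test_rank_deficient_design_names_aliased_column(small_cohort):
    df = small_cohort.merged_longitudinal()
    df["dup"] = df["visit_time"]
    with pytest.raises(ValueError, match="dup"):
        LinearMixedModel(fixed_terms=("time", "dup")).fit(df)


def test_random_effects_with_exchangeable_residuals_refused(small_cohort):
    with pytest.raises(ValueError, match="aliased"):
        LinearMixedModel(random_terms="intercept", cov_structure="CS").fit(small_cohort)


@pytest.mark.parametrize("structure", ["IND", "CS", "AR1", "HCS", "UN"])
def test_reported_loglik_matches_multivariate_normal_density(structure, small_cohort):
    """The optimizer's ML log-likelihood equals the sum of per-subject MVN
    densities recomputed independently from the fitted parameters."""
    re = "intercept" if structure in ("IND", "AR1") else "none"
    fit = LinearMixedModel(fixed_terms=("time", "family_history"),
                           random_terms=re, cov_structure=structure,
                           method="ML").fit(small_cohort)
    total = 0.0
    for sid, y, X in fit.subject_slices():
        V = fit.marginal_covariance(sid)
        total += stats.multivariate_normal.logpdf(y, X @ fit.beta_values_, V,
                                                  allow_singular=False)
    assert total == pytest.approx(fit.loglik_, abs=1e-6)


def test_aic_bic_arithmetic_identity(small_cohort):
    fit = fit_lmm(small_cohort, fixed_terms=("time",), method="ML")
    aic, bic = information_criteria(fit.loglik_, fit.n_params_, fit.n_obs_)
    assert fit.aic_ == pytest.approx(aic, abs=1e-12)
    assert fit.bic_ == pytest.approx(bic, abs=1e-12)
    assert fit.aic_ == pytest.approx(-2 * fit.loglik_ + 2 * fit.n_params_)


def test_ml_matches_statsmodels_random_intercept(small_cohort):
    statsmodels = pytest.importorskip("statsmodels.formula.api")
    df = small_cohort.merged_longitudinal()
    ours = LinearMixedModel(fixed_terms=("time", "family_history"),
                            method="ML").fit(df)
    sm = statsmodels.mixedlm("sqrt_sbp ~ time + family_history", df,
                             groups=df["subject_id"]).fit(reml=False)
    assert ours.loglik_ == pytest.approx(sm.llf, abs=1e-5)
    assert ours.beta_values_[0] == pytest.approx(sm.params["Intercept"], abs=1e-6)


def test_hcs_recovers_equal_variances_on_cs_data():
    """CS is the equal-variance special case of HCS: per-occasion SDs fitted by
    HCS on exchangeable data stay within a narrow ratio."""
    k, m = 500, 10  # ~5000 observations
    df = balanced_frame(k, m, sigma_u=1.0, sigma_e=1.0, seed=5)
    fit = LinearMixedModel(fixed_terms=(), random_terms="none",
                           cov_structure="HCS", method="ML", bin_width=1.0).fit(df)
    sd = fit.sigma_params_["sigma_by_occasion"]
    assert sd.max() / sd.min() < 1.2


def test_unstructured_ml_and_reml_match_sample_covariance():
    """With saturated occasion means and complete data, the UN fit has the
    closed-form solution: sample covariance with divisor N (ML) / N-1 (REML)."""
    rng = np.random.default_rng(2)
    N, m = 60, 4
    A = rng.normal(0, 1, (m, m))
    Sig = A @ A.T + np.eye(m)
    Y = rng.multivariate_normal(np.arange(1.0, m + 1), Sig, size=N)
    df = pd.DataFrame({
        "subject_id": np.repeat(np.arange(N), m),
        "visit_time": np.tile(np.arange(m, dtype=float), N),
        "sqrt_sbp": Y.ravel(),
    })
    df["occ"] = "t" + df["visit_time"].astype(int).astype(str)
    for method, ddof in (("ML", 0), ("REML", 1)):
        fit = LinearMixedModel(fixed_terms=("occ",), random_terms="none",
                               cov_structure="UN", method=method,
                               bin_width=1.0).fit(df)
        S = np.cov(Y.T, ddof=ddof)
        assert np.abs(fit.sigma_params_["Sigma"].to_numpy() - S).max() < 1e-6


def test_duplicate_grid_bins_rejected():
    df = pd.DataFrame({"subject_id": [0, 0, 1, 1],
                       "visit_time": [0.0, 0.2, 0.0, 6.0],
                       "sqrt_sbp": [1.0, 2.0, 3.0, 4.0]})
    with pytest.raises(ValueError, match="duplicate"):
        LinearMixedModel(fixed_terms=(), random_terms="none",
                         cov_structure="UN", bin_width=6.0).fit(df)


def test_compare_structures_tie_case_and_stable_order(small_cohort):
    out = compare_cov_structures(small_cohort, structures=("CS", "CS"))
    # identical structures give identical rows in input order
    assert (out["structure"] == "CS").all()
    assert out.iloc[0]["aic"] == pytest.approx(out.iloc[1]["aic"], abs=1e-6)


def test_compare_structures_reports_errors_per_row(small_cohort):
    base = LinearMixedModel(random_terms="intercept", method="ML")
    out = compare_cov_structures(small_cohort, base, structures=("IND", "UN"))
    row_un = out.set_index("structure").loc["UN"]
    assert not row_un["converged"] and row_un["error"] != ""
    assert out.set_index("structure").loc["IND", "converged"]


def test_random_effect_parameter_counting(small_cohort):
    out = compare_random_effects(small_cohort,
                                 LinearMixedModel(fixed_terms=("time",),
                                                  cov_structure="IND", method="ML"))
    k = out.set_index("random_terms")["n_params"]
    assert k["intercept+slope"] - k["intercept"] == 2  # slope var + covariance
    assert k["slope"] == k["intercept"]


def test_intercept_recovered_within_its_confidence_interval():
    """Coverage of the generating intercept by its own 95% CI across replicate
    cohorts (expected ~95 of 100)."""
    hits = 0
    n_rep = 100
    for r in range(n_rep):
        c = generate_cohort(recovery_config(seed=30_000 + r).replace(n_subjects=100))
        fit = LinearMixedModel(fixed_terms=("time", "family_history"),
                               method="REML").fit(c)
        row = fit.beta_.loc["intercept"]
        hits += row["ci_low"] <= 11.71 <= row["ci_high"]
    assert hits >= 90


def test_screen_alpha_one_retains_everything(small_cohort):
    out = univariable_screen(small_cohort, ["family_history", "smoking"], alpha=1.0)
    assert out["retained"].all()


def test_screen_excludes_constant_covariate(small_cohort):
    df = small_cohort.merged_longitudinal()
    df["flat"] = "x"
    with pytest.warns(UserWarning, match="constant"):
        out = univariable_screen(df, ["flat"])
    assert not out["retained"].any()


def test_screen_power_for_strong_effect():
    """A 1.0-effect covariate on the sqrt scale is always retained."""
    for r in range(20):
        cfg = recovery_config(seed=40_000 + r).replace(
            n_subjects=60,
            beta_long={"intercept": 11.71, "time": -0.001,
                       "family_history[Positive]": 1.0})
        c = generate_cohort(cfg)
        out = univariable_screen(c, ["family_history"])
        assert out.loc[0, "retained"]


def test_check_normality_recommendations():
    rng = np.random.default_rng(0)
    gauss = rng.normal(0, 1, 500) + 10
    assert check_normality(gauss).recommendation == "none"
    skewed = (rng.normal(0, 1, 500) + 12) ** 2  # square root is exactly Gaussian
    assert check_normality(skewed).recommendation == "sqrt"
    with pytest.raises(ValueError):
        check_normality(np.array([-1.0] * 30))
    with pytest.raises(ValueError):
        check_normality(np.ones(5))
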