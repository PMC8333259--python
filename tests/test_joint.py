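"""Joint model: quadrature oracle, separability, EM ascent, conditional survival."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import norm

from sbpjoint import (CohortTable, JointModel, WeibullRegressionModel,
                      association_test, fit_joint, joint_loglik,
                      random_intercept_loglik, wald_z)
from sbpjoint.cohort import generate_cohort, recovery_config

LT = ("time", "family_history")
ST = ("family_history", "smoking")
THETA = dict(beta=np.array([11.7, -0.001, 0.2]), sigma_u=0.6, sigma_e=0.7,
             scale=8e-4, shape=1.1, alpha=np.array([0.5, 0.3]))


@pytest.fixture(scope="module")
def one_subject():
    return CohortTable(
        longitudinal=pd.DataFrame({"subject_id": [0, 0],
                                   "visit_time": [0.0, 6.0],
                                   "sqrt_sbp": [11.9, 12.3],
                                   "sbp": [11.9**2, 12.3**2]}),
        survival=pd.DataFrame({"subject_id": [0], "time": [20.0], "event": [1]}),
        covariates=pd.DataFrame({"subject_id": [0]}),
    )


def trapezoid_loglik(one, beta, su, se, scale, shape, gamma, n_panels=100_000):
    """Dense numerical integration over u on [-8 su, 8 su] (independent oracle)."""
    us = np.linspace(-8 * su, 8 * su, n_panels + 1)
    Xy = np.array([[1, 0.0], [1, 6.0]])
    y = one.longitudinal["sqrt_sbp"].to_numpy()
    mu = Xy @ beta
    T = float(one.survival["time"].iloc[0])
    f_long = norm.pdf(y[0], mu[0] + us, se) * norm.pdf(y[1], mu[1] + us, se)
    h = scale * shape * T ** (shape - 1) * np.exp(gamma * us)
    S = np.exp(-scale * T**shape * np.exp(gamma * us))
    return float(np.log(np.trapezoid(f_long * h * S * norm.pdf(us, 0, su), us)))


def test_quadrature_matches_dense_trapezoid_integration(one_subject):
    beta = np.array([11.8, 0.01])
    args = (0.6, 0.7, 8e-4, 1.1)
    oracle = trapezoid_loglik(one_subject, beta, *args, gamma=0.5)
    got = joint_loglik(one_subject, beta, *args, np.empty(0), 0.5, ("time",), ())
    assert got == pytest.approx(oracle, rel=1e-6)


def test_plain_and_adaptive_quadrature_agree(one_subject):
    beta = np.array([11.8, 0.01])
    a = joint_loglik(one_subject, beta, 0.6, 0.7, 8e-4, 1.1, np.empty(0), 0.5,
                     ("time",), (), adaptive=True)
    b = joint_loglik(one_subject, beta, 0.6, 0.7, 8e-4, 1.1, np.empty(0), 0.5,
                     ("time",), (), adaptive=False, n_nodes=61)
    assert a == pytest.approx(b, rel=1e-8)


def test_quadrature_node_count_converged(recovery_cohort):
    """Increasing nodes 7 -> 15 -> 31 leaves the log-likelihood unchanged to
    well below 1e-4 at 15 nodes."""
    vals = [joint_loglik(recovery_cohort, **THETA, gamma=0.1,
                         longitudinal_terms=LT, survival_terms=ST, n_nodes=nn)
            for nn in (7, 15, 31)]
    assert abs(vals[1] - vals[2]) < 1e-4
    assert abs(vals[0] - vals[2]) < 1e-2


def test_separability_at_zero_association(recovery_cohort):
    """gamma = 0: joint loglik = LMM marginal loglik + Weibull loglik."""
    jl = joint_loglik(recovery_cohort, **THETA, gamma=0.0,
                      longitudinal_terms=LT, survival_terms=ST)
    ll_lmm = random_intercept_loglik(recovery_cohort, LT, THETA["beta"],
                                     THETA["sigma_u"], THETA["sigma_e"])
    ll_wb = WeibullRegressionModel(terms=ST).loglik_at(
        THETA["scale"], THETA["shape"], THETA["alpha"], data=recovery_cohort)
    assert jl == pytest.approx(ll_lmm + ll_wb, abs=1e-6)


def test_fit_improves_on_separate_initialization(recovery_cohort):
    fit = JointModel(longitudinal_terms=LT, survival_terms=ST).fit(recovery_cohort)
    assert fit.loglik_ >= fit.init_loglik_ - 1e-8
    # EM trace is non-decreasing up to the documented tolerance
    hist = np.array(fit.history_)
    assert np.all(np.diff(hist) > -1e-6 * np.maximum(1, np.abs(hist[:-1])))
    assert fit.gamma_se_ > 0
    assert fit.sigma_u_ > 0 and fit.sigma_e_ > 0


def test_fit_from_truth_converges_quickly_when_noise_tiny():
    cfg = recovery_config(seed=21).replace(n_subjects=120, sigma_e=0.05)
    c = generate_cohort(cfg)
    truth = np.concatenate([[11.71, -0.001, 0.235], [0.65, 0.05],
                            [cfg.weibull_scale, 1.2], [0.549, 0.312], [0.03]])
    fit = JointModel(longitudinal_terms=LT, survival_terms=ST,
                     em_before_polish=True).fit(c, init=truth)
    assert fit.loglik_ >= fit.init_loglik_
    # intercept recovered within ~3 SE (SE ~ sigma_u/sqrt(n) = 0.06)
    assert abs(fit.beta_[0] - 11.71) < 0.2


def test_quadrature_doubling_barely_moves_gamma(recovery_cohort):
    f15 = JointModel(longitudinal_terms=LT, survival_terms=ST,
                     n_quadrature=15).fit(recovery_cohort)
    f31 = JointModel(longitudinal_terms=LT, survival_terms=ST,
                     n_quadrature=31).fit(recovery_cohort)
    assert abs(f15.gamma_ - f31.gamma_) < 1e-3


def test_association_wald_arithmetic():
    z, p = wald_z(0.03, 0.0038)
    assert round(z, 3) == 7.895
    z0, p0 = wald_z(0.0, 1.0)
    assert z0 == 0.0 and p0 == 1.0
    with pytest.raises(ValueError):
        wald_z(1.0, 0.0)


def test_association_test_direction(recovery_cohort):
    fit = JointModel(longitudinal_terms=LT, survival_terms=ST).fit(recovery_cohort)
    z, p, direction = association_test(fit)
    assert z == pytest.approx(fit.gamma_ / fit.gamma_se_)
    assert 0 <= p <= 1
    if fit.gamma_ > 0:
        assert "higher death hazard" in direction
    else:
        assert "lower death hazard" in direction


def test_wald_and_likelihood_ratio_tests_agree_under_null():
    """Wald and LRT decisions for gamma=0 agree in the vast majority of null
    replicates (small-scale equivalence check)."""
    from scipy.stats import chi2
    agree = 0
    n_rep = 20
    for r in range(n_rep):
        cfg = recovery_config(seed=60_000 + r).replace(n_subjects=150,
                                                       gamma_assoc=0.0)
        c = generate_cohort(cfg)
        fit = JointModel(longitudinal_terms=LT, survival_terms=ST).fit(c)
        z, p_wald, _ = association_test(fit)
        # under gamma=0 the constrained MLE is exactly the separate-fit
        # initialization (separability), so init_loglik_ is the null maximum
        lrt = 2 * (fit.loglik_ - fit.init_loglik_)
        p_lrt = chi2.sf(max(lrt, 0.0), 1)
        agree += (p_wald < 0.05) == (p_lrt < 0.05)
    assert agree >= 0.9 * n_rep


def test_conditional_survival_properties(recovery_cohort):
    fit = JointModel(longitudinal_terms=LT, survival_terms=ST).fit(recovery_cohort)
    sid = recovery_cohort.survival["subject_id"].iloc[0]
    s = fit.conditional_survival(np.array([0.0, 10.0, 20.0, 40.0]), sid)
    assert s[0] == pytest.approx(1.0)
    assert np.all(np.diff(s) <= 0)
    with pytest.raises(ValueError):
        fit.conditional_survival(-1.0, sid)


def test_conditional_survival_closed_form_matches_numeric(recovery_cohort):
    """Shared-intercept closed form equals direct numerical integration of the
    hazard for a random subject."""
    fit = JointModel(longitudinal_terms=LT, survival_terms=ST).fit(recovery_cohort)
    rng = np.random.default_rng(2)
    sid = rng.choice(recovery_cohort.survival["subject_id"].to_numpy())
    i = int(np.where(fit._data.subject_ids == sid)[0][0])
    u = float(fit.posterior_modes_.loc[sid])
    eta = float(fit._data.Xt[i] @ fit.alpha_)
    t = 25.0
    from scipy.integrate import quad
    haz = lambda s: (fit.scale_ * fit.shape_ * s ** (fit.shape_ - 1)
                     * np.exp(eta + fit.gamma_ * u))
    cumhaz, err = quad(haz, 0.0, t, epsabs=1e-12, epsrel=1e-12)
    numeric = np.exp(-cumhaz)
    assert fit.conditional_survival(t, sid) == pytest.approx(numeric, abs=1e-8)


def test_current_value_association_fits(small_cohort):
    fit = JointModel(longitudinal_terms=LT, survival_terms=ST,
                     association="current_value").fit(small_cohort)
    assert np.isfinite(fit.loglik_)
    assert fit.loglik_ >= fit.init_loglik_ - 1e-8
    sid = small_cohort.survival["subject_id"].iloc[0]
    assert fit.conditional_survival(0.0, sid) == pytest.approx(1.0)


def test_invalid_spec_rejected(small_cohort):
    with pytest.raises(ValueError):
        JointModel(association="bogus").fit(small_cohort)
    with pytest.raises(ValueError):
        JointModel(n_quadrature=2).fit(small_cohort)
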