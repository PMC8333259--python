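"""Survival module: hand-computed oracles, cross-checks against lifelines,
parameterization identities and diagnostic calibration."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from sbpjoint import (CoxPHModel, WeibullRegressionModel, km_estimate,
                      logrank_test, ph_test, ratio_table, weibull_fit)


# ---------------------------------------------------------------------------
# Kaplan-Meier


def test_km_matches_hand_computed_product_limit(toy_survival):
    km = km_estimate(toy_survival)
    assert np.allclose(km.event_times, [1, 3, 4])
    assert np.allclose(km.survival, [0.75, 0.375, 0.0])
    assert km.median_defined and km.median == 3.0


def test_km_all_censored_means_flat_curve():
    df = pd.DataFrame({"time": [1.0, 2.0, 3.0], "event": [0, 0, 0]})
    km = km_estimate(df)
    assert km.event_times.size == 0
    assert not km.median_defined
    assert km.survival_at([0.5, 2.5]).tolist() == [1.0, 1.0]


def test_km_without_censoring_equals_empirical_survival():
    rng = np.random.default_rng(0)
    t = rng.exponential(1.0, 200)
    df = pd.DataFrame({"time": t, "event": 1})
    km = km_estimate(df)
    grid = np.quantile(t, [0.1, 0.5, 0.9])
    emp = [(t > g).mean() for g in grid]
    assert np.allclose(km.survival_at(grid), emp, atol=1e-12)


def test_km_empty_group_raises():
    df = pd.DataFrame({"time": [], "event": [], "g": []})
    with pytest.raises(ValueError):
        km_estimate(df, group_col="g")


@settings(derandomize=True, max_examples=25, deadline=None)
@given(st.lists(st.tuples(st.floats(0.1, 50), st.booleans()),
                min_size=3, max_size=40))
def test_km_is_nonincreasing_step_function(records):
    df = pd.DataFrame(records, columns=["time", "event"])
    df["event"] = df["event"].astype(int)
    km = km_estimate(df)
    assert np.all(np.diff(km.survival) <= 1e-12)
    assert np.all(km.survival <= 1.0) and np.all(km.survival >= 0.0)
    if km.event_times.size > 1:
        assert np.all(np.diff(km.at_risk) < 0)


# ---------------------------------------------------------------------------
# log-rank


def brute_force_logrank(df, group_col):
    """O-E with hypergeometric variance, tabulated per event time."""
    groups = sorted(df[group_col].unique())
    gref = groups[0]
    O = E = V = 0.0
    for t in sorted(df.loc[df.event == 1, "time"].unique()):
        at_risk = df[df.time >= t]
        d = int((df.event[(df.time == t)] == 1).sum())
        n = len(at_risk)
        n1 = int((at_risk[group_col] == gref).sum())
        d1 = int(((at_risk[group_col] == gref) & (at_risk.time == t)
                  & (at_risk.event == 1)).sum())
        O += d1
        E += d * n1 / n
        if n > 1:
            V += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    return (O - E) ** 2 / V


def test_logrank_identical_groups_is_zero(toy_survival):
    df = pd.concat([toy_survival.assign(g="a"), toy_survival.assign(g="b")])
    res = logrank_test(df, "g")
    assert res.chi_square == pytest.approx(0.0, abs=1e-12)
    assert res.p_value == pytest.approx(1.0)


def test_logrank_matches_brute_force_on_toy_table():
    df = pd.DataFrame({"time": [1.0, 3.0, 2.0, 4.0], "event": [1, 0, 1, 1],
                       "g": ["a", "a", "b", "b"]})
    res = logrank_test(df, "g")
    assert res.chi_square == pytest.approx(brute_force_logrank(df, "g"), rel=1e-10)
    assert res.df == 1


def test_logrank_invariant_to_label_swap():
    rng = np.random.default_rng(1)
    df = pd.DataFrame({"time": rng.exponential(1, 100),
                       "event": rng.binomial(1, 0.7, 100),
                       "g": rng.choice(["a", "b"], 100)})
    r1 = logrank_test(df, "g")
    df2 = df.assign(g=df.g.map({"a": "b", "b": "a"}))
    r2 = logrank_test(df2, "g")
    assert r1.chi_square == pytest.approx(r2.chi_square, rel=1e-12)


def test_logrank_single_group_raises():
    df = pd.DataFrame({"time": [1.0, 2.0], "event": [1, 1], "g": ["a", "a"]})
    with pytest.raises(ValueError):
        logrank_test(df, "g")


# ---------------------------------------------------------------------------
# Cox


def test_cox_matches_grid_search_on_toy_data():
    toy = pd.DataFrame({"time": [1.0, 2.0, 3.0, 4.0, 5.0],
                        "event": [1, 1, 1, 1, 0],
                        "x": [1.0, 0.0, 1.0, 0.0, 1.0]})
    fit = CoxPHModel(terms=("x",)).fit(toy)

    def pll(b):
        eta = toy.x.to_numpy() * b
        t, d = toy.time.to_numpy(), toy.event.to_numpy()
        return sum(eta[i] - np.log(np.exp(eta[t >= t[i]]).sum())
                   for i in range(len(t)) if d[i])

    grid = np.linspace(-3, 3, 60001)
    best = grid[int(np.argmax([pll(b) for b in grid]))]
    assert fit.coef_[0] == pytest.approx(best, abs=1e-4)
    assert fit.loglik_ == pytest.approx(pll(fit.coef_[0]), abs=1e-10)


def test_cox_null_covariate_gives_zero_coefficient_and_null_loglik():
    df = pd.DataFrame({"time": [1.0, 2.0, 3.0, 4.0], "event": [1, 1, 0, 1],
                       "x": [0.0, 0.0, 0.0, 0.0]})
    with pytest.warns(UserWarning, match="constant"):
        fit = CoxPHModel(terms=("x",)).fit(df)
    assert fit.coef_[0] == 0.0
    assert fit.loglik_ == pytest.approx(fit.null_loglik_, abs=1e-12)


def test_cox_agrees_with_lifelines_without_ties():
    lifelines = pytest.importorskip("lifelines")
    rng = np.random.default_rng(5)
    n = 300
    x = rng.binomial(1, 0.5, n).astype(float)
    z = rng.normal(0, 1, n)
    t = rng.exponential(np.exp(-0.7 * x - 0.3 * z))
    cens = rng.exponential(1.5, n)
    df = pd.DataFrame({"time": np.minimum(t, cens),
                       "event": (t <= cens).astype(int), "x": x, "z": z})
    ours = CoxPHModel(terms=("x", "z")).fit(df)
    cph = lifelines.CoxPHFitter().fit(df, "time", "event")
    assert np.allclose(ours.coef_, cph.params_.to_numpy(), atol=1e-5)
    assert np.allclose(ours.params_["se"], cph.standard_errors_.to_numpy(), atol=1e-5)


def test_cox_recovers_generating_log_hazard_ratio():
    """Mean estimate near the generating log-HR 0.7 over replicates."""
    rng = np.random.default_rng(11)
    ests = []
    for _ in range(60):
        n = 500
        x = rng.binomial(1, 0.5, n).astype(float)
        t = rng.exponential(np.exp(-0.7 * x))
        cens = rng.exponential(2.0, n)
        df = pd.DataFrame({"time": np.minimum(t, cens),
                           "event": (t <= cens).astype(int), "x": x})
        ests.append(CoxPHModel(terms=("x",)).fit(df).coef_[0])
    assert abs(np.mean(ests) - 0.7) < 0.05


# ---------------------------------------------------------------------------
# proportional-hazards diagnostic


def _sim_ph(n, rng, decay=False):
    x = rng.binomial(1, 0.5, n).astype(float)
    if decay:
        # piecewise hazards: effect present early, gone late
        t0 = rng.exponential(np.exp(-1.2 * x))
        t = np.where(t0 < 0.3, t0, 0.3 + rng.exponential(1.0, n))
    else:
        t = rng.exponential(np.exp(-0.7 * x))
    cens = rng.exponential(2.0, n)
    return pd.DataFrame({"time": np.minimum(t, cens),
                         "event": (t <= cens).astype(int), "x": x})


def test_ph_test_type_one_error_near_nominal():
    rng = np.random.default_rng(21)
    rej = 0
    n_rep = 300
    for _ in range(n_rep):
        df = _sim_ph(150, rng)
        p = ph_test(df, ("x",)).set_index("covariate").loc["x", "p_value"]
        rej += p < 0.05
    rate = rej / n_rep
    assert 0.02 < rate < 0.09


def test_ph_test_detects_decaying_hazard_ratio():
    rng = np.random.default_rng(22)
    hits = 0
    for _ in range(25):
        df = _sim_ph(500, rng, decay=True)
        p = ph_test(df, ("x",)).set_index("covariate").loc["GLOBAL", "p_value"]
        hits += p < 0.05
    assert hits >= 20  # power > 80%


# ---------------------------------------------------------------------------
# Weibull


def test_weibull_exponential_special_case_closed_form():
    rng = np.random.default_rng(3)
    t = rng.exponential(2.0, 500)
    df = pd.DataFrame({"time": t, "event": 1})
    fit = WeibullRegressionModel(terms=(), fixed_shape=1.0).fit(df)
    assert fit.scale_ == pytest.approx(len(t) / t.sum(), rel=1e-8)


def test_weibull_all_censored_raises():
    df = pd.DataFrame({"time": [1.0, 2.0], "event": [0, 0]})
    with pytest.raises(ValueError, match="censor"):
        weibull_fit(df, ())


def _sim_weibull(n, rng, rho=1.5, beta=0.8):
    x = rng.binomial(1, 0.5, n).astype(float)
    lam = 0.5
    e = rng.exponential(1.0, n)
    t = (e / (lam * np.exp(beta * x))) ** (1 / rho)
    cens = rng.exponential(np.quantile(t, 0.9), n)
    return pd.DataFrame({"time": np.minimum(t, cens),
                         "event": (t <= cens).astype(int), "x": x}), lam, rho, beta


def test_weibull_parameter_recovery_within_two_se():
    rng = np.random.default_rng(7)
    hits_rho = hits_beta = 0
    n_rep = 60
    for _ in range(n_rep):
        df, lam, rho, beta = _sim_weibull(400, rng)
        fit = WeibullRegressionModel(terms=("x",)).fit(df)
        hits_rho += abs(fit.shape_ - rho) <= 2 * fit.shape_se_
        hits_beta += abs(fit.ph_params_.loc["x", "estimate"] - beta) <= \
            2 * fit.ph_params_.loc["x", "se"]
    assert hits_rho / n_rep >= 0.9
    assert hits_beta / n_rep >= 0.9


def test_weibull_parameterization_conversion_identity():
    rng = np.random.default_rng(9)
    df, *_ = _sim_weibull(300, rng)
    fit = WeibullRegressionModel(terms=("x",)).fit(df)
    ph = fit.ph_params_["estimate"].to_numpy()
    aft = fit.aft_params_["estimate"].to_numpy()[1:-1]
    assert np.allclose(ph, -aft * fit.shape_, atol=1e-10)


def test_weibull_matches_lifelines_aft():
    lifelines = pytest.importorskip("lifelines")
    rng = np.random.default_rng(13)
    df, *_ = _sim_weibull(400, rng)
    ours = WeibullRegressionModel(terms=("x",)).fit(df)
    aft = lifelines.WeibullAFTFitter().fit(df, "time", "event")
    assert ours.shape_ == pytest.approx(
        np.exp(aft.params_[("rho_", "Intercept")]), rel=1e-4)
    assert ours.aft_params_.loc["x", "estimate"] == pytest.approx(
        aft.params_[("lambda_", "x")], abs=1e-4)


def test_weibull_optimum_dominates_perturbations():
    rng = np.random.default_rng(15)
    df, *_ = _sim_weibull(200, rng)
    fit = WeibullRegressionModel(terms=("x",)).fit(df)
    beta = fit.ph_params_["estimate"].to_numpy()
    ll_opt = fit.loglik_
    for _ in range(50):
        pert = rng.normal(0, 0.05, 3)
        ll = fit.loglik_at(fit.scale_ * np.exp(pert[0]),
                           fit.shape_ * np.exp(pert[1] * 0.2),
                           beta + pert[2:], data=df)
        assert ll <= ll_opt + 1e-9


def test_ratio_table_exponentiates_estimates_and_ci():
    tab = pd.DataFrame({"estimate": [0.0, 1.0],
                        "ci_low": [-0.5, 0.5], "ci_high": [0.5, 1.5]},
                       index=["a", "b"])
    out = ratio_table(tab)
    assert out.loc["a", "ratio"] == pytest.approx(1.0)
    assert out.loc["b", "ratio"] == pytest.approx(np.e)
    assert out.loc["a", "ratio_ci_low"] == pytest.approx(np.exp(-0.5))
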