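"""Survival analysis under right censoring: Kaplan-Meier, log-rank, Cox PH with
a log(time)-interaction proportionality diagnostic, and Weibull regression.

Kaplan-Meier curves and the log-rank test are computed through lifelines. The
Cox partial likelihood (Breslow ties) and the Weibull likelihood are maximized
by Newton-Raphson here, because the proportional-hazards diagnostic needs
risk-set internals and the Weibull fit is reported in two linked
parameterizations:

* ``PH_loghazard``: hazard h(t) = lambda * rho * t**(rho-1) * exp(x'b);
  exp(b) is a hazard ratio (>1 means higher death risk).
* ``AFT_logtime``: log T = mu + x'b_aft + sigma*W (Gumbel W); coefficients act
  multiplicatively on survival time.

The exact conversion is b_PH = -b_AFT * rho, mu = -log(lambda)/rho,
sigma = 1/rho; both tables are always available on a fit.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test
from scipy import stats
from sklearn.base import BaseEstimator

import warnings

from ._design import term_columns
from .cohort import CohortTable


def _surv_frame(data) -> pd.DataFrame:
    if isinstance(data, CohortTable):
        return data.merged_survival()
    return data


def _design_no_intercept(df, terms, drop_constant=False):
    """Covariate design without intercept. Constant columns are kept with a
    warning (their partial-likelihood score is identically zero) or dropped
    when they would alias an explicit baseline parameter."""
    blocks, names = [], []
    for term in terms:
        cols, cnames = term_columns(df, term)
        blocks.append(cols)
        names.extend(cnames)
    X = np.hstack(blocks) if blocks else np.empty((len(df), 0))
    const = [j for j in range(X.shape[1]) if np.ptp(X[:, j]) == 0]
    if const:
        cn = [names[j] for j in const]
        warnings.warn(f"constant covariate column(s) {cn}: no information in the data")
        if drop_constant:
            keep = [j for j in range(X.shape[1]) if j not in const]
            X = X[:, keep]
            names = [names[j] for j in keep]
            const = []
    varying = [j for j in range(X.shape[1]) if j not in const]
    if varying and np.linalg.matrix_rank(X[:, varying]) < len(varying):
        raise ValueError("covariate design is rank deficient (collinear columns)")
    return X, names


# ---------------------------------------------------------------------------
# Kaplan-Meier


@dataclass
class KMCurve:
    """Product-limit estimate: right-continuous non-increasing step function."""

    event_times: np.ndarray
    survival: np.ndarray
    at_risk: np.ndarray
    events: np.ndarray
    median: float = np.nan
    median_defined: bool = False
    label: str | None = None

    def survival_at(self, t) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        idx = np.searchsorted(self.event_times, t, side="right")
        s = np.concatenate([[1.0], self.survival])
        return s[idx]

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time": self.event_times,
                "survival": self.survival,
                "at_risk": self.at_risk,
                "events": self.events,
            }
        )


def km_estimate(data, duration_col="time", event_col="event", group_col=None):
    """Kaplan-Meier curve(s); returns a KMCurve or dict {group: KMCurve}.

    The median is the smallest time with S(t) <= 0.5; ``median_defined`` is
    False when the curve never reaches 0.5.
    """
    df = _surv_frame(data)
    if group_col is None:
        return _km_single(df[duration_col], df[event_col], None)
    out = {}
    for g, sub in df.groupby(group_col, observed=True):
        if len(sub) == 0:
            raise ValueError(f"empty group {g!r}")
        out[g] = _km_single(sub[duration_col], sub[event_col], str(g))
    if not out:
        raise ValueError(f"no groups found in column {group_col!r}")
    return out


def _km_single(durations, events, label):
    durations = np.asarray(durations, dtype=float)
    events = np.asarray(events)
    if durations.size == 0:
        raise ValueError(f"empty group {label!r}")
    if np.any(durations < 0):
        raise ValueError("negative survival times")
    kmf = KaplanMeierFitter()
    kmf.fit(durations, events)
    tab = kmf.event_table
    ev = tab[tab["observed"] > 0]
    times = ev.index.to_numpy(dtype=float)
    at_risk = ev["at_risk"].to_numpy(dtype=float)
    d = ev["observed"].to_numpy(dtype=float)
    surv = kmf.survival_function_at_times(times).to_numpy()
    below = np.where(surv <= 0.5)[0]
    if below.size:
        median, defined = float(times[below[0]]), True
    else:
        median, defined = np.nan, False
    return KMCurve(times, surv, at_risk, d, median, defined, label)


# ---------------------------------------------------------------------------
# log-rank


@dataclass
class LogRankResult:
    chi_square: float
    df: int
    p_value: float


def logrank_test(data, group_col, duration_col="time", event_col="event") -> LogRankResult:
    """Observed-minus-expected log-rank test across the groups of ``group_col``."""
    df = _surv_frame(data)
    groups = df[group_col]
    k = groups.nunique()
    if k < 2:
        raise ValueError("log-rank test needs at least two non-empty groups")
    res = multivariate_logrank_test(df[duration_col], groups, df[event_col])
    return LogRankResult(float(res.test_statistic), k - 1, float(res.p_value))


# ---------------------------------------------------------------------------
# Cox proportional hazards (Breslow ties)


class CoxPHModel(BaseEstimator):
    """Cox proportional-hazards regression, Newton-Raphson on the Breslow
    partial likelihood; convergence when the score norm drops below ``tol``."""

    def __init__(self, terms=(), tol=1e-8, max_iter=100):
        self.terms = terms
        self.tol = tol
        self.max_iter = max_iter

    def fit(self, data, duration_col="time", event_col="event"):
        df = _surv_frame(data).reset_index(drop=True)
        X, names = _design_no_intercept(df, tuple(self.terms))
        t = df[duration_col].to_numpy(dtype=float)
        d = df[event_col].to_numpy(dtype=int)
        if d.sum() == 0:
            raise ValueError("no events observed; Cox model is not estimable")
        order = np.argsort(t, kind="mergesort")
        self._t, self._d, self._X = t[order], d[order], X[order]
        self._names = names
        p = X.shape[1]
        beta = np.zeros(p)
        ll = self._loglik(beta)
        for it in range(self.max_iter):
            U, I = self._score_info(beta)
            if np.linalg.norm(U) < self.tol:
                break
            try:
                step = np.linalg.solve(I, U)
            except np.linalg.LinAlgError:
                step = np.linalg.lstsq(I, U, rcond=None)[0]
            # step-halving
            lam = 1.0
            for _ in range(30):
                cand = beta + lam * step
                ll_new = self._loglik(cand)
                if ll_new >= ll - 1e-12:
                    break
                lam /= 2
            beta, ll = cand, ll_new
            if np.abs(beta).max() > 50:
                worst = names[int(np.argmax(np.abs(beta)))]
                raise RuntimeError(
                    f"monotone partial likelihood (perfect separation?); "
                    f"coefficient for {worst!r} is diverging"
                )
        else:
            raise RuntimeError(
                f"Cox Newton-Raphson did not converge in {self.max_iter} iterations; "
                f"final score norm {np.linalg.norm(U):.3g}"
            )
        U, I = self._score_info(beta)
        self.coef_ = beta
        self.loglik_ = float(ll)
        self.null_loglik_ = float(self._loglik(np.zeros(p)))
        with np.errstate(invalid="ignore"):
            try:
                cov = np.linalg.inv(I)
            except np.linalg.LinAlgError:
                cov = np.linalg.pinv(I)
        se = np.sqrt(np.abs(np.diag(cov)))
        se[se == 0] = np.inf
        z = np.divide(beta, se, out=np.zeros_like(beta), where=se > 0)
        self.cov_ = cov
        self.params_ = pd.DataFrame(
            {
                "estimate": beta,
                "se": se,
                "z": z,
                "p": 2 * stats.norm.sf(np.abs(z)),
                "hazard_ratio": np.exp(beta),
            },
            index=names,
        )
        self.converged_ = True
        return self

    # Breslow partial likelihood with suffix-sum risk sets
    def _risk_quantities(self, beta, want_info=False):
        X, t, d = self._X, self._t, self._d
        eta = X @ beta
        w = np.exp(eta - eta.max())
        logshift = eta.max()
        # suffix sums over subjects ordered by time ascending
        s0 = np.cumsum(w[::-1])[::-1]
        s1 = np.cumsum((w[:, None] * X)[::-1], axis=0)[::-1]
        s2 = None
        if want_info:
            xxw = np.einsum("i,ij,ik->ijk", w, X, X)
            s2 = np.cumsum(xxw[::-1], axis=0)[::-1]
        # tie groups: first index of each distinct time
        first = np.concatenate([[0], 1 + np.where(np.diff(t) > 0)[0]])
        grp = np.searchsorted(t[first], t)  # group id per subject
        start = first[grp]  # risk-set start index per subject
        return w, logshift, s0, s1, s2, start

    def _loglik(self, beta):
        X, d = self._X, self._d
        eta = X @ beta
        w, shift, s0, s1, s2, start = self._risk_quantities(beta)
        return float(np.sum(d * (eta - (np.log(s0[start]) + shift))))

    def _score_info(self, beta):
        X, d = self._X, self._d
        w, shift, s0, s1, s2, start = self._risk_quantities(beta, want_info=True)
        xbar = s1[start] / s0[start][:, None]
        U = (d[:, None] * (X - xbar)).sum(axis=0)
        Vt = s2[start] / s0[start][:, None, None] - np.einsum("ij,ik->ijk", xbar, xbar)
        I = np.einsum("i,ijk->jk", d.astype(float), Vt)
        return U, I

    def event_quantities(self):
        """Per-event risk-set mean and covariance of the covariates, plus the
        Schoenfeld residuals (used by the proportionality diagnostic)."""
        w, shift, s0, s1, s2, start = self._risk_quantities(self.coef_, want_info=True)
        ev = self._d == 1
        xbar = s1[start] / s0[start][:, None]
        Vt = s2[start] / s0[start][:, None, None] - np.einsum("ij,ik->ijk", xbar, xbar)
        return {
            "time": self._t[ev],
            "x": self._X[ev],
            "xbar": xbar[ev],
            "V": Vt[ev],
            "schoenfeld": self._X[ev] - xbar[ev],
        }


def cox_fit(data, terms, duration_col="time", event_col="event", **kwargs) -> CoxPHModel:
    return CoxPHModel(terms=terms, **kwargs).fit(data, duration_col, event_col)


def ph_test(data, terms, duration_col="time", event_col="event") -> pd.DataFrame:
    """Score test for covariate-by-log(time) interactions in the Cox model.

    For each covariate a 1-df-per-column (joint over dummy columns) score
    chi-square of adding x*log(t) to the fitted model; the ``GLOBAL`` row tests
    all interactions jointly. Small p-values indicate non-proportional hazards.
    """
    fit = CoxPHModel(terms=terms).fit(data, duration_col, event_col)
    q = fit.event_quantities()
    tt = q["time"]
    if np.any(tt <= 0):
        raise ValueError("event times must be positive for the log(time) diagnostic")
    g = np.log(tt)
    sch = q["schoenfeld"]
    V = q["V"]
    p = sch.shape[1]
    U_theta = (g[:, None] * sch).sum(axis=0)
    I_tt = np.einsum("i,ijk->jk", g * g, V)
    I_tb = np.einsum("i,ijk->jk", g, V)
    I_bb = np.einsum("ijk->jk", V)
    I_bb_inv = np.linalg.pinv(I_bb)

    def block_stat(cols):
        cols = np.asarray(cols)
        Ueff = U_theta[cols]
        Ieff = I_tt[np.ix_(cols, cols)] - I_tb[cols] @ I_bb_inv @ I_tb[:, cols]
        stat = float(Ueff @ np.linalg.solve(Ieff, Ueff))
        return stat, len(cols)

    names = fit._names
    rows = []
    for term in fit.terms:
        cols = [j for j, nm in enumerate(names) if nm == term or nm.startswith(f"{term}[")]
        if not cols:
            continue
        stat, dof = block_stat(cols)
        rows.append({"covariate": term, "chi_square": stat, "df": dof,
                     "p_value": float(stats.chi2.sf(stat, dof))})
    stat, dof = block_stat(list(range(p)))
    rows.append({"covariate": "GLOBAL", "chi_square": stat, "df": dof,
                 "p_value": float(stats.chi2.sf(stat, dof))})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Weibull regression


PARAMETERIZATIONS = ("PH_loghazard", "AFT_logtime")


class WeibullRegressionModel(BaseEstimator):
    """Weibull survival regression by Newton-Raphson on the censored likelihood

        l = sum_i [ delta_i * log f(t_i) + (1 - delta_i) * log S(t_i) ]

    fitted on the proportional-hazards scale and reported in the declared
    parameterization (with the exact PH <-> AFT conversion always available).
    """

    def __init__(self, terms=(), parameterization="PH_loghazard",
                 fixed_shape=None, tol=1e-8, max_iter=100):
        self.terms = terms
        self.parameterization = parameterization
        self.fixed_shape = fixed_shape
        self.tol = tol
        self.max_iter = max_iter

    # internal parameter vector: [log lambda, log rho, beta_PH...]
    def _unpack(self, theta):
        if self.fixed_shape is None:
            return theta[0], theta[1], theta[2:]
        return theta[0], np.log(self.fixed_shape), theta[1:]

    def _loglik_grad(self, theta, t, d, X, logt):
        a, r, beta = self._unpack(theta)
        rho = np.exp(r)
        eta = X @ beta if X.shape[1] else np.zeros(len(t))
        logLam = a + rho * logt + eta
        Lam = np.exp(logLam)
        ll = np.sum(d * (a + r + (rho - 1) * logt + eta) - Lam)
        ga = np.sum(d - Lam)
        gr = np.sum(d * (1 + rho * logt) - rho * logt * Lam)
        gb = X.T @ (d - Lam) if X.shape[1] else np.empty(0)
        if self.fixed_shape is None:
            grad = np.concatenate([[ga, gr], gb])
        else:
            grad = np.concatenate([[ga], gb])
        return float(ll), grad

    def fit(self, data, duration_col="time", event_col="event"):
        if self.parameterization not in PARAMETERIZATIONS:
            raise ValueError(f"parameterization must be one of {PARAMETERIZATIONS}")
        df = _surv_frame(data).reset_index(drop=True)
        X, names = _design_no_intercept(df, tuple(self.terms), drop_constant=True)
        t = df[duration_col].to_numpy(dtype=float)
        d = df[event_col].to_numpy(dtype=int)
        if np.any(t <= 0):
            raise ValueError("survival times must be positive")
        if d.sum() == 0:
            raise ValueError("all observations censored; Weibull shape is not identifiable")
        logt = np.log(t)
        p = X.shape[1]
        n_core = 1 if self.fixed_shape is not None else 2
        theta = np.zeros(n_core + p)
        theta[0] = np.log(d.sum() / t.sum())  # exponential rate start
        ll, grad = self._loglik_grad(theta, t, d, X, logt)
        for it in range(self.max_iter):
            if np.linalg.norm(grad) < self.tol:
                break
            H = self._num_hessian(theta, t, d, X, logt)
            try:
                step = np.linalg.solve(-H, grad)
            except np.linalg.LinAlgError:
                step = np.linalg.lstsq(-H, grad, rcond=None)[0]
            lam = 1.0
            for _ in range(40):
                cand = theta + lam * step
                ll_new, grad_new = self._loglik_grad(cand, t, d, X, logt)
                if np.isfinite(ll_new) and ll_new >= ll - 1e-12:
                    break
                lam /= 2
            theta, ll, grad = cand, ll_new, grad_new
        else:
            raise RuntimeError(
                f"Weibull Newton-Raphson did not converge; score norm "
                f"{np.linalg.norm(grad):.3g} after {self.max_iter} iterations"
            )
        H = self._num_hessian(theta, t, d, X, logt)
        cov = np.linalg.inv(-H)
        self._theta = theta
        self._cov_theta = cov
        self.loglik_ = float(ll)
        a, r, beta = self._unpack(theta)
        self.scale_ = float(np.exp(a))
        self.shape_ = float(np.exp(r))
        self.coef_names_ = names
        self._build_tables(names, p)
        self.converged_ = True
        return self

    def _num_hessian(self, theta, t, d, X, logt, h=1e-6):
        k = len(theta)
        H = np.zeros((k, k))
        for j in range(k):
            e = np.zeros(k)
            e[j] = h * max(1.0, abs(theta[j]))
            _, gp = self._loglik_grad(theta + e, t, d, X, logt)
            _, gm = self._loglik_grad(theta - e, t, d, X, logt)
            H[:, j] = (gp - gm) / (2 * e[j])
        return 0.5 * (H + H.T)

    def _build_tables(self, names, p):
        theta, cov = self._theta, self._cov_theta
        rho = self.shape_
        if self.fixed_shape is None:
            a_i, r_i, b_sl = 0, 1, slice(2, None)
        else:
            a_i, r_i, b_sl = 0, None, slice(1, None)
        beta_ph = theta[b_sl]
        se_ph = np.sqrt(np.diag(cov)[b_sl])
        # PH table (covariates only)
        self.ph_params_ = _coef_table(names, beta_ph, se_ph)
        # AFT via delta method on the full theta vector
        a = theta[a_i]
        mu = -a / rho
        beta_aft = -beta_ph / rho
        sigma = 1.0 / rho
        k = len(theta)
        J = np.zeros((p + 2, k))  # rows: mu, beta_aft..., sigma
        J[0, a_i] = -1.0 / rho
        if r_i is not None:
            J[0, r_i] = a / rho  # d mu / d r = a/rho (r = log rho)
            J[-1, r_i] = -1.0 / rho
        for j in range(p):
            J[1 + j, (2 if self.fixed_shape is None else 1) + j] = -1.0 / rho
            if r_i is not None:
                J[1 + j, r_i] = beta_ph[j] / rho
        cov_aft = J @ cov @ J.T
        aft_est = np.concatenate([[mu], beta_aft, [sigma]])
        aft_se = np.sqrt(np.abs(np.diag(cov_aft)))
        self.aft_params_ = _coef_table(["intercept"] + names + ["log_scale(sigma)"],
                                       aft_est, aft_se)
        self.params_ = (self.ph_params_ if self.parameterization == "PH_loghazard"
                        else self.aft_params_.iloc[1:-1] if p else self.aft_params_)
        self.ratios_ = np.exp(self.params_["estimate"].to_numpy())
        se_r = np.sqrt(np.diag(cov)[r_i]) if r_i is not None else 0.0
        self.shape_se_ = float(self.shape_ * se_r)

    def loglik_at(self, scale, shape, beta, data=None, duration_col="time",
                  event_col="event", t=None, d=None, X=None):
        """Evaluate the censored Weibull log-likelihood at given PH parameters."""
        if t is None:
            df = _surv_frame(data).reset_index(drop=True)
            X, _ = _design_no_intercept(df, tuple(self.terms), drop_constant=True)
            t = df[duration_col].to_numpy(dtype=float)
            d = df[event_col].to_numpy(dtype=int)
        beta = np.asarray(beta, dtype=float)
        eta = X @ beta if X.shape[1] else np.zeros(len(t))
        Lam = scale * t**shape * np.exp(eta)
        return float(np.sum(d * (np.log(scale * shape) + (shape - 1) * np.log(t) + eta) - Lam))


def _coef_table(names, est, se):
    z = np.divide(est, se, out=np.zeros_like(est), where=se > 0)
    zq = stats.norm.ppf(0.975)
    return pd.DataFrame(
        {
            "estimate": est,
            "se": se,
            "z": z,
            "p": 2 * stats.norm.sf(np.abs(z)),
            "ci_low": est - zq * se,
            "ci_high": est + zq * se,
        },
        index=names,
    )


def weibull_fit(data, terms, parameterization="PH_loghazard", **kwargs) -> WeibullRegressionModel:
    return WeibullRegressionModel(terms=terms, parameterization=parameterization,
                                  **kwargs).fit(data)


def ratio_table(fit_or_table, ci=True) -> pd.DataFrame:
    """Elementwise exp() of a coefficient table: exp(estimate) and exp(CI).

    Accepts a fitted :class:`WeibullRegressionModel` (or any object with a
    ``params_`` table) or a DataFrame with an ``estimate`` column (optionally
    ``ci_low``/``ci_high`` or ``se``).
    """
    tab = getattr(fit_or_table, "params_", fit_or_table)
    out = pd.DataFrame(index=tab.index)
    out["estimate"] = tab["estimate"]
    out["ratio"] = np.exp(tab["estimate"])
    if ci:
        if {"ci_low", "ci_high"} <= set(tab.columns):
            lo, hi = tab["ci_low"], tab["ci_high"]
        elif "se" in tab.columns:
            zq = stats.norm.ppf(0.975)
            lo, hi = tab["estimate"] - zq * tab["se"], tab["estimate"] + zq * tab["se"]
        else:
            return out
        out["ratio_ci_low"] = np.exp(lo)
        out["ratio_ci_high"] = np.exp(hi)
    return out
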