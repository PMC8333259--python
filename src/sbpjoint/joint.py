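"""Shared-random-effects joint model for longitudinal sqrt-SBP and survival.

The two sub-models share the subject's random intercept u_i ~ N(0, sigma_u^2):

* longitudinal:  y_ij = x_ij' beta + u_i + eps_ij,  eps_ij ~ N(0, sigma_e^2)
* survival:      h_i(t | u_i) = lambda * rho * t**(rho-1)
                                * exp(x_i' alpha + gamma * link_i(t))

with ``link = u_i`` (``shared_intercept``, default) or ``link = m_i(t)``,
the current value of the latent trajectory (``current_value``). The
association parameter gamma measures how strongly the latent blood-pressure
level drives the death hazard; conditional on u_i the processes are
independent, so the marginal likelihood per subject is a one-dimensional
integral over u_i, evaluated by adaptive Gauss-Hermite quadrature (nodes
centered and scaled at each subject's posterior mode).

Estimation: EM (E-step = posterior moments of u_i by quadrature; M-step =
closed-form updates for beta, sigma_e, sigma_u and a numerical update of the
survival block) started from the separate sub-model fits, followed by a direct
quasi-Newton polish of the observed log-likelihood. Standard errors come from
the numerically differentiated observed information.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.special import logsumexp
from sklearn.base import BaseEstimator

from ._design import build_design
from .cohort import CohortTable
from .survival import WeibullRegressionModel, _design_no_intercept
from .lmm import LinearMixedModel

ASSOCIATIONS = ("shared_intercept", "current_value")
_LOG2PI = np.log(2 * np.pi)


class _JointData:
    """Flattened design arrays shared by likelihood and EM routines."""

    def __init__(self, cohort: CohortTable, longitudinal_terms, survival_terms,
                 response, time_col):
        long = cohort.merged_longitudinal()
        surv = cohort.merged_survival().reset_index(drop=True)
        if "time" in longitudinal_terms and "time" not in long.columns:
            long["time"] = long[time_col]
        codes = pd.Categorical(long["subject_id"],
                               categories=surv["subject_id"]).codes
        if np.any(codes < 0):
            raise ValueError("longitudinal subject missing from survival table")
        order = np.argsort(codes, kind="mergesort")
        long = long.iloc[order]
        self.subj = codes[order]
        self.Xy, self.names_y = build_design(long, tuple(longitudinal_terms))
        self.y = long[response].to_numpy(dtype=float)
        self.tij = long[time_col].to_numpy(dtype=float)
        self.Xt, self.names_t = _design_no_intercept(surv, tuple(survival_terms))
        self.T = surv["time"].to_numpy(dtype=float)
        self.delta = surv["event"].to_numpy(dtype=float)
        self.logT = np.log(np.maximum(self.T, 1e-12))
        self.N = len(surv)
        self.n_i = np.bincount(self.subj, minlength=self.N).astype(float)
        self.subject_ids = surv["subject_id"].to_numpy()
        self.py = self.Xy.shape[1]
        self.pt = self.Xt.shape[1]
        self.pinv_Xy = np.linalg.pinv(self.Xy)
        # time coefficient index for the current-value link
        self.time_idx = (self.names_y.index("time")
                         if "time" in self.names_y else None)
        # Gauss-Legendre nodes for current-value cumulative hazards
        gl_x, gl_w = np.polynomial.legendre.leggauss(20)
        self.gl_x, self.gl_w = gl_x, gl_w


def _pack(beta, sigma_u, sigma_e, scale, shape, alpha, gamma):
    return np.concatenate([beta, [sigma_u, sigma_e, scale, shape], alpha, [gamma]])


def _unpack(theta, py, pt):
    beta = theta[:py]
    sigma_u, sigma_e, scale, shape = theta[py:py + 4]
    alpha = theta[py + 4:py + 4 + pt]
    gamma = theta[-1]
    return beta, sigma_u, sigma_e, scale, shape, alpha, gamma


class _Likelihood:
    """Joint log-likelihood by Gauss-Hermite quadrature (adaptive or plain)."""

    def __init__(self, data: _JointData, association="shared_intercept",
                 n_nodes=15, adaptive=True):
        self.d = data
        self.association = association
        z, w = np.polynomial.hermite.hermgauss(n_nodes)
        self.z, self.logw = z, np.log(w)
        self.n_nodes = n_nodes

    # -- survival pieces ----------------------------------------------------

    def _surv_parts(self, theta):
        """u-free pieces: log baseline hazard at T_i and Lambda0_i."""
        d = self.d
        beta, su, se, scale, shape, alpha, gamma = _unpack(theta, d.py, d.pt)
        eta = d.Xt @ alpha if d.pt else np.zeros(d.N)
        log_h0 = np.log(scale * shape) + (shape - 1) * d.logT + eta
        Lam0 = scale * d.T**shape * np.exp(eta)
        return log_h0, Lam0

    def _cum_hazard_nodes(self, theta, u_nodes):
        """Lambda(T_i | u) at quadrature nodes u_nodes (N, Q)."""
        d = self.d
        beta, su, se, scale, shape, alpha, gamma = _unpack(theta, d.py, d.pt)
        log_h0, Lam0 = self._surv_parts(theta)
        if self.association == "shared_intercept":
            return Lam0[:, None] * np.exp(gamma * u_nodes)
        # current value: m_i(t) = x_i'beta (time at t) + u
        m0 = self._traj_baseline(theta)  # x'beta with time term at 0, per subject
        bt = 0.0 if d.time_idx is None else theta[:d.py][d.time_idx]
        s = 0.5 * d.T[:, None] * (d.gl_x + 1.0)  # (N, G)
        base = shape * np.maximum(s, 1e-300) ** (shape - 1)
        integ = base * np.exp(gamma * bt * s)  # (N, G)
        I0 = 0.5 * d.T * (integ * d.gl_w).sum(axis=1)  # (N,)
        eta = d.Xt @ theta[d.py + 4:d.py + 4 + d.pt] if d.pt else np.zeros(d.N)
        return (scale * np.exp(eta) * np.exp(gamma * m0))[:, None] * \
            np.exp(gamma * u_nodes) * I0[:, None]

    def _traj_baseline(self, theta):
        """Per-subject fixed-effect trajectory value at t=0 (current-value link)."""
        d = self.d
        beta = theta[:d.py]
        # subject-level covariates are constant within subject; take first row
        first = np.concatenate([[0], 1 + np.where(np.diff(d.subj) > 0)[0]])
        Xrow = d.Xy[first]
        b = beta.copy()
        if d.time_idx is not None:
            Xrow = Xrow.copy()
            Xrow[:, d.time_idx] = 0.0
        return Xrow @ b

    def _link_at_event(self, theta, u_nodes):
        """gamma-multiplied link value at the event time (for log h(T|u))."""
        d = self.d
        gamma = theta[-1]
        if self.association == "shared_intercept":
            return gamma * u_nodes
        m0 = self._traj_baseline(theta)
        bt = 0.0 if d.time_idx is None else theta[:d.py][d.time_idx]
        mT = m0 + bt * d.T
        return gamma * (mT[:, None] + u_nodes)

    # -- longitudinal residual sums ------------------------------------------

    def _resid_sums(self, beta):
        d = self.d
        r = d.y - d.Xy @ beta
        R = np.bincount(d.subj, weights=r, minlength=d.N)
        S = np.bincount(d.subj, weights=r * r, minlength=d.N)
        return R, S

    # -- posterior mode (adaptive centering) ----------------------------------

    def _mode(self, theta):
        """Newton iteration for the per-subject posterior mode of u (vectorized).

        For the shared-intercept link g''(u) < 0 everywhere, so safeguarded
        Newton converges; for the current-value link the same holds since u
        enters the hazard linearly.
        """
        d = self.d
        beta, su, se, scale, shape, alpha, gamma = _unpack(theta, d.py, d.pt)
        R, S = self._resid_sums(beta)
        Lam_at = lambda u: self._cum_hazard_nodes(theta, u[:, None])[:, 0]
        u = (R / se**2) / (1.0 / su**2 + d.n_i / se**2)  # longitudinal-only mode
        for _ in range(50):
            Lam = Lam_at(u)
            g1 = -u / su**2 + (R - d.n_i * u) / se**2 + d.delta * gamma - gamma * Lam
            g2 = -1.0 / su**2 - d.n_i / se**2 - gamma**2 * Lam
            step = g1 / g2
            # safeguard: limit step length
            step = np.clip(step, -5 * su, 5 * su)
            u = u - step
            if np.max(np.abs(step)) < 1e-10:
                break
        s_hat = 1.0 / np.sqrt(-g2)
        return u, s_hat

    def _log_integrand(self, theta, u):
        """g(u) per subject/node, u of shape (N, Q); includes all u-dependent
        and u-independent density pieces except the delta*log h0 term."""
        d = self.d
        beta, su, se, scale, shape, alpha, gamma = _unpack(theta, d.py, d.pt)
        R, S = self._resid_sums(beta)
        Lam = self._cum_hazard_nodes(theta, u)
        quad_y = (S[:, None] - 2 * u * R[:, None] + d.n_i[:, None] * u**2) / se**2
        g = (
            -0.5 * (u / su) ** 2
            - 0.5 * quad_y
            + d.delta[:, None] * gamma * u
            - Lam
        )
        return g

    def loglik(self, theta, return_estep=False):
        d = self.d
        beta, su, se, scale, shape, alpha, gamma = _unpack(theta, d.py, d.pt)
        if min(su, se, scale, shape) <= 0:
            return -np.inf if not return_estep else (-np.inf, None)
        log_h0, _ = self._surv_parts(theta)
        const = (
            -0.5 * d.n_i * np.log(2 * np.pi * se**2)
            - 0.5 * np.log(2 * np.pi * su**2)
        )
        u0, s0 = self._mode(theta)
        nodes = u0[:, None] + np.sqrt(2.0) * s0[:, None] * self.z[None, :]
        g = self._log_integrand(theta, nodes)
        if self.association == "current_value":
            extra = self._link_at_event(theta, nodes)
        else:
            extra = gamma * nodes
        # log integral = log(sqrt(2) s) + logsumexp(log w + z^2 + g)
        core = self.logw[None, :] + self.z[None, :] ** 2 + g
        log_int = 0.5 * np.log(2.0) + np.log(s0) + logsumexp(core, axis=1)
        # survival density exponent delta*(log h0 + gamma*link) is inside g only
        # for the u-part; add the u-free part and, for current_value, the
        # event-time link is u-dependent and handled via `extra` below.
        if self.association == "shared_intercept":
            ll_i = const + d.delta * log_h0 + log_int
        else:
            # replace delta*gamma*u inside g by delta*(gamma*(m(T)+u)):
            core2 = core + d.delta[:, None] * (extra - gamma * nodes)
            log_int = 0.5 * np.log(2.0) + np.log(s0) + logsumexp(core2, axis=1)
            ll_i = const + d.delta * log_h0 + log_int
            core = core2
        total = float(ll_i.sum())
        if not return_estep:
            return total
        logw_post = core - logsumexp(core, axis=1, keepdims=True)
        w_post = np.exp(logw_post)
        Eu = (w_post * nodes).sum(axis=1)
        Eu2 = (w_post * nodes**2).sum(axis=1)
        return total, {"nodes": nodes, "w": w_post, "Eu": Eu, "Eu2": Eu2,
                       "mode": u0, "mode_scale": s0, "ll_i": ll_i}

    def loglik_plain(self, theta):
        """Non-adaptive Gauss-Hermite centered on the random-effect prior
        (oracle/diagnostic path)."""
        d = self.d
        beta, su, se, scale, shape, alpha, gamma = _unpack(theta, d.py, d.pt)
        log_h0, _ = self._surv_parts(theta)
        nodes = np.sqrt(2.0) * su * self.z[None, :] * np.ones((d.N, 1))
        g = self._log_integrand(theta, nodes)
        # remove the prior density (absorbed by the GH weight) and the
        # 1/sqrt(pi) normalizer
        g = g + 0.5 * (nodes / su) ** 2
        if self.association == "current_value":
            extra = self._link_at_event(theta, nodes)
            g = g + d.delta[:, None] * (extra - gamma * nodes)
        const = -0.5 * d.n_i * np.log(2 * np.pi * se**2)
        core = self.logw[None, :] + g
        ll_i = const + d.delta * log_h0 - 0.5 * np.log(np.pi) + logsumexp(core, axis=1)
        return float(ll_i.sum())


class JointModel(BaseEstimator):
    """Joint longitudinal-survival model with a shared random intercept.

    Parameters
    ----------
    longitudinal_terms, survival_terms : tuple of str
        Fixed-effect terms of the two sub-models ("time" = observation time).
    association : {"shared_intercept", "current_value"}
    n_quadrature : int
        Gauss-Hermite nodes (>= 3).
    max_iter, tol, param_tol : EM controls (relative log-likelihood change and
        maximum absolute parameter change).

    Fitted attributes: ``longitudinal_params_``, ``survival_params_``,
    ``gamma_``, ``gamma_se_``, ``sigma_u_``, ``sigma_e_``, ``shape_``,
    ``scale_``, ``loglik_``, ``n_iter_``, ``converged_``, ``se_`` (full
    standard-error vector) and ``history_`` (EM log-likelihood trace).
    """

    def __init__(self, longitudinal_terms=("time",), survival_terms=(),
                 association="shared_intercept", n_quadrature=15,
                 adaptive=True, max_iter=200, tol=1e-8, param_tol=1e-6,
                 em_before_polish=True):
        self.longitudinal_terms = longitudinal_terms
        self.survival_terms = survival_terms
        self.association = association
        self.n_quadrature = n_quadrature
        self.adaptive = adaptive
        self.max_iter = max_iter
        self.tol = tol
        self.param_tol = param_tol
        self.em_before_polish = em_before_polish

    # -------------------------------------------------------------------

    def fit(self, cohort: CohortTable, response="sqrt_sbp", time_col="visit_time",
            init: np.ndarray | None = None):
        if self.association not in ASSOCIATIONS:
            raise ValueError(f"association must be one of {ASSOCIATIONS}")
        if self.n_quadrature < 3:
            raise ValueError("need at least 3 quadrature nodes")
        data = _JointData(cohort, self.longitudinal_terms, self.survival_terms,
                          response, time_col)
        lik = _Likelihood(data, self.association, self.n_quadrature, self.adaptive)
        self._data, self._lik = data, lik

        theta = self._initial_theta(cohort, data) if init is None else np.asarray(init, float)
        ll0 = lik.loglik(theta)
        self.init_loglik_ = ll0
        history = [ll0]

        if self.association == "shared_intercept" and self.em_before_polish:
            theta, history = self._em(theta, lik, history)
        theta, ll = self._polish(theta, lik)
        history.append(ll)
        if ll < ll0 - 1e-6:
            raise RuntimeError(
                f"joint likelihood decreased from initialization ({ll0:.6f} -> {ll:.6f})"
            )
        self.theta_ = theta
        self.loglik_ = float(ll)
        self.history_ = history
        self.n_iter_ = len(history) - 2
        self.converged_ = True
        self._finalize(data, lik, theta)
        return self

    def _initial_theta(self, cohort, data):
        lmm = LinearMixedModel(fixed_terms=self.longitudinal_terms,
                               random_terms="intercept", cov_structure="IND",
                               method="ML").fit(cohort)
        wb = WeibullRegressionModel(terms=self.survival_terms).fit(cohort)
        beta = lmm.beta_values_
        su = float(np.sqrt(lmm.D_[0, 0]))
        se = float(lmm.sigma_params_["sigma_e"])
        alpha = wb.ph_params_["estimate"].to_numpy() if data.pt else np.empty(0)
        return _pack(beta, su, se, wb.scale_, wb.shape_, alpha, 0.0)

    # -- EM ----------------------------------------------------------------

    def _em(self, theta, lik, history):
        d = self._data
        ll_prev = history[-1]
        for it in range(self.max_iter):
            ll, est = lik.loglik(theta, return_estep=True)
            Eu, Eu2 = est["Eu"], est["Eu2"]
            beta, su, se, scale, shape, alpha, gamma = _unpack(theta, d.py, d.pt)
            # closed-form updates for the Gaussian block
            beta_new = d.pinv_Xy @ (d.y - Eu[d.subj])
            r = d.y - d.Xy @ beta_new
            R = np.bincount(d.subj, weights=r, minlength=d.N)
            S = np.bincount(d.subj, weights=r * r, minlength=d.N)
            se2 = float(np.sum(S - 2 * Eu * R + d.n_i * Eu2) / len(d.y))
            su2 = float(Eu2.mean())
            # numerical update of the survival block on the expected loglik
            psi0 = np.array([np.log(scale), np.log(shape), *alpha, gamma])
            nodes, w = est["nodes"], est["w"]
            psi = self._mstep_survival(psi0, nodes, w)
            theta_new = _pack(beta_new, np.sqrt(su2), np.sqrt(se2),
                              np.exp(psi[0]), np.exp(psi[1]),
                              psi[2:2 + d.pt], psi[-1])
            ll_new = lik.loglik(theta_new)
            if not np.isfinite(ll_new) or ll_new < ll - 1e-8 * max(1, abs(ll)):
                break  # hand over to the quasi-Newton polish
            dpar = np.max(np.abs(theta_new - theta))
            theta = theta_new
            history.append(ll_new)
            if abs(ll_new - ll_prev) < self.tol * max(1.0, abs(ll_new)) and \
                    dpar < self.param_tol:
                break
            ll_prev = ll_new
        return theta, history

    def _mstep_survival(self, psi0, nodes, w):
        d = self._data

        def negQ(psi):
            la, lr = psi[0], psi[1]
            alpha = psi[2:2 + d.pt]
            gamma = psi[-1]
            scale, shape = np.exp(la), np.exp(lr)
            eta = d.Xt @ alpha if d.pt else np.zeros(d.N)
            logh = la + lr + (shape - 1) * d.logT + eta
            Lam = scale * d.T[:, None] ** shape * np.exp(eta[:, None] + gamma * nodes)
            q = np.sum(d.delta * (logh + gamma * (w * nodes).sum(1))) - np.sum(w * Lam)
            # gradient
            ELam = (w * Lam).sum(1)
            EuLam = (w * nodes * Lam).sum(1)
            g_la = np.sum(d.delta - ELam)
            g_lr = np.sum(d.delta * (1 + shape * d.logT)) - np.sum(shape * d.logT * ELam)
            g_al = d.Xt.T @ (d.delta - ELam) if d.pt else np.empty(0)
            g_ga = np.sum(d.delta * (w * nodes).sum(1)) - np.sum(EuLam)
            grad = np.concatenate([[g_la, g_lr], g_al, [g_ga]])
            return -q, -grad

        res = optimize.minimize(negQ, psi0, jac=True, method="L-BFGS-B",
                                options={"maxiter": 40})
        return res.x if np.isfinite(res.fun) else psi0

    # -- direct maximization -------------------------------------------------

    def _polish(self, theta, lik):
        d = self._data

        def to_internal(th):
            th = th.copy()
            th[d.py:d.py + 4] = np.log(th[d.py:d.py + 4])
            return th

        def to_natural(x):
            x = x.copy()
            x[d.py:d.py + 4] = np.exp(x[d.py:d.py + 4])
            return x

        def neg(x):
            ll = lik.loglik(to_natural(x))
            return -ll if np.isfinite(ll) else 1e10

        res = optimize.minimize(neg, to_internal(theta), method="BFGS",
                                options={"gtol": 1e-6, "maxiter": 500})
        theta_new = to_natural(res.x)
        ll_new = lik.loglik(theta_new)
        ll_old = lik.loglik(theta)
        if ll_new >= ll_old:
            return theta_new, ll_new
        return theta, ll_old

    # -- inference -----------------------------------------------------------

    def _finalize(self, d, lik, theta):
        beta, su, se, scale, shape, alpha, gamma = _unpack(theta, d.py, d.pt)
        H = self._observed_information(theta)
        try:
            cov = np.linalg.inv(H)
        except np.linalg.LinAlgError as exc:
            raise RuntimeError(
                "observed information matrix is singular; consider rescaling "
                "covariates or simplifying the model"
            ) from exc
        se_all = np.sqrt(np.abs(np.diag(cov)))
        self.cov_ = cov
        self.se_ = se_all
        self.beta_ = beta
        self.sigma_u_ = float(su)
        self.sigma_e_ = float(se)
        self.scale_ = float(scale)
        self.shape_ = float(shape)
        self.alpha_ = alpha
        self.gamma_ = float(gamma)
        py, pt = d.py, d.pt
        self.gamma_se_ = float(se_all[-1])
        self.sigma_u_se_ = float(se_all[py])
        self.sigma_e_se_ = float(se_all[py + 1])
        self.scale_se_ = float(se_all[py + 2])
        self.shape_se_ = float(se_all[py + 3])
        dfree = len(d.y) - py
        self.longitudinal_params_ = _ttable(d.names_y, beta, se_all[:py], dfree)
        self.survival_params_ = _ztable(d.names_t, alpha, se_all[py + 4:py + 4 + pt])
        z = self.gamma_ / self.gamma_se_ if self.gamma_se_ > 0 else np.nan
        self.association_row_ = pd.Series(
            {"estimate": self.gamma_, "se": self.gamma_se_, "z": z,
             "p": 2 * stats.norm.sf(abs(z)) if np.isfinite(z) else np.nan},
            name="association(gamma)")
        _, est = lik.loglik(theta, return_estep=True)
        self.posterior_modes_ = pd.Series(est["mode"], index=d.subject_ids)
        self.posterior_means_ = pd.Series(est["Eu"], index=d.subject_ids)

    def _observed_information(self, theta, rel_step=1e-5):
        lik = self._lik
        k = len(theta)
        H = np.zeros((k, k))
        h = rel_step * np.maximum(np.abs(theta), 1.0)
        f0 = lik.loglik(theta)
        for i in range(k):
            for j in range(i, k):
                ei = np.zeros(k); ei[i] = h[i]
                ej = np.zeros(k); ej[j] = h[j]
                if i == j:
                    fpp = lik.loglik(theta + ei)
                    fmm = lik.loglik(theta - ei)
                    H[i, i] = (fpp - 2 * f0 + fmm) / h[i] ** 2
                else:
                    fpp = lik.loglik(theta + ei + ej)
                    fpm = lik.loglik(theta + ei - ej)
                    fmp = lik.loglik(theta - ei + ej)
                    fmm = lik.loglik(theta - ei - ej)
                    H[i, j] = H[j, i] = (fpp - fpm - fmp + fmm) / (4 * h[i] * h[j])
        return -H

    # -- public helpers --------------------------------------------------------

    def loglik(self, theta=None, plain=False):
        th = self.theta_ if theta is None else np.asarray(theta, dtype=float)
        return self._lik.loglik_plain(th) if plain else self._lik.loglik(th)

    def association_test(self):
        return association_test(self)

    def conditional_survival(self, t, subject_id):
        """S(t | covariates, posterior-mode u) for one subject.

        Closed form under the shared-intercept link; numeric quadrature of the
        hazard under the current-value link.
        """
        t = np.asarray(t, dtype=float)
        if np.any(t < 0):
            raise ValueError("time must be non-negative")
        d = self._data
        i = int(np.where(d.subject_ids == subject_id)[0][0])
        u = float(self.posterior_modes_.loc[subject_id])
        eta = float(d.Xt[i] @ self.alpha_) if d.pt else 0.0
        if self.association == "shared_intercept":
            Lam = self.scale_ * t**self.shape_ * np.exp(eta + self.gamma_ * u)
        else:
            first = np.concatenate([[0], 1 + np.where(np.diff(d.subj) > 0)[0]])
            Xrow = d.Xy[first][i].copy()
            bt = 0.0
            if d.time_idx is not None:
                bt = self.beta_[d.time_idx]
                Xrow[d.time_idx] = 0.0
            m0 = float(Xrow @ self.beta_) + u
            gl_x, gl_w = d.gl_x, d.gl_w
            s = 0.5 * t[..., None] * (gl_x + 1.0)
            integ = self.shape_ * np.maximum(s, 1e-300) ** (self.shape_ - 1) * \
                np.exp(self.gamma_ * (m0 + bt * s))
            Lam = self.scale_ * np.exp(eta) * 0.5 * t * (integ * gl_w).sum(axis=-1)
        return np.exp(-Lam)

    def summary(self) -> str:
        """Two-panel report: longitudinal and survival sub-models + association."""
        lines = ["Joint longitudinal-survival model "
                 f"(association: {self.association})", ""]
        lines.append("Longitudinal sub-model (sqrt-SBP)")
        lines.append(self.longitudinal_params_.round(4).to_string())
        lines.append(f"  sigma_u = {self.sigma_u_:.4f} (SE {self.sigma_u_se_:.4f})   "
                     f"sigma_e = {self.sigma_e_:.4f} (SE {self.sigma_e_se_:.4f})")
        lines.append("")
        lines.append("Survival sub-model (Weibull PH)")
        if len(self.survival_params_):
            lines.append(self.survival_params_.round(4).to_string())
        lines.append(f"  shape rho = {self.shape_:.4f} (SE {self.shape_se_:.4f})   "
                     f"scale lambda = {self.scale_:.3e}")
        lines.append("")
        z, p, direction = association_test(self)
        lines.append(f"Association gamma = {self.gamma_:.4f} "
                     f"(SE {self.gamma_se_:.4f}, z = {z:.3f}, p = {p:.3g})")
        lines.append(f"  {direction}")
        lines.append(f"log-likelihood = {self.loglik_:.4f}")
        return "\n".join(lines)


def _ttable(names, est, se, dfree):
    tval = np.divide(est, se, out=np.zeros_like(est), where=se > 0)
    return pd.DataFrame(
        {"estimate": est, "se": se, "t": tval,
         "p": 2 * stats.t.sf(np.abs(tval), dfree)},
        index=names)


def _ztable(names, est, se):
    z = np.divide(est, se, out=np.zeros_like(est), where=se > 0)
    return pd.DataFrame(
        {"estimate": est, "se": se, "z": z, "p": 2 * stats.norm.sf(np.abs(z)),
         "hazard_ratio": np.exp(est)},
        index=names)


def fit_joint(cohort, longitudinal_terms=("time",), survival_terms=(),
              association="shared_intercept", init=None, **kwargs) -> JointModel:
    """Functional wrapper over :class:`JointModel`."""
    return JointModel(longitudinal_terms=longitudinal_terms,
                      survival_terms=survival_terms, association=association,
                      **kwargs).fit(cohort, init=init)


def joint_loglik(cohort, beta, sigma_u, sigma_e, scale, shape, alpha, gamma,
                 longitudinal_terms=("time",), survival_terms=(),
                 association="shared_intercept", n_nodes=15, adaptive=True,
                 response="sqrt_sbp", time_col="visit_time") -> float:
    """Joint log-likelihood at given parameters (no fitting)."""
    data = _JointData(cohort, longitudinal_terms, survival_terms, response, time_col)
    lik = _Likelihood(data, association, n_nodes, adaptive)
    theta = _pack(np.asarray(beta, float), sigma_u, sigma_e, scale, shape,
                  np.asarray(alpha, float), gamma)
    return lik.loglik(theta) if adaptive else lik.loglik_plain(theta)


def wald_z(estimate: float, se: float) -> tuple[float, float]:
    """Wald ratio z = estimate/SE and its two-sided normal p-value."""
    if se <= 0:
        raise ValueError("standard error must be positive")
    z = estimate / se
    return float(z), float(2 * stats.norm.sf(abs(z)))


def association_test(fit: JointModel):
    """Wald test of gamma = 0: (z, two-sided p, direction statement)."""
    if not hasattr(fit, "gamma_se_") or not np.isfinite(fit.gamma_se_) \
            or fit.gamma_se_ <= 0:
        raise ValueError("fit has no valid standard error for gamma")
    z = fit.gamma_ / fit.gamma_se_
    p = 2 * stats.norm.sf(abs(z))
    if fit.gamma_ > 0:
        direction = ("positive association: higher latent sqrt-SBP level, "
                     "higher death hazard")
    elif fit.gamma_ < 0:
        direction = ("negative association: higher latent sqrt-SBP level, "
                     "lower death hazard")
    else:
        direction = "no association"
    return z, p, direction
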