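"""Linear mixed-effects models for sqrt-SBP under selectable covariance structures.

The marginal model per subject i is

    Y_i ~ N(X_i beta, Z_i D Z_i' + Sigma_i)

where D is the random-effect covariance (none / intercept / slope /
intercept+slope) and Sigma_i the residual covariance, one of:

* ``IND``  independent, sigma_e^2 I
* ``CS``   compound symmetry (exchangeable), parameterized as between+within
           variance so the common correlation is restricted to [0, 1)
* ``AR1``  first-order autoregressive by within-subject visit index
* ``HCS``/``CSH``  heterogeneous compound symmetry: per-occasion standard
           deviations on a binned visit grid with a common correlation
* ``UN``   unstructured covariance on the binned visit grid, fitted by EM

Structured-likelihood fits use profiled (beta solved by GLS) numerical
optimization on transformed variance parameters; UN uses a closed-form EM for
the multivariate normal with arbitrary missingness (exact REML variant
integrates beta against a flat prior). Random effects are only allowed with
IND or AR1 residuals: CS/HCS/UN residual correlation is aliased with a random
intercept.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats
from sklearn.base import BaseEstimator

from ._design import build_design
from .cohort import CohortTable

STRUCTURES = ("IND", "CS", "CSH", "AR1", "UN", "HCS")
RANDOM_TERMS = ("none", "intercept", "slope", "intercept+slope")
_CANON = {"CSH": "HCS"}


def _canon_structure(s: str) -> str:
    if s not in STRUCTURES:
        raise ValueError(f"cov_structure must be one of {STRUCTURES}, got {s!r}")
    return _CANON.get(s, s)


def information_criteria(loglik: float, n_params: int, n_obs: int) -> tuple[float, float]:
    """AIC = -2*loglik + 2*k and BIC = -2*loglik + k*log(n)."""
    return (-2.0 * loglik + 2.0 * n_params,
            -2.0 * loglik + n_params * np.log(n_obs))


# ---------------------------------------------------------------------------
# data preparation


@dataclass
class _Prep:
    y: np.ndarray
    X: np.ndarray
    names: list
    subj: np.ndarray          # integer codes, contiguous per subject
    subj_ids: np.ndarray      # original ids in code order
    times: np.ndarray
    starts: np.ndarray        # slice starts per subject
    counts: np.ndarray
    bins: np.ndarray | None   # grid indices for HCS/UN
    grid: np.ndarray | None   # bin labels (months)


def _prepare(data, fixed_terms, response, subject_col, time_col, need_bins, bin_width):
    if isinstance(data, CohortTable):
        df = data.merged_longitudinal()
    else:
        df = data.copy()
    if "time" in fixed_terms and "time" not in df.columns:
        df["time"] = df[time_col]
    df = df.sort_values([subject_col, time_col], kind="mergesort").reset_index(drop=True)
    X, names = build_design(df, tuple(fixed_terms))
    y = df[response].to_numpy(dtype=float)
    codes, uniques = pd.factorize(df[subject_col])
    order = np.argsort(codes, kind="mergesort")
    # factorize preserves first-appearance order; rows are already grouped
    counts = np.bincount(codes)
    starts = np.concatenate([[0], np.cumsum(counts)[:-1]])
    times = df[time_col].to_numpy(dtype=float)
    bins = grid = None
    if need_bins:
        if bin_width is None:
            gaps = np.diff(times)
            within = gaps[np.diff(codes) == 0]
            within = within[within > 0]
            bin_width = float(np.median(within)) if within.size else 1.0
        b = np.rint(times / bin_width).astype(int)
        for i in range(len(counts)):
            sl = slice(starts[i], starts[i] + counts[i])
            if len(np.unique(b[sl])) != counts[i]:
                raise ValueError(
                    f"subject {uniques[i]!r} has duplicate visits in one grid bin "
                    f"(bin width {bin_width}); HCS/UN need distinct occasions"
                )
        grid_labels = np.unique(b)
        remap = {v: k for k, v in enumerate(grid_labels)}
        bins = np.array([remap[v] for v in b])
        grid = grid_labels * bin_width
    return _Prep(y, X, names, codes, np.asarray(uniques), times, starts, counts, bins, grid)


# ---------------------------------------------------------------------------
# structured covariance: parameter transforms and Sigma builders


def _n_resid_params(struct, m):
    return {"IND": 1, "CS": 2, "AR1": 2, "HCS": m + 1}[struct]


def _resid_sigma(struct, params, idx):
    """Residual covariance for one subject/pattern.

    ``idx``: within-subject visit indices (AR1) or grid-bin indices (HCS).
    """
    n = len(idx)
    if struct == "IND":
        (lse,) = params
        return np.exp(2 * lse) * np.eye(n)
    if struct == "CS":
        lsb, lsw = params
        return np.exp(2 * lsb) * np.ones((n, n)) + np.exp(2 * lsw) * np.eye(n)
    if struct == "AR1":
        lse, zphi = params
        phi = np.tanh(zphi)
        j = np.arange(n)
        return np.exp(2 * lse) * phi ** np.abs(j[:, None] - j[None, :])
    if struct == "HCS":
        *lsd, zr = params
        rho = 1.0 / (1.0 + np.exp(-zr))  # common correlation in (0, 1)
        sd = np.exp(np.asarray(lsd))[np.asarray(idx)]
        R = np.full((n, n), rho) + (1 - rho) * np.eye(n)
        return np.outer(sd, sd) * R
    raise AssertionError(struct)


def _n_re_params(re):
    return {"none": 0, "intercept": 1, "slope": 1, "intercept+slope": 3}[re]


def _re_cov(re, params):
    if re == "none":
        return None
    if re in ("intercept", "slope"):
        return np.array([[np.exp(2 * params[0])]])
    l11, l21, l22 = np.exp(params[0]), params[1], np.exp(params[2])
    L = np.array([[l11, 0.0], [l21, l22]])
    return L @ L.T


def _re_design(re, t):
    """Random-effect design for one subject given its visit times."""
    n = len(t)
    if re == "none":
        return None
    if re == "intercept":
        return np.ones((n, 1))
    if re == "slope":
        return np.asarray(t, dtype=float)[:, None]
    return np.column_stack([np.ones(n), np.asarray(t, dtype=float)])


class _Objective:
    """Profiled negative (restricted) log-likelihood over variance parameters."""

    def __init__(self, prep: _Prep, struct, re, method):
        self.prep = prep
        self.struct = struct
        self.re = re
        self.method = method
        self.n, self.p = prep.X.shape
        self.m = int(prep.bins.max()) + 1 if prep.bins is not None else 0
        # group subjects by covariance pattern
        key_of = {}
        self.groups = []  # (pattern_idx_array, subject_code_list)
        for i in range(len(prep.counts)):
            sl = slice(prep.starts[i], prep.starts[i] + prep.counts[i])
            if struct == "HCS":
                key = tuple(prep.bins[sl])
            else:
                key = prep.counts[i]
            if key not in key_of:
                key_of[key] = len(self.groups)
                self.groups.append((key, []))
            self.groups[key_of[key]][1].append(i)
        self._cache = {}

    def _group_arrays(self, gi):
        if gi in self._cache:
            return self._cache[gi]
        key, subs = self.groups[gi]
        prep = self.prep
        n_i = prep.counts[subs[0]]
        G = len(subs)
        Y = np.empty((G, n_i))
        X = np.empty((G, n_i, self.p))
        T = np.empty((G, n_i))
        for g, i in enumerate(subs):
            sl = slice(prep.starts[i], prep.starts[i] + prep.counts[i])
            Y[g] = prep.y[sl]
            X[g] = prep.X[sl]
            T[g] = prep.times[sl]
        idx = np.asarray(key) if self.struct == "HCS" else np.arange(n_i)
        self._cache[gi] = (Y, X, T, idx, subs)
        return self._cache[gi]

    def split(self, params):
        k = _n_re_params(self.re)
        return params[:k], params[k:]

    def components(self, params):
        """Return (logdet_total, A, b, q) accumulated over subjects."""
        re_p, res_p = self.split(params)
        D = _re_cov(self.re, re_p)
        logdet = 0.0
        A = np.zeros((self.p, self.p))
        b = np.zeros(self.p)
        q = 0.0
        for gi in range(len(self.groups)):
            Y, X, T, idx, subs = self._group_arrays(gi)
            G, n_i = Y.shape
            Sig = _resid_sigma(self.struct, res_p, idx)
            if self.re in ("none", "intercept"):
                V = Sig.copy()
                if self.re == "intercept":
                    V += D[0, 0]
                L = np.linalg.cholesky(V)
                logdet += 2 * G * np.log(np.diag(L)).sum()
                from scipy.linalg import solve_triangular

                rhs = np.concatenate(
                    [Y.T, X.transpose(1, 0, 2).reshape(n_i, -1)], axis=1
                )
                sol = solve_triangular(L, rhs, lower=True)
                Yt = sol[:, :G]
                Xt = sol[:, G:].reshape(n_i, G, self.p)
                q += float(np.einsum("ig,ig->", Yt, Yt))
                b += np.einsum("igp,ig->p", Xt, Yt)
                A += np.einsum("igp,igq->pq", Xt, Xt)
            else:
                Z = np.stack([_re_design(self.re, T[g]) for g in range(G)])
                V = Sig[None] + np.einsum("gik,kl,gjl->gij", Z, D, Z)
                L = np.linalg.cholesky(V)
                logdet += 2 * np.log(np.einsum("gii->gi", L)).sum()
                Yt = np.linalg.solve(L, Y[..., None])[..., 0]
                Xt = np.linalg.solve(L, X)
                q += float(np.einsum("gi,gi->", Yt, Yt))
                b += np.einsum("gip,gi->p", Xt, Yt)
                A += np.einsum("gip,giq->pq", Xt, Xt)
        return logdet, A, b, q

    def loglik_parts(self, params):
        logdet, A, b, q = self.components(params)
        cA = np.linalg.cholesky(A)
        beta = np.linalg.solve(A, b)
        rss = q - b @ beta
        n, p = self.n, self.p
        ll_ml = -0.5 * (logdet + rss + n * np.log(2 * np.pi))
        ll = ll_ml
        if self.method == "REML":
            ll = ll_ml - 0.5 * 2 * np.log(np.diag(cA)).sum() + 0.5 * p * np.log(2 * np.pi)
        return ll, beta, A

    def __call__(self, params):
        try:
            with np.errstate(over="raise", invalid="raise"):
                ll, _, _ = self.loglik_parts(params)
        except (np.linalg.LinAlgError, FloatingPointError):
            return 1e10
        if not np.isfinite(ll):
            return 1e10
        return -ll


# ---------------------------------------------------------------------------
# estimator


class LinearMixedModel(BaseEstimator):
    """Gaussian linear mixed model with structured residual covariance.

    Parameters
    ----------
    fixed_terms : tuple of str
        Covariate names (the literal name ``"time"`` maps to the observation
        time column). The intercept is always included.
    random_terms : {"none", "intercept", "slope", "intercept+slope"}
    cov_structure : {"IND", "CS", "CSH", "AR1", "UN", "HCS"}
        ``CSH`` and ``HCS`` are two names for the heterogeneous
        compound-symmetry structure.
    method : {"ML", "REML"}
    bin_width : float, optional
        Visit-grid bin width (months) for HCS/UN; inferred from the median
        within-subject gap when omitted.
    """

    def __init__(
        self,
        fixed_terms=("time",),
        random_terms="intercept",
        cov_structure="IND",
        method="REML",
        bin_width=None,
        tol=1e-8,
        max_iter=500,
        n_restarts=3,
    ):
        self.fixed_terms = fixed_terms
        self.random_terms = random_terms
        self.cov_structure = cov_structure
        self.method = method
        self.bin_width = bin_width
        self.tol = tol
        self.max_iter = max_iter
        self.n_restarts = n_restarts

    # -- fitting ------------------------------------------------------------

    def fit(self, data, response="sqrt_sbp", subject_col="subject_id",
            time_col="visit_time"):
        struct = _canon_structure(self.cov_structure)
        re = self.random_terms
        if re not in RANDOM_TERMS:
            raise ValueError(f"random_terms must be one of {RANDOM_TERMS}")
        if self.method not in ("ML", "REML"):
            raise ValueError("method must be 'ML' or 'REML'")
        if re != "none" and struct not in ("IND", "AR1"):
            raise ValueError(
                f"random effects with residual structure {struct} are aliased; "
                "use IND or AR1 residuals with random effects"
            )
        prep = _prepare(data, self.fixed_terms, response, subject_col, time_col,
                        need_bins=struct in ("HCS", "UN"), bin_width=self.bin_width)
        if prep.counts.max() == 1 and (re != "none" or struct != "IND"):
            raise ValueError(
                "only one observation per subject: within-subject variance "
                "components are not identifiable (fit an ordinary regression instead)"
            )
        self._prep = prep
        self._struct = struct
        self.n_obs_ = len(prep.y)
        self.n_subjects_ = len(prep.counts)

        if struct == "UN":
            self._fit_unstructured(prep)
        else:
            self._fit_structured(prep, struct, re)

        p = prep.X.shape[1]
        self.aic_, self.bic_ = information_criteria(self.loglik_, self.n_params_,
                                                    self.n_obs_)
        # fixed-effect table
        cov_beta = np.linalg.inv(self._A)
        se = np.sqrt(np.diag(cov_beta))
        df_resid = self.n_obs_ - p
        tval = self.beta_values_ / se
        pval = 2 * stats.t.sf(np.abs(tval), df_resid)
        tq = stats.t.ppf(0.975, df_resid)
        self.cov_beta_ = cov_beta
        self.df_resid_ = df_resid
        self.beta_ = pd.DataFrame(
            {
                "estimate": self.beta_values_,
                "se": se,
                "t": tval,
                "p": pval,
                "ci_low": self.beta_values_ - tq * se,
                "ci_high": self.beta_values_ + tq * se,
            },
            index=self._prep.names,
        )
        return self

    def _fit_structured(self, prep, struct, re):
        obj = _Objective(prep, struct, re, self.method)
        m = obj.m
        # initial values from OLS residual variance
        beta0, *_ = np.linalg.lstsq(prep.X, prep.y, rcond=None)
        s2 = float(np.var(prep.y - prep.X @ beta0))
        s2 = max(s2, 1e-8)
        ls = 0.5 * np.log(s2)
        half = 0.5 * np.log(s2 / 2)
        re_x0 = {"none": [], "intercept": [half], "slope": [half - np.log(10.0)],
                 "intercept+slope": [half, 0.0, half - np.log(10.0)]}[re]
        if struct == "IND":
            res_x0 = [half if re != "none" else ls]
        elif struct == "CS":
            res_x0 = [half, half]
        elif struct == "AR1":
            res_x0 = [half if re != "none" else ls, np.arctanh(0.3)]
        else:  # HCS
            res_x0 = [ls] * m + [np.log(0.3 / 0.7)]
        x0 = np.array(re_x0 + res_x0, dtype=float)

        best = None
        rng = np.random.default_rng(0)
        for attempt in range(self.n_restarts + 1):
            start = x0 if attempt == 0 else x0 + rng.normal(0, 0.5, size=x0.size)
            res = optimize.minimize(
                obj, start, method="L-BFGS-B",
                options={"maxiter": self.max_iter, "ftol": 1e-13, "gtol": 1e-8},
            )
            if best is None or res.fun < best.fun - 1e-10:
                best = res
            if best.success and best.fun < 1e9:
                break
        if best.fun >= 1e9:
            raise RuntimeError(
                f"variance-parameter optimization failed for {struct}: {best.message}; "
                f"trace: nit={best.nit}, fun={best.fun}"
            )
        self.converged_ = bool(best.success)
        self._opt_result = best
        ll, beta, A = obj.loglik_parts(best.x)
        self.loglik_ = float(ll)
        self.beta_values_ = beta
        self._A = A
        re_p, res_p = obj.split(best.x)
        self.D_ = _re_cov(re, re_p)
        self.sigma_params_ = self._natural_resid_params(struct, res_p, obj.m)
        self.n_params_ = prep.X.shape[1] + len(best.x)
        self._obj = obj
        self._varparams = best.x
        self.blups_ = self._compute_blups() if re != "none" else None

    @staticmethod
    def _natural_resid_params(struct, res_p, m):
        if struct == "IND":
            return {"sigma_e": float(np.exp(res_p[0]))}
        if struct == "CS":
            sb2, sw2 = np.exp(2 * res_p[0]), np.exp(2 * res_p[1])
            return {
                "sigma_between": float(np.sqrt(sb2)),
                "sigma_within": float(np.sqrt(sw2)),
                "sigma_total": float(np.sqrt(sb2 + sw2)),
                "rho": float(sb2 / (sb2 + sw2)),
            }
        if struct == "AR1":
            return {"sigma_e": float(np.exp(res_p[0])), "phi": float(np.tanh(res_p[1]))}
        if struct == "HCS":
            *lsd, zr = res_p
            return {
                "sigma_by_occasion": np.exp(np.asarray(lsd)),
                "rho": float(1.0 / (1.0 + np.exp(-zr))),
            }
        raise AssertionError(struct)

    def _compute_blups(self):
        prep, re = self._prep, self.random_terms
        re_p, res_p = self._obj.split(self._varparams)
        D = _re_cov(re, re_p)
        out = {}
        resid = prep.y - prep.X @ self.beta_values_
        for i in range(len(prep.counts)):
            sl = slice(prep.starts[i], prep.starts[i] + prep.counts[i])
            idx = (prep.bins[sl] if self._struct == "HCS" else np.arange(prep.counts[i]))
            Sig = _resid_sigma(self._struct, res_p, idx)
            Z = _re_design(re, prep.times[sl])
            V = Sig + Z @ D @ Z.T
            out[prep.subj_ids[i]] = D @ Z.T @ np.linalg.solve(V, resid[sl])
        cols = {"intercept": ["u0"], "slope": ["u1"], "intercept+slope": ["u0", "u1"]}[re]
        return pd.DataFrame(out).T.set_axis(cols, axis=1)

    # -- unstructured covariance via EM --------------------------------------

    def _fit_unstructured(self, prep):
        m = int(prep.bins.max()) + 1
        N = len(prep.counts)
        p = prep.X.shape[1]
        reml = self.method == "REML"
        # per-subject observed grid indices
        obs_idx = []
        for i in range(N):
            sl = slice(prep.starts[i], prep.starts[i] + prep.counts[i])
            obs_idx.append(prep.bins[sl])
        beta, *_ = np.linalg.lstsq(prep.X, prep.y, rcond=None)
        resid = prep.y - prep.X @ beta
        Sigma = np.eye(m) * max(float(np.var(resid)), 1e-6)
        prev_ll = -np.inf
        self.converged_ = False
        for it in range(self.max_iter):
            # GLS for beta and loglik pieces
            A = np.zeros((p, p))
            b = np.zeros(p)
            logdet = 0.0
            q = 0.0
            Vinv = []
            for i in range(N):
                o = obs_idx[i]
                sl = slice(prep.starts[i], prep.starts[i] + prep.counts[i])
                V = Sigma[np.ix_(o, o)]
                Vi = np.linalg.inv(V)
                Vinv.append(Vi)
                sign, ld = np.linalg.slogdet(V)
                logdet += ld
                Xi = prep.X[sl]
                A += Xi.T @ Vi @ Xi
                b += Xi.T @ Vi @ prep.y[sl]
            beta = np.linalg.solve(A, b)
            Cb = np.linalg.inv(A)
            for i in range(N):
                sl = slice(prep.starts[i], prep.starts[i] + prep.counts[i])
                r = prep.y[sl] - prep.X[sl] @ beta
                q += r @ Vinv[i] @ r
            ll = -0.5 * (logdet + q + self.n_obs_ * np.log(2 * np.pi))
            if reml:
                sign, ldA = np.linalg.slogdet(A)
                ll += -0.5 * ldA + 0.5 * p * np.log(2 * np.pi)
            # E/M step for Sigma
            M = np.zeros((m, m))
            for i in range(N):
                o = obs_idx[i]
                mis = np.setdiff1d(np.arange(m), o)
                sl = slice(prep.starts[i], prep.starts[i] + prep.counts[i])
                r = prep.y[sl] - prep.X[sl] @ beta
                Vi = Vinv[i]
                if mis.size:
                    B = Sigma[np.ix_(mis, o)] @ Vi
                    e_full = np.concatenate([r, B @ r])
                    Ablk = np.vstack([np.eye(len(o)), B])
                    cond = Sigma[np.ix_(mis, mis)] - B @ Sigma[np.ix_(o, mis)]
                else:
                    B = None
                    e_full = r
                    Ablk = np.eye(len(o))
                    cond = None
                Ee = np.outer(e_full, e_full)
                if reml:
                    W = Ablk @ prep.X[sl]
                    Ee = Ee + W @ Cb @ W.T
                perm = np.concatenate([o, mis]) if mis.size else o
                M[np.ix_(perm, perm)] += Ee
                if cond is not None:
                    M[np.ix_(mis, mis)] += cond
            Sigma = 0.5 * (M + M.T) / N
            if abs(ll - prev_ll) < self.tol * max(1.0, abs(ll)):
                self.converged_ = True
                break
            prev_ll = ll
        # recompute GLS quantities at the final Sigma so that beta, A and the
        # reported log-likelihood are mutually consistent
        A = np.zeros((p, p))
        b = np.zeros(p)
        logdet = 0.0
        Vinv = []
        for i in range(N):
            o = obs_idx[i]
            sl = slice(prep.starts[i], prep.starts[i] + prep.counts[i])
            V = Sigma[np.ix_(o, o)]
            Vi = np.linalg.inv(V)
            Vinv.append(Vi)
            logdet += np.linalg.slogdet(V)[1]
            Xi = prep.X[sl]
            A += Xi.T @ Vi @ Xi
            b += Xi.T @ Vi @ prep.y[sl]
        beta = np.linalg.solve(A, b)
        q = 0.0
        for i in range(N):
            sl = slice(prep.starts[i], prep.starts[i] + prep.counts[i])
            r = prep.y[sl] - prep.X[sl] @ beta
            q += r @ Vinv[i] @ r
        ll = -0.5 * (logdet + q + self.n_obs_ * np.log(2 * np.pi))
        if reml:
            ll += -0.5 * np.linalg.slogdet(A)[1] + 0.5 * p * np.log(2 * np.pi)
        self.loglik_ = float(ll)
        self.beta_values_ = beta
        self._A = A
        self.D_ = None
        self.blups_ = None
        self.sigma_params_ = {
            "Sigma": pd.DataFrame(Sigma, index=prep.grid, columns=prep.grid)
        }
        self.n_params_ = p + m * (m + 1) // 2
        self._Sigma_un = Sigma
        self._obs_idx = obs_idx

    # -- utilities -----------------------------------------------------------

    def marginal_covariance(self, subject_id):
        """Fitted marginal covariance V_i for one subject (testing aid)."""
        prep = self._prep
        i = int(np.where(prep.subj_ids == subject_id)[0][0])
        sl = slice(prep.starts[i], prep.starts[i] + prep.counts[i])
        if self._struct == "UN":
            o = self._obs_idx[i]
            return self._Sigma_un[np.ix_(o, o)]
        re_p, res_p = self._obj.split(self._varparams)
        idx = prep.bins[sl] if self._struct == "HCS" else np.arange(prep.counts[i])
        V = _resid_sigma(self._struct, res_p, idx)
        if self.random_terms != "none":
            D = _re_cov(self.random_terms, re_p)
            Z = _re_design(self.random_terms, prep.times[sl])
            V = V + Z @ D @ Z.T
        return V

    def subject_slices(self):
        prep = self._prep
        for i in range(len(prep.counts)):
            sl = slice(prep.starts[i], prep.starts[i] + prep.counts[i])
            yield prep.subj_ids[i], prep.y[sl], prep.X[sl]

    def wald_test(self, term):
        """Joint Wald chi-square over all design columns of one term."""
        cols = [j for j, nm in enumerate(self._prep.names)
                if nm == term or nm.startswith(f"{term}[")]
        if not cols:
            raise KeyError(f"term {term!r} not in fitted model")
        b = self.beta_values_[cols]
        C = self.cov_beta_[np.ix_(cols, cols)]
        stat = float(b @ np.linalg.solve(C, b))
        df = len(cols)
        return stat, df, float(stats.chi2.sf(stat, df))


def fit_lmm(data, fixed_terms=("time",), random_terms="intercept",
            cov_structure="IND", method="REML", **kwargs) -> LinearMixedModel:
    """Functional wrapper over :class:`LinearMixedModel`."""
    return LinearMixedModel(
        fixed_terms=fixed_terms, random_terms=random_terms,
        cov_structure=cov_structure, method=method, **kwargs
    ).fit(data)


# ---------------------------------------------------------------------------
# model selection and screening


def _compare(data, base: LinearMixedModel, variants, attr, fit_kwargs):
    rows = []
    fits = {}
    for v in variants:
        model = LinearMixedModel(**{**base.get_params(), attr: v})
        row = {attr if attr != "cov_structure" else "structure": v}
        try:
            model.fit(data, **fit_kwargs)
            row.update(
                aic=model.aic_, bic=model.bic_, loglik=model.loglik_,
                n_params=model.n_params_, converged=model.converged_, error="",
            )
            fits[v] = model
        except Exception as exc:  # report per-row, not fatal
            row.update(aic=np.nan, bic=np.nan, loglik=np.nan, n_params=np.nan,
                       converged=False, error=str(exc))
        rows.append(row)
    out = pd.DataFrame(rows)
    out = out.sort_values("aic", kind="mergesort", na_position="last").reset_index(drop=True)
    key = out.columns[0]
    out.attrs["selected"] = None if out["aic"].isna().all() else out.iloc[0][key]
    out.attrs["fits"] = fits
    return out


def compare_cov_structures(data, base: LinearMixedModel | None = None,
                           structures=("CS", "AR1", "UN", "HCS"), **fit_kwargs):
    """Fit each residual covariance structure; rank by AIC (minimizer selected)."""
    base = base if base is not None else LinearMixedModel(random_terms="none")
    return _compare(data, base, list(structures), "cov_structure", fit_kwargs)


def compare_random_effects(data, base: LinearMixedModel | None = None,
                           configurations=("intercept", "slope", "intercept+slope"),
                           **fit_kwargs):
    """Fit each random-effect configuration; rank by AIC."""
    base = base if base is not None else LinearMixedModel(cov_structure="IND")
    return _compare(data, base, list(configurations), "random_terms", fit_kwargs)


def univariable_screen(data, candidates, alpha=0.25, time_term="time",
                       method="REML", **fit_kwargs) -> pd.DataFrame:
    """Single-covariate mixed-model screen at a modest significance level.

    Each candidate is fitted in a random-intercept model with observation time;
    covariates whose joint Wald p-value is below ``alpha`` are retained.
    Constant covariates are excluded with a warning.
    """
    if not 0 < alpha <= 1:
        raise ValueError("alpha must lie in (0, 1]")
    if isinstance(data, CohortTable):
        df = data.merged_longitudinal()
    else:
        df = data
    rows = []
    for cand in candidates:
        if df[cand].nunique(dropna=True) <= 1:
            warnings.warn(f"covariate {cand!r} is constant; excluded from screen")
            rows.append({"covariate": cand, "statistic": np.nan, "df": 0,
                         "p_value": np.nan, "retained": False})
            continue
        model = LinearMixedModel(
            fixed_terms=(time_term, cand), random_terms="intercept",
            cov_structure="IND", method=method,
        ).fit(df, **fit_kwargs)
        stat, dof, p = model.wald_test(cand)
        rows.append({"covariate": cand, "statistic": stat, "df": dof,
                     "p_value": p, "retained": bool(p < alpha)})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# normality panel


@dataclass
class NormalityResult:
    table: pd.DataFrame
    recommendation: str


def check_normality(values, alpha=0.05) -> NormalityResult:
    """Shapiro-Wilk and Kolmogorov-Smirnov (against the fitted Gaussian) for the
    raw, square-root and log transforms; recommends the first transform, in the
    order none -> sqrt -> log, with both p-values above ``alpha``.
    """
    x = np.asarray(values, dtype=float)
    if x.size < 20:
        raise ValueError("need at least 20 values for the normality panel")
    if np.any(x <= 0):
        raise ValueError("non-positive values: sqrt/log transforms are undefined")
    rows = []
    candidates = [("none", x), ("sqrt", np.sqrt(x)), ("log", np.log(x))]
    rec = None
    for name, v in candidates:
        sw = stats.shapiro(v).pvalue
        ks = stats.kstest(v, "norm", args=(v.mean(), v.std(ddof=1))).pvalue
        rows.append({"transform": name, "shapiro_p": sw, "ks_p": ks})
        if rec is None and sw > alpha and ks > alpha:
            rec = name
    table = pd.DataFrame(rows)
    if rec is None:  # nothing passes: fall back to the best-supported transform
        rec = table.set_index("transform")[["shapiro_p", "ks_p"]].min(axis=1).idxmax()
    return NormalityResult(table=table, recommendation=rec)


# ---------------------------------------------------------------------------
# likelihood evaluation helpers (used by the joint model and in tests)


def random_intercept_loglik(data, fixed_terms, beta, sigma_u, sigma_e,
                            response="sqrt_sbp", subject_col="subject_id",
                            time_col="visit_time") -> float:
    """Exact marginal Gaussian log-likelihood of a random-intercept model with
    independent residuals at the *given* parameters (no fitting)."""
    prep = _prepare(data, tuple(fixed_terms), response, subject_col, time_col,
                    need_bins=False, bin_width=None)
    r = prep.y - prep.X @ np.asarray(beta, dtype=float)
    s2u, s2e = sigma_u**2, sigma_e**2
    n = prep.counts.astype(float)
    subj = np.repeat(np.arange(len(prep.counts)), prep.counts)
    R = np.bincount(subj, weights=r)
    S = np.bincount(subj, weights=r * r)
    logdet = n * np.log(s2e) + np.log1p(n * s2u / s2e)
    quad = (S - (s2u / (s2e + n * s2u)) * R**2) / s2e
    return float(-0.5 * np.sum(logdet + quad + n * np.log(2 * np.pi)))
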