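"""End-to-end analysis workflow for a hypertension cohort.

Runs the full study sequence on a cohort (read from CSV or simulated):
descriptives -> normality panel -> univariable screens (mixed-model and Cox)
-> residual-covariance and random-effect selection -> multivariable LMM ->
Kaplan-Meier / log-rank -> proportional-hazards diagnostic -> Weibull
regression -> joint model -> association test, and writes every table analog
as CSV plus a human-readable text report.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .cohort import CohortTable, SyntheticConfig, generate_cohort, read_cohort
from .lmm import (LinearMixedModel, check_normality, compare_cov_structures,
                  compare_random_effects, univariable_screen)
from .survival import (CoxPHModel, WeibullRegressionModel, km_estimate,
                       logrank_test, ph_test, ratio_table)
from .joint import JointModel, association_test

logger = logging.getLogger(__name__)

#: Covariates offered to the univariable screens by default.
DEFAULT_CANDIDATES = (
    "gender", "residence", "age_group", "alcohol", "khat", "smoking", "stress",
    "stage", "lifestyle_change", "cholesterol", "adherence", "related_disease",
    "family_history", "diabetes", "fasting_blood_sugar",
)

#: Residual structure used for the final subject-specific model, given the
#: marginally selected structure (a random intercept absorbs the exchangeable
#: correlation of CS/HCS/UN, so only AR1 survives alongside it).
_RESIDUAL_WITH_RE = {"CS": "IND", "HCS": "IND", "CSH": "IND", "UN": "IND",
                     "AR1": "AR1", "IND": "IND"}


@dataclass
class AnalysisConfig:
    """Configuration of :func:`run_full_analysis`."""

    synthetic: SyntheticConfig | None = None
    input_dir: str | None = None
    screening_alpha: float = 0.25
    significance_level: float = 0.05
    cov_candidates: tuple = ("CS", "AR1", "UN", "HCS")
    re_candidates: tuple = ("intercept", "slope", "intercept+slope")
    candidates: tuple = DEFAULT_CANDIDATES
    association: str = "shared_intercept"
    km_group_covariates: tuple = ("age_group", "alcohol", "khat", "diabetes",
                                  "cholesterol", "adherence")
    normality_subsample: int = 1000
    out_dir: str | None = None
    seed: int = 0

    def validate(self):
        if not 0 < self.screening_alpha <= 1:
            raise ValueError("screening_alpha must lie in (0, 1]")
        if not 0 < self.significance_level <= 1:
            raise ValueError("significance_level must lie in (0, 1]")
        if not self.cov_candidates or not self.re_candidates:
            raise ValueError("candidate lists must be non-empty")
        if self.synthetic is None and self.input_dir is None:
            raise ValueError("either a synthetic config or an input directory is required")


@dataclass
class AnalysisReport:
    """All tables and scalar results of one pipeline run."""

    tables: dict = field(default_factory=dict)
    scalars: dict = field(default_factory=dict)
    log: list = field(default_factory=list)

    def equals(self, other: "AnalysisReport") -> bool:
        if set(self.tables) != set(other.tables):
            return False
        if json.dumps(self.scalars, sort_keys=True, default=str) != \
                json.dumps(other.scalars, sort_keys=True, default=str):
            return False
        for k, t in self.tables.items():
            o = other.tables[k]
            try:
                pd.testing.assert_frame_equal(
                    t.reset_index(drop=True), o.reset_index(drop=True),
                    check_dtype=False, check_exact=False, rtol=1e-9, atol=1e-12)
            except AssertionError:
                return False
        return self.log == other.log


def describe(cohort: CohortTable) -> pd.DataFrame:
    """Per-covariate category frequencies and within-category death proportions."""
    surv = cohort.merged_survival()
    rows = []
    n = len(surv)
    for cov in surv.columns:
        if cov in ("subject_id", "time", "event", "death_time"):
            continue
        if pd.api.types.is_numeric_dtype(surv[cov]) and surv[cov].nunique() > 10:
            continue  # continuous covariates are summarized elsewhere
        for cat, sub in surv.groupby(cov, observed=True):
            rows.append({
                "covariate": cov,
                "category": str(cat),
                "n": len(sub),
                "fraction": len(sub) / n,
                "deaths": int(sub["event"].sum()),
                "death_proportion": float(sub["event"].mean()),
            })
    rows.append({"covariate": "OVERALL", "category": "all", "n": n, "fraction": 1.0,
                 "deaths": int(surv["event"].sum()),
                 "death_proportion": float(surv["event"].mean())})
    return pd.DataFrame(rows)


def followup_summary(cohort: CohortTable) -> dict:
    t = cohort.survival["time"]
    return {"followup_median": float(t.median()), "followup_mean": float(t.mean()),
            "followup_sd": float(t.std(ddof=1)), "followup_max": float(t.max())}


def run_full_analysis(config: AnalysisConfig) -> AnalysisReport:
    """Execute the whole workflow; see the module docstring for the sequence.

    Every selection decision (retained covariates, chosen covariance
    structure, chosen random effects) is logged with the criterion value that
    drove it. Any stage error aborts with the stage name while preserving the
    partial report.
    """
    config.validate()
    report = AnalysisReport()
    log = report.log

    def stage(name):
        log.append(f"stage: {name}")
        logger.info("stage: %s", name)

    try:
        stage("load")
        if config.input_dir is not None:
            cohort = read_cohort(config.input_dir)
        else:
            syn = config.synthetic.replace(seed=config.seed)
            cohort = generate_cohort(syn)
        cohort.validate()
        report.scalars["n_subjects"] = int(len(cohort.survival))
        report.scalars["n_observations"] = int(len(cohort.longitudinal))
        report.scalars["seed"] = config.seed

        stage("descriptives")
        report.tables["descriptives"] = describe(cohort)
        report.scalars.update(followup_summary(cohort))
        report.scalars["event_fraction"] = float(cohort.survival["event"].mean())

        stage("normality")
        sbp = cohort.longitudinal["sbp"].to_numpy()
        if len(sbp) > config.normality_subsample:
            rng = np.random.default_rng(config.seed)
            sbp = rng.choice(sbp, size=config.normality_subsample, replace=False)
        norm_res = check_normality(sbp)
        report.tables["normality"] = norm_res.table
        report.scalars["normality_recommendation"] = norm_res.recommendation
        log.append(f"normality: recommended transform = {norm_res.recommendation}; "
                   "modeling proceeds on the sqrt scale")

        stage("longitudinal univariable screen")
        candidates = [c for c in config.candidates
                      if c in cohort.covariates.columns]
        screen_long = univariable_screen(cohort, candidates,
                                         alpha=config.screening_alpha)
        report.tables["longitudinal_screen"] = screen_long
        retained_long = list(screen_long.loc[screen_long["retained"], "covariate"])
        log.append(f"longitudinal screen (alpha={config.screening_alpha}): "
                   f"retained {retained_long}")

        stage("survival univariable screen (Cox)")
        surv_df = cohort.merged_survival()
        rows = []
        for cand in candidates:
            if surv_df[cand].nunique() <= 1:
                rows.append({"covariate": cand, "p_value": np.nan, "retained": False})
                continue
            try:
                cf = CoxPHModel(terms=(cand,)).fit(surv_df)
                # joint Wald over the candidate's columns
                b = cf.coef_
                C = cf.cov_
                stat = float(b @ np.linalg.solve(C, b))
                from scipy import stats as sstats
                p = float(sstats.chi2.sf(stat, len(b)))
            except Exception as exc:
                logger.warning("Cox screen failed for %s: %s", cand, exc)
                rows.append({"covariate": cand, "p_value": np.nan, "retained": False})
                continue
            rows.append({"covariate": cand, "p_value": p,
                         "retained": bool(p < config.screening_alpha)})
        screen_surv = pd.DataFrame(rows)
        report.tables["cox_screen"] = screen_surv
        retained_surv = list(screen_surv.loc[screen_surv["retained"], "covariate"])
        log.append(f"Cox screen (alpha={config.screening_alpha}): "
                   f"retained {retained_surv}")

        fixed_long = tuple(["time"] + retained_long)

        stage("covariance structure selection")
        base = LinearMixedModel(fixed_terms=fixed_long, random_terms="none",
                                method="ML")
        cov_sel = compare_cov_structures(cohort, base,
                                         structures=config.cov_candidates)
        report.tables["covariance_selection"] = cov_sel.drop(columns=["error"])
        sel_struct = cov_sel.attrs["selected"]
        log.append(f"covariance selection: {sel_struct} "
                   f"(AIC {cov_sel.iloc[0]['aic']:.2f})")

        stage("random effects selection")
        base_re = LinearMixedModel(fixed_terms=fixed_long, cov_structure="IND",
                                   method="ML")
        re_sel = compare_random_effects(cohort, base_re,
                                        configurations=config.re_candidates)
        report.tables["random_effects_selection"] = re_sel.drop(columns=["error"])
        sel_re = re_sel.attrs["selected"]
        log.append(f"random-effect selection: {sel_re} "
                   f"(AIC {re_sel.iloc[0]['aic']:.2f})")

        stage("multivariable linear mixed model")
        resid = _RESIDUAL_WITH_RE.get(sel_struct, "IND")
        if resid != sel_struct:
            log.append(f"residual structure {sel_struct} is aliased with the random "
                       f"effect; subject-specific model uses {resid} residuals")
        lmm_fit = LinearMixedModel(fixed_terms=fixed_long, random_terms=sel_re,
                                   cov_structure=resid, method="REML").fit(cohort)
        tab3 = lmm_fit.beta_.copy()
        tab3.insert(0, "term", tab3.index)
        report.tables["lmm_multivariable"] = tab3.reset_index(drop=True)
        report.scalars["lmm_loglik"] = lmm_fit.loglik_
        report.scalars["lmm_aic"] = lmm_fit.aic_
        report.scalars["lmm_sigma_u"] = (float(np.sqrt(lmm_fit.D_[0, 0]))
                                         if lmm_fit.D_ is not None else np.nan)

        stage("Kaplan-Meier / log-rank")
        km_all = km_estimate(cohort)
        report.scalars["km_median_defined"] = bool(km_all.median_defined)
        report.scalars["km_median"] = float(km_all.median) if km_all.median_defined else None
        km_frames = [km_all.as_frame().assign(covariate="OVERALL", group="all")]
        lr_rows = []
        for cov in config.km_group_covariates:
            if cov not in surv_df.columns:
                continue
            curves = km_estimate(cohort, group_col=cov)
            for g, c in curves.items():
                km_frames.append(c.as_frame().assign(covariate=cov, group=str(g)))
            lr = logrank_test(cohort, cov)
            lr_rows.append({"covariate": cov, "chi_square": lr.chi_square,
                            "df": lr.df, "p_value": lr.p_value})
        report.tables["km_curves"] = pd.concat(km_frames, ignore_index=True)
        report.tables["logrank"] = pd.DataFrame(lr_rows)

        stage("proportional hazards diagnostic")
        ph_terms = tuple(retained_surv) if retained_surv else tuple(retained_long)
        ph_tab = ph_test(cohort, ph_terms)
        report.tables["ph_test"] = ph_tab
        global_p = float(ph_tab.loc[ph_tab["covariate"] == "GLOBAL", "p_value"].iloc[0])
        report.scalars["ph_global_p"] = global_p
        if global_p < config.significance_level:
            log.append(f"PH assumption rejected globally (p={global_p:.4g}); "
                       "proceeding with the parametric Weibull model")
        else:
            log.append(f"PH assumption not rejected (p={global_p:.4g}); Weibull "
                       "model fitted as the study's parametric analog anyway")

        stage("Weibull regression")
        wb = WeibullRegressionModel(terms=ph_terms).fit(cohort)
        tab4 = wb.params_.copy()
        tab4["exp_coef"] = np.exp(tab4["estimate"])
        tab4.insert(0, "term", tab4.index)
        report.tables["weibull"] = tab4.reset_index(drop=True)
        report.tables["weibull_ratios"] = ratio_table(wb).reset_index(names="term")
        report.scalars["weibull_shape"] = wb.shape_
        report.scalars["weibull_loglik"] = wb.loglik_

        stage("joint model")
        jm = JointModel(longitudinal_terms=fixed_long, survival_terms=ph_terms,
                        association=config.association).fit(cohort)
        t5a = jm.longitudinal_params_.copy()
        t5a.insert(0, "term", t5a.index)
        t5b = jm.survival_params_.copy()
        t5b.insert(0, "term", t5b.index)
        report.tables["joint_longitudinal"] = t5a.reset_index(drop=True)
        report.tables["joint_survival"] = t5b.reset_index(drop=True)
        z, p, direction = association_test(jm)
        report.scalars.update({
            "gamma": jm.gamma_, "gamma_se": jm.gamma_se_, "gamma_z": float(z),
            "gamma_p": float(p), "association_direction": direction,
            "joint_loglik": jm.loglik_, "joint_sigma_u": jm.sigma_u_,
            "joint_sigma_e": jm.sigma_e_, "joint_shape": jm.shape_,
            "selected_structure": str(sel_struct), "selected_random": str(sel_re),
        })
        log.append(f"association: gamma={jm.gamma_:.4f} (z={z:.3f}, p={p:.3g})")

        if config.out_dir is not None:
            stage("write report")
            write_report(report, config.out_dir)
        return report
    except Exception as exc:
        last = next((l[7:] for l in reversed(log) if l.startswith("stage: ")), "?")
        raise RuntimeError(f"pipeline failed at stage {last!r}: {exc}") from exc


# ---------------------------------------------------------------------------
# serialization


def write_report(report: AnalysisReport, out_dir) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for name, tab in report.tables.items():
        tab.to_csv(out / f"{name}.csv", index=False)
    with open(out / "scalars.json", "w") as fh:
        json.dump(report.scalars, fh, indent=2, sort_keys=True, default=str)
    with open(out / "run_log.txt", "w") as fh:
        fh.write("\n".join(report.log) + "\n")
    with open(out / "report.txt", "w") as fh:
        fh.write(render_text_report(report))


def read_report(in_dir) -> AnalysisReport:
    p = Path(in_dir)
    # keep literal category labels such as "None"; only empty cells are missing
    tables = {f.stem: pd.read_csv(f, keep_default_na=False, na_values=[""],
                                  float_precision="round_trip")
              for f in sorted(p.glob("*.csv"))}
    with open(p / "scalars.json") as fh:
        scalars = json.load(fh)
    log = (p / "run_log.txt").read_text().rstrip("\n").split("\n")
    return AnalysisReport(tables=tables, scalars=scalars, log=log)


def render_text_report(report: AnalysisReport) -> str:
    s = report.scalars
    lines = ["Hypertension cohort analysis", "=" * 32, ""]
    lines.append(f"subjects: {s.get('n_subjects')}   observations: {s.get('n_observations')}")
    ef = s.get("event_fraction")
    if ef is not None:
        lines.append(f"deaths: {100 * ef:.1f}%   follow-up median {s.get('followup_median'):.1f} "
                     f"mean {s.get('followup_mean'):.1f} sd {s.get('followup_sd'):.1f} months")
    lines.append(f"normality: recommended transform = {s.get('normality_recommendation')}")
    lines.append(f"selected covariance structure: {s.get('selected_structure')}   "
                 f"random effects: {s.get('selected_random')}")
    if "gamma" in s:
        lines.append("")
        lines.append(f"joint-model association gamma = {s['gamma']:.4f} "
                     f"(SE {s['gamma_se']:.4f}, z = {s['gamma_z']:.3f}, p = {s['gamma_p']:.3g})")
        lines.append(s.get("association_direction", ""))
    lines.append("")
    lines.append("run log:")
    lines.extend("  " + l for l in report.log)
    return "\n".join(lines) + "\n"
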