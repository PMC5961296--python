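"""Validation experiments for the pooled-analysis pipeline.

Self-contained drivers that exercise the whole package against known
answers: printed-count arithmetic reproduced through the summary code
path, reduction of the frailty model to an ordinary Cox fit, closed-form
attributable-fraction checks, and simulation experiments (hazard-ratio
CI coverage, attributable-fraction recovery against the generator's
analytic truth, bootstrap CI coverage).  Used by the acceptance test
suite and the reproduction script; every function is deterministic given
its seed.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd

from .attributable_fraction import (
    CounterfactualSpec, DEFAULT_FACTORS, apply_counterfactual_records,
    build_prediction_paths, compute_aaf, expected_deaths, make_refitter,
)
from .attributable_fraction import _resample_within_studies
from .cohort_data import apply_categorization, split_episodes, summarize_cohort
from .frailty_cox import (
    BreslowBaseline, DesignInfo, FrailtyCoxFit, ModelSpec, fit_frailty_cox,
)
from .pipeline import default_table3_spec
from .survival_basics import kaplan_meier, log_rank_test
from .synthetic_cohort import CohortConfig, generate_cohort, true_attributable_fraction

_BASE = dict(
    study_id="S00", region="Africa", subregion="Southern Africa",
    sex="male", birth_weight_group="ge2500", ever_breastfed="yes",
    weaning_age_days=183.0, arv_category="none",
    art_start_age_days=np.nan, art_end_age_days=np.nan, cd4_group="ge350",
    maternal_death_age_days=np.nan, child_death_age_days=np.nan,
    censor_age_days=730.0,
)


def _records(rows):
    out = []
    for i, r in enumerate(rows):
        d = dict(_BASE, child_id=f"c{i:05d}")
        d.update(r)
        out.append(d)
    return pd.DataFrame(out)


# --------------------------------------------------------------------------
# printed-count arithmetic through summarize_cohort
# --------------------------------------------------------------------------

def crude_death_proportions() -> dict[str, float]:
    """Per-study crude death percentages recomputed from published per-study
    child and death counts (deaths/children, to one decimal)."""
    counts = {"ZEBS": (763, 93), "DitrameB": (90, 16), "Zvitambo": (3118, 245)}
    rows = []
    for sid, (n, d) in counts.items():
        rows += [{"study_id": sid, "child_death_age_days": 100.0,
                  "censor_age_days": 100.0}] * d
        rows += [{"study_id": sid}] * (n - d)
    summary = summarize_cohort(apply_categorization(_records(rows)))
    tab = summary.per_study.set_index("study_id")["death_pct"]
    return {sid: float(tab[sid]) for sid in counts}


def post_maternal_death_mortality_pct() -> float:
    """Mortality among children whose mothers died (51 of 300), as a
    percentage, recomputed through the cohort summary."""
    rows = ([{"maternal_death_age_days": 90.0, "child_death_age_days": 180.0,
              "censor_age_days": 180.0}] * 51
            + [{"maternal_death_age_days": 90.0}] * 249
            + [{}] * 200)
    summary = summarize_cohort(apply_categorization(_records(rows)))
    return float(summary.overall["post_maternal_death_mortality_pct"])


def cohort_composition_percentages() -> dict[str, float]:
    """Pooled-population composition percentages recomputed from published
    counts (N = 19 219): ever breastfed 13 418, CD4 >= 350 11 129."""
    n = 19219
    rows = []
    for i in range(n):
        rows.append({
            "ever_breastfed": "yes" if i < 13418 else "no",
            "weaning_age_days": 183.0 if i < 13418 else np.nan,
            "cd4_group": ("ge350" if i < 11129 else
                          "lt350" if i < 11129 + 7010 else "unknown"),
        })
    summary = summarize_cohort(apply_categorization(_records(rows)))
    prev = summary.prevalences.set_index(["covariate", "level"])["pct"]
    return {
        "ever_breastfed_pct": float(prev[("ever_breastfed", "yes")]),
        "cd4_ge350_pct": float(prev[("cd4_group", "ge350")]),
    }


# --------------------------------------------------------------------------
# oracle fixtures
# --------------------------------------------------------------------------

def _dense_config(seed=7, n=500, theta=0.0, studies=1) -> CohortConfig:
    return CohortConfig(
        n_studies=studies, n_asia_studies=0,
        children_per_study=max(n // studies, 1),
        frailty_variance=theta, round_days=False, seed=seed,
        baseline_rates=(2.4e-3, 1.3e-3, 6.4e-4, 3.2e-4, 1.6e-4),
        maternal_death_rate=4e-4,
        prevalences={
            "sex": {"male": .5, "female": .5},
            "birth_weight_group": {"ge2500": .85, "lt2500": .15},
            "ever_breastfed": {"yes": .7, "no": .3},
            "cd4_group": {"ge350": .6, "lt350": .4},
            "arv_category": {"none": .4, "mono_dual_pmtct": .6},
        },
        true_log_hr={
            "birth_weight_group:lt2500": math.log(2.9),
            "ever_breastfed:no": math.log(2.5),
            "mother_dead": math.log(6.0),
        },
        ever_bf_unknown_prob=0.0, weaning_missing_prob=0.0,
        arv_missing_prob=0.0,
    )


def reduction_to_cox_max_delta(seed: int = 7, n: int = 500) -> float:
    """Max |beta difference| between the frailty fit at theta = 0 (single
    study) and lifelines' counting-process Cox fit on the same episodes."""
    from lifelines import CoxTimeVaryingFitter

    eps = split_episodes(apply_categorization(
        generate_cohort(_dense_config(seed=seed, n=n))))
    spec = ModelSpec(covariates={"birth_weight_group": "ge2500",
                                 "ever_breastfed": "yes", "mother_dead": "0"})
    fit = fit_frailty_cox(eps, spec, theta=0.0)
    pairs = [("birth_weight_group", "lt2500"), ("ever_breastfed", "no"),
             ("mother_dead", "1")]
    df = eps.copy()
    cols = []
    for c, l in pairs:
        df[f"{c}_x"] = (df[c].astype(str) == l).astype(float)
        cols.append(f"{c}_x")
    ctv = CoxTimeVaryingFitter()
    ctv.fit(df[["child_id", "start", "stop", "event"] + cols],
            id_col="child_id", start_col="start", stop_col="stop",
            event_col="event")
    ours = fit.beta[[f"{c}:{l}" for c, l in pairs]].to_numpy()
    return float(np.max(np.abs(ours - ctv.params_.to_numpy())))


def closed_form_aaf_error(n: int = 2000, seed: int = 3) -> float:
    """|aAF - analytic AF| for a single binary factor under constant
    hazards at the true parameters (theta = 0, hazard ratio 2)."""
    lam0, t, p = 1e-4, 365.0, 0.5
    times = np.array([183.0, 365.0, 730.0])
    base = BreslowBaseline(times, lam0 * np.diff(np.concatenate([[0.], times])))
    design = DesignInfo(
        covariates=[("birth_weight_group", "ge2500", ["lt2500"])],
        columns=["birth_weight_group:lt2500"])
    fit = FrailtyCoxFit(
        beta=pd.Series([math.log(2.0)], index=design.columns),
        se_beta=pd.Series([0.1], index=design.columns),
        cov_beta=pd.DataFrame([[0.01]], index=design.columns,
                              columns=design.columns),
        theta=0.0, frailties=pd.Series([1.0], index=["S00"]),
        baseline=base, loglik=0.0, n_events=1, n_subjects=n,
        n_iterations=1, converged=True, design=design,
        spec=ModelSpec(covariates={"birth_weight_group": "ge2500"}))
    rng = np.random.default_rng(seed)
    bw = np.where(rng.random(n) < p, "lt2500", "ge2500")
    rec = _records([{"birth_weight_group": b} for b in bw])
    res = compute_aaf(fit, rec,
                      CounterfactualSpec("birth_weight_group", "ge2500"),
                      horizons=[t])
    p_emp = float((bw == "lt2500").mean())
    l1 = 2 * lam0
    closed = (p_emp * (math.exp(-lam0 * t) - math.exp(-l1 * t))
              / (1 - p_emp * math.exp(-l1 * t)
                 - (1 - p_emp) * math.exp(-lam0 * t)))
    return abs(res.aaf(t) - closed)


# --------------------------------------------------------------------------
# simulation experiments
# --------------------------------------------------------------------------

#: Targets of the recovery experiments: generator truth for the main model.
RECOVERY_TERMS = {
    "birth_weight_group:lt2500": 2.92,
    "ever_breastfed:no": 2.48,
    "mother_dead:1": 11.08,
    "arv_category:art_life": 0.51,
}


def hr_coverage_experiment(reps: int = 40, seed: int = 5000,
                           n_studies: int = 20, children: int = 960
                           ) -> dict[str, dict]:
    """Replicate cohorts under the pooled study conditions; count how often
    each estimated hazard ratio's 95% CI covers the generating truth."""
    out = {t: {"covered": 0, "reps": reps, "true_hr": hr, "estimates": []}
           for t, hr in RECOVERY_TERMS.items()}
    spec = default_table3_spec()
    for r in range(reps):
        cfg = CohortConfig(n_studies=n_studies, children_per_study=children,
                           seed=seed + r)
        cat = apply_categorization(generate_cohort(cfg))
        fit = fit_frailty_cox(split_episodes(cat), spec)
        hr_tab = fit.hazard_ratios()
        for term, truth in RECOVERY_TERMS.items():
            row = hr_tab.loc[term]
            out[term]["estimates"].append(float(row["hr"]))
            if row["ci_lower"] <= truth <= row["ci_upper"]:
                out[term]["covered"] += 1
    return out


def _recovery_config(n_children: int = 32000) -> CohortConfig:
    """Large-cohort recovery conditions: the default pooled-population
    generator with complete 730-day follow-up, which isolates estimator
    performance from follow-up incompleteness."""
    n_studies = 20
    return CohortConfig(
        n_studies=n_studies,
        children_per_study=max(n_children // n_studies, 1),
        study_followup_days=tuple([730] * n_studies),
        followup_jitter_days=0.0, ltfu_rate=0.0)


def _all_factor_aafs(fit: FrailtyCoxFit, records: pd.DataFrame,
                     horizon: float) -> dict[str, float]:
    """aAF of each of the four factors plus the combination, sharing one
    factual-path expansion."""
    paths = build_prediction_paths(records, horizon)
    D = expected_deaths(fit, paths, horizon)
    out = {}
    specs = [CounterfactualSpec(f, l) for f, l in DEFAULT_FACTORS.items()]
    for sp in specs:
        cf = apply_counterfactual_records(records, [sp])
        Dcf = expected_deaths(fit, build_prediction_paths(cf, horizon), horizon)
        out[sp.factor] = (D - Dcf) / D
    cf = apply_counterfactual_records(records, specs)
    Dcf = expected_deaths(fit, build_prediction_paths(cf, horizon), horizon)
    out["combined"] = (D - Dcf) / D
    return out


def aaf_recovery_experiment(n_children: int = 32000, B: int = 30,
                            seed: int = 777, horizon: float = 730.0
                            ) -> dict[str, dict]:
    """Estimated aAF on one large synthetic cohort versus the generator's
    analytic attributable fraction, with a bootstrap standard error.

    One set of B within-study child resamples serves all factors.
    """
    cfg = _recovery_config(n_children)
    rec = generate_cohort(cfg, seed=seed)
    cat = apply_categorization(rec)
    analysed = cat.loc[~cat["excluded"].astype(bool)]
    refit = make_refitter(default_table3_spec())
    fit = refit(analysed)
    est = _all_factor_aafs(fit, analysed, horizon)

    factor_maps = dict(DEFAULT_FACTORS)
    truth = {f: true_attributable_fraction(cfg, f, horizon,
                                           n_children=120000, seed=seed + 1)
             for f in factor_maps}
    truth["combined"] = true_attributable_fraction(
        cfg, factor_maps, horizon, n_children=120000, seed=seed + 1)

    rng = np.random.default_rng(seed + 2)
    draws: dict[str, list[float]] = {k: [] for k in est}
    for _b in range(B):
        boot = _resample_within_studies(analysed, rng)
        fit_b = refit(boot)
        for k, v in _all_factor_aafs(fit_b, boot, horizon).items():
            draws[k].append(v)
    out = {}
    for k in est:
        se = float(np.std(draws[k], ddof=1))
        out[k] = {"estimate": float(est[k]), "true": float(truth[k]),
                  "boot_se": se, "B": B,
                  "abs_z": abs(est[k] - truth[k]) / se if se > 0 else np.inf}
    return out


def _bootstrap_coverage_config(n_children: int, seed: int) -> CohortConfig:
    """Scaled-down conditions for bootstrap CI calibration: a handful of
    study clusters, one binary risk factor, moderate censoring."""
    n_studies = 5
    return CohortConfig(
        n_studies=n_studies, n_asia_studies=0,
        children_per_study=max(n_children // n_studies, 1),
        frailty_variance=0.25, seed=seed,
        baseline_rates=(1.6e-3, 9e-4, 4.5e-4, 2.2e-4, 1.1e-4),
        maternal_death_rate=0.0,
        study_followup_days=(400, 550, 600, 730, 730),
        prevalences={
            "sex": {"male": .5, "female": .5},
            "birth_weight_group": {"ge2500": .75, "lt2500": .25},
            "ever_breastfed": {"yes": 1.0},
            "cd4_group": {"ge350": 1.0},
            "arv_category": {"none": 1.0},
        },
        true_log_hr={"birth_weight_group:lt2500": math.log(2.5)},
        ever_bf_unknown_prob=0.0, weaning_missing_prob=0.0,
        arv_missing_prob=0.0)


def aaf_bootstrap_coverage_experiment(reps: int = 50, B: int = 60,
                                      n_children: int = 1500,
                                      seed: int = 8000,
                                      horizon: float = 730.0) -> dict:
    """Nominal-95% percentile-bootstrap CI coverage of the true AF of a
    single binary factor across replicate cohorts."""
    cfg0 = _bootstrap_coverage_config(n_children, seed)
    truth = true_attributable_fraction(cfg0, "birth_weight_group", horizon,
                                       n_children=200000, seed=seed)
    from .attributable_fraction import bootstrap_aaf

    spec = ModelSpec(covariates={"birth_weight_group": "ge2500"})
    covered, widths = 0, []
    for r in range(reps):
        cfg = _bootstrap_coverage_config(n_children, seed + 1 + r)
        cat = apply_categorization(generate_cohort(cfg))
        res = bootstrap_aaf(
            cat, make_refitter(spec),
            CounterfactualSpec("birth_weight_group", "ge2500"),
            horizons=[horizon], B=B, seed=seed + 10000 + r)
        row = res.table.iloc[0]
        covered += row["ci_lower"] <= truth <= row["ci_upper"]
        widths.append(float(row["ci_upper"] - row["ci_lower"]))
    return {"covered": int(covered), "reps": reps, "B": B,
            "true_af": float(truth), "mean_ci_width": float(np.mean(widths))}


# --------------------------------------------------------------------------
# conservation / invariance suite
# --------------------------------------------------------------------------

def conservation_suite(seed: int = 99) -> dict[str, float]:
    """Exact structural identities: person-time conservation under episode
    splitting, KM = 1 - ECDF without censoring, log-rank p = 1 on
    duplicated groups, aAF = 0 under zero prevalence and under a null
    effect.  Returns the measured discrepancies (all should be 0)."""
    rng = np.random.default_rng(seed)
    n = 1000
    t = rng.integers(1, 900, size=n).astype(float)
    died = rng.random(n) < 0.3
    md = np.where(rng.random(n) < 0.3, rng.integers(0, 900, size=n), np.nan)
    wean = np.where(rng.random(n) < 0.7, rng.integers(0, 900, size=n), np.nan)
    rec = _records([
        {"child_death_age_days": t[i] if died[i] else np.nan,
         "censor_age_days": t[i],
         "maternal_death_age_days": md[i],
         "weaning_age_days": min(wean[i], t[i]) if np.isfinite(wean[i]) else np.nan,
         "study_id": f"S{i % 7}"}
        for i in range(n)])
    cat = apply_categorization(rec)
    end = np.minimum(np.where(cat["child_death_age_days"].notna(),
                              cat["child_death_age_days"],
                              cat["censor_age_days"]), 730.0)
    pt_errors = []
    for scheme in ("maternal_vital_only", "plus_bf_cessation", "bf_by_art_joint"):
        eps = split_episodes(cat, scheme=scheme)
        pt_errors.append(abs(float((eps["stop"] - eps["start"]).sum())
                             - float(end.sum())))
    pt_error = max(pt_errors)

    # KM vs empirical CDF with no censoring
    t2 = rng.integers(1, 700, size=300).astype(float)
    rec2 = _records([{"child_death_age_days": x, "censor_age_days": x}
                     for x in t2])
    km = kaplan_meier(rec2)
    grid = np.arange(1, 701, dtype=float)
    ecdf = np.searchsorted(np.sort(t2), grid, side="right") / len(t2)
    km_error = float(np.max(np.abs(km.survival_at(grid) - (1 - ecdf))))

    # log-rank on duplicated groups
    recA = rec2.assign(g="a")
    recB = rec2.assign(g="b", child_id=rec2["child_id"] + "x")
    stat, p = log_rank_test(pd.concat([recA, recB]), "g")
    logrank_error = max(abs(stat), abs(p - 1.0))

    # aAF exact zeros
    zero_prev = closed_form_zero = None
    times = np.array([365.0, 730.0])
    base = BreslowBaseline(times, 1e-4 * np.diff(np.concatenate([[0.], times])))
    design = DesignInfo(
        covariates=[("birth_weight_group", "ge2500", ["lt2500"])],
        columns=["birth_weight_group:lt2500"])

    def fit_with(log_hr):
        return FrailtyCoxFit(
            beta=pd.Series([log_hr], index=design.columns),
            se_beta=pd.Series([0.1], index=design.columns),
            cov_beta=pd.DataFrame([[0.01]], index=design.columns,
                                  columns=design.columns),
            theta=0.0, frailties=pd.Series([1.0], index=["S00"]),
            baseline=base, loglik=0.0, n_events=1, n_subjects=1,
            n_iterations=1, converged=True, design=design,
            spec=ModelSpec(covariates={"birth_weight_group": "ge2500"}))

    rec3 = _records([{"birth_weight_group": "ge2500"}] * 50)
    zero_prev = abs(compute_aaf(
        fit_with(math.log(3.0)), rec3,
        CounterfactualSpec("birth_weight_group", "ge2500"),
        horizons=[730.0]).aaf(730.0))
    rec4 = _records([{"birth_weight_group":
                      "lt2500" if i % 2 else "ge2500"} for i in range(50)])
    closed_form_zero = abs(compute_aaf(
        fit_with(0.0), rec4,
        CounterfactualSpec("birth_weight_group", "ge2500"),
        horizons=[730.0]).aaf(730.0))

    return {
        "person_time_error": pt_error,
        "km_vs_ecdf_error": km_error,
        "logrank_duplicate_error": float(logrank_error),
        "aaf_zero_prevalence": float(zero_prev),
        "aaf_null_effect": float(closed_form_zero),
    }
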