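"""End-to-end orchestration: run configuration, stages, outputs, manifest.

``run_pipeline`` reproduces the full pooled analysis on any conforming
cohort (a child-record CSV or a simulated cohort): categorization ->
episode expansion -> descriptive tables and survival curves -> univariate
screen -> stepwise-descending selection -> final shared-frailty Cox fits
(main multivariable model, weaning-as-time-dependent model among breastfed
children, joint breastfeeding-by-ART model) -> counterfactual adjusted
attributable fractions with bootstrap CIs.  Every exclusion and imputation
count is logged and recorded in a machine-readable manifest.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .attributable_fraction import (
    CounterfactualSpec, DEFAULT_FACTORS, aaf_table, bootstrap_aaf, compute_aaf,
    make_refitter,
)
from .cohort_data import (
    CategorizationRules, RECORD_COLUMNS, apply_categorization, split_episodes,
    summarize_cohort,
)
from .frailty_cox import (
    ModelSpec, fit_frailty_cox, fit_joint_bf_art, stepwise_descending_select,
    univariate_screen,
)
from .survival_basics import (
    cumulative_incidence, kaplan_meier, log_rank_test, mortality_rate_per_100cy,
    plot_km,
)
from .synthetic_cohort import CohortConfig, generate_cohort

logger = logging.getLogger(__name__)


def default_table3_spec() -> ModelSpec:
    """Candidate covariates of the main multivariable mortality model."""
    return ModelSpec(
        covariates={
            "region": "Africa",
            "sex": "male",
            "birth_weight_group": "ge2500",
            "ever_breastfed": "yes",
            "cd4_group": "ge350",
            "arv_category": "none",
            "mother_dead": "0",
        },
        time_dependent=("mother_dead",),
        always_keep=("arv_category",),
        forced=("region", "cd4_group"),
        selection="stepwise_descending",
    )


def weaning_td_spec() -> ModelSpec:
    """Breastfeeding cessation as a time-dependent exposure (breastfed
    children only); reference is currently breastfed."""
    return ModelSpec(
        covariates={
            "currently_breastfed": "1",
            "region": "Africa",
            "birth_weight_group": "ge2500",
            "cd4_group": "ge350",
            "arv_category": "none",
        },
        time_dependent=("currently_breastfed",),
        always_keep=("arv_category",),
        forced=("region", "cd4_group"),
    )


@dataclass
class RunConfig:
    """Validated run configuration (YAML/JSON serializable)."""

    input_csv: str | None = None
    simulate: CohortConfig | None = None
    rules: CategorizationRules = field(default_factory=CategorizationRules)
    seed: int = 0
    aaf_horizons: tuple[float, ...] = (183.0, 365.0, 730.0)
    aaf_bootstrap: int = 0  # 0 disables bootstrap CIs
    run_selection: bool = True
    run_weaning_td: bool = True
    run_joint_bf_art: bool = True
    run_aaf: bool = True
    exclude_imputed_weaning: bool = False
    exclude_imputed_arv: bool = False
    output_dir: str = "heusurv_out"

    def __post_init__(self):
        if (self.input_csv is None) == (self.simulate is None):
            raise ValueError("exactly one of input_csv / simulate must be set")

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if d.get("simulate") is not None:
            d["simulate"] = CohortConfig.from_dict(d["simulate"])
        if "rules" in d and isinstance(d["rules"], dict):
            d["rules"] = CategorizationRules(**d["rules"])
        if "aaf_horizons" in d:
            d["aaf_horizons"] = tuple(float(h) for h in d["aaf_horizons"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def to_dict(self) -> dict:
        from dataclasses import asdict
        d = asdict(self)
        return d


def bundled_config_path() -> Path:
    """Path of the bundled fixture run configuration (small synthetic
    multi-study cohort approximating the pooled population)."""
    return Path(__file__).parent / "configs" / "pooled_cohort.yaml"


def validate_input(path) -> pd.DataFrame:
    """Schema and invariant diagnostics for a child-record CSV.

    Always returns a diagnostics table (possibly empty) with one row per
    violation: (row identifier, column, problem).
    """
    df = pd.read_csv(path)
    issues = []
    for col in RECORD_COLUMNS:
        if col not in df.columns:
            issues.append({"child_id": "", "column": col, "problem": "missing column"})
    if issues:
        return pd.DataFrame(issues)
    num = {c: pd.to_numeric(df[c], errors="coerce") for c in (
        "weaning_age_days", "maternal_death_age_days",
        "child_death_age_days", "censor_age_days")}
    for col, vals in num.items():
        miss_pct = 100.0 * vals.isna().mean()
        logger.info("validate: %s %.1f%% missing", col, miss_pct)
        bad = vals < 0
        for cid in df.loc[bad, "child_id"]:
            issues.append({"child_id": cid, "column": col, "problem": "negative age"})
    late = num["child_death_age_days"] > num["censor_age_days"]
    for cid in df.loc[late.fillna(False), "child_id"]:
        issues.append({"child_id": cid, "column": "child_death_age_days",
                       "problem": "death after censoring date"})
    contra = (df["ever_breastfed"].astype(object) == "no") & num["weaning_age_days"].notna()
    for cid in df.loc[contra, "child_id"]:
        issues.append({"child_id": cid, "column": "weaning_age_days",
                       "problem": "weaning date on never-breastfed child"})
    return pd.DataFrame(issues, columns=["child_id", "column", "problem"])


def _config_hash(config: RunConfig) -> str:
    js = json.dumps(config.to_dict(), sort_keys=True, default=str)
    return hashlib.sha256(js.encode()).hexdigest()[:16]


def run_pipeline(config: RunConfig) -> dict:
    """Execute every stage and write all table analogues plus a manifest.

    Returns the manifest dict (also written to ``manifest.json`` in the
    output directory).
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "package_version": __version__,
        "seed": config.seed,
        "config_hash": _config_hash(config),
        "stages": {},
        "outputs": [],
    }

    def save(df: pd.DataFrame, name: str, stage: str):
        path = out / name
        df.to_csv(path, index=False)
        manifest["outputs"].append({"file": name, "stage": stage})

    # ---- input ----------------------------------------------------------
    if config.simulate is not None:
        records = generate_cohort(config.simulate, seed=config.seed)
        manifest["stages"]["input"] = {"simulated": True,
                                       "n_children": int(len(records))}
    else:
        records = pd.read_csv(config.input_csv)
        manifest["stages"]["input"] = {"simulated": False,
                                       "n_children": int(len(records))}

    # ---- categorization -------------------------------------------------
    cat = apply_categorization(records, config.rules)
    report = cat.attrs["categorization_report"]
    manifest["stages"]["categorization"] = report
    if config.exclude_imputed_weaning:
        n0 = len(cat)
        cat = cat.loc[~cat["weaning_imputed"].astype(bool)].copy()
        logger.info("sensitivity filter: excluded %d children with imputed "
                    "weaning", n0 - len(cat))
        manifest["stages"]["sensitivity_exclusions"] = {
            "imputed_weaning": n0 - len(cat)}
    if config.exclude_imputed_arv and "arv_imputed" in cat.columns:
        n0 = len(cat)
        cat = cat.loc[~cat["arv_imputed"].astype(bool)].copy()
        manifest["stages"].setdefault("sensitivity_exclusions", {})[
            "imputed_arv"] = n0 - len(cat)

    # ---- descriptives ---------------------------------------------------
    summary = summarize_cohort(cat)
    save(summary.per_study, "per_study_summary.csv", "descriptives")
    save(summary.prevalences, "covariate_prevalences.csv", "descriptives")
    (out / "overall_summary.json").write_text(json.dumps(summary.overall, indent=2))
    manifest["outputs"].append({"file": "overall_summary.json", "stage": "descriptives"})

    analysed = cat.loc[~cat["excluded"].astype(bool)]
    ci = cumulative_incidence(analysed, [91, 183, 365, 730])
    save(ci, "cumulative_incidence.csv", "descriptives")
    curves = kaplan_meier(analysed, group_by="region")
    if len(curves) > 1:
        stat, p = log_rank_test(analysed, "region")
        manifest["stages"]["km_by_region"] = {"logrank_stat": stat, "logrank_p": p}
        try:
            plot_km(curves, out / "survival_by_region.png",
                    title="24-month survival by region")
            manifest["outputs"].append({"file": "survival_by_region.png",
                                        "stage": "descriptives"})
        except Exception as exc:  # plotting must never sink the analysis
            logger.warning("KM plot failed: %s", exc)

    episodes = split_episodes(cat, scheme="maternal_vital_only")
    rates = mortality_rate_per_100cy(episodes, group_by="arv_category")
    save(rates, "mortality_rates_by_arv.csv", "descriptives")

    # ---- model selection and main fit -----------------------------------
    spec = default_table3_spec()
    screen = univariate_screen(episodes, spec)
    save(screen, "univariate_screen.csv", "screen")
    if config.run_selection:
        final_spec = stepwise_descending_select(episodes, spec, screen=screen)
    else:
        final_spec = spec
    fit = fit_frailty_cox(episodes, final_spec)
    hr = fit.hazard_ratios().reset_index(names="term")
    save(hr, "main_model_hazard_ratios.csv", "main_model")
    (out / "main_model_fit.json").write_text(json.dumps(fit.to_dict(), indent=2))
    manifest["outputs"].append({"file": "main_model_fit.json", "stage": "main_model"})
    manifest["stages"]["main_model"] = {
        "covariates": list(final_spec.covariates),
        "theta": fit.theta,
        "n_events": fit.n_events,
        "converged": fit.converged,
    }

    # ---- weaning as time-dependent exposure (breastfed children) --------
    if config.run_weaning_td:
        bf = cat.loc[cat["ever_breastfed"].astype(object) == "yes"]
        eps_bf = split_episodes(bf, scheme="plus_bf_cessation")
        fit_td = fit_frailty_cox(eps_bf, weaning_td_spec())
        save(fit_td.hazard_ratios().reset_index(names="term"),
             "weaning_td_hazard_ratios.csv", "weaning_td")
        manifest["stages"]["weaning_td"] = {"theta": fit_td.theta,
                                            "n_events": fit_td.n_events}

    # ---- joint breastfeeding-by-ART model --------------------------------
    if config.run_joint_bf_art:
        eps_joint = split_episodes(cat, scheme="bf_by_art_joint")
        fit_joint = fit_joint_bf_art(eps_joint)
        save(fit_joint.hazard_ratios().reset_index(names="term"),
             "joint_bf_art_hazard_ratios.csv", "joint_bf_art")
        save(mortality_rate_per_100cy(eps_joint, group_by="bf_art_category"),
             "joint_bf_art_rates.csv", "joint_bf_art")
        manifest["stages"]["joint_bf_art"] = {"theta": fit_joint.theta}

    # ---- adjusted attributable fractions ---------------------------------
    if config.run_aaf:
        results = {}
        singles = [CounterfactualSpec(f, l) for f, l in DEFAULT_FACTORS.items()
                   if f in final_spec.covariates or f == "mother_dead"]
        combos = {sp.factor: [sp] for sp in singles}
        if len(singles) > 1:
            combos["all_factors_combined"] = singles
        refit = make_refitter(final_spec)
        for name, sps in combos.items():
            if config.aaf_bootstrap >= 2:
                results[name] = bootstrap_aaf(
                    analysed, refit, sps, config.aaf_horizons,
                    B=config.aaf_bootstrap, seed=config.seed + 1)
            else:
                results[name] = compute_aaf(fit, analysed, sps, config.aaf_horizons)
        tab = aaf_table(results)
        save(tab, "attributable_fractions.csv", "aaf")
        manifest["stages"]["aaf"] = {
            "factors": list(combos), "B": config.aaf_bootstrap,
            "horizons": list(config.aaf_horizons)}

    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
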