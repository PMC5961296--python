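"""Shared gamma-frailty Cox estimation: oracles, invariances, recovery."""

import json
import math
import shutil
import subprocess

import numpy as np
import pandas as pd
import pytest
from scipy import integrate, stats

from heusurv import (
    BreslowBaseline, CohortConfig, DesignInfo, FrailtyCoxFit, ModelSpec,
    apply_categorization, fit_frailty_cox, fit_joint_bf_art, generate_cohort,
    predict_marginal_survival, split_episodes, stepwise_descending_select,
    univariate_screen,
)
from heusurv.synthetic_cohort import JOINT_BF_ART_TRUE_LOG_HR
from conftest import SMALL_SPEC, dense_single_study_config, make_records


def _episodes(cfg):
    return split_episodes(apply_categorization(generate_cohort(cfg)),
                          scheme="maternal_vital_only")


def _toy_fit(theta=0.5, log_hr=math.log(2.0)):
    """Hand-assembled fit object with a known baseline, for prediction tests."""
    base = BreslowBaseline(np.array([50., 100., 200., 400.]),
                           np.array([0.01, 0.02, 0.015, 0.03]))
    design = DesignInfo(covariates=[("exposed", "0", ["1"])],
                        columns=["exposed:1"])
    return FrailtyCoxFit(
        beta=pd.Series([log_hr], index=["exposed:1"]),
        se_beta=pd.Series([0.1], index=["exposed:1"]),
        cov_beta=pd.DataFrame([[0.01]], index=["exposed:1"],
                              columns=["exposed:1"]),
        theta=theta, frailties=pd.Series([1.0], index=["S00"]),
        baseline=base, loglik=0.0, n_events=1, n_subjects=2,
        n_iterations=1, converged=True,
        design=design, spec=ModelSpec(covariates={"exposed": "0"}))


class TestReductionToCox:
    def test_matches_lifelines_with_zero_frailty(self, dense_cohort):
        eps = split_episodes(dense_cohort)
        fit = fit_frailty_cox(eps, SMALL_SPEC, theta=0.0)
        from lifelines import CoxTimeVaryingFitter
        df = eps.copy()
        pairs = [("birth_weight_group", "lt2500"), ("ever_breastfed", "no"),
                 ("mother_dead", "1")]
        cols = []
        for c, l in pairs:
            df[f"{c}_x"] = (df[c].astype(str) == l).astype(float)
            cols.append(f"{c}_x")
        ctv = CoxTimeVaryingFitter()
        ctv.fit(df[["child_id", "start", "stop", "event"] + cols],
                id_col="child_id", start_col="start", stop_col="stop",
                event_col="event")
        ours = fit.beta[[f"{c}:{l}" for c, l in pairs]].to_numpy()
        assert np.max(np.abs(ours - ctv.params_.to_numpy())) < 1e-6

    def test_agrees_with_r_survival_at_shared_theta(self, dense_cohort, tmp_path):
        if shutil.which("Rscript") is None:
            pytest.fail("Rscript unavailable for the cross-validation oracle")
        cfg = dense_single_study_config(seed=11, n=960, theta=0.4, studies=8)
        eps = _episodes(cfg)
        fit = fit_frailty_cox(eps, SMALL_SPEC)
        assert fit.theta > 0
        df = eps.copy()
        pairs = [("birth_weight_group", "lt2500"), ("ever_breastfed", "no"),
                 ("mother_dead", "1")]
        for c, l in pairs:
            df[f"{c}_x"] = (df[c].astype(str) == l).astype(int)
        csv = tmp_path / "fix.csv"
        df[["child_id", "study_id", "start", "stop", "event"]
           + [f"{c}_x" for c, _ in pairs]].to_csv(csv, index=False)
        rcode = f"""
suppressMessages(library(survival))
d <- read.csv("{csv}")
d$event <- as.logical(d$event)
f <- coxph(Surv(start, stop, event) ~ birth_weight_group_x +
           ever_breastfed_x + mother_dead_x +
           frailty(study_id, distribution="gamma", theta={fit.theta!r}),
           data=d, ties="breslow")
cat(paste(coef(f), collapse=","))
"""
        out = subprocess.run(["Rscript", "-e", rcode], capture_output=True,
                             text=True, check=True)
        r_beta = np.array([float(x) for x in out.stdout.strip().split(",")])
        ours = fit.beta[[f"{c}:{l}" for c, l in pairs]].to_numpy()
        assert np.max(np.abs(ours - r_beta)) < 1e-3


class TestFitBehaviour:
    def test_constant_covariate_dropped_with_warning(self, dense_cohort):
        eps = split_episodes(dense_cohort)
        eps = eps[eps["birth_weight_group"] == "ge2500"]
        spec = ModelSpec(covariates={"birth_weight_group": "lt2500",
                                     "ever_breastfed": "yes"})
        with pytest.warns(UserWarning, match="no-contrast"):
            fit = fit_frailty_cox(eps, spec, theta=0.0)
        assert "birth_weight_group:ge2500" in fit.dropped_columns
        assert np.isfinite(fit.beta["ever_breastfed:no"])

    def test_no_events_rejected(self):
        rec = apply_categorization(make_records([{}] * 5))
        eps = split_episodes(rec)
        with pytest.raises(ValueError, match="events"):
            fit_frailty_cox(eps, ModelSpec(covariates={"sex": "male"}))

    def test_time_rescaling_leaves_beta_unchanged(self, dense_cohort):
        eps = split_episodes(dense_cohort)
        fit1 = fit_frailty_cox(eps, SMALL_SPEC, theta=0.0)
        eps2 = eps.assign(start=eps["start"] * 3.7, stop=eps["stop"] * 3.7)
        fit2 = fit_frailty_cox(eps2, SMALL_SPEC, theta=0.0)
        np.testing.assert_allclose(fit1.beta, fit2.beta, atol=1e-8)

    def test_frailties_average_near_one(self, default_fit):
        assert default_fit.frailties.mean() == pytest.approx(1.0, abs=0.15)
        assert default_fit.theta >= 0
        b = default_fit.baseline
        assert b.cumhaz[0] >= 0
        assert np.all(np.diff(b.cumhaz) >= 0)
        assert b(0.0) == 0.0

    def test_theta_shrinks_to_zero_without_heterogeneity(self):
        # cohorts generated with no between-study heterogeneity: the
        # estimated frailty variance should collapse toward zero
        thetas = []
        for s in range(30):
            cfg = dense_single_study_config(seed=300 + s, n=800, theta=0.0,
                                            studies=8)
            cfg.true_log_hr = {"birth_weight_group:lt2500": math.log(2.0)}
            eps = _episodes(cfg)
            fit = fit_frailty_cox(
                eps, ModelSpec(covariates={"birth_weight_group": "ge2500"}))
            thetas.append(fit.theta)
        assert float(np.median(thetas)) < 0.02

    def test_beta_bias_shrinks_with_sample_size(self):
        truth = math.log(2.9)
        errs = {}
        for n in (500, 2000, 8000):
            e = []
            for r in range(8):
                cfg = dense_single_study_config(seed=1000 + r, n=n, theta=0.2,
                                                studies=8)
                cfg.true_log_hr = {"birth_weight_group:lt2500": truth}
                eps = _episodes(cfg)
                fit = fit_frailty_cox(
                    eps, ModelSpec(covariates={"birth_weight_group": "ge2500"}))
                e.append(abs(fit.beta["birth_weight_group:lt2500"] - truth))
            errs[n] = float(np.mean(e))
        assert errs[500] > errs[2000] > errs[8000]


class TestScreenAndSelection:
    def test_duplicate_covariate_identical_hr(self, dense_cohort):
        eps = split_episodes(dense_cohort)
        eps["bw_copy"] = eps["birth_weight_group"]
        spec = ModelSpec(covariates={"birth_weight_group": "ge2500",
                                     "bw_copy": "ge2500"})
        tab = univariate_screen(eps, spec, theta=0.0)
        a = tab[tab["covariate"] == "birth_weight_group"]["hr"].to_numpy()
        b = tab[tab["covariate"] == "bw_copy"]["hr"].to_numpy()
        np.testing.assert_allclose(a, b, rtol=1e-10)

    def test_strong_effect_reaches_tiny_p(self):
        cfg = dense_single_study_config(seed=51, n=5000, theta=0.0, studies=5)
        cfg.true_log_hr = {"birth_weight_group:lt2500": math.log(3.0)}
        eps = _episodes(cfg)
        tab = univariate_screen(
            eps, ModelSpec(covariates={"birth_weight_group": "ge2500"}),
            theta=0.0)
        assert tab["block_p"].iloc[0] < 1e-4

    def test_null_covariate_type_one_error(self):
        # a covariate with no true effect should clear the p < 0.1 entry
        # screen in roughly 10% of replicates
        hits = 0
        reps = 60
        for s in range(reps):
            cfg = dense_single_study_config(seed=2000 + s, n=400, theta=0.0,
                                            studies=4)
            cfg.true_log_hr = {}
            eps = _episodes(cfg)
            tab = univariate_screen(
                eps, ModelSpec(covariates={"birth_weight_group": "ge2500"}),
                theta=0.0)
            hits += tab["block_p"].iloc[0] < 0.1
        assert stats.binomtest(hits, reps, 0.1).pvalue > 0.01

    def test_noise_covariate_dropped_by_stepwise(self):
        dropped = 0
        reps = 15
        for s in range(reps):
            cfg = dense_single_study_config(seed=400 + s, n=1200, theta=0.1,
                                            studies=6)
            cfg.true_log_hr = {"birth_weight_group:lt2500": math.log(2.9)}
            rec = apply_categorization(generate_cohort(cfg))
            rng = np.random.default_rng(s)
            noise = pd.Series(rng.choice(["lo", "hi"], size=len(rec)),
                              index=rec["child_id"].to_numpy())
            eps = split_episodes(rec)
            eps["noise"] = noise.reindex(eps["child_id"]).to_numpy()
            spec = ModelSpec(
                covariates={"birth_weight_group": "ge2500", "noise": "lo"},
                selection="stepwise_descending")
            final = stepwise_descending_select(eps, spec)
            dropped += "noise" not in final.covariates
            assert "birth_weight_group" in final.covariates
        assert dropped >= int(0.8 * reps)

    def test_always_kept_covariate_survives_null_effect(self):
        cfg = dense_single_study_config(seed=61, n=1500, theta=0.1, studies=6)
        cfg.true_log_hr = {"birth_weight_group:lt2500": math.log(2.9)}
        eps = _episodes(cfg)
        spec = ModelSpec(
            covariates={"birth_weight_group": "ge2500",
                        "arv_category": "none"},
            always_keep=("arv_category",), selection="stepwise_descending")
        final = stepwise_descending_select(eps, spec)
        assert "arv_category" in final.covariates

    def test_empty_candidates_keep_forced_only(self, dense_cohort):
        eps = split_episodes(dense_cohort)
        spec = ModelSpec(covariates={"sex": "male", "arv_category": "none"},
                         always_keep=("arv_category",),
                         entry_p=1e-9, selection="stepwise_descending")
        final = stepwise_descending_select(eps, spec)
        assert set(final.covariates) <= {"arv_category"}


class TestJointBfArt:
    def test_recovers_category_hazard_ratios(self):
        cfg = CohortConfig(
            n_studies=10, children_per_study=1500, seed=71,
            true_log_hr=dict(JOINT_BF_ART_TRUE_LOG_HR),
            baseline_rates=(9e-4, 4.8e-4, 2.4e-4, 1.2e-4, 6e-5),
            ever_bf_unknown_prob=0.0, weaning_missing_prob=0.0,
            arv_missing_prob=0.0)
        rec = apply_categorization(generate_cohort(cfg))
        eps = split_episodes(rec, scheme="bf_by_art_joint")
        fit = fit_joint_bf_art(eps)
        hr = fit.hazard_ratios()
        for cat, true_hr in [("B", 0.63), ("C", 0.08), ("D", 0.04)]:
            row = hr.loc[f"bf_art_category:{cat}"]
            assert row["ci_lower"] < true_hr < row["ci_upper"], (cat, dict(row))

    def test_all_person_time_in_reference_flags_levels(self):
        rec = apply_categorization(make_records(
            [{"ever_breastfed": "no", "child_death_age_days": 100.0,
              "censor_age_days": 100.0}] * 3
            + [{"ever_breastfed": "no"}] * 50))
        rec["child_id"] = [f"c{i}" for i in range(len(rec))]
        eps = split_episodes(rec, scheme="bf_by_art_joint")
        with pytest.warns(UserWarning, match="no person-time"):
            fit_joint_bf_art(eps, adjusters={}, theta=0.0)

    def test_category_relabeling_permutes_hazard_ratios(self):
        cfg = CohortConfig(
            n_studies=4, children_per_study=400, seed=73,
            true_log_hr=dict(JOINT_BF_ART_TRUE_LOG_HR),
            baseline_rates=(9e-4, 4.8e-4, 2.4e-4, 1.2e-4, 6e-5),
            ever_bf_unknown_prob=0.0, weaning_missing_prob=0.0,
            arv_missing_prob=0.0)
        rec = apply_categorization(generate_cohort(cfg))
        eps = split_episodes(rec, scheme="bf_by_art_joint")
        fit = fit_frailty_cox(
            eps, ModelSpec(covariates={"bf_art_category": "A"}), theta=0.0)
        relab = {"A": "A", "B": "D", "C": "B", "D": "C"}
        eps2 = eps.assign(
            bf_art_category=eps["bf_art_category"].map(relab))
        fit2 = fit_frailty_cox(
            eps2, ModelSpec(covariates={"bf_art_category": "A"}), theta=0.0)
        for old, new in relab.items():
            if old == "A":
                continue
            assert fit.beta[f"bf_art_category:{old}"] == pytest.approx(
                fit2.beta[f"bf_art_category:{new}"], abs=1e-8)


class TestPrediction:
    def test_survival_one_at_time_zero(self):
        fit = _toy_fit()
        paths = pd.DataFrame({"child_id": ["a"], "study_id": ["S00"],
                              "start": [0.0], "stop": [730.0],
                              "exposed": ["1"]})
        assert predict_marginal_survival(fit, paths, 0.0)["a"] == 1.0

    def test_theta_zero_limit_matches_exponential(self):
        paths = pd.DataFrame({"child_id": ["a"], "study_id": ["S00"],
                              "start": [0.0], "stop": [730.0],
                              "exposed": ["1"]})
        fit = _toy_fit(theta=1e-9)
        S = predict_marginal_survival(fit, paths, 300.0)["a"]
        H = 2.0 * fit.baseline(300.0)
        assert abs(S - math.exp(-H)) < 1e-10

    def test_matches_gamma_quadrature(self):
        theta = 0.5
        fit = _toy_fit(theta=theta)
        paths = pd.DataFrame({"child_id": ["a", "b"], "study_id": "S00",
                              "start": 0.0, "stop": 730.0,
                              "exposed": ["1", "0"]})
        S = predict_marginal_survival(fit, paths, 300.0)
        g = stats.gamma(a=1 / theta, scale=theta)
        for cid, x in [("a", 1.0), ("b", 0.0)]:
            H = math.exp(math.log(2.0) * x) * fit.baseline(300.0)
            Sq, _ = integrate.quad(lambda u: math.exp(-u * H) * g.pdf(u),
                                   0, np.inf)
            assert abs(S[cid] - Sq) < 1e-8

    def test_time_dependent_path_accumulates_hazard(self):
        # exposure switching on at day 100 accumulates baseline hazard
        # before 100 at the reference rate and doubled afterwards
        fit = _toy_fit(theta=0.0)
        paths = pd.DataFrame({
            "child_id": ["a", "a"], "study_id": "S00",
            "start": [0.0, 100.0], "stop": [100.0, 730.0],
            "exposed": ["0", "1"]})
        S = predict_marginal_survival(fit, paths, 300.0)["a"]
        H = fit.baseline(100.0) + 2.0 * (fit.baseline(300.0) - fit.baseline(100.0))
        assert S == pytest.approx(math.exp(-H), abs=1e-12)

    def test_incomplete_path_rejected(self):
        fit = _toy_fit()
        paths = pd.DataFrame({"child_id": ["a"], "study_id": ["S00"],
                              "start": [0.0], "stop": [200.0],
                              "exposed": ["1"]})
        with pytest.raises(ValueError, match="path"):
            predict_marginal_survival(fit, paths, 300.0)

    def test_conditional_prediction_uses_study_frailty(self):
        fit = _toy_fit(theta=0.5)
        fit.frailties = pd.Series([2.0], index=["S00"])
        paths = pd.DataFrame({"child_id": ["a"], "study_id": ["S00"],
                              "start": [0.0], "stop": [730.0],
                              "exposed": ["0"]})
        S = predict_marginal_survival(fit, paths, 300.0, conditional=True)["a"]
        assert S == pytest.approx(math.exp(-2.0 * fit.baseline(300.0)), abs=1e-12)
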