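"""Counterfactual aAF: closed forms, identities, bootstrap behaviour."""

import math

import numpy as np
import pandas as pd
import pytest

from heusurv import (
    BreslowBaseline, CohortConfig, CounterfactualSpec, DesignInfo,
    FrailtyCoxFit, ModelSpec, apply_categorization, bootstrap_aaf,
    compute_aaf, expected_deaths, generate_cohort, make_refitter,
)
from heusurv.attributable_fraction import build_prediction_paths
from conftest import make_records


def _binary_fit(log_hr, theta=0.0, lam0=1e-4, knots=(183., 365., 730.)):
    """Fit object with one binary factor and an exactly linear-in-t baseline
    (steps at the query horizons, so H0(t) = lam0 * t there)."""
    times = np.asarray(knots)
    base = BreslowBaseline(times, lam0 * np.diff(np.concatenate([[0.], times])))
    design = DesignInfo(
        covariates=[("birth_weight_group", "ge2500", ["lt2500"])],
        columns=["birth_weight_group:lt2500"])
    return FrailtyCoxFit(
        beta=pd.Series([log_hr], index=design.columns),
        se_beta=pd.Series([0.1], index=design.columns),
        cov_beta=pd.DataFrame([[0.01]], index=design.columns,
                              columns=design.columns),
        theta=theta, frailties=pd.Series([1.0], index=["S00"]),
        baseline=base, loglik=0.0, n_events=1, n_subjects=1,
        n_iterations=1, converged=True, design=design,
        spec=ModelSpec(covariates={"birth_weight_group": "ge2500"}))


def _cohort(n, p_exposed, seed=0):
    rng = np.random.default_rng(seed)
    bw = np.where(rng.random(n) < p_exposed, "lt2500", "ge2500")
    rec = make_records([{"birth_weight_group": b} for b in bw])
    rec["child_id"] = [f"c{i}" for i in range(n)]
    return rec


class TestExpectedDeaths:
    def test_zero_hazard_zero_deaths(self):
        fit = _binary_fit(math.log(2.0), lam0=0.0)
        rec = _cohort(50, 0.5)
        paths = build_prediction_paths(rec, 730.0)
        assert expected_deaths(fit, paths, 730.0) == pytest.approx(0.0)

    def test_identical_children_scale_linearly(self):
        fit = _binary_fit(0.0, lam0=1e-4)
        rec = _cohort(200, 0.0)
        paths = build_prediction_paths(rec, 730.0)
        S = math.exp(-1e-4 * 365.0)
        assert expected_deaths(fit, paths, 365.0) == pytest.approx(
            200 * (1 - S), abs=1e-9)

    def test_paths_extend_past_censoring(self):
        # a child censored at day 100 still contributes a full-horizon
        # prediction: the path is extended, not truncated
        fit = _binary_fit(0.0, lam0=1e-4)
        rec = _cohort(1, 0.0)
        rec["censor_age_days"] = 100.0
        paths = build_prediction_paths(rec, 730.0)
        assert paths["stop"].max() == 730.0
        assert expected_deaths(fit, paths, 730.0) == pytest.approx(
            1 - math.exp(-1e-4 * 730.0), abs=1e-12)


class TestComputeAAF:
    def test_matches_closed_form_at_true_parameters(self):
        lam0, t, p = 1e-4, 365.0, 0.5
        fit = _binary_fit(math.log(2.0), lam0=lam0)
        rec = _cohort(2000, p, seed=3)
        res = compute_aaf(fit, rec,
                          CounterfactualSpec("birth_weight_group", "ge2500"),
                          horizons=[t])
        p_emp = float((rec["birth_weight_group"] == "lt2500").mean())
        l1 = 2 * lam0
        closed = (p_emp * (math.exp(-lam0 * t) - math.exp(-l1 * t))
                  / (1 - p_emp * math.exp(-l1 * t)
                     - (1 - p_emp) * math.exp(-lam0 * t)))
        assert res.aaf(t) == pytest.approx(closed, abs=1e-8)

    def test_zero_prevalence_gives_exact_zero(self):
        fit = _binary_fit(math.log(2.0))
        rec = _cohort(100, 0.0)
        res = compute_aaf(fit, rec,
                          CounterfactualSpec("birth_weight_group", "ge2500"),
                          horizons=[365.0])
        assert res.aaf(365.0) == 0.0

    def test_null_effect_gives_zero(self):
        fit = _binary_fit(0.0)
        rec = _cohort(500, 0.4)
        res = compute_aaf(fit, rec,
                          CounterfactualSpec("birth_weight_group", "ge2500"),
                          horizons=[365.0, 730.0])
        assert np.allclose(res.table["aaf"], 0.0, atol=1e-14)

    def test_decomposition_identity(self):
        fit = _binary_fit(math.log(2.5))
        rec = _cohort(500, 0.3, seed=5)
        res = compute_aaf(fit, rec,
                          CounterfactualSpec("birth_weight_group", "ge2500"),
                          horizons=[365.0])
        row = res.table.iloc[0]
        assert row["attributable_deaths"] + row["expected_deaths_cf"] == \
            pytest.approx(row["expected_deaths"], abs=1e-10)
        assert row["attributable_deaths"] == pytest.approx(
            row["aaf"] * row["expected_deaths"], abs=1e-10)

    def test_invariant_to_duplicating_records(self):
        fit = _binary_fit(math.log(2.5))
        rec = _cohort(300, 0.3, seed=7)
        dup = pd.concat([rec, rec.assign(child_id=rec["child_id"] + "bis")],
                        ignore_index=True)
        a = compute_aaf(fit, rec,
                        CounterfactualSpec("birth_weight_group", "ge2500"),
                        horizons=[365.0]).aaf(365.0)
        b = compute_aaf(fit, dup,
                        CounterfactualSpec("birth_weight_group", "ge2500"),
                        horizons=[365.0]).aaf(365.0)
        assert a == pytest.approx(b, abs=1e-12)

    def test_joint_aaf_dominates_single_factors_on_toy(self):
        # two harmful multiplicative factors: the combined counterfactual
        # removes at least as many expected deaths as either alone
        times = np.array([365.0])
        base = BreslowBaseline(times, np.array([0.05]))
        design = DesignInfo(
            covariates=[("birth_weight_group", "ge2500", ["lt2500"]),
                        ("ever_breastfed", "yes", ["no"])],
            columns=["birth_weight_group:lt2500", "ever_breastfed:no"])
        fit = FrailtyCoxFit(
            beta=pd.Series([math.log(3.0), math.log(2.0)], index=design.columns),
            se_beta=pd.Series([0.1, 0.1], index=design.columns),
            cov_beta=pd.DataFrame(np.eye(2) * 0.01, index=design.columns,
                                  columns=design.columns),
            theta=0.0, frailties=pd.Series([1.0], index=["S00"]),
            baseline=base, loglik=0.0, n_events=1, n_subjects=1,
            n_iterations=1, converged=True, design=design,
            spec=ModelSpec(covariates={"birth_weight_group": "ge2500",
                                       "ever_breastfed": "yes"}))
        # enumerate all four exposure cells explicitly
        rows = []
        for bw in ("ge2500", "lt2500"):
            for bf in ("yes", "no"):
                rows += [{"birth_weight_group": bw, "ever_breastfed": bf,
                          "weaning_age_days": 183.0 if bf == "yes" else np.nan}] * 25
        rec = make_records(rows)
        rec["child_id"] = [f"c{i}" for i in range(len(rec))]
        s_bw = CounterfactualSpec("birth_weight_group", "ge2500")
        s_bf = CounterfactualSpec("ever_breastfed", "yes")
        a = compute_aaf(fit, rec, s_bw, horizons=[365.0]).aaf(365.0)
        b = compute_aaf(fit, rec, s_bf, horizons=[365.0]).aaf(365.0)
        joint = compute_aaf(fit, rec, [s_bw, s_bf], horizons=[365.0]).aaf(365.0)
        assert joint >= max(a, b) - 1e-12

    def test_counterfactual_equal_to_factual_is_zero(self):
        fit = _binary_fit(math.log(2.0))
        rec = _cohort(100, 1.0)
        res = compute_aaf(fit, rec,
                          CounterfactualSpec("birth_weight_group", "lt2500"),
                          horizons=[365.0])
        assert res.aaf(365.0) == 0.0


class TestBootstrap:
    @pytest.fixture(scope="class")
    def small_setup(self):
        cfg = CohortConfig(
            n_studies=4, n_asia_studies=0, children_per_study=250,
            frailty_variance=0.2, seed=31,
            baseline_rates=(1.6e-3, 9e-4, 4.5e-4, 2.2e-4, 1.1e-4),
            maternal_death_rate=0.0,
            prevalences={"sex": {"male": .5, "female": .5},
                         "birth_weight_group": {"ge2500": .7, "lt2500": .3},
                         "ever_breastfed": {"yes": 1.0},
                         "cd4_group": {"ge350": 1.0},
                         "arv_category": {"none": 1.0}},
            true_log_hr={"birth_weight_group:lt2500": math.log(2.5)},
            ever_bf_unknown_prob=0.0, weaning_missing_prob=0.0,
            arv_missing_prob=0.0)
        rec = apply_categorization(generate_cohort(cfg))
        spec = ModelSpec(covariates={"birth_weight_group": "ge2500"})
        return rec, spec

    def test_deterministic_for_fixed_seed(self, small_setup):
        rec, spec = small_setup
        kw = dict(specs=CounterfactualSpec("birth_weight_group", "ge2500"),
                  horizons=[730.0], B=2, seed=5)
        r1 = bootstrap_aaf(rec, make_refitter(spec), **kw)
        r2 = bootstrap_aaf(rec, make_refitter(spec), **kw)
        pd.testing.assert_frame_equal(r1.table, r2.table)

    def test_null_factor_ci_contains_zero(self, small_setup):
        rec, spec = small_setup
        rng = np.random.default_rng(8)
        rec = rec.copy()
        # a label independent of survival: its aAF CI must straddle 0
        rec["birth_weight_group"] = rng.choice(["ge2500", "lt2500"], len(rec))
        res = bootstrap_aaf(
            rec, make_refitter(spec),
            CounterfactualSpec("birth_weight_group", "ge2500"),
            horizons=[730.0], B=40, seed=9)
        row = res.table.iloc[0]
        assert row["ci_lower"] <= 0.0 <= row["ci_upper"]

    def test_small_b_rejected(self, small_setup):
        rec, spec = small_setup
        with pytest.raises(ValueError):
            bootstrap_aaf(rec, make_refitter(spec),
                          CounterfactualSpec("birth_weight_group", "ge2500"),
                          B=1, seed=1)

    def test_resampling_preserves_study_sizes(self, small_setup):
        from heusurv.attributable_fraction import _resample_within_studies
        rec, _ = small_setup
        boot = _resample_within_studies(rec, np.random.default_rng(0))
        orig = rec.groupby("study_id").size()
        new = boot.groupby("study_id").size()
        pd.testing.assert_series_equal(orig, new)
        assert boot["child_id"].is_unique
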