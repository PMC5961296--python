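"""Shared fixtures: record builders and small synthetic-cohort configs.

Heavy artifacts (generated cohorts, fitted models) are session-scoped so
that the whole suite pays for them once.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from hypothesis import settings, HealthCheck

from heusurv import (
    CohortConfig, ModelSpec, apply_categorization, default_table3_spec,
    fit_frailty_cox, generate_cohort, split_episodes,
)

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


RECORD_DEFAULTS = dict(
    study_id="S00",
    region="Africa",
    subregion="Southern Africa",
    sex="male",
    birth_weight_group="ge2500",
    ever_breastfed="yes",
    weaning_age_days=183.0,
    arv_category="none",
    art_start_age_days=np.nan,
    art_end_age_days=np.nan,
    cd4_group="ge350",
    maternal_death_age_days=np.nan,
    child_death_age_days=np.nan,
    censor_age_days=730.0,
)


def make_records(rows: list[dict]) -> pd.DataFrame:
    """Child-record table from per-row overrides of sensible defaults."""
    out = []
    for i, row in enumerate(rows):
        rec = dict(RECORD_DEFAULTS, child_id=f"c{i:04d}")
        rec.update(row)
        out.append(rec)
    return pd.DataFrame(out)


@pytest.fixture
def record_builder():
    return make_records


def dense_single_study_config(seed=7, n=500, theta=0.0, studies=1,
                              round_days=False) -> CohortConfig:
    """Small, event-dense fixture: boosted hazards, no unknown levels, no
    missing-data masking — used for oracle comparisons."""
    return CohortConfig(
        n_studies=studies, n_asia_studies=0,
        children_per_study=max(n // studies, 1),
        frailty_variance=theta, round_days=round_days, seed=seed,
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
            "birth_weight_group:lt2500": np.log(2.9),
            "ever_breastfed:no": np.log(2.5),
            "mother_dead": np.log(6.0),
        },
        ever_bf_unknown_prob=0.0, weaning_missing_prob=0.0,
        arv_missing_prob=0.0,
    )


SMALL_SPEC = ModelSpec(
    covariates={"birth_weight_group": "ge2500", "ever_breastfed": "yes",
                "mother_dead": "0"},
    time_dependent=("mother_dead",),
)


@pytest.fixture(scope="session")
def dense_cohort():
    """Categorized dense fixture cohort (single study, continuous times)."""
    rec = generate_cohort(dense_single_study_config())
    return apply_categorization(rec)


@pytest.fixture(scope="session")
def default_cohort():
    """One moderately sized cohort under the default study conditions."""
    cfg = CohortConfig(n_studies=10, children_per_study=500, seed=42)
    rec = generate_cohort(cfg)
    return cfg, apply_categorization(rec)


@pytest.fixture(scope="session")
def default_fit(default_cohort):
    """Frailty-Cox fit of the main model on the default cohort."""
    _cfg, cat = default_cohort
    eps = split_episodes(cat, scheme="maternal_vital_only")
    return fit_frailty_cox(eps, default_table3_spec())
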