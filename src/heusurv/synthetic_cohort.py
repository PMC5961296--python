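"""Synthetic multi-study cohorts with known ground truth.

The pooled individual-participant data behind the analysis (21 trials,
N = 19 219) are not publicly deposited, so every downstream stage is
exercised on simulated cohorts that emulate the pooled data's structure:

- ~20 study clusters, each with a shared gamma frailty ``u_s`` (mean 1,
  variance ``theta``) multiplying a piecewise-constant baseline hazard of
  infant/child death that declines with age;
- fixed covariates drawn at the pooled prevalences (low birth weight
  ~12%, never breastfed ~30%, maternal ARV mix ~23/61/12/4%, antenatal
  CD4 >= 350 ~58%, ~80% of studies African);
- time-dependent processes: maternal death (constant rate), weaning
  (lognormal, median ~181 days, ceasing at maternal death), and the
  maternal 3-drug-ART window implied by the ARV category;
- administrative censoring at each study's planned follow-up plus random
  loss to follow-up, everything capped at 730 days.

Death times are drawn by piecewise-exponential inversion on the refinement
of the baseline age breakpoints and each child's covariate change-points,
so the generating hazard is exactly ``u_s h0(t) exp(x_i(t)' beta)`` with a
known ``beta``.  Covariate trajectories are generated independently of the
death process given the covariates (no reverse causation).

``true_attributable_fraction`` evaluates the generating model's own
attributable fraction exactly (closed-form piecewise-constant cumulative
hazards, gamma frailty integrated analytically), providing the ground
truth against which the estimated counterfactual aAF is validated.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .cohort_data import RECORD_COLUMNS

_LN = math.log

#: Default true log hazard ratios: the multivariable-model flavor (fixed
#: ever/never breastfeeding, time-dependent maternal vital status).
DEFAULT_TRUE_LOG_HR: dict[str, float] = {
    "region:Asia": _LN(0.05),
    "birth_weight_group:lt2500": _LN(2.92),
    "birth_weight_group:unknown": _LN(2.40),
    "ever_breastfed:no": _LN(2.48),
    "cd4_group:lt350": _LN(1.43),
    "cd4_group:unknown": _LN(1.49),
    "arv_category:mono_dual_pmtct": _LN(0.78),
    "arv_category:art_pmtct": _LN(0.66),
    "arv_category:art_life": _LN(0.51),
    "mother_dead": _LN(11.08),
}

#: Alternative truth flavor for the joint breastfeeding-by-ART analysis:
#: hazard driven by the four time-dependent exposure categories
#: (A: not breastfed/no 3-drug ART is the reference) plus adjusters.
JOINT_BF_ART_TRUE_LOG_HR: dict[str, float] = {
    "region:Asia": _LN(0.05),
    "birth_weight_group:lt2500": _LN(2.92),
    "birth_weight_group:unknown": _LN(2.40),
    "cd4_group:lt350": _LN(1.43),
    "cd4_group:unknown": _LN(1.49),
    "bf_art:B": _LN(0.63),
    "bf_art:C": _LN(0.08),
    "bf_art:D": _LN(0.04),
}

DEFAULT_PREVALENCES: dict[str, dict[str, float]] = {
    "sex": {"male": 0.512, "female": 0.488},
    "birth_weight_group": {"ge2500": 0.866, "lt2500": 0.121, "unknown": 0.013},
    "ever_breastfed": {"yes": 0.698, "no": 0.302},
    "cd4_group": {"ge350": 0.579, "lt350": 0.365, "unknown": 0.056},
    "arv_category": {"none": 0.229, "mono_dual_pmtct": 0.614,
                     "art_pmtct": 0.117, "art_life": 0.040},
}

#: Planned per-study follow-up (days), loosely spanning the spread of study
#: follow-up durations in multi-study PMTCT pools.
DEFAULT_STUDY_FOLLOWUP = (210, 250, 340, 365, 370, 370, 400, 410, 460, 550,
                          550, 550, 560, 700, 730, 730, 730, 730, 730, 730)


@dataclass
class CohortConfig:
    """All simulator parameters; defaults emulate the pooled study conditions.

    Rates are per day, ages in days from birth; ``true_log_hr`` keys are
    either ``"covariate:level"`` for fixed covariates, the time-dependent
    indicators ``"mother_dead"``/``"currently_breastfed"``/
    ``"mother_on_art3"``, or ``"bf_art:B|C|D"`` for the joint exposure.
    """

    n_studies: int = 20
    children_per_study: int | Sequence[int] = 960
    n_asia_studies: int = 4
    frailty_variance: float = 0.25
    baseline_breakpoints: tuple[float, ...] = (28.0, 91.0, 183.0, 365.0)
    baseline_rates: tuple[float, ...] = (3.0e-4, 1.6e-4, 8.0e-5, 4.0e-5, 2.0e-5)
    true_log_hr: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_TRUE_LOG_HR))
    prevalences: dict[str, dict[str, float]] = field(
        default_factory=lambda: {k: dict(v) for k, v in DEFAULT_PREVALENCES.items()})
    maternal_death_rate: float = 2.2e-5
    weaning_median_days: float = 181.0
    weaning_log_sigma: float = 0.79
    art_pmtct_max_days: float = 183.0
    study_followup_days: tuple[float, ...] | None = None
    followup_jitter_days: float = 30.0
    ltfu_rate: float = 1.5e-4
    followup_cap_days: float = 730.0
    weaning_missing_prob: float = 0.077
    arv_missing_prob: float = 0.0023
    ever_bf_unknown_prob: float = 0.023
    round_days: bool = True
    seed: int = 20170701

    def __post_init__(self) -> None:
        if self.frailty_variance < 0:
            raise ValueError("frailty variance must be nonnegative")
        if not (0 <= self.n_asia_studies <= self.n_studies):
            raise ValueError("n_asia_studies must lie in [0, n_studies]")
        if len(self.baseline_rates) != len(self.baseline_breakpoints) + 1:
            raise ValueError("need one baseline rate per age interval")
        if any(r < 0 for r in self.baseline_rates) or self.maternal_death_rate < 0:
            raise ValueError("rates must be nonnegative")
        for cov, probs in self.prevalences.items():
            tot = sum(probs.values())
            if abs(tot - 1.0) > 1e-8:
                raise ValueError(f"prevalences for {cov!r} sum to {tot}, not 1")
        if isinstance(self.children_per_study, Sequence) and not isinstance(
                self.children_per_study, (int, np.integer)):
            if len(self.children_per_study) != self.n_studies:
                raise ValueError("children_per_study list must match n_studies")

    # -- derived layout ----------------------------------------------------
    def study_sizes(self) -> np.ndarray:
        if isinstance(self.children_per_study, (int, np.integer)):
            return np.full(self.n_studies, int(self.children_per_study))
        return np.asarray(list(self.children_per_study), int)

    def study_table(self) -> pd.DataFrame:
        """Study labels, regions/subregions and planned follow-up."""
        n_africa = self.n_studies - self.n_asia_studies
        regions = ["Africa"] * n_africa + ["Asia"] * self.n_asia_studies
        sub_af = ["Southern Africa"] * max(n_africa - 4, 0) + \
                 ["East Africa"] * min(2, n_africa) + ["West Africa"] * min(2, n_africa)
        sub = (sub_af[:n_africa] + ["Southeast Asia"] * max(self.n_asia_studies - 1, 0)
               + ["South Asia"] * min(1, self.n_asia_studies))
        fu = self.study_followup_days
        if fu is None:
            base = list(DEFAULT_STUDY_FOLLOWUP)
            fu = [base[i % len(base)] for i in range(self.n_studies)]
        return pd.DataFrame({
            "study_id": [f"S{i:02d}" for i in range(self.n_studies)],
            "region": regions,
            "subregion": sub[: self.n_studies],
            "planned_followup_days": list(fu)[: self.n_studies],
        })

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: Mapping) -> "CohortConfig":
        d = dict(d)
        for key in ("baseline_breakpoints", "baseline_rates", "study_followup_days"):
            if key in d and d[key] is not None:
                d[key] = tuple(d[key])
        return cls(**d)


# --------------------------------------------------------------------------
# covariate and change-point sampling
# --------------------------------------------------------------------------

def _draw_categorical(rng, probs: Mapping[str, float], n: int) -> np.ndarray:
    levels = list(probs)
    p = np.asarray([probs[l] for l in levels], float)
    return np.asarray(levels, object)[rng.choice(len(levels), size=n, p=p / p.sum())]


def draw_covariates(config: CohortConfig, rng: np.random.Generator,
                    sizes: np.ndarray | None = None) -> dict[str, np.ndarray]:
    """Draw fixed covariates and latent change-point ages for every child.

    Returns plain arrays (one entry per child), including the *uncensored*
    maternal death age ``md`` (np.inf if the mother survives indefinitely),
    the raw weaning age ``wean_raw`` (before truncation at maternal death),
    and the maternal 3-drug ART window ``art_start``/``art_end``.
    """
    studies = config.study_table()
    sizes = config.study_sizes() if sizes is None else sizes
    n = int(sizes.sum())
    study_idx = np.repeat(np.arange(config.n_studies), sizes)
    cov: dict[str, np.ndarray] = {
        "study_idx": study_idx,
        "study_id": studies["study_id"].to_numpy()[study_idx],
        "region": studies["region"].to_numpy()[study_idx],
        "subregion": studies["subregion"].to_numpy()[study_idx],
    }
    for name in ("sex", "birth_weight_group", "ever_breastfed",
                 "cd4_group", "arv_category"):
        cov[name] = _draw_categorical(rng, config.prevalences[name], n)
    ever_bf = cov["ever_breastfed"] == "yes"

    md = rng.exponential(1.0 / config.maternal_death_rate, size=n) \
        if config.maternal_death_rate > 0 else np.full(n, np.inf)
    wean_raw = np.where(
        ever_bf,
        rng.lognormal(math.log(config.weaning_median_days),
                      config.weaning_log_sigma, size=n),
        0.0,
    )
    on3 = np.isin(cov["arv_category"], ("art_pmtct", "art_life"))
    art_start = np.where(on3, 0.0, np.inf)
    # 3-drug ART for PMTCT runs to weaning or 6 months (delivery if
    # formula-fed); ART for life runs indefinitely
    art_end = np.where(
        cov["arv_category"] == "art_life", np.inf,
        np.where(cov["arv_category"] == "art_pmtct",
                 np.where(ever_bf,
                          np.minimum(wean_raw, config.art_pmtct_max_days), 0.0),
                 -np.inf))
    cov.update(md=md, wean_raw=wean_raw, art_start=art_start, art_end=art_end)
    return cov


def apply_counterfactual_truth(cov: dict[str, np.ndarray], factors: Mapping[str, str],
                               config: CohortConfig) -> dict[str, np.ndarray]:
    """Reassign exposures in the generating model (the ground-truth analogue
    of the estimator's counterfactual): supported factors are
    ``birth_weight_group`` (-> ge2500), ``ever_breastfed`` (-> yes, weaning
    imputed at 6 months), ``arv_category`` (-> art_life) and ``mother_dead``
    (-> mother never dies).  Downstream change-points (weaning truncation,
    ART window) are recomputed consistently.
    """
    out = {k: np.array(v, copy=True) for k, v in cov.items()}
    n = len(out["md"])
    for factor, level in factors.items():
        if factor == "birth_weight_group":
            out["birth_weight_group"][:] = level
        elif factor == "ever_breastfed":
            newly = out["ever_breastfed"] != level
            out["ever_breastfed"][:] = level
            if level == "yes":
                out["wean_raw"] = np.where(
                    newly, float(config.art_pmtct_max_days), out["wean_raw"])
            else:
                out["wean_raw"] = np.where(newly, 0.0, out["wean_raw"])
        elif factor == "arv_category":
            out["arv_category"][:] = level
            on3 = level in ("art_pmtct", "art_life")
            out["art_start"] = np.full(n, 0.0 if on3 else np.inf)
            if level == "art_life":
                out["art_end"] = np.full(n, np.inf)
            elif level == "art_pmtct":
                out["art_end"] = np.where(
                    out["ever_breastfed"] == "yes",
                    np.minimum(out["wean_raw"], config.art_pmtct_max_days), 0.0)
            else:
                out["art_end"] = np.full(n, -np.inf)
        elif factor == "mother_dead":
            out["md"] = np.full(n, np.inf)
        else:
            raise KeyError(f"unknown counterfactual factor {factor!r}")
    return out


# --------------------------------------------------------------------------
# the generating hazard: piecewise-constant rates per child
# --------------------------------------------------------------------------

def _hazard_grid(config: CohortConfig, cov: dict[str, np.ndarray]):
    """Per-child interval edges and rates (excluding the frailty factor).

    Returns ``edges`` (n x (m+1), padded with +inf) and ``rates``
    (n x m) such that the hazard of child i at age t in
    (edges[i, j], edges[i, j+1]] is ``rates[i, j]`` times the frailty.
    """
    cap = float(config.followup_cap_days)
    n = len(cov["md"])
    blhr = config.true_log_hr

    # fixed part of the linear predictor
    fixed_lp = np.zeros(n)
    for key, b in blhr.items():
        if ":" in key and not key.startswith("bf_art:"):
            name, level = key.split(":", 1)
            fixed_lp += b * (cov[name] == level)

    md = cov["md"]
    ever_bf = cov["ever_breastfed"] == "yes"
    wean_eff = np.where(ever_bf, np.minimum(cov["wean_raw"], md), 0.0)
    art_end_eff = np.minimum(cov["art_end"], md)

    cand = [md, wean_eff, art_end_eff, cov["art_start"]]
    C = np.stack([np.asarray(c, float) for c in cand], axis=1)
    bps = np.asarray(config.baseline_breakpoints, float)
    C = np.concatenate([np.broadcast_to(bps, (n, bps.size)), C], axis=1)
    C = np.where((C > 0) & (C < cap), C, np.inf)
    C.sort(axis=1)
    dup = np.zeros_like(C, bool)
    dup[:, 1:] = C[:, 1:] == C[:, :-1]
    C[dup] = np.inf
    C.sort(axis=1)
    edges = np.column_stack([np.zeros(n), C, np.full(n, np.inf)])
    # replace first +inf per row by the cap so the last finite interval ends at cap
    first_inf = np.argmax(~np.isfinite(edges), axis=1)
    edges[np.arange(n), first_inf] = cap

    lo, hi = edges[:, :-1], edges[:, 1:]
    valid = np.isfinite(hi)
    mid = np.where(valid, 0.5 * (lo + np.where(valid, hi, 0)), 0.0)

    base_idx = np.searchsorted(bps, mid, side="right")
    base_rate = np.asarray(config.baseline_rates, float)[base_idx]

    td_lp = np.zeros_like(mid)
    mother_dead = mid > md[:, None]
    currently_bf = mid < wean_eff[:, None]
    on_art3 = (mid > cov["art_start"][:, None] - 1e-12) & (mid < art_end_eff[:, None])
    if "mother_dead" in blhr:
        td_lp += blhr["mother_dead"] * mother_dead
    if "currently_breastfed" in blhr:
        td_lp += blhr["currently_breastfed"] * currently_bf
    if "mother_on_art3" in blhr:
        td_lp += blhr["mother_on_art3"] * on_art3
    for cat, bf_v, art_v in (("B", False, True), ("C", True, False), ("D", True, True)):
        key = f"bf_art:{cat}"
        if key in blhr:
            td_lp += blhr[key] * ((currently_bf == bf_v) & (on_art3 == art_v))

    rates = np.where(valid, base_rate * np.exp(fixed_lp[:, None] + td_lp), 0.0)
    return edges, rates


def _cumhaz_at(edges: np.ndarray, rates: np.ndarray, t: float) -> np.ndarray:
    lo, hi = edges[:, :-1], edges[:, 1:]
    overlap = np.clip(np.minimum(hi, t) - np.minimum(lo, t), 0.0, None)
    overlap = np.where(np.isfinite(overlap), overlap, 0.0)
    return (rates * overlap).sum(axis=1)


def _sample_death_times(edges, rates, frailty, rng) -> np.ndarray:
    """Piecewise-exponential inversion; np.inf when no death before the cap."""
    r = rates * frailty[:, None]
    lo, hi = edges[:, :-1], edges[:, 1:]
    with np.errstate(invalid="ignore"):
        width = np.where(np.isfinite(hi) & np.isfinite(lo), hi - lo, 0.0)
    seg = r * width
    cum = np.cumsum(seg, axis=1)
    target = rng.exponential(1.0, size=len(r))
    total = cum[:, -1]
    died = target <= total
    cum_prev = np.concatenate([np.zeros((len(r), 1)), cum[:, :-1]], axis=1)
    j = np.argmax(cum >= target[:, None], axis=1)
    rows = np.arange(len(r))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = lo[rows, j] + (target - cum_prev[rows, j]) / r[rows, j]
    return np.where(died, t, np.inf)


# --------------------------------------------------------------------------
# public operations
# --------------------------------------------------------------------------

def generate_cohort(config: CohortConfig, seed: int | None = None) -> pd.DataFrame:
    """Generate one synthetic cohort in the child-record CSV schema.

    Deterministic for a fixed config and seed (``seed`` defaults to
    ``config.seed``).  Observed fields mimic real data collection: maternal
    death and weaning ages are recorded only when they occur during the
    child's follow-up, a fraction of weaning dates/ARV categories/feeding
    statuses is masked as missing, and ages are rounded to whole days
    (deaths and censorings rounded up, so day-0 events land on day 1).
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    theta = config.frailty_variance
    u = (rng.gamma(1.0 / theta, theta, size=config.n_studies)
         if theta > 0 else np.ones(config.n_studies))

    cov = draw_covariates(config, rng)
    n = len(cov["md"])
    edges, rates = _hazard_grid(config, cov)
    t_death = _sample_death_times(edges, rates, u[cov["study_idx"]], rng)

    studies = config.study_table()
    planned = studies["planned_followup_days"].to_numpy(float)[cov["study_idx"]]
    jit = rng.uniform(-config.followup_jitter_days, config.followup_jitter_days, n)
    ltfu = (rng.exponential(1.0 / config.ltfu_rate, size=n)
            if config.ltfu_rate > 0 else np.full(n, np.inf))
    censor = np.clip(np.minimum(planned + jit, ltfu), 1.0, config.followup_cap_days)

    died = t_death <= censor
    exit_age = np.where(died, t_death, censor)

    def up(x):
        return np.ceil(x) if config.round_days else x

    def near(x):
        return np.round(x) if config.round_days else x

    exit_rec = np.maximum(up(exit_age), 1.0)
    death_rec = np.where(died, exit_rec, np.nan)

    md_obs = np.where(cov["md"] <= exit_age, near(cov["md"]), np.nan)
    ever_bf = cov["ever_breastfed"] == "yes"
    wean_eff = np.where(ever_bf, np.minimum(cov["wean_raw"], cov["md"]), np.nan)
    # weaning before exit is recorded as observed; a child still breastfed
    # at exit is recorded as weaned at exit (breastfed throughout
    # follow-up) — that is known from study visits, not missing data
    wean_obs = np.where(ever_bf, np.minimum(near(wean_eff), exit_rec), np.nan)
    # a fraction of known-initiated breastfeeding lacks a weaning date
    mask_wean = ever_bf & (rng.random(n) < config.weaning_missing_prob)
    wean_obs = np.where(mask_wean, np.nan, wean_obs)

    arv = cov["arv_category"].copy()
    arv[rng.random(n) < config.arv_missing_prob] = "missing"
    ever_bf_col = cov["ever_breastfed"].astype(object).copy()
    ever_bf_col[rng.random(n) < config.ever_bf_unknown_prob] = "unknown"

    on3 = np.isin(arv, ("art_pmtct", "art_life"))
    art_start = np.where(on3, 0.0, np.nan)
    art_end = np.where(on3, cov["art_end"], np.nan)
    art_end = np.where(np.isfinite(art_end) | ~on3, near(art_end), np.inf)

    rec = pd.DataFrame({
        "child_id": [f"{sid}-C{i:05d}" for i, sid in enumerate(cov["study_id"])],
        "study_id": cov["study_id"],
        "region": cov["region"],
        "subregion": cov["subregion"],
        "sex": cov["sex"],
        "birth_weight_group": cov["birth_weight_group"],
        "ever_breastfed": ever_bf_col,
        "weaning_age_days": wean_obs,
        "arv_category": arv,
        "art_start_age_days": art_start,
        "art_end_age_days": art_end,
        "cd4_group": cov["cd4_group"],
        "maternal_death_age_days": md_obs,
        "child_death_age_days": death_rec,
        "censor_age_days": exit_rec,
    })
    return rec[RECORD_COLUMNS]


def true_attributable_fraction(
    config: CohortConfig,
    factors: Mapping[str, str] | str,
    horizon_days: float | Sequence[float],
    n_children: int | None = None,
    seed: int | None = None,
    cov: dict[str, np.ndarray] | None = None,
) -> float | dict[float, float]:
    """Exact attributable fraction of the generating model.

    For a population of children drawn from (or supplied via ``cov``) the
    config's covariate distribution, computes

        AF(t) = (D(t) - D_cf(t)) / D(t),
        D(t) = sum_i (1 - S_i(t)),    S_i(t) = (1 + theta L_i(t))^(-1/theta),

    where ``L_i(t)`` is the child's cumulative hazard under the factual
    (resp. counterfactually reassigned) covariate path, integrated in
    closed form over the piecewise-constant pieces, and the gamma frailty
    is marginalized analytically.  ``factors`` may be a single factor name
    (mapped to its protective reassignment) or a mapping of factor ->
    counterfactual level; see :func:`apply_counterfactual_truth`.

    Returns a float for a scalar horizon, else ``{horizon: AF}``.
    """
    default_levels = {"birth_weight_group": "ge2500", "ever_breastfed": "yes",
                      "arv_category": "art_life", "mother_dead": "alive"}
    if isinstance(factors, str):
        if factors not in default_levels:
            raise KeyError(f"unknown factor {factors!r}")
        factors = {factors: default_levels[factors]}
    for f in factors:
        if f not in default_levels:
            raise KeyError(f"unknown factor {f!r}")

    if cov is None:
        rng = np.random.default_rng(config.seed if seed is None else seed)
        sizes = None
        if n_children is not None:
            base = config.study_sizes().astype(float)
            sizes = np.maximum(1, np.round(base * n_children / base.sum())).astype(int)
        cov = draw_covariates(config, rng, sizes=sizes)
    cov_cf = apply_counterfactual_truth(cov, factors, config)

    e_f, r_f = _hazard_grid(config, cov)
    e_c, r_c = _hazard_grid(config, cov_cf)
    theta = config.frailty_variance

    def surv(L):
        if theta < 1e-12:
            return np.exp(-L)
        return np.exp(-np.log1p(theta * L) / theta)

    scalar = np.isscalar(horizon_days)
    horizons = [float(horizon_days)] if scalar else [float(h) for h in horizon_days]
    out: dict[float, float] = {}
    for t in horizons:
        D = float(np.sum(1.0 - surv(_cumhaz_at(e_f, r_f, t))))
        Dcf = float(np.sum(1.0 - surv(_cumhaz_at(e_c, r_c, t))))
        out[t] = (D - Dcf) / D if D > 0 else 0.0
    return out[horizons[0]] if scalar else out


def monte_carlo_attributable_fraction(
    config: CohortConfig,
    factors: Mapping[str, str] | str,
    horizon_days: float,
    n_children: int,
    seed: int,
) -> tuple[float, float]:
    """Brute-force Monte-Carlo AF oracle: simulate deaths (no censoring)
    under factual and counterfactual exposure and difference the death
    proportions.  Returns (AF, approximate MC standard error of AF).
    """
    if isinstance(factors, str):
        factors = {factors: {"birth_weight_group": "ge2500",
                             "ever_breastfed": "yes",
                             "arv_category": "art_life",
                             "mother_dead": "alive"}[factors]}
    rng = np.random.default_rng(seed)
    base = config.study_sizes().astype(float)
    sizes = np.maximum(1, np.round(base * n_children / base.sum())).astype(int)
    cov = draw_covariates(config, rng, sizes=sizes)
    cov_cf = apply_counterfactual_truth(cov, factors, config)
    theta = config.frailty_variance
    u = (rng.gamma(1.0 / theta, theta, size=config.n_studies)
         if theta > 0 else np.ones(config.n_studies))
    # common frailties and common exponential draws couple the two arms,
    # shrinking the MC variance of the difference
    n = len(cov["md"])
    target = rng.exponential(1.0, size=n)

    def death_prop(c):
        edges, rates = _hazard_grid(config, c)
        r = rates * u[c["study_idx"]][:, None]
        total = _cumhaz_at(edges, r, float(horizon_days))
        return target <= total  # death by the horizon

    dead_f = death_prop(cov)
    dead_c = death_prop(cov_cf)
    p_f = dead_f.mean()
    af = (p_f - dead_c.mean()) / p_f
    # delta-method SE of the coupled difference-ratio
    diff = dead_f.astype(float) - dead_c.astype(float)
    var = (np.var(diff) / n + (af ** 2) * np.var(dead_f.astype(float)) / n) / (p_f ** 2)
    return float(af), float(math.sqrt(var))
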