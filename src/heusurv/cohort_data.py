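"""Child-level analysis data model and counting-process episode expansion.

The analysis input is a flat table with one row per child (the *record*
schema, :data:`RECORD_COLUMNS`): identifiers, fixed covariates, and the ages
(in days from birth) at which time-dependent events occurred — maternal
death, weaning, maternal ART start/stop — together with the child's death
and censoring ages.  All ages are child age in days; "24 months" is 730
days and "6 months" is 183 days throughout.

Two operations prepare such records for modelling:

``apply_categorization``
    applies the pooled-analysis conventions: mothers with missing
    antiretroviral information are assigned to the single/dual-PMTCT
    category, children with unknown breastfeeding status are flagged for
    exclusion, missing categorical covariates become explicit ``unknown``
    levels, unknown weaning dates are imputed (6 months, study exit or
    maternal death — whichever is earliest), and follow-up is truncated at
    24 months.

``split_episodes``
    expands each child into contiguous counting-process intervals
    ``(start, stop]`` on which every covariate — including the
    time-dependent indicators ``mother_dead``, ``currently_breastfed`` and
    ``mother_on_art3`` — is constant.  Events sit at the ``stop`` of the
    last interval.  A covariate change on the same day as a death does not
    open a new interval, so the death is attributed to the pre-change
    covariate value.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Canonical input schema: one row per child, ages in integer-valued days.
RECORD_COLUMNS = [
    "child_id",
    "study_id",
    "region",
    "subregion",
    "sex",
    "birth_weight_group",
    "ever_breastfed",
    "weaning_age_days",
    "arv_category",
    "art_start_age_days",
    "art_end_age_days",
    "cd4_group",
    "maternal_death_age_days",
    "child_death_age_days",
    "censor_age_days",
]

REGIONS = ["Africa", "Asia"]
SEX_LEVELS = ["male", "female", "unknown"]
BW_LEVELS = ["ge2500", "lt2500", "unknown"]
CD4_LEVELS = ["ge350", "lt350", "unknown"]
ARV_LEVELS = ["none", "mono_dual_pmtct", "art_pmtct", "art_life"]
BF_LEVELS = ["yes", "no"]

#: Fixed covariates copied verbatim onto episodes.
FIXED_COVARIATES = [
    "region",
    "sex",
    "birth_weight_group",
    "ever_breastfed",
    "arv_category",
    "cd4_group",
]

SCHEMES = ("maternal_vital_only", "plus_bf_cessation", "bf_by_art_joint")

#: Joint breastfeeding-by-ART exposure levels (A = not breastfed, mother not
#: on 3-drug ART, the reference; D = breastfed with mother on 3-drug ART).
BF_ART_LEVELS = ["A", "B", "C", "D"]


@dataclass(frozen=True)
class CategorizationRules:
    """Conventions applied to raw child records before modelling.

    Parameters
    ----------
    followup_cap_days:
        Administrative truncation of follow-up (24 months = 730 days).
    unknown_weaning_impute_days:
        Breastfed children with unknown weaning date are assumed to have
        breastfed from birth to this age (6 months = 183 days), study exit,
        or maternal death — whichever comes first.
    art_end_impute_days:
        Unknown maternal ART stop (3-drug ART for PMTCT) is imputed as the
        earlier of weaning and this age.
    """

    followup_cap_days: float = 730.0
    unknown_weaning_impute_days: float = 183.0
    art_end_impute_days: float = 183.0

    def __post_init__(self) -> None:
        if self.followup_cap_days <= 0:
            raise ValueError("followup_cap_days must be positive")
        if not (0 < self.unknown_weaning_impute_days <= self.followup_cap_days):
            raise ValueError("unknown_weaning_impute_days must lie in (0, cap]")
        if not (0 < self.art_end_impute_days <= self.followup_cap_days):
            raise ValueError("art_end_impute_days must lie in (0, cap]")


def _check_nonnegative(records: pd.DataFrame) -> None:
    age_cols = [
        "weaning_age_days",
        "art_start_age_days",
        "art_end_age_days",
        "maternal_death_age_days",
        "child_death_age_days",
        "censor_age_days",
    ]
    for col in age_cols:
        if col not in records.columns:
            continue
        vals = pd.to_numeric(records[col], errors="coerce")
        bad = vals < 0
        if bad.any():
            offenders = records.loc[bad, "child_id"].astype(str).tolist()[:5]
            raise ValueError(
                f"negative {col} for child record(s) {offenders} "
                f"({int(bad.sum())} total)"
            )


def apply_categorization(
    records: pd.DataFrame, rules: CategorizationRules | None = None
) -> pd.DataFrame:
    """Apply the pooled-analysis categorization and imputation conventions.

    Returns a new record table with normalized categorical levels, imputed
    change-point ages, follow-up truncated at ``rules.followup_cap_days``,
    and two bookkeeping columns: ``excluded`` (children with unknown
    breastfeeding status, who are dropped from all analyses) and
    ``weaning_imputed``.  A count of every imputation/exclusion is stored in
    ``result.attrs["categorization_report"]`` and logged at INFO level.

    The operation is idempotent: applying it to its own output is a no-op.
    """
    if records is None or len(records) == 0:
        raise ValueError("apply_categorization: empty record table")
    rules = rules or CategorizationRules()
    _check_nonnegative(records)

    df = records.copy()
    report: dict[str, int] = {"n_input": int(len(df))}

    # mothers with missing ARV information follow the study protocol:
    # reassigned to the single/dual-PMTCT category
    arv = df["arv_category"].astype(object)
    arv_missing = arv.isna() | arv.isin(["missing", "unknown", ""])
    df.loc[arv_missing, "arv_category"] = "mono_dual_pmtct"
    if "arv_imputed" in df.columns:
        df["arv_imputed"] = df["arv_imputed"].fillna(False) | arv_missing
    else:
        df["arv_imputed"] = arv_missing
    report["n_arv_reassigned"] = int(arv_missing.sum())

    # missing categoricals become explicit "unknown" levels (kept in models)
    for col, levels in [("sex", SEX_LEVELS), ("birth_weight_group", BW_LEVELS),
                        ("cd4_group", CD4_LEVELS)]:
        v = df[col].astype(object)
        miss = v.isna() | ~v.isin(levels)
        v[miss] = "unknown"
        df[col] = v
        report[f"n_{col}_unknown"] = int((df[col] == "unknown").sum())
    if "subregion" in df.columns:
        df["subregion"] = df["subregion"].astype(object).fillna("unknown")

    # unknown infant-feeding status cannot be analysed: flag for exclusion
    bf = df["ever_breastfed"].astype(object)
    bf_known = bf.isin(["yes", "no"])
    df["ever_breastfed"] = np.where(bf_known, bf, "unknown")
    df["excluded"] = ~bf_known
    report["n_excluded_unknown_breastfeeding"] = int((~bf_known).sum())

    # truncate follow-up at the cap; deaths beyond the cap become censorings
    cap = float(rules.followup_cap_days)
    death = pd.to_numeric(df["child_death_age_days"], errors="coerce")
    censor = pd.to_numeric(df["censor_age_days"], errors="coerce")
    end = np.where(death.notna(), np.minimum(death, censor), censor)
    late_death = death.notna() & (death > cap)
    report["n_deaths_capped_to_censoring"] = int(late_death.sum())
    end = np.minimum(end, cap)
    death_kept = death.where(death.notna() & (death <= cap) & (death <= censor))
    df["child_death_age_days"] = death_kept
    df["censor_age_days"] = end

    # unknown weaning date for a breastfed child: breastfed from birth to
    # 6 months, study exit, or maternal death, whichever occurred first
    md = pd.to_numeric(df["maternal_death_age_days"], errors="coerce")
    wean = pd.to_numeric(df["weaning_age_days"], errors="coerce")
    need = (df["ever_breastfed"] == "yes") & wean.isna()
    imputed = np.minimum(
        float(rules.unknown_weaning_impute_days),
        np.minimum(np.asarray(end, dtype=float), md.fillna(np.inf).to_numpy()),
    )
    df["weaning_age_days"] = wean.where(~need, pd.Series(imputed, index=df.index))
    if "weaning_imputed" in df.columns:
        df["weaning_imputed"] = df["weaning_imputed"].fillna(False) | need
    else:
        df["weaning_imputed"] = need
    report["n_weaning_imputed"] = int(df["weaning_imputed"].sum())

    # maternal 3-drug ART exposure window
    start = pd.to_numeric(df.get("art_start_age_days"), errors="coerce")
    stop = pd.to_numeric(df.get("art_end_age_days"), errors="coerce")
    on3 = df["arv_category"].isin(["art_pmtct", "art_life"])
    df["art_start_age_days"] = start.where(~on3 | start.notna(), 0.0)
    # ART for life continues beyond follow-up
    df.loc[on3 & (df["arv_category"] == "art_life") & stop.isna(),
           "art_end_age_days"] = np.inf
    # 3-drug ART for PMTCT with unknown stop: until weaning or 6 months,
    # whichever came first; formula-fed children stop at delivery
    pm = on3 & (df["arv_category"] == "art_pmtct") & stop.isna()
    wean_now = pd.to_numeric(df["weaning_age_days"], errors="coerce")
    art_imp = np.where(
        df["ever_breastfed"] == "yes",
        np.minimum(wean_now.fillna(np.inf), float(rules.art_end_impute_days)),
        0.0,
    )
    report["n_art_end_imputed"] = int(pm.sum())
    stop = pd.to_numeric(df["art_end_age_days"], errors="coerce")
    df["art_end_age_days"] = stop.where(~pm, pd.Series(art_imp, index=df.index))

    df.attrs["categorization_report"] = report
    logger.info("categorization: %s", report)
    return df


def _followup_end(records: pd.DataFrame) -> np.ndarray:
    death = pd.to_numeric(records["child_death_age_days"], errors="coerce")
    censor = pd.to_numeric(records["censor_age_days"], errors="coerce")
    return np.where(death.notna(), np.minimum(death, censor), censor).astype(float)


def split_episodes(records: pd.DataFrame, scheme: str = "maternal_vital_only") -> pd.DataFrame:
    """Expand categorized child records into counting-process episodes.

    Each child becomes 1–4 contiguous half-open intervals ``(start, stop]``
    starting at 0, cut at every change-point (maternal death, weaning,
    maternal ART start/stop, depending on ``scheme``) that falls strictly
    inside the follow-up interval.  The returned frame has one row per
    episode with the fixed covariates plus scheme-dependent time-dependent
    indicators:

    - ``maternal_vital_only`` — ``mother_dead``;
    - ``plus_bf_cessation`` — adds ``currently_breastfed`` (breastfeeding
      ceases at weaning or maternal death);
    - ``bf_by_art_joint`` — adds ``mother_on_art3`` and the four-level
      ``bf_art_category`` (A: not breastfed/no ART, B: not breastfed/ART,
      C: breastfed/no ART, D: breastfed/ART).

    Children flagged ``excluded`` or with zero follow-up are dropped.
    """
    if scheme not in SCHEMES:
        raise ValueError(f"unknown scheme {scheme!r}; expected one of {SCHEMES}")
    df = records
    if "excluded" in df.columns:
        df = df.loc[~df["excluded"].astype(bool)]
    end = _followup_end(df)
    keep = end > 0
    if not keep.all():
        logger.info("split_episodes: dropping %d records with zero follow-up",
                    int((~keep).sum()))
        df, end = df.loc[keep], end[keep]
    n = len(df)
    if n == 0:
        raise ValueError("split_episodes: no analysable records")

    md = pd.to_numeric(df["maternal_death_age_days"], errors="coerce").to_numpy(float)
    md = np.where(np.isnan(md), np.inf, md)
    wean = pd.to_numeric(df["weaning_age_days"], errors="coerce").to_numpy(float)
    ever_bf = (df["ever_breastfed"].astype(object) == "yes").to_numpy()
    # breastfeeding ceases at weaning or at the mother's death
    wean_eff = np.where(ever_bf, np.minimum(np.where(np.isnan(wean), np.inf, wean), md), 0.0)
    a_start = pd.to_numeric(df["art_start_age_days"], errors="coerce").to_numpy(float)
    a_end = pd.to_numeric(df["art_end_age_days"], errors="coerce").to_numpy(float)
    on3_cat = df["arv_category"].isin(["art_pmtct", "art_life"]).to_numpy()
    a_start = np.where(on3_cat & ~np.isnan(a_start), a_start, np.inf)
    a_end = np.where(on3_cat, np.where(np.isnan(a_end), np.inf, a_end), -np.inf)
    # the mother's death also ends ART exposure
    a_end_eff = np.where(on3_cat, np.minimum(a_end, md), -np.inf)

    cuts = [md]
    if scheme in ("plus_bf_cessation", "bf_by_art_joint"):
        cuts.append(wean_eff)
    if scheme == "bf_by_art_joint":
        cuts.extend([a_start, a_end_eff])
    C = np.stack(cuts, axis=1)
    # keep only change-points strictly inside (0, end): a change on the day
    # of death/censoring does not open a new episode
    C = np.where((C > 0) & (C < end[:, None]), C, np.inf)
    C.sort(axis=1)
    dup = np.zeros_like(C, dtype=bool)
    dup[:, 1:] = C[:, 1:] == C[:, :-1]
    C[dup] = np.inf
    C.sort(axis=1)

    n_cuts = (np.isfinite(C)).sum(axis=1)
    m = n_cuts + 1  # episodes per child
    rows = np.repeat(np.arange(n), m)
    total = int(m.sum())
    pos = np.arange(total) - np.repeat(np.cumsum(m) - m, m)
    Cpad = np.column_stack([np.zeros(n), C])
    starts = Cpad[rows, pos]
    is_last = pos == (m[rows] - 1)
    stops = np.where(is_last, end[rows], C[rows, np.minimum(pos, C.shape[1] - 1)])

    death = pd.to_numeric(df["child_death_age_days"], errors="coerce").to_numpy(float)
    has_event = ~np.isnan(death)
    event = is_last & has_event[rows]

    mid = 0.5 * (starts + stops)
    mother_dead = (mid > md[rows]).astype(np.int8)
    out = {
        "child_id": df["child_id"].to_numpy()[rows],
        "study_id": df["study_id"].to_numpy()[rows],
        "start": starts,
        "stop": stops,
        "event": event,
    }
    for col in FIXED_COVARIATES:
        if col in df.columns:
            out[col] = df[col].to_numpy()[rows]
    out["mother_dead"] = mother_dead
    if scheme in ("plus_bf_cessation", "bf_by_art_joint"):
        cur_bf = (mid < wean_eff[rows]).astype(np.int8)
        out["currently_breastfed"] = cur_bf
    if scheme == "bf_by_art_joint":
        on_art = ((mid > a_start[rows]) | (a_start[rows] == 0)) & (mid < a_end_eff[rows])
        on_art = on_art.astype(np.int8)
        out["mother_on_art3"] = on_art
        cat = np.array(["A", "B", "C", "D"], dtype=object)[cur_bf * 2 + on_art]
        out["bf_art_category"] = cat
    return pd.DataFrame(out)


def merge_adjacent_episodes(episodes: pd.DataFrame) -> pd.DataFrame:
    """Re-merge contiguous episodes of a child with identical covariates.

    Inverse check for :func:`split_episodes`: covariate paths are
    right-continuous step functions, so merging adjacent equal-covariate
    intervals recovers the minimal representation.
    """
    cov_cols = [c for c in episodes.columns
                if c not in ("start", "stop", "event")]
    eps = episodes.sort_values(["child_id", "start"], kind="stable").reset_index(drop=True)
    same_child = eps["child_id"].eq(eps["child_id"].shift())
    contiguous = eps["start"].eq(eps["stop"].shift())
    same_cov = np.ones(len(eps), dtype=bool)
    for c in cov_cols:
        if c == "child_id":
            continue
        same_cov &= eps[c].eq(eps[c].shift()).to_numpy()
    new_block = ~(same_child & contiguous & same_cov)
    block = new_block.cumsum()
    agg = {c: "first" for c in cov_cols}
    agg.update(start=("start", "first"), stop=("stop", "last"), event=("event", "last"))
    g = eps.groupby(block, sort=True)
    merged = pd.DataFrame({
        **{c: g[c].first() for c in cov_cols},
        "start": g["start"].first(),
        "stop": g["stop"].last(),
        "event": g["event"].last(),
    })
    return merged.reset_index(drop=True)[episodes.columns.tolist()]


@dataclass
class CohortSummary:
    """Per-study counts, overall figures, and covariate prevalences."""

    per_study: pd.DataFrame
    overall: dict
    prevalences: pd.DataFrame

    def to_frames(self) -> dict[str, pd.DataFrame]:
        return {
            "per_study": self.per_study,
            "overall": pd.DataFrame([self.overall]),
            "prevalences": self.prevalences,
        }


def summarize_cohort(records: pd.DataFrame) -> CohortSummary:
    """Descriptive counts: crude death proportions per study and overall,
    covariate prevalences (percentages to 1 decimal), and post-maternal-death
    child mortality among children whose mother died during follow-up.
    """
    if records is None or len(records) == 0:
        raise ValueError("summarize_cohort: empty record table")
    df = records
    if "excluded" in df.columns:
        df = df.loc[~df["excluded"].astype(bool)]
    death = pd.to_numeric(df["child_death_age_days"], errors="coerce")
    died = death.notna()

    per_study = (
        df.assign(died=died)
        .groupby("study_id", sort=True)
        .agg(n_children=("child_id", "size"), n_deaths=("died", "sum"))
        .reset_index()
    )
    per_study["death_pct"] = (100.0 * per_study["n_deaths"] / per_study["n_children"]).round(1)

    end = _followup_end(df)
    md = pd.to_numeric(df["maternal_death_age_days"], errors="coerce")
    mother_died = md.notna() & (md.to_numpy() <= end)
    post_md_death = mother_died & died & (death >= md)
    n_md = int(mother_died.sum())
    overall = {
        "n_children": int(len(df)),
        "n_deaths": int(died.sum()),
        "death_pct": round(100.0 * died.sum() / len(df), 1),
        "n_mothers_died": n_md,
        "n_child_deaths_after_maternal_death": int(post_md_death.sum()),
        "post_maternal_death_mortality_pct":
            round(100.0 * post_md_death.sum() / n_md, 1) if n_md else float("nan"),
    }

    rows = []
    for col in FIXED_COVARIATES:
        if col not in df.columns:
            continue
        counts = df[col].value_counts(dropna=False)
        for level, cnt in counts.items():
            rows.append({
                "covariate": col,
                "level": level,
                "n": int(cnt),
                "pct": round(100.0 * cnt / len(df), 1),
            })
    return CohortSummary(per_study=per_study, overall=overall,
                         prevalences=pd.DataFrame(rows))
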