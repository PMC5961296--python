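"""Descriptive survival statistics: Kaplan-Meier curves, log-rank tests,
cumulative incidence of death, and mortality rates per 100 child-years.

Kaplan-Meier estimation and log-rank testing delegate to lifelines; this
module fixes the conventions used throughout the pooled analysis (ages in
days, censorings at an event time remain at risk for that event, Greenwood
confidence intervals on the log(-log) scale, 365.25 days per child-year)
and adds the person-time bookkeeping for episode tables.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test

DAYS_PER_YEAR = 365.25


@dataclass
class KMCurve:
    """Product-limit survival estimate for one group."""

    event_times: np.ndarray
    survival: np.ndarray
    at_risk: np.ndarray
    events: np.ndarray
    label: str | None = None
    _fitter: KaplanMeierFitter | None = None

    def survival_at(self, t) -> np.ndarray:
        """Step-function evaluation of S(t) (1 before the first event)."""
        idx = np.searchsorted(self.event_times, np.asarray(t, float), side="right")
        s = np.concatenate([[1.0], self.survival])
        return s[idx]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "time": self.event_times, "survival": self.survival,
            "at_risk": self.at_risk, "events": self.events,
        })


def _duration_event(data: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    """Child-level (duration, event) from either records or episodes."""
    if {"start", "stop", "event"}.issubset(data.columns):
        g = data.sort_values(["child_id", "stop"]).groupby("child_id", sort=False)
        dur = g["stop"].last().to_numpy(float)
        ev = g["event"].last().to_numpy(bool)
        return dur, ev
    death = pd.to_numeric(data["child_death_age_days"], errors="coerce")
    censor = pd.to_numeric(data["censor_age_days"], errors="coerce")
    dur = np.where(death.notna(), np.minimum(death, censor), censor).astype(float)
    return dur, death.notna().to_numpy()


def kaplan_meier(data: pd.DataFrame, group_by: str | None = None) -> dict[str, KMCurve] | KMCurve:
    """Kaplan-Meier survival curve(s), optionally per level of ``group_by``.

    Accepts either a child record table or an episode table (in which case
    each child's total follow-up and final event status are used).
    """
    if group_by is None:
        groups = {"all": data}
    else:
        groups = {str(k): v for k, v in data.groupby(group_by, sort=True)}
    out: dict[str, KMCurve] = {}
    for label, sub in groups.items():
        dur, ev = _duration_event(sub)
        if len(dur) == 0:
            warnings.warn(f"group {label!r} has no subjects; empty curve")
            out[label] = KMCurve(np.array([]), np.array([]), np.array([]),
                                 np.array([]), label)
            continue
        kmf = KaplanMeierFitter()
        kmf.fit(dur, ev, label=label)
        ev_rows = kmf.event_table[kmf.event_table["observed"] > 0]
        times = ev_rows.index.to_numpy(float)
        out[label] = KMCurve(
            event_times=times,
            survival=kmf.survival_function_.loc[times].to_numpy().ravel(),
            at_risk=ev_rows["at_risk"].to_numpy(float),
            events=ev_rows["observed"].to_numpy(float),
            label=label,
            _fitter=kmf,
        )
    return out if group_by is not None else out["all"]


def log_rank_test(data: pd.DataFrame, group_by: str) -> tuple[float, float]:
    """Log-rank chi-square statistic and p-value across the groups."""
    groups = data[group_by]
    if groups.nunique() < 2:
        raise ValueError("log-rank test needs at least two groups")
    dur, ev = _duration_event(data)
    if {"start", "stop", "event"}.issubset(data.columns):
        # group label taken from each child's first episode
        lab = data.sort_values(["child_id", "stop"]).groupby("child_id", sort=False)[group_by].first()
        g = lab.to_numpy()
    else:
        g = groups.to_numpy()
    if ev.sum() == 0:
        raise ValueError("log-rank test needs at least one event")
    res = multivariate_logrank_test(dur, g, ev)
    return float(res.test_statistic), float(res.p_value)


def mortality_rate_per_100cy(episodes: pd.DataFrame,
                             group_by: str | None = None) -> pd.DataFrame:
    """Deaths per 100 child-years of follow-up.

    Person-time is attributed to the group of the episode's (current)
    covariate value, so time-dependent exposures are handled naturally.
    """
    df = episodes.copy()
    df["_py"] = (df["stop"] - df["start"]) / DAYS_PER_YEAR
    df["_d"] = df["event"].astype(int)
    keys = [group_by] if group_by else []
    if keys:
        g = df.groupby(keys, sort=True)
    else:
        g = df.groupby(np.zeros(len(df)), sort=True)
    out = g.agg(deaths=("_d", "sum"), child_years=("_py", "sum")).reset_index()
    if not keys:
        out = out.drop(columns=out.columns[0])
    zero = out["child_years"] <= 0
    if zero.any():
        warnings.warn("zero person-time in some group(s); rate undefined")
    with np.errstate(divide="ignore", invalid="ignore"):
        out["rate_per_100cy"] = np.where(
            zero, np.nan, 100.0 * out["deaths"] / out["child_years"])
    return out


def cumulative_incidence(data: pd.DataFrame, horizons) -> pd.DataFrame:
    """1 - KM survival at each horizon with Greenwood (log(-log)) 95% CIs."""
    dur, ev = _duration_event(data)
    kmf = KaplanMeierFitter()
    kmf.fit(dur, ev)
    last = dur.max()
    rows = []
    for t in horizons:
        tq = float(t)
        if tq > last:
            warnings.warn(f"horizon {t} beyond last observed time {last}; "
                          "carrying last value")
            tq = float(last)
        s = float(kmf.predict(tq))
        ci = kmf.confidence_interval_survival_function_
        idx = ci.index.searchsorted(tq, side="right") - 1
        lo_s, hi_s = ci.iloc[max(idx, 0)].to_numpy()
        rows.append({
            "horizon_days": float(t),
            "cum_incidence": 1.0 - s,
            "ci_lower": 1.0 - hi_s,
            "ci_upper": 1.0 - lo_s,
        })
    return pd.DataFrame(rows)


def plot_km(curves: dict[str, KMCurve], path=None, title: str | None = None):
    """Plot survival curves (one line per group); optionally save to file."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(7, 5))
    for label, c in curves.items():
        if c._fitter is not None:
            c._fitter.plot_survival_function(ax=ax)
        else:
            ax.step(np.concatenate([[0], c.event_times]),
                    np.concatenate([[1.0], c.survival]),
                    where="post", label=label)
    ax.set_xlabel("age (days)")
    ax.set_ylabel("survival probability")
    if title:
        ax.set_title(title)
    ax.legend()
    if path is not None:
        fig.savefig(path, dpi=120, bbox_inches="tight")
        plt.close(fig)
    return fig
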