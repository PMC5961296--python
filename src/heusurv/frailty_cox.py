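"""Shared gamma-frailty Cox proportional-hazards models on counting-process data.

Model.  Child ``i`` in study (cluster) ``s`` has hazard

    h_is(t) = u_s * h0(t) * exp(x_is(t)' beta),

where the study frailty ``u_s`` is gamma distributed with mean 1 and
variance ``theta`` and ``x_is(t)`` is a piecewise-constant covariate path
carried on counting-process episodes ``(start, stop]``.  ``theta = 0``
recovers the ordinary Cox model.

Estimation is by the classical EM algorithm for gamma frailty:

- E-step: with ``D_s`` events and cumulative risk-weighted baseline hazard
  ``A_s = sum_i int Y_i(t) exp(x_i(t)'beta) dH0(t)`` in cluster ``s``, the
  posterior frailty mean is ``u_s = (1/theta + D_s) / (1/theta + A_s)``.
- M-step: ``beta`` maximizes the Breslow partial likelihood with
  ``log u_s`` as an offset (Newton-Raphson); ``H0`` is the Breslow step
  estimator under the same offsets; ``theta`` maximizes the closed-form
  gamma marginal log-likelihood profile.

Standard errors come from the observed information of the final offset
partial likelihood.  Marginal survival predictions integrate the frailty
analytically: ``S_i(t) = (1 + theta * H_i(t))^(-1/theta)`` with
``H_i(t) = int exp(x_i(s)'beta) dH0(s)``.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import optimize, special, stats

logger = logging.getLogger(__name__)

_THETA_MAX = 20.0
_BETA_CLAMP = 20.0


# --------------------------------------------------------------------------
# model specification and design matrices
# --------------------------------------------------------------------------

@dataclass
class ModelSpec:
    """Which covariates enter the model and how selection treats them.

    ``covariates`` maps covariate name -> reference level (the omitted
    dummy).  ``always_keep`` are retained through stepwise selection
    regardless of significance (maternal ARV category in the pooled
    analysis); ``forced`` are design adjusters (region, maternal CD4) that
    likewise never leave the model.
    """

    covariates: dict[str, str]
    time_dependent: tuple[str, ...] = ()
    cluster: str = "study_id"
    always_keep: tuple[str, ...] = ()
    forced: tuple[str, ...] = ()
    selection: str = "none"  # none | stepwise_descending
    entry_p: float = 0.1
    stay_p: float = 0.05

    def copy_with(self, covariates: dict[str, str]) -> "ModelSpec":
        return ModelSpec(
            covariates=dict(covariates),
            time_dependent=self.time_dependent,
            cluster=self.cluster,
            always_keep=self.always_keep,
            forced=self.forced,
            selection=self.selection,
            entry_p=self.entry_p,
            stay_p=self.stay_p,
        )


@dataclass
class DesignInfo:
    """Explicit dummy coding: ordered (covariate, reference, non-reference
    levels) with one design column per non-reference level."""

    covariates: list[tuple[str, str, list[str]]]  # (name, reference, other levels)
    columns: list[str]

    @classmethod
    def from_data(cls, episodes: pd.DataFrame, spec: ModelSpec) -> "DesignInfo":
        covs, cols = [], []
        for name, ref in spec.covariates.items():
            if name not in episodes.columns:
                raise KeyError(f"covariate {name!r} not present in episode table")
            levels = pd.unique(episodes[name].astype(object))
            levels = sorted(str(v) for v in levels)
            if str(ref) not in levels:
                # reference absent from data: still usable, all levels coded
                logger.warning("reference level %r of %r absent from data", ref, name)
            others = [l for l in levels if l != str(ref)]
            covs.append((name, str(ref), others))
            cols.extend(f"{name}:{l}" for l in others)
        return cls(covariates=covs, columns=cols)

    def matrix(self, episodes: pd.DataFrame) -> np.ndarray:
        X = np.zeros((len(episodes), len(self.columns)))
        j = 0
        for name, _ref, others in self.covariates:
            vals = episodes[name].astype(object).astype(str).to_numpy()
            for lev in others:
                X[:, j] = vals == lev
                j += 1
        return X

    def block_slices(self) -> dict[str, slice]:
        out, j = {}, 0
        for name, _ref, others in self.covariates:
            out[name] = slice(j, j + len(others))
            j += len(others)
        return out


# --------------------------------------------------------------------------
# Breslow partial likelihood on (start, stop] episodes
# --------------------------------------------------------------------------

class _CoxData:
    """Preprocessed arrays for fast repeated partial-likelihood evaluation."""

    def __init__(self, start, stop, event, X, cluster_codes):
        self.start = np.asarray(start, float)
        self.stop = np.asarray(stop, float)
        self.event = np.asarray(event, bool)
        self.X = np.asarray(X, float)
        self.cluster = np.asarray(cluster_codes)
        if np.any(self.start >= self.stop):
            raise ValueError("episodes must satisfy start < stop")
        ev_times = self.stop[self.event]
        self.tau, self.d = np.unique(ev_times, return_counts=True)  # event times, ties
        if self.tau.size == 0:
            raise ValueError("no events in data")
        # event-time covariate sums (Breslow numerator)
        order = np.argsort(ev_times, kind="stable")
        Xe = self.X[self.event][order]
        te = ev_times[order]
        cut = np.searchsorted(te, self.tau, side="left")
        cs = np.vstack([np.zeros((1, self.X.shape[1])), np.cumsum(Xe, axis=0)])
        hi = np.searchsorted(te, self.tau, side="right")
        self.sum_x_events = cs[hi] - cs[cut]
        # sort orders for risk-set sweeps
        self.ord_start = np.argsort(self.start, kind="stable")
        self.ord_stop = np.argsort(self.stop, kind="stable")
        self.start_sorted = self.start[self.ord_start]
        self.stop_sorted = self.stop[self.ord_stop]
        # positions: number of starts < tau_k / stops < tau_k
        self.k_in = np.searchsorted(self.start_sorted, self.tau, side="left")
        self.k_out = np.searchsorted(self.stop_sorted, self.tau, side="left")
        self.n, self.p = self.X.shape
        # upper-triangle covariate cross-products, reused by every Hessian
        self.iu, self.ju = np.triu_indices(self.p)
        self.XX = self.X[:, self.iu] * self.X[:, self.ju]

    def risk_sums(self, w: np.ndarray, V: np.ndarray | None = None):
        """S0_k = sum of w over the risk set at each event time; optionally
        column-wise sums of V (n x q) weighted the same way."""
        cw_in = np.empty(self.n + 1)
        cw_in[0] = 0.0
        np.cumsum(w[self.ord_start], out=cw_in[1:])
        cw_out = np.empty(self.n + 1)
        cw_out[0] = 0.0
        np.cumsum(w[self.ord_stop], out=cw_out[1:])
        S0 = cw_in[self.k_in] - cw_out[self.k_out]
        if V is None:
            return S0
        q = V.shape[1]
        cv_in = np.empty((self.n + 1, q))
        cv_in[0] = 0.0
        np.cumsum(V[self.ord_start], axis=0, out=cv_in[1:])
        cv_out = np.empty((self.n + 1, q))
        cv_out[0] = 0.0
        np.cumsum(V[self.ord_stop], axis=0, out=cv_out[1:])
        SV = cv_in[self.k_in] - cv_out[self.k_out]
        return S0, SV


def _pl_loglik_grad_hess(data: _CoxData, beta: np.ndarray, offset: np.ndarray,
                         want_hess: bool = True):
    eta = data.X @ beta + offset
    eta = np.clip(eta, -500, 500)
    w = np.exp(eta)
    p = data.p
    if want_hess:
        iu, ju = data.iu, data.ju
        V = np.empty((data.n, p + iu.size))
        np.multiply(data.X, w[:, None], out=V[:, :p])
        np.multiply(data.XX, w[:, None], out=V[:, p:])
        S0, SV = data.risk_sums(w, V)
        S1 = SV[:, :p]
        S2u = SV[:, p:]
    else:
        S0, S1 = data.risk_sums(w, data.X * w[:, None])
        S2u = None
    ll = float(np.sum(eta[data.event]) - np.sum(data.d * np.log(S0)))
    xbar = S1 / S0[:, None]
    grad = data.sum_x_events.sum(axis=0) - (data.d[:, None] * xbar).sum(axis=0)
    if not want_hess:
        return ll, grad, None
    K = data.tau.size
    S2 = np.zeros((K, p, p))
    S2[:, iu, ju] = S2u
    S2[:, ju, iu] = S2u
    H = -(np.einsum("k,kij->ij", data.d / S0, S2)
          - np.einsum("k,ki,kj->ij", data.d, xbar, xbar))
    return ll, grad, H


def _newton_cox(data: _CoxData, offset: np.ndarray, beta0: np.ndarray,
                tol: float = 1e-9, max_iter: int = 60):
    """Maximize the Breslow partial likelihood in beta for fixed offsets."""
    beta = beta0.copy()
    if data.p == 0:
        ll, _, _ = _pl_loglik_grad_hess(data, beta, offset, want_hess=False)
        return beta, ll, np.zeros(0), np.zeros((0, 0))
    ll, grad, H = _pl_loglik_grad_hess(data, beta, offset)
    for _ in range(max_iter):
        try:
            step = np.linalg.solve(-H + 1e-12 * np.eye(data.p), grad)
        except np.linalg.LinAlgError:
            step = np.linalg.lstsq(-H, grad, rcond=None)[0]
        # damped update with step halving
        for _half in range(30):
            cand = np.clip(beta + step, -_BETA_CLAMP, _BETA_CLAMP)
            ll_new, grad_new, H_new = _pl_loglik_grad_hess(data, cand, offset)
            if np.isfinite(ll_new) and ll_new >= ll - 1e-12:
                break
            step = step / 2
        delta = np.max(np.abs(cand - beta)) if data.p else 0.0
        beta, ll, grad, H = cand, ll_new, grad_new, H_new
        if delta < tol:
            break
    return beta, ll, grad, H


def _breslow_increments(data: _CoxData, beta: np.ndarray, offset: np.ndarray):
    w = np.exp(np.clip(data.X @ beta + offset, -500, 500))
    S0 = data.risk_sums(w)
    return data.d / S0  # baseline hazard jumps at data.tau


class BreslowBaseline:
    """Breslow step estimate of the baseline cumulative hazard H0(t)."""

    def __init__(self, times: np.ndarray, increments: np.ndarray,
                 support_end: float = np.inf):
        self.times = np.asarray(times, float)
        self.increments = np.asarray(increments, float)
        self.cumhaz = np.cumsum(self.increments)
        #: last follow-up time observed by the fit; evaluation beyond it is
        #: an extrapolation (flat) worth flagging
        self.support_end = float(support_end)

    def __call__(self, t):
        """H0(t) = sum of jumps at event times <= t (flat beyond support)."""
        t = np.asarray(t, float)
        idx = np.searchsorted(self.times, t, side="right")
        out = np.where(idx > 0, self.cumhaz[np.minimum(idx, len(self.times)) - 1], 0.0)
        return out if out.ndim else float(out)

    def increments_between(self, start, stop):
        """H0(stop) - H0(start) for vectorized half-open intervals."""
        return self.__call__(stop) - self.__call__(start)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"time": self.times, "increment": self.increments,
                             "cumhaz": self.cumhaz})


# --------------------------------------------------------------------------
# the fit object
# --------------------------------------------------------------------------

@dataclass
class FrailtyCoxFit:
    """Result of a shared gamma-frailty Cox fit.

    ``beta``/``se_beta`` are indexed by design column ("covariate:level");
    ``theta`` is the frailty variance; ``frailties`` holds the posterior
    cluster frailty means; ``baseline`` the Breslow cumulative hazard.
    """

    beta: pd.Series
    se_beta: pd.Series
    cov_beta: pd.DataFrame
    theta: float
    frailties: pd.Series
    baseline: BreslowBaseline
    loglik: float
    n_events: int
    n_subjects: int
    n_iterations: int
    converged: bool
    design: DesignInfo
    spec: ModelSpec
    dropped_columns: list[str] = field(default_factory=list)

    def hazard_ratios(self) -> pd.DataFrame:
        """Table of HR, 95% CI and Wald p per design column."""
        hr = np.exp(self.beta)
        lo = np.exp(self.beta - 1.96 * self.se_beta)
        hi = np.exp(self.beta + 1.96 * self.se_beta)
        z = self.beta / self.se_beta
        p = 2 * stats.norm.sf(np.abs(z))
        return pd.DataFrame({"hr": hr, "ci_lower": lo, "ci_upper": hi,
                             "z": z, "p": p})

    def wald_block_p(self, covariate: str) -> float:
        """Joint Wald chi-square p-value for all levels of one covariate."""
        sl = self.design.block_slices()[covariate]
        cols = self.design.columns[sl]
        cols = [c for c in cols if c not in self.dropped_columns]
        if not cols:
            return 1.0
        b = self.beta[cols].to_numpy()
        V = self.cov_beta.loc[cols, cols].to_numpy()
        try:
            stat = float(b @ np.linalg.solve(V, b))
        except np.linalg.LinAlgError:
            stat = float(b @ np.linalg.pinv(V) @ b)
        return float(stats.chi2.sf(stat, df=len(cols)))

    def to_dict(self) -> dict:
        return {
            "beta": self.beta.to_dict(),
            "se_beta": self.se_beta.to_dict(),
            "theta": self.theta,
            "frailties": self.frailties.to_dict(),
            "baseline_times": self.baseline.times.tolist(),
            "baseline_increments": self.baseline.increments.tolist(),
            "loglik": self.loglik,
            "n_events": self.n_events,
            "n_subjects": self.n_subjects,
            "n_iterations": self.n_iterations,
            "converged": self.converged,
            "dropped_columns": self.dropped_columns,
        }


def _gamma_marginal_terms(theta: float, D: np.ndarray, A: np.ndarray) -> float:
    """Cluster terms of the gamma-frailty marginal log-likelihood."""
    if theta < 1e-10:
        return float(np.sum(-A + 0.0))  # limit absorbed in the Cox terms
    nu = 1.0 / theta
    return float(np.sum(special.gammaln(nu + D) - special.gammaln(nu)
                        + nu * np.log(nu) - (nu + D) * np.log(nu + A)))


def fit_frailty_cox(
    episodes: pd.DataFrame,
    spec: ModelSpec,
    theta: float | None = None,
    tol: float = 1e-6,
    max_iter: int = 200,
    init_beta: pd.Series | None = None,
    init_frailties: pd.Series | None = None,
    theta_bracket: tuple[float, float] | None = None,
) -> FrailtyCoxFit:
    """Fit the shared gamma-frailty Cox model by EM.

    Parameters
    ----------
    episodes:
        Counting-process table with columns ``child_id``, ``start``,
        ``stop``, ``event``, the cluster column named by ``spec.cluster``,
        and every covariate in ``spec.covariates``.
    spec:
        Covariates with reference levels; see :class:`ModelSpec`.
    theta:
        If given, the frailty variance is held fixed at this value
        (``theta=0`` reduces to an ordinary Cox fit); otherwise it is
        estimated by profile marginal likelihood.
    init_beta, init_frailties:
        Optional warm starts (e.g. a previous fit on closely related data,
        as in bootstrap resampling); aligned by design-column / cluster
        name, missing entries default to 0 / 1.
    theta_bracket:
        Restrict the profile search for theta to this bracket instead of
        the default coarse-grid-plus-Brent scan (a localized search around
        a known point estimate).

    Notes
    -----
    Covariate levels with no contrast (design columns constant in the data)
    are dropped with a warning rather than failing; levels with zero events
    are reported with large standard errors (quasi-separation).
    """
    design = DesignInfo.from_data(episodes, spec)
    X = design.matrix(episodes)
    keep = ~np.all(X == X[0:1, :], axis=0) if len(X) else np.ones(X.shape[1], bool)
    dropped = [c for c, k in zip(design.columns, keep) if not k]
    if dropped:
        warnings.warn(f"dropping no-contrast design column(s): {dropped}")
    cols = [c for c, k in zip(design.columns, keep) if k]
    X = X[:, keep]

    clusters, cluster_codes = np.unique(episodes[spec.cluster].astype(str), return_inverse=True)
    data = _CoxData(episodes["start"], episodes["stop"], episodes["event"],
                    X, cluster_codes)
    n_clusters = clusters.size
    D = np.bincount(cluster_codes[data.event], minlength=n_clusters).astype(float)

    estimate_theta = theta is None
    if not estimate_theta and float(theta) < 0:
        raise ValueError("frailty variance must be nonnegative")

    iter_count = 0

    def inner_em(th: float, beta0: np.ndarray, u0: np.ndarray,
                 inner_tol: float | None = None, inner_max: int | None = None):
        """EM over (beta, frailties) at fixed theta.

        One quasi-Newton step per M-step, warm-started at the current beta;
        the Hessian changes slowly near the fixed point, so it is refreshed
        only periodically or when a step fails to improve the offset
        partial likelihood.
        """
        nonlocal iter_count
        inner_tol = tol if inner_tol is None else inner_tol
        inner_max = max_iter if inner_max is None else inner_max
        beta_c, u_c = beta0.copy(), u0.copy()
        H_cache: np.ndarray | None = None
        u_hist: list | None = None
        ok = False
        for it in range(1, inner_max + 1):
            iter_count += 1
            off = np.log(u_c)[cluster_codes]
            refresh = H_cache is None or it <= 3 or it % 10 == 0
            ll0, grad, H = _pl_loglik_grad_hess(data, beta_c, off, want_hess=refresh)
            if refresh:
                H_cache = H
            if data.p:
                try:
                    step = np.linalg.solve(-H_cache + 1e-12 * np.eye(data.p), grad)
                except np.linalg.LinAlgError:
                    step = np.linalg.lstsq(-H_cache, grad, rcond=None)[0]
                beta_new = np.clip(beta_c + step, -_BETA_CLAMP, _BETA_CLAMP)
                ll1, _, _ = _pl_loglik_grad_hess(data, beta_new, off, want_hess=False)
                if not np.isfinite(ll1) or ll1 < ll0 - 1e-10:
                    beta_new, _, _, H_cache = _newton_cox(data, off, beta_c, max_iter=3)
            else:
                beta_new = beta_c
            dH0 = _breslow_increments(data, beta_new, off)
            base = BreslowBaseline(data.tau, dH0)
            # cluster cumulative risk under the unit-frailty linear predictor
            risk = np.exp(np.clip(X @ beta_new, -500, 500))
            A = np.bincount(cluster_codes,
                            weights=risk * base.increments_between(data.start, data.stop),
                            minlength=n_clusters)
            u_new = np.ones(n_clusters) if th == 0.0 else \
                (1.0 / th + D) / (1.0 / th + A)
            # Aitken acceleration of the linearly-convergent frailty
            # sequence, applied to three consecutive iterates every 8th
            # iteration (guarded elementwise; rejected components keep the
            # plain EM update)
            if th > 0:
                r = it % 8
                if r == 6:
                    u_hist = [u_new, None]
                elif r == 7 and u_hist is not None:
                    u_hist[1] = u_new
                elif r == 0 and u_hist is not None and u_hist[1] is not None:
                    u1, u2 = u_hist
                    denom = u_new - 2.0 * u2 + u1
                    with np.errstate(divide="ignore", invalid="ignore"):
                        acc = u1 - (u2 - u1) ** 2 / denom
                    good = np.isfinite(acc) & (np.abs(denom) > 1e-14) & (acc > 1e-8)
                    u_new = np.where(good, acc, u_new)
                    u_hist = None
            # convergence on the regression parameters; the frailty values
            # (posterior means, quoted to far fewer digits) get a looser band
            delta = max(
                np.max(np.abs(beta_new - beta_c)) if data.p else 0.0,
                np.max(np.abs(u_new - u_c)) / 100.0,
            )
            beta_c, u_c = beta_new, u_new
            if delta < inner_tol:
                ok = True
                break
        # marginal log-likelihood at this (theta; beta, H0, u)
        ev_eta = (X @ beta_c)[data.event]
        jumps = dH0[np.searchsorted(data.tau, data.stop[data.event])]
        event_terms = float(np.sum(np.log(jumps)) + np.sum(ev_eta))
        if th > 0:
            mll = event_terms + _gamma_marginal_terms(th, D, A)
        else:
            mll = event_terms - float(np.sum(A))
        return beta_c, u_c, mll, ok

    beta = np.zeros(X.shape[1])
    if init_beta is not None:
        beta = np.asarray([float(init_beta.get(c, 0.0)) for c in cols])
    u = np.ones(n_clusters)
    if init_frailties is not None:
        u = np.asarray([float(init_frailties.get(c, 1.0)) for c in clusters])
        u = np.clip(u, 1e-6, None)
    if estimate_theta:
        # profile the marginal likelihood over theta: coarse log-grid to
        # bracket the maximum, then Brent between the bracketing neighbors.
        # Each evaluation solves the inner EM, warm-started at the previous
        # solution; a looser inner tolerance suffices during the search.
        warm = {"beta": beta, "u": u}

        def profile(th: float, final: bool = False) -> float:
            b, uu, mll, _ = inner_em(
                float(th), warm["beta"], warm["u"],
                inner_tol=None if final else max(tol, 1e-5) * 10,
                inner_max=None if final else 100)
            warm["beta"], warm["u"] = b, uu
            return mll

        if theta_bracket is not None:
            lo, hi = max(float(theta_bracket[0]), 1e-8), float(theta_bracket[1])
            mll_zero = profile(0.0)
            res = optimize.minimize_scalar(
                lambda t: -profile(float(t)), bounds=(lo, hi),
                method="bounded", options={"xatol": 1e-6})
            th = float(res.x)
            if -res.fun < mll_zero or th < 1e-6:
                th = 0.0
        else:
            grid = [0.0, 0.01, 0.025, 0.05, 0.1, 0.2, 0.4, 0.8, 1.6, 3.2, 6.4,
                    _THETA_MAX]
            vals = [profile(g) for g in grid]
            k = int(np.argmax(vals))
            if k == 0:
                th = 0.0
            else:
                lo = grid[max(k - 1, 0)]
                hi = grid[min(k + 1, len(grid) - 1)]
                res = optimize.minimize_scalar(
                    lambda t: -profile(float(t)), bounds=(max(lo, 1e-8), hi),
                    method="bounded", options={"xatol": 1e-6})
                th = float(res.x)
                if -res.fun < vals[0] or th < 1e-6:
                    th = 0.0
    else:
        th = float(theta)
    beta, u, marg_ll, converged = inner_em(th, beta, u)
    n_iter = iter_count
    if not converged:
        logger.warning("frailty EM did not converge in %d iterations at "
                       "theta=%.4g", max_iter, th)

    # polish the M-step to full convergence at the final frailties, then
    # take the observed information of the offset partial likelihood there
    off = np.log(u)[cluster_codes]
    beta, _, _, H = _newton_cox(data, off, beta)
    try:
        cov = np.linalg.inv(-H + 1e-12 * np.eye(len(beta)))
    except np.linalg.LinAlgError:
        cov = np.linalg.pinv(-H)
    se = np.sqrt(np.maximum(np.diag(cov), 0.0))
    big = se > 10
    if big.any():
        warnings.warn(
            "level(s) with little or no event information (quasi-separation): "
            f"{[c for c, b in zip(cols, big) if b]}")

    dH0 = _breslow_increments(data, beta, off)
    base = BreslowBaseline(data.tau, dH0, support_end=float(data.stop.max()))
    risk = np.exp(np.clip(X @ beta, -500, 500))
    A = np.bincount(cluster_codes, weights=risk * base.increments_between(data.start, data.stop),
                    minlength=n_clusters)
    # marginal log-likelihood at convergence:
    # event terms sum log dH0(t_i) + x_i'beta, plus the gamma cluster terms
    ev_eta = (X @ beta)[data.event]
    jump_at_event = dH0[np.searchsorted(data.tau, data.stop[data.event])]
    event_terms = float(np.sum(np.log(jump_at_event)) + np.sum(ev_eta))
    if th > 0:
        marg_ll = event_terms + _gamma_marginal_terms(th, D, A)
    else:
        marg_ll = event_terms - float(np.sum(A))

    full_cols = design.columns
    beta_s = pd.Series(0.0, index=full_cols)
    se_s = pd.Series(np.nan, index=full_cols)
    beta_s[cols] = beta
    se_s[cols] = se
    cov_df = pd.DataFrame(cov, index=cols, columns=cols).reindex(
        index=full_cols, columns=full_cols)

    return FrailtyCoxFit(
        beta=beta_s, se_beta=se_s, cov_beta=cov_df, theta=float(th),
        frailties=pd.Series(u, index=clusters),
        baseline=base, loglik=marg_ll,
        n_events=int(data.event.sum()),
        n_subjects=int(pd.unique(episodes["child_id"]).size),
        n_iterations=n_iter, converged=converged,
        design=design, spec=spec, dropped_columns=dropped,
    )


# --------------------------------------------------------------------------
# univariate screen and stepwise-descending selection
# --------------------------------------------------------------------------

def univariate_screen(
    episodes: pd.DataFrame,
    spec: ModelSpec,
    theta: float | None = None,
) -> pd.DataFrame:
    """One single-covariate frailty-Cox fit per covariate in ``spec``.

    Returns a tidy table with one row per non-reference level (HR, 95% CI,
    Wald p) plus the block p-value shared by all levels of a covariate.
    """
    rows = []
    for name, ref in spec.covariates.items():
        sub = spec.copy_with({name: ref})
        fit = fit_frailty_cox(episodes, sub, theta=theta)
        tab = fit.hazard_ratios()
        block_p = fit.wald_block_p(name)
        for col in tab.index:
            rows.append({
                "covariate": name, "term": col,
                "hr": tab.loc[col, "hr"],
                "ci_lower": tab.loc[col, "ci_lower"],
                "ci_upper": tab.loc[col, "ci_upper"],
                "p": tab.loc[col, "p"],
                "block_p": block_p,
            })
    return pd.DataFrame(rows)


def stepwise_descending_select(
    episodes: pd.DataFrame,
    spec: ModelSpec,
    screen: pd.DataFrame | None = None,
    theta: float | None = None,
) -> ModelSpec:
    """Stepwise-descending covariate selection.

    Candidates are covariates with univariate block p below ``spec.entry_p``
    plus the always-kept and forced covariates; the covariate with the
    largest multivariable block Wald p at or above ``spec.stay_p`` is
    dropped, iterating until every remaining covariate is significant.
    Covariates are kept or dropped as blocks (all levels together), and
    always-kept/forced covariates never leave.
    """
    if screen is None:
        screen = univariate_screen(episodes, spec, theta=theta)
    keep_always = set(spec.always_keep) | set(spec.forced)
    block_p = screen.groupby("covariate")["block_p"].first()
    current = {
        name: ref for name, ref in spec.covariates.items()
        if name in keep_always or block_p.get(name, 1.0) < spec.entry_p
    }
    if not current:
        return spec.copy_with({})
    while True:
        fit = fit_frailty_cox(episodes, spec.copy_with(current), theta=theta)
        droppable = {n: fit.wald_block_p(n) for n in current if n not in keep_always}
        if not droppable:
            break
        worst, worst_p = max(droppable.items(), key=lambda kv: kv[1])
        if worst_p >= spec.stay_p:
            logger.info("stepwise: dropping %s (block p=%.4f)", worst, worst_p)
            del current[worst]
            if not current:
                break
        else:
            break
    final = spec.copy_with(current)
    final.selection = "none"
    return final


def fit_joint_bf_art(
    episodes: pd.DataFrame,
    adjusters: Mapping[str, str] | None = None,
    theta: float | None = None,
) -> FrailtyCoxFit:
    """Fit the four-level joint breastfeeding-by-maternal-ART model.

    ``episodes`` must come from ``split_episodes(..., "bf_by_art_joint")``,
    carrying the time-dependent ``bf_art_category`` (A reference: child not
    breastfed, mother not on 3-drug ART).  Default adjusters: region,
    maternal antenatal CD4 group and birth weight.
    """
    if "bf_art_category" not in episodes.columns:
        raise KeyError("episodes lack 'bf_art_category'; use the bf_by_art_joint scheme")
    present = set(episodes["bf_art_category"].astype(str).unique())
    absent = [l for l in ("B", "C", "D") if l not in present]
    if absent:
        warnings.warn(
            f"joint breastfeeding-by-ART level(s) {absent} carry no "
            "person-time; their hazard ratios are undefined")
    covs: dict[str, str] = {"bf_art_category": "A"}
    if adjusters is None:
        adjusters = {"region": "Africa", "cd4_group": "ge350",
                     "birth_weight_group": "ge2500"}
    covs.update(adjusters)
    spec = ModelSpec(covariates=covs, time_dependent=("bf_art_category",))
    return fit_frailty_cox(episodes, spec, theta=theta)


# --------------------------------------------------------------------------
# marginal survival prediction
# --------------------------------------------------------------------------

def predict_marginal_survival(
    fit: FrailtyCoxFit,
    paths: pd.DataFrame,
    t: float,
    conditional: bool = False,
) -> pd.Series:
    """Predicted survival probability at age ``t`` per child.

    ``paths`` is an episode-style table (``child_id``, ``start``, ``stop``
    and the model covariates) describing each child's covariate step
    function on at least ``[0, t]``; episode boundaries beyond ``t`` are
    truncated.  The child's cumulative hazard is

        H_i(t) = sum over path episodes of exp(x'beta) * [H0(min(stop,t)) - H0(min(start,t))]

    and marginal survival integrates the gamma frailty analytically,
    ``S_i = (1 + theta H_i)^(-1/theta)`` (``exp(-H_i)`` when theta < 1e-8).
    With ``conditional=True``, survival is conditional on each study's
    estimated frailty, ``exp(-u_s H_i)``.
    """
    if t < 0:
        raise ValueError("t must be nonnegative")
    last = paths.groupby("child_id")["stop"].max()
    if (last < t).any():
        missing = last.index[last < t].tolist()[:5]
        raise ValueError(
            f"covariate path does not reach t={t} for child(ren) {missing}")
    if t > fit.baseline.support_end:
        warnings.warn("t beyond the fitted baseline support; H0 extended flat")
    X = fit.design.matrix(paths)
    keep = [i for i, c in enumerate(fit.design.columns)
            if c not in fit.dropped_columns]
    eta = X[:, keep] @ fit.beta[[fit.design.columns[i] for i in keep]].to_numpy()
    lo = np.minimum(paths["start"].to_numpy(float), t)
    hi = np.minimum(paths["stop"].to_numpy(float), t)
    dH = fit.baseline.increments_between(lo, hi)
    contrib = np.exp(eta) * dH
    ids, codes = np.unique(paths["child_id"].to_numpy(), return_inverse=True)
    H = np.bincount(codes, weights=contrib, minlength=ids.size)
    if conditional:
        u = fit.frailties.reindex(paths[fit.spec.cluster].astype(str)).to_numpy()
        uH = np.bincount(codes, weights=u * contrib, minlength=ids.size)
        S = np.exp(-uH)
    elif fit.theta < 1e-8:
        S = np.exp(-H)
    else:
        S = np.exp(-np.log1p(fit.theta * H) / fit.theta)
    return pd.Series(S, index=pd.Index(ids, name="child_id"))
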