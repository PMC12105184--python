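"""Weighted stratified Cox partial likelihood for recurrent events.

One engine maximizes the (optionally weighted) stratified partial
likelihood with Breslow handling of ties and counting-process risk sets

    l(β) = Σ_strata Σ_events w_i [ x_iᵀβ − log Σ_{j at risk} w_j e^{x_jᵀβ} ],

by Newton–Raphson with step-halving.  Per-row observation weights enter
both the event terms and the risk-set sums, so the gradient is exactly the
weighted score equation of the balanced analysis; weights are treated as
fixed constants.  Robust (sandwich) variance aggregates score residuals
within subject clusters across rows and strata.

Model presets map the standard recurrent-event estimators onto this
engine: Cox on time-to-first-event, Andersen–Gill (AG), Lin–Wei–Yang–Ying
(LWYY = AG point estimate with cluster-robust variance), PWP gap-time and
counting-process variants, PWP with robust variance, and the weighted PWP
model in which each risk set is entropy-balanced (or inverse-probability
weighted) on baseline covariates before fitting.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm

from . import balance as bal
from .data import (
    EventHistory,
    first_event_subset,
    to_counting_process,
    to_gap_time,
    truncate_strata,
)

__all__ = [
    "ModelSpec",
    "FitResult",
    "FitError",
    "neg_log_partial_likelihood",
    "score",
    "fit",
    "fit_cox_first_event",
    "fit_ag",
    "fit_lwyy",
    "fit_pwp_gt",
    "fit_pwp_cp",
    "fit_pwp_robust",
    "fit_weighted_pwp",
]

_Z = norm.ppf(0.975)


class FitError(RuntimeError):
    """Estimation failed (no events, separation, singular information)."""


@dataclass
class ModelSpec:
    """Configuration mapping one named model onto the shared engine."""

    risk_interval: str = "gap"  # "gap" | "counting_process"
    stratify_by_event_number: bool = False
    weights: dict[int, bal.StratumWeights] | None = None
    variance: str = "naive"  # "naive" | "robust_cluster"
    adjust_covariates: Sequence[str] | None = None
    first_event_only: bool = False
    label: str = "cox"


@dataclass
class FitResult:
    """Treatment-effect estimate from one model fit.

    ``coef`` is the log-hazard-ratio for treatment; ``se`` is the standard
    error the model prescribes (naive or robust), used for the Wald 95% CI
    on the hazard-ratio scale.
    """

    model_label: str
    coef: float
    naive_se: float
    robust_se: float | None
    variance_used: str
    n_events_used: int
    strata_used: list[int]
    converged: bool
    iterations: int
    coef_all: np.ndarray = field(default=None, repr=False)
    term_names: list[str] = field(default_factory=list, repr=False)

    @property
    def se(self) -> float:
        return self.robust_se if self.variance_used == "robust_cluster" else self.naive_se

    @property
    def hr(self) -> float:
        return float(np.exp(self.coef))

    @property
    def ci95(self) -> tuple[float, float]:
        return (
            float(np.exp(self.coef - _Z * self.se)),
            float(np.exp(self.coef + _Z * self.se)),
        )

    def summary(self) -> dict:
        lo, hi = self.ci95
        return {
            "model": self.model_label,
            "coef": self.coef,
            "hr": self.hr,
            "se": self.se,
            "ci95_low": lo,
            "ci95_high": hi,
            "n_events": self.n_events_used,
            "strata": list(self.strata_used),
            "converged": self.converged,
        }


# ---------------------------------------------------------------------------
# array preparation


def _design(h: EventHistory, spec: ModelSpec):
    """Flatten an EventHistory + spec into fitting arrays.

    Returns (stratum, start, stop, status, X, w, cluster, term_names).
    """
    hh = first_event_subset(h) if spec.first_event_only else h
    hh = to_gap_time(hh) if spec.risk_interval == "gap" else to_counting_process(hh)
    df = hh.table

    if spec.weights is not None:
        if not spec.stratify_by_event_number:
            raise ValueError("per-stratum weights require stratification")
        keep = sorted(spec.weights)
        df = df[df["k"].isin(keep)].reset_index(drop=True)

    terms = ["treatment"] + list(spec.adjust_covariates or [])
    X = df[terms].to_numpy(dtype=float)
    stratum = (
        df["k"].to_numpy(dtype=int)
        if spec.stratify_by_event_number
        else np.zeros(len(df), dtype=int)
    )
    w = np.ones(len(df))
    if spec.weights is not None:
        for k, sw in spec.weights.items():
            mask = df["k"].to_numpy() == k
            wmap = pd.Series(sw.weights, index=list(sw.subject_ids))
            w[mask] = wmap.reindex(df.loc[mask, "id"]).to_numpy()
        if np.any(~np.isfinite(w)):
            raise ValueError("weights do not cover every risk-set member")
    cluster = pd.factorize(df["id"])[0]
    return (
        stratum,
        df["start"].to_numpy(dtype=float),
        df["stop"].to_numpy(dtype=float),
        df["status"].to_numpy(dtype=int),
        X,
        w,
        cluster,
        terms,
    )


class _StratumData:
    """Pre-sorted per-stratum arrays for repeated likelihood evaluation."""

    def __init__(self, start, stop, status, X, w):
        self.X = X
        self.w = w
        self.stop = stop
        self.start = start
        self.status = status
        order_stop = np.argsort(stop, kind="stable")
        self.order_stop = order_stop
        self.sorted_stop = stop[order_stop]
        order_start = np.argsort(start, kind="stable")
        self.order_start = order_start
        self.sorted_start = start[order_start]
        ev = status == 1
        self.event_rows = np.flatnonzero(ev)
        t = stop[ev]
        wt = w[ev]
        # Breslow: group tied event times
        self.times, inv = np.unique(t, return_inverse=True)
        self.dw = np.bincount(inv, weights=wt)  # Σ w over events at each time
        self.n_events = int(ev.sum())
        self.has_entry = bool(np.any(start > 0))

    def _risk_suffix(self, vals):
        """Σ of vals over {j: stop_j ≥ t} − {j: start_j ≥ t} at each event time."""
        v_stop = vals[self.order_stop]
        suf_stop = np.concatenate(
            [np.cumsum(v_stop[::-1], axis=0)[::-1], np.zeros((1,) + vals.shape[1:])]
        )
        idx = np.searchsorted(self.sorted_stop, self.times, side="left")
        out = suf_stop[idx]
        if self.has_entry:
            v_start = vals[self.order_start]
            suf_start = np.concatenate(
                [np.cumsum(v_start[::-1], axis=0)[::-1], np.zeros((1,) + vals.shape[1:])]
            )
            jdx = np.searchsorted(self.sorted_start, self.times, side="left")
            out = out - suf_start[jdx]
        return out

    def moments(self, beta):
        """S0, S1, S2 risk-set sums at each unique event time."""
        eta = self.X @ beta
        eta = np.clip(eta, -500, 500)
        r = self.w * np.exp(eta)
        p = self.X.shape[1]
        s0 = self._risk_suffix(r)
        s1 = self._risk_suffix(r[:, None] * self.X)
        xxt = self.X[:, :, None] * self.X[:, None, :]
        s2 = self._risk_suffix(r[:, None, None] * xxt)
        return r, s0, s1, s2

    def loglik_score_info(self, beta):
        r, s0, s1, s2 = self.moments(beta)
        if np.any(s0 <= 0):
            raise FitError("empty risk set at an event time")
        ev = self.event_rows
        eta = self.X @ beta
        ll = float(np.sum(self.w[ev] * eta[ev]) - np.sum(self.dw * np.log(s0)))
        m = s1 / s0[:, None]
        sc = (self.w[ev, None] * self.X[ev]).sum(axis=0) - (self.dw[:, None] * m).sum(
            axis=0
        )
        v = s2 / s0[:, None, None] - m[:, :, None] * m[:, None, :]
        info = (self.dw[:, None, None] * v).sum(axis=0)
        return ll, sc, info

    def score_residual_rows(self, beta):
        """Per-row score residuals U_j (rows sum to the stratum score)."""
        r, s0, s1, _ = self.moments(beta)
        m = s1 / s0[:, None]
        # prefix sums over event times of dw/S0 and dw·m/S0
        c0 = np.concatenate([[0.0], np.cumsum(self.dw / s0)])
        c1 = np.concatenate(
            [np.zeros((1, m.shape[1])), np.cumsum(self.dw[:, None] * m / s0[:, None], axis=0)]
        )
        hi = np.searchsorted(self.times, self.stop, side="right")
        lo = np.searchsorted(self.times, self.start, side="right")
        b0 = c0[hi] - c0[lo]
        b1 = c1[hi] - c1[lo]
        U = -r[:, None] * (self.X * b0[:, None] - b1)
        ev = self.event_rows
        # m at each event row's own time
        pos = np.searchsorted(self.times, self.stop[ev])
        U[ev] += self.w[ev, None] * (self.X[ev] - m[pos])
        return U


def _split_strata(stratum, start, stop, status, X, w):
    out = []
    for s in np.unique(stratum):
        idx = np.flatnonzero(stratum == s)
        sd = _StratumData(start[idx], stop[idx], status[idx], X[idx], w[idx])
        out.append((s, idx, sd))
    return out


# ---------------------------------------------------------------------------
# public likelihood surface


def neg_log_partial_likelihood(
    beta: np.ndarray | float, h: EventHistory, spec: ModelSpec
) -> float:
    """Negative weighted log partial likelihood at ``beta``."""
    beta = np.atleast_1d(np.asarray(beta, dtype=float))
    stratum, start, stop, status, X, w, _, _ = _design(h, spec)
    if status.sum() == 0:
        raise FitError("no events: partial likelihood is constant")
    ll = 0.0
    for _, _, sd in _split_strata(stratum, start, stop, status, X, w):
        if sd.n_events:
            ll += sd.loglik_score_info(beta)[0]
    return -ll


def score(beta: np.ndarray | float, h: EventHistory, spec: ModelSpec) -> np.ndarray:
    """Gradient of the weighted log partial likelihood at ``beta``."""
    beta = np.atleast_1d(np.asarray(beta, dtype=float))
    stratum, start, stop, status, X, w, _, _ = _design(h, spec)
    if status.sum() == 0:
        raise FitError("no events: partial likelihood is constant")
    sc = np.zeros(X.shape[1])
    for _, _, sd in _split_strata(stratum, start, stop, status, X, w):
        if sd.n_events:
            sc += sd.loglik_score_info(beta)[1]
    return sc


def _newton(strata_data, p, max_iter=50, tol_beta=1e-9, tol_score=1e-8):
    beta = np.zeros(p)

    def evaluate(b):
        ll, sc, info = 0.0, np.zeros(p), np.zeros((p, p))
        for _, _, sd in strata_data:
            if sd.n_events == 0:
                continue
            l_, s_, i_ = sd.loglik_score_info(b)
            ll += l_
            sc += s_
            info += i_
        return ll, sc, info

    ll, sc, info = evaluate(beta)
    it = 0
    converged = False
    for it in range(1, max_iter + 1):
        if np.abs(sc).max() < tol_score:
            converged = True
            break
        try:
            step = np.linalg.solve(info, sc)
        except np.linalg.LinAlgError as e:
            raise FitError("singular information matrix") from e
        # step-halving: accept any step that does not decrease the
        # log-likelihood beyond floating-point noise at its magnitude
        slack = 1e-9 * (abs(ll) + 1.0)
        t = 1.0
        for _ in range(30):
            cand = beta + t * step
            ll_new, sc_new, info_new = evaluate(cand)
            if np.isfinite(ll_new) and ll_new >= ll - slack:
                break
            t *= 0.5
        delta = np.abs(t * step).max()
        beta, ll, sc, info = cand, ll_new, sc_new, info_new
        if np.abs(beta).max() > 50:
            raise FitError("estimate diverging: monotone likelihood (separation)")
        if delta < tol_beta:
            converged = np.abs(sc).max() < tol_score
            break
    else:
        converged = np.abs(sc).max() < tol_score
    if not converged and np.abs(sc).max() >= 1e-6:
        raise FitError(f"Newton–Raphson did not converge ({it} iterations)")
    if np.abs(beta).max() > 10:
        # a log-hazard-ratio this size only arises from a monotone
        # likelihood: the score tends to zero while the estimate runs away
        raise FitError("monotone likelihood (separation): estimate unbounded")
    return beta, ll, sc, info, it, True


def fit(h: EventHistory, spec: ModelSpec) -> FitResult:
    """Maximize the (weighted, stratified) partial likelihood."""
    stratum, start, stop, status, X, w, cluster, terms = _design(h, spec)
    n_events = int(status.sum())
    if n_events == 0:
        raise FitError("no events: partial likelihood is constant")
    p = X.shape[1]
    strata_data = _split_strata(stratum, start, stop, status, X, w)
    beta, ll, sc, info, it, converged = _newton(strata_data, p)

    try:
        naive_cov = np.linalg.inv(info)
    except np.linalg.LinAlgError as e:
        raise FitError("singular information matrix at the optimum") from e

    robust_se = None
    if spec.variance == "robust_cluster":
        U = np.zeros((len(cluster), p))
        for _, idx, sd in strata_data:
            if sd.n_events:
                U[idx] = sd.score_residual_rows(beta)
        n_cl = cluster.max() + 1
        S = np.zeros((n_cl, p))
        np.add.at(S, cluster, U)
        meat = S.T @ S
        rcov = naive_cov @ meat @ naive_cov
        robust_se = float(np.sqrt(rcov[0, 0]))

    strata_used = sorted(int(s) for s, _, sd in strata_data if sd.n_events)
    return FitResult(
        model_label=spec.label,
        coef=float(beta[0]),
        naive_se=float(np.sqrt(naive_cov[0, 0])),
        robust_se=robust_se,
        variance_used=spec.variance,
        n_events_used=n_events,
        strata_used=strata_used,
        converged=converged,
        iterations=it,
        coef_all=beta,
        term_names=terms,
    )


# ---------------------------------------------------------------------------
# model presets


def fit_cox_first_event(h, adjust=None) -> FitResult:
    """Cox proportional-hazards model on time to the first event."""
    return fit(
        h,
        ModelSpec(
            risk_interval="counting_process",
            first_event_only=True,
            adjust_covariates=adjust,
            label="cox_first_event",
        ),
    )


def fit_ag(h, adjust=None) -> FitResult:
    """Andersen–Gill: common baseline hazard, calendar-time risk intervals."""
    return fit(
        h,
        ModelSpec(
            risk_interval="counting_process",
            adjust_covariates=adjust,
            label="ag",
        ),
    )


def fit_lwyy(h, adjust=None) -> FitResult:
    """Lin–Wei–Yang–Ying marginal rate model: AG estimate, robust variance."""
    return fit(
        h,
        ModelSpec(
            risk_interval="counting_process",
            variance="robust_cluster",
            adjust_covariates=adjust,
            label="lwyy",
        ),
    )


def fit_pwp_gt(h, adjust=None) -> FitResult:
    """PWP gap-time model: stratified by event number, clock reset per event."""
    return fit(
        h,
        ModelSpec(
            risk_interval="gap",
            stratify_by_event_number=True,
            adjust_covariates=adjust,
            label="pwp_gt",
        ),
    )


def fit_pwp_cp(h, adjust=None) -> FitResult:
    """PWP counting-process model: stratified, calendar-time intervals."""
    return fit(
        h,
        ModelSpec(
            risk_interval="counting_process",
            stratify_by_event_number=True,
            adjust_covariates=adjust,
            label="pwp_cp",
        ),
    )


def fit_pwp_robust(h, adjust=None) -> FitResult:
    """PWP gap-time model with cluster-robust (sandwich) variance."""
    return fit(
        h,
        ModelSpec(
            risk_interval="gap",
            stratify_by_event_number=True,
            variance="robust_cluster",
            adjust_covariates=adjust,
            label="pwp_robust",
        ),
    )


def fit_weighted_pwp(
    h: EventHistory,
    balance_covariates: Sequence[str] | None = None,
    weight_method: str = "entropy",
    truncation: str = "eligibility",
    smd_threshold: float = 0.1,
    tol: float = 1e-8,
    max_iter: int = 200,
) -> FitResult:
    """Entropy-balance-weighted PWP gap-time model.

    Restores within-risk-set covariate balance between arms before the
    stratified fit, correcting the collider bias that conditioning on
    prior events induces.  Pipeline: restrict to strata with both arms
    represented by ≥2 subjects; solve per-stratum balancing weights
    (stratum 1 keeps unit weights); optionally truncate further at the
    first stratum whose post-weighting |SMD| ≥ ``smd_threshold``; fit the
    weighted stratified gap-time Cox model with cluster-robust variance.

    Parameters
    ----------
    balance_covariates:
        Columns to balance; all covariates by default ("fully weighted").
    weight_method:
        ``"entropy"`` (KL-minimal balancing weights) or ``"ipw"``
        (stabilized inverse-probability-of-treatment weights).
    truncation:
        ``"eligibility"`` (arm-size rule only), ``"smd"`` (additionally
        drop from the first stratum failing the SMD check onward), or
        ``"none"`` (still requires eligibility — balancing is undefined
        below two subjects per arm).
    """
    hh = to_gap_time(h)
    k_elig = bal.eligible_strata(hh)
    hh = truncate_strata(hh, k_elig)
    cols = list(balance_covariates or hh.covariate_columns)
    if weight_method == "entropy":
        # A stratum can pass the arm-size rule yet be infeasible to balance
        # (pooled mean outside an arm's covariate hull, typical of tiny late
        # strata); the retained prefix ends at the first such stratum.
        weights = bal.entropy_balance_all_strata(
            hh, cols, tol=tol, max_iter=max_iter, k_max=k_elig,
            stop_on_infeasible=True,
        )
        k_elig = max(weights)
        hh = truncate_strata(hh, k_elig)
    elif weight_method == "ipw":
        weights = bal.ipw_all_strata(
            hh, cols, k_max=k_elig, stop_on_separation=True
        )
        k_elig = max(weights)
        hh = truncate_strata(hh, k_elig)
    elif weight_method == "none":
        weights = {
            k: bal.StratumWeights(
                k,
                tuple(hh.table.loc[hh.table["k"] == k, "id"]),
                np.ones(int((hh.table["k"] == k).sum())),
                True,
                0.0,
                0.0,
            )
            for k in range(1, k_elig + 1)
        }
    else:
        raise ValueError(f"unknown weight_method {weight_method!r}")

    if truncation == "smd":
        km = bal.kmax_by_smd(hh, weights, threshold=smd_threshold, covariates=cols)
        weights = {k: v for k, v in weights.items() if k < km}
        if not weights:
            raise FitError("SMD truncation removed every stratum")
    elif truncation not in ("eligibility", "none"):
        raise ValueError(f"unknown truncation {truncation!r}")

    return fit(
        hh,
        ModelSpec(
            risk_interval="gap",
            stratify_by_event_number=True,
            weights=weights,
            variance="robust_cluster",
            label="weighted_pwp",
        ),
    )
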