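"""Per-risk-set covariate balancing for recurrent-event strata.

Conditioning later risk sets on having experienced previous events breaks
the randomization of a trial: baseline covariates that influence the
outcome drift out of balance between arms (collider stratification).  This
module restores balance within each risk set by re-weighting.

The primary scheme is entropy balancing: within each arm of risk set *k*,
find weights minimizing the Kullback–Leibler divergence from uniform
reference weights subject to the arm-wise weighted covariate means both
equalling the pooled risk-set means, with arm sums fixed at the arm sizes.
The KL dual gives exponential-tilting weights ``w_i ∝ exp(λᵀ u_i)`` with
one dual variable per moment constraint, solved by damped Newton
iterations.  A stabilized inverse-probability-of-treatment alternative and
standardized-mean-difference diagnostics are also provided.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .data import EventHistory

__all__ = [
    "BalanceProblem",
    "StratumWeights",
    "InfeasibleBalanceError",
    "BalanceConvergenceError",
    "solve_entropy_balance",
    "entropy_balance_all_strata",
    "stabilized_ipw",
    "ipw_all_strata",
    "smd",
    "stratum_smd_table",
    "eligible_strata",
    "kmax_by_smd",
]


class InfeasibleBalanceError(ValueError):
    """The pooled target moment lies outside an arm's covariate hull."""


class BalanceConvergenceError(RuntimeError):
    """The dual Newton solve did not reach tolerance within max_iter."""


@dataclass(frozen=True)
class BalanceProblem:
    """One stratum's balancing problem.

    ``moments`` holds the chosen moment functions of the covariates
    evaluated on the risk-set members (first moments by default, so it is
    simply the covariate matrix).  The target is the pooled mean of each
    column over both arms.
    """

    stratum: int
    moments: np.ndarray  # (n_members, P)
    treatment: np.ndarray  # (n_members,) in {0,1}
    reference: np.ndarray | None = None  # default uniform 1/N_k

    @property
    def target(self) -> np.ndarray:
        return self.moments.mean(axis=0)

    @property
    def n_members(self) -> int:
        return self.moments.shape[0]


@dataclass
class StratumWeights:
    """Solved weights for one risk set, indexed by subject id order."""

    stratum: int
    subject_ids: tuple
    weights: np.ndarray
    converged: bool
    max_constraint_violation: float
    divergence: float  # KL divergence D1(w ‖ d)
    iterations: int = 0

    def as_series(self) -> pd.Series:
        return pd.Series(self.weights, index=list(self.subject_ids))


def _tilt_solve(
    u: np.ndarray, target: np.ndarray, d: np.ndarray, tol: float, max_iter: int
) -> tuple[np.ndarray, int, float]:
    """Solve min KL(w‖d) s.t. mean_w(u) = target over one arm.

    Returns weights normalized to sum to len(u), the iteration count and
    the final constraint violation.  Uses Newton steps with halving on the
    dual potential  f(λ) = log Σ d_i exp(λᵀ(u_i − target)),  whose gradient
    vanishes exactly at the balanced tilt.
    """
    z = u - target
    lam = np.zeros(z.shape[1])

    def grad_hess(l):
        s = z @ l
        m = s.max()
        w = d * np.exp(s - m)
        w = w / w.sum()
        g = w @ z
        h = (w[:, None] * z).T @ z - np.outer(g, g)
        return g, h

    it = 0
    for it in range(1, max_iter + 1):
        g, h = grad_hess(lam)
        viol = np.abs(g).max()
        if viol < tol:
            break
        try:
            step = np.linalg.solve(h + 1e-12 * np.eye(len(lam)), -g)
        except np.linalg.LinAlgError:
            step = -g
        # backtracking on the dual potential value via gradient norm
        t = 1.0
        f0 = _logsumexp_d(z, d, lam)
        for _ in range(40):
            cand = lam + t * step
            if _logsumexp_d(z, d, cand) < f0 + 1e-12:
                break
            t *= 0.5
        lam = lam + t * step
        if not np.all(np.isfinite(lam)) or np.abs(lam).max() > 1e8:
            raise InfeasibleBalanceError(
                "dual variables diverged; target moment outside covariate hull"
            )
    g, _ = grad_hess(lam)
    viol = float(np.abs(g).max())
    s = z @ lam
    w = d * np.exp(s - s.max())
    w = w / w.sum() * len(u)
    return w, it, viol


def _logsumexp_d(z, d, lam):
    s = z @ lam
    m = s.max()
    return m + np.log(np.sum(d * np.exp(s - m)))


def solve_entropy_balance(
    problem: BalanceProblem, tol: float = 1e-8, max_iter: int = 200
) -> StratumWeights:
    """Entropy-balance both arms of one risk set to the pooled moments.

    Each arm is tilted independently toward the pooled risk-set means; the
    resulting weights sum to the arm sizes, are strictly positive, and have
    the exponential-family form the KL dual prescribes.

    Raises
    ------
    InfeasibleBalanceError
        If a target moment lies outside the convex hull of an arm's
        covariate values (no positive weights can attain it).
    BalanceConvergenceError
        If Newton fails to reach ``tol`` within ``max_iter``.
    """
    u = np.asarray(problem.moments, dtype=float)
    a = np.asarray(problem.treatment)
    n = problem.n_members
    if u.ndim != 2 or len(a) != n:
        raise ValueError("moments must be (n, P) aligned with treatment")
    for arm in (0, 1):
        if (a == arm).sum() < 2:
            raise ValueError(f"arm {arm} has fewer than 2 members in stratum")
    target = problem.target
    d_full = (
        np.full(n, 1.0 / n)
        if problem.reference is None
        else np.asarray(problem.reference, dtype=float)
    )
    if np.any(d_full <= 0):
        raise ValueError("reference weights must be strictly positive")

    # feasibility: the target must lie strictly inside each arm's
    # per-coordinate range (necessary; sufficient for first moments in 1-D)
    for arm in (0, 1):
        ua = u[a == arm]
        lo, hi = ua.min(axis=0), ua.max(axis=0)
        bad = (target < lo - 1e-12) | (target > hi + 1e-12)
        degenerate = (hi - lo < 1e-300) & (np.abs(target - lo) > 1e-12)
        if np.any(bad | degenerate):
            p = int(np.argmax(bad | degenerate))
            raise InfeasibleBalanceError(
                f"stratum {problem.stratum}: pooled mean of covariate {p} "
                f"({target[p]:.6g}) outside arm-{arm} range [{lo[p]:.6g}, {hi[p]:.6g}]"
            )

    w = np.empty(n)
    iters, viols = [], []
    for arm in (0, 1):
        idx = a == arm
        wa, it, viol = _tilt_solve(u[idx], target, d_full[idx], tol, max_iter)
        w[idx] = wa
        iters.append(it)
        viols.append(viol)
    max_viol = float(max(viols))
    converged = max_viol < tol
    if not converged:
        raise BalanceConvergenceError(
            f"stratum {problem.stratum}: constraint violation {max_viol:.3g} "
            f"after {max_iter} iterations"
        )
    d1 = float(np.sum(w * np.log(w / d_full)))
    return StratumWeights(
        stratum=problem.stratum,
        subject_ids=(),
        weights=w,
        converged=converged,
        max_constraint_violation=max_viol,
        divergence=d1,
        iterations=max(iters),
    )


def _stratum_frame(h: EventHistory, k: int) -> pd.DataFrame:
    return h.table[h.table["k"] == k]


def entropy_balance_all_strata(
    h: EventHistory,
    balance_covariates: Sequence[str] | None = None,
    tol: float = 1e-8,
    max_iter: int = 200,
    k_max: int | None = None,
    stop_on_infeasible: bool = False,
) -> dict[int, StratumWeights]:
    """Entropy-balance every stratum of an event history.

    Stratum 1 keeps unit weights (it is the randomized sample); strata
    ``k > 1`` are balanced on ``balance_covariates`` (all covariates by
    default — pass a subset for a partly-weighted analysis).  Strata above
    ``k_max`` (default: all strata passing :func:`eligible_strata`) are
    omitted.  With ``stop_on_infeasible`` an infeasible or non-convergent
    stratum ends the prefix instead of raising: the returned dict covers
    strata 1 .. (first failing stratum − 1).
    """
    cols = list(balance_covariates or h.covariate_columns)
    if not cols:
        raise ValueError("no covariates available to balance")
    if k_max is None:
        k_max = eligible_strata(h)
    groups = dict(iter(h.table.groupby("k", sort=True)))
    out: dict[int, StratumWeights] = {}
    for k in range(1, k_max + 1):
        g = groups[k]
        ids = tuple(g["id"])
        if k == 1:
            # unit weights against uniform reference 1/N: D1 = Σ 1·log(N)
            out[k] = StratumWeights(
                stratum=1,
                subject_ids=ids,
                weights=np.ones(len(g)),
                converged=True,
                max_constraint_violation=0.0,
                divergence=float(len(g) * np.log(len(g))),
                iterations=0,
            )
            continue
        prob = BalanceProblem(
            stratum=k,
            moments=g[cols].to_numpy(dtype=float),
            treatment=g["treatment"].to_numpy(),
        )
        try:
            sw = solve_entropy_balance(prob, tol=tol, max_iter=max_iter)
        except (InfeasibleBalanceError, BalanceConvergenceError) as e:
            if stop_on_infeasible:
                break
            raise type(e)(f"stratum {k}: {e}") from e
        sw.subject_ids = ids
        out[k] = sw
    return out


def stabilized_ipw(
    covariates: np.ndarray | pd.DataFrame, treatment: np.ndarray
) -> np.ndarray:
    """Stabilized inverse-probability-of-treatment weights for one risk set.

    ``sw_i = P(A = a_i) / P(A = a_i | X_i)`` with the numerator the observed
    arm frequency and the denominator from a main-effects logistic
    regression of treatment on the covariates.
    """
    import statsmodels.api as sm

    X = np.asarray(covariates, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    a = np.asarray(treatment)
    if len(np.unique(a)) < 2:
        raise ValueError("both arms must be present in the risk set")
    design = sm.add_constant(X, has_constant="add")
    import warnings

    with np.errstate(all="ignore"), warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = sm.GLM(a, design, family=sm.families.Binomial()).fit(maxiter=100)
    p1 = res.predict(design)
    if np.any(p1 < 1e-10) or np.any(p1 > 1 - 1e-10):
        raise RuntimeError(
            "perfect separation in propensity model; consider truncating strata"
        )
    p_obs = np.where(a == 1, p1, 1 - p1)
    marg = a.mean()
    num = np.where(a == 1, marg, 1 - marg)
    return num / p_obs


def ipw_all_strata(
    h: EventHistory,
    balance_covariates: Sequence[str] | None = None,
    k_max: int | None = None,
    stop_on_separation: bool = False,
) -> dict[int, StratumWeights]:
    """Stabilized IPW per stratum (unit weights in stratum 1)."""
    cols = list(balance_covariates or h.covariate_columns)
    if k_max is None:
        k_max = eligible_strata(h)
    groups = dict(iter(h.table.groupby("k", sort=True)))
    out: dict[int, StratumWeights] = {}
    for k in range(1, k_max + 1):
        g = groups[k]
        ids = tuple(g["id"])
        if k == 1:
            w = np.ones(len(g))
        else:
            try:
                w = stabilized_ipw(
                    g[cols].to_numpy(dtype=float), g["treatment"].to_numpy()
                )
            except RuntimeError:
                if stop_on_separation:
                    break
                raise
        n = len(w)
        d1 = float(np.sum(w * np.log(np.maximum(w, 1e-300) * n)))
        out[k] = StratumWeights(
            stratum=k,
            subject_ids=ids,
            weights=w,
            converged=True,
            max_constraint_violation=np.nan,
            divergence=d1,
        )
    return out


def smd(
    values: np.ndarray, treatment: np.ndarray, weights: np.ndarray | None = None
) -> float:
    """Standardized mean difference of one covariate between arms.

    Weighted arm means divided by the *unweighted* sample standard
    deviation of the whole stratum, so pre- and post-weighting SMDs share
    a scale.
    """
    x = np.asarray(values, dtype=float)
    a = np.asarray(treatment)
    w = np.ones_like(x) if weights is None else np.asarray(weights, dtype=float)
    if not (np.any(a == 1) and np.any(a == 0)):
        raise ValueError("both arms must be present")
    sd = x.std(ddof=1)
    if sd == 0:
        raise ZeroDivisionError("zero pooled standard deviation")
    m1 = np.average(x[a == 1], weights=w[a == 1])
    m0 = np.average(x[a == 0], weights=w[a == 0])
    return float((m1 - m0) / sd)


def stratum_smd_table(
    h: EventHistory,
    weights: dict[int, StratumWeights] | None = None,
    covariates: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Per-stratum SMD of each covariate, optionally after weighting."""
    cols = list(covariates or h.covariate_columns)
    rows = []
    strata = sorted(weights) if weights is not None else range(1, h.max_stratum + 1)
    for k in strata:
        g = _stratum_frame(h, k)
        w = weights[k].weights if weights is not None else None
        for c in cols:
            try:
                v = smd(g[c].to_numpy(), g["treatment"].to_numpy(), w)
            except (ValueError, ZeroDivisionError):
                v = np.nan
            rows.append({"stratum": k, "covariate": c, "smd": v})
    return pd.DataFrame(rows)


def eligible_strata(h: EventHistory) -> int:
    """Largest K' such that strata 1..K' all have ≥2 members in each arm.

    Later strata shrink as fewer subjects accumulate events; balancing (and
    stable estimation generally) needs both arms represented with at least
    two individuals.  Stratum 1 always qualifies.
    """
    counts = pd.crosstab(h.table["k"], h.table["treatment"])
    counts = counts.reindex(columns=[0, 1], fill_value=0)
    k_prime = 1
    for k in range(1, h.max_stratum + 1):
        if k in counts.index and (counts.loc[k] >= 2).all():
            k_prime = k
        else:
            break
    return k_prime


def kmax_by_smd(
    h: EventHistory,
    weights: dict[int, StratumWeights],
    threshold: float = 0.1,
    covariates: Sequence[str] | None = None,
) -> int:
    """First stratum whose post-weighting balance fails ``|SMD| < threshold``.

    The analysis retains strata ``1 .. k_max − 1``.  If every weighted
    stratum is balanced, returns ``max(weights) + 1`` (retain everything).
    Stratum 1 is never the cut point: it keeps the randomized sample with
    unit weights, so only strata whose membership conditions on event
    history are screened.
    """
    cols = list(covariates or h.covariate_columns)
    for k in sorted(weights):
        if k == 1:
            continue
        g = _stratum_frame(h, k)
        for c in cols:
            try:
                v = smd(g[c].to_numpy(), g["treatment"].to_numpy(), weights[k].weights)
            except (ValueError, ZeroDivisionError):
                return k
            if abs(v) >= threshold:
                return k
    return max(weights) + 1
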