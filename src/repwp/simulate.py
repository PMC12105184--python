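"""Weibull gap-time simulator for randomized recurrent-event trials.

Each subject's successive gap times are drawn from Weibull distributions
whose scale depends on the event number, the treatment arm and baseline
covariates:

    S_k(t) = exp(−λ_k t^{q_k}),   λ_k = exp(−q_k (β0_k + A β + Xᵀγ)),

so the within-stratum hazard ratio for treatment is HR = e^{−q_k β} and
for each covariate HR_cov = e^{−q_k γ_p}.  Event-number-dependent β0_k
makes the baseline hazard rise with the number of prior events — the
regime in which conditioning later risk sets on event history induces
collider bias.  Subjects are censored administratively at the end of
follow-up; gap time k is generated only for subjects whose event k − 1
was observed.  Times are in days with a two-year (730-day) default
follow-up.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data import EventHistory

__all__ = [
    "ScenarioConfig",
    "SimulatedTrial",
    "coef_from_hr",
    "simulate_subject",
    "simulate_trial",
    "make_scenario",
    "SCENARIOS",
]

# shared shape/baseline settings of the four study scenarios
_Q = (1.5, 1.5, 1.5, 1.5, 1.5)
_B0 = (6.0, 5.5, 5.0, 4.0, 3.0)
SCENARIOS = {
    1: {"hr_treatment": 0.75, "hr_covariate": 0.9},
    2: {"hr_treatment": 0.75, "hr_covariate": 1.2},
    3: {"hr_treatment": 1.0, "hr_covariate": 0.9},
    4: {"hr_treatment": 1.0, "hr_covariate": 1.2},
}


@dataclass(frozen=True)
class ScenarioConfig:
    """Full parameterization of one simulated trial.

    ``q`` and ``beta0`` are per-event-number vectors; event numbers beyond
    their length reuse the last entry (constant baseline hazard for late
    events).  ``hr_treatment``/``hr_covariate`` are within-stratum hazard
    ratios; the corresponding log-scale coefficients follow from
    :func:`coef_from_hr` stratum by stratum.
    """

    q: tuple = _Q
    beta0: tuple = _B0
    hr_treatment: float = 0.75
    hr_covariate: float = 0.9
    n_covariates: int = 5
    n: int = 300
    follow_up: float = 730.0
    n_sim: int = 1000
    seed: int = 0
    scenario_id: int | None = None
    keep_censored_gap: bool = True

    def __post_init__(self):
        if len(self.q) != len(self.beta0):
            raise ValueError("q and beta0 must have equal length")
        if any(v <= 0 for v in self.q) or self.hr_treatment <= 0 or self.hr_covariate <= 0:
            raise ValueError("q and hazard ratios must be positive")

    def q_at(self, k: int) -> float:
        return self.q[min(k, len(self.q)) - 1]

    def beta0_at(self, k: int) -> float:
        return self.beta0[min(k, len(self.beta0)) - 1]


@dataclass
class SimulatedTrial:
    history: EventHistory
    treatment_coef: float  # β such that HR = e^{−qβ} within each stratum
    covariate_coefs: np.ndarray
    scenario_id: int | None = None


def coef_from_hr(hr: float, q: float) -> float:
    """Coefficient on the Weibull log-scale: β = −log(hr)/q."""
    if hr <= 0 or q <= 0:
        raise ValueError("hr and q must be positive")
    return -np.log(hr) / q


def _gap_time(u, q, lam):
    # inverse-transform: S(t) = exp(−λ t^q) = u  ⇒  t = (−log u / λ)^{1/q}
    return (-np.log(u) / lam) ** (1.0 / q)


def simulate_subject(
    config: ScenarioConfig,
    arm: int,
    covariates: np.ndarray,
    rng: np.random.Generator,
) -> list[tuple]:
    """Sequential gap times for one subject.

    Returns rows ``(k, start, stop, status)`` on the gap scale; the gap
    crossing the follow-up horizon is recorded censored and truncated at
    the remaining time.
    """
    rows = []
    elapsed = 0.0
    k = 1
    while elapsed < config.follow_up:
        q = config.q_at(k)
        b = coef_from_hr(config.hr_treatment, q)
        g = coef_from_hr(config.hr_covariate, q)
        lam = np.exp(-q * (config.beta0_at(k) + arm * b + covariates.sum() * g))
        t = _gap_time(rng.uniform(), q, lam)
        remaining = config.follow_up - elapsed
        if t >= remaining:
            if config.keep_censored_gap:
                rows.append((k, 0.0, remaining, 0))
            break
        rows.append((k, 0.0, t, 1))
        elapsed += t
        k += 1
    return rows


def simulate_trial(config: ScenarioConfig) -> SimulatedTrial:
    """Simulate one randomized trial; returns a gap-scale EventHistory.

    Treatment is Bernoulli(0.5); covariates are iid standard normal.  All
    subjects in a stratum are advanced together (vectorized), so the
    output is deterministic given ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    n, P = config.n, config.n_covariates
    arm = rng.binomial(1, 0.5, size=n)
    X = rng.standard_normal((n, P))

    ids = np.arange(n)
    remaining = np.full(n, config.follow_up)
    active = np.ones(n, dtype=bool)
    xsum = X.sum(axis=1)

    frames = []
    k = 1
    while active.any():
        idx = np.flatnonzero(active)
        q = config.q_at(k)
        b = coef_from_hr(config.hr_treatment, q)
        g = coef_from_hr(config.hr_covariate, q)
        lam = np.exp(-q * (config.beta0_at(k) + arm[idx] * b + xsum[idx] * g))
        t = _gap_time(rng.uniform(size=len(idx)), q, lam)
        censored = t >= remaining[idx]
        stop = np.where(censored, remaining[idx], t)
        keep = ~censored | config.keep_censored_gap
        frames.append(
            pd.DataFrame(
                {
                    "id": ids[idx][keep],
                    "k": k,
                    "start": 0.0,
                    "stop": stop[keep],
                    "status": (~censored[keep]).astype(int),
                }
            )
        )
        remaining[idx] -= t
        active[idx[censored]] = False
        active &= remaining > 0
        k += 1

    df = pd.concat(frames, ignore_index=True)
    subj = pd.DataFrame(
        {"id": ids, "treatment": arm, **{f"x{j+1}": X[:, j] for j in range(P)}}
    )
    df = df.merge(subj, on="id").sort_values(["id", "k"]).reset_index(drop=True)
    history = EventHistory(df, time_scale="gap", validate=False)
    return SimulatedTrial(
        history=history,
        treatment_coef=float(-np.log(config.hr_treatment)),  # log-HR truth
        covariate_coefs=np.full(P, coef_from_hr(config.hr_covariate, config.q_at(1))),
        scenario_id=config.scenario_id,
    )


def make_scenario(
    scenario_id: int, n: int = 300, n_sim: int = 1000, seed: int = 0, **overrides
) -> ScenarioConfig:
    """Standard study scenarios: 1 (HR .75, HRcov .9), 2 (.75, 1.2),
    3 (null, .9), 4 (null, 1.2)."""
    if scenario_id not in SCENARIOS:
        raise ValueError(f"unknown scenario {scenario_id}; choose 1-4")
    kw = dict(SCENARIOS[scenario_id])
    kw.update(overrides)
    return ScenarioConfig(
        n=n, n_sim=n_sim, seed=seed, scenario_id=scenario_id, **kw
    )
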