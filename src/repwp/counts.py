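"""Rate-based comparators: Poisson and negative-binomial count regression.

Both collapse the event history to one record per subject — total events
and total follow-up — and model the event rate with a log link and
``log(exposure)`` offset.  The negative binomial is the NB2 form
(variance μ + μ²/θ, gamma-distributed multiplicative heterogeneity) with
the dispersion estimated by maximum likelihood.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from statsmodels.discrete.discrete_model import NegativeBinomial

from .cox import FitResult
from .data import EventHistory

__all__ = ["aggregate_counts", "fit_poisson", "fit_negbin"]


def aggregate_counts(h: EventHistory) -> pd.DataFrame:
    """One row per subject: event_count, exposure, treatment, covariates.

    Exposure is total observed time (calendar follow-up from randomization;
    identical to the sum of gap durations when there are no risk-free
    intervals).
    """
    out = h.subject_table().rename(
        columns={"n_events": "event_count", "follow_up": "exposure"}
    )
    if (out["exposure"] <= 0).any():
        raise ValueError("non-positive exposure for some subject")
    return out


def _glm_result(label, res, terms) -> FitResult:
    params = np.asarray(res.params)
    bse = np.asarray(res.bse)
    return FitResult(
        model_label=label,
        coef=float(params[1]),  # treatment follows the intercept
        naive_se=float(bse[1]),
        robust_se=None,
        variance_used="naive",
        n_events_used=int(res.model.endog.sum()),
        strata_used=[],
        converged=bool(getattr(res, "converged", True)),
        iterations=int(getattr(res, "fit_history", {}).get("iteration", 0) or 0),
        coef_all=params,
        term_names=terms,
    )


def _count_design(counts: pd.DataFrame, adjust: Sequence[str] | None):
    terms = ["treatment"] + list(adjust or [])
    X = sm.add_constant(counts[terms].to_numpy(dtype=float), has_constant="add")
    y = counts["event_count"].to_numpy(dtype=float)
    for arm in (0, 1):
        if (counts["treatment"] == arm).sum() == 0:
            raise ValueError(f"arm {arm} absent from the count data")
    return y, X, counts["exposure"].to_numpy(dtype=float), ["const"] + terms


def fit_poisson(counts: pd.DataFrame, adjust: Sequence[str] | None = None) -> FitResult:
    """Poisson rate regression; treatment effect as a rate ratio."""
    y, X, T, terms = _count_design(counts, adjust)
    res = sm.GLM(y, X, family=sm.families.Poisson(), offset=np.log(T)).fit()
    return _glm_result("poisson", res, terms)


def fit_negbin(counts: pd.DataFrame, adjust: Sequence[str] | None = None) -> FitResult:
    """NB2 negative-binomial rate regression with ML dispersion."""
    y, X, T, terms = _count_design(counts, adjust)
    model = NegativeBinomial(y, X, exposure=T, loglike_method="nb2")
    res = model.fit(disp=False, maxiter=200)
    out = _glm_result("negbin", res, terms + ["alpha"])
    out.converged = bool(res.mle_retvals.get("converged", True))
    return out
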