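"""Event-history data model for recurrent events in randomized trials.

The canonical representation is a long-format counting-process table with
one row per (subject, event number): each row carries a half-open at-risk
interval ``(start, stop]``, an event/censoring status, a binary treatment
arm and baseline covariates.  Two time scales are supported:

* ``counting_process`` — calendar time from randomization; row *k* starts
  where row *k − 1* stopped.
* ``gap`` — the clock restarts at zero after each event, so every row is
  ``(0, gap]`` where the gap is the duration since the previous event.

Both scales carry the same information and :func:`to_gap_time` /
:func:`to_counting_process` convert losslessly between them.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "EventHistory",
    "RiskSet",
    "SchemaError",
    "ConsistencyError",
    "read_long_table",
    "to_gap_time",
    "to_counting_process",
    "build_risk_set",
    "first_event_subset",
    "load_bladder_fixture",
    "CANONICAL_COLUMNS",
]

CANONICAL_COLUMNS = ("id", "k", "start", "stop", "status", "treatment")


class SchemaError(ValueError):
    """The input table is missing required columns or has bad types."""


class ConsistencyError(ValueError):
    """The table violates an event-history invariant."""


@dataclass(frozen=True)
class RiskSet:
    """Subjects eligible for the *k*-th event.

    Stratum 1 is the full randomized sample; stratum ``k > 1`` contains
    exactly the subjects whose (k − 1)-th event was observed.
    """

    stratum: int
    member_ids: tuple
    n_treated: int
    n_control: int

    @property
    def size(self) -> int:
        return self.n_treated + self.n_control


@dataclass
class EventHistory:
    """Long-format recurrent-event history.

    Parameters
    ----------
    table:
        DataFrame with columns ``id, k, start, stop, status, treatment``
        followed by zero or more covariate columns.  Covariates and
        treatment must be constant within subject.
    time_scale:
        ``"counting_process"`` or ``"gap"``.
    """

    table: pd.DataFrame
    time_scale: str = "counting_process"
    validate: bool = field(default=True, repr=False)

    def __post_init__(self) -> None:
        if self.time_scale not in ("gap", "counting_process"):
            raise ValueError(f"unknown time scale {self.time_scale!r}")
        self.table = self.table.reset_index(drop=True)
        if self.validate:
            _validate(self.table, self.time_scale)

    # -- basic descriptors -------------------------------------------------
    @property
    def n_subjects(self) -> int:
        return self.table["id"].nunique()

    @property
    def max_stratum(self) -> int:
        return int(self.table["k"].max())

    @property
    def covariate_columns(self) -> list[str]:
        return [c for c in self.table.columns if c not in CANONICAL_COLUMNS]

    @property
    def n_events(self) -> int:
        return int(self.table["status"].sum())

    def subject_table(self) -> pd.DataFrame:
        """One row per subject: treatment, covariates, totals."""
        g = self.table.groupby("id", sort=True)
        out = g[["treatment", *self.covariate_columns]].first()
        out["n_events"] = g["status"].sum().astype(int)
        if self.time_scale == "gap":
            out["follow_up"] = g["stop"].sum() - g["start"].sum()
        else:
            out["follow_up"] = g["stop"].max()
        return out.reset_index()

    def copy(self) -> "EventHistory":
        return EventHistory(self.table.copy(), self.time_scale, validate=False)


def _validate(df: pd.DataFrame, time_scale: str) -> None:
    missing = [c for c in CANONICAL_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"missing required columns: {missing}")
    for col in ("k", "start", "stop", "status", "treatment"):
        if not np.issubdtype(np.asarray(df[col]).dtype, np.number):
            raise SchemaError(f"column {col!r} must be numeric")
    if not set(np.unique(df["status"])) <= {0, 1}:
        raise SchemaError("status must be binary 0/1")
    if not set(np.unique(df["treatment"])) <= {0, 1}:
        raise SchemaError("treatment must be binary 0/1")
    if (df["start"] < 0).any():
        raise ConsistencyError("negative start time")
    if (df["stop"] <= df["start"]).any():
        bad = df.index[df["stop"] <= df["start"]].tolist()
        raise ConsistencyError(f"zero-length or inverted interval at rows {bad}")

    for sid, g in df.groupby("id", sort=False):
        g = g.sort_values("k")
        ks = g["k"].to_numpy()
        if not np.array_equal(ks, np.arange(1, len(ks) + 1)):
            raise ConsistencyError(f"subject {sid!r}: event numbers not 1..m")
        # row k>1 requires the previous event to have been observed
        if len(g) > 1 and not np.all(g["status"].to_numpy()[:-1] == 1):
            raise ConsistencyError(
                f"subject {sid!r}: record after a censored interval"
            )
        const_cols = ["treatment"] + [
            c for c in df.columns if c not in CANONICAL_COLUMNS
        ]
        for c in const_cols:
            if g[c].nunique() > 1:
                raise ConsistencyError(f"subject {sid!r}: {c!r} not constant")
        if time_scale == "gap":
            if (g["start"] != 0).any():
                raise ConsistencyError(f"subject {sid!r}: gap rows must start at 0")
        else:
            starts = g["start"].to_numpy()
            stops = g["stop"].to_numpy()
            expected = np.concatenate([[0.0], stops[:-1]])
            if not np.allclose(starts, expected):
                raise ConsistencyError(
                    f"subject {sid!r}: counting-process intervals not contiguous"
                )


def read_long_table(
    path,
    column_map: Mapping[str, str] | None = None,
    time_scale: str = "counting_process",
    covariates: Sequence[str] | None = None,
) -> EventHistory:
    """Read a delimited long-format event table.

    Parameters
    ----------
    path:
        CSV file with header ``id,k,start,stop,status,treatment,x1..xP``
        (or any names remapped through ``column_map``).
    column_map:
        Mapping from file column names to canonical names, e.g.
        ``{"enum": "k", "rx": "treatment"}``.
    covariates:
        Optional subset of non-canonical columns to keep; default keeps all.
    """
    df = pd.read_csv(path)
    if column_map:
        df = df.rename(columns=dict(column_map))
    absent = [c for c in CANONICAL_COLUMNS if c not in df.columns]
    if absent:
        raise SchemaError(f"missing required columns: {absent}")
    extra = [c for c in df.columns if c not in CANONICAL_COLUMNS]
    if covariates is not None:
        missing = [c for c in covariates if c not in extra]
        if missing:
            raise SchemaError(f"covariate columns not found: {missing}")
        extra = list(covariates)
    df = df[[*CANONICAL_COLUMNS, *extra]]
    return EventHistory(df, time_scale=time_scale)


def to_gap_time(h: EventHistory) -> EventHistory:
    """Re-express intervals on the gap scale: each row becomes ``(0, stop−start]``."""
    if h.time_scale == "gap":
        return h.copy()
    df = h.table.copy()
    df["stop"] = df["stop"] - df["start"]
    df["start"] = 0.0
    return EventHistory(df, time_scale="gap", validate=False)


def to_counting_process(h: EventHistory) -> EventHistory:
    """Re-express gap rows on the calendar scale by accumulating durations."""
    if h.time_scale == "counting_process":
        return h.copy()
    df = h.table.sort_values(["id", "k"]).reset_index(drop=True)
    dur = (df["stop"] - df["start"]).to_numpy()
    cum = df.assign(_d=dur).groupby("id", sort=False)["_d"].cumsum().to_numpy()
    df["stop"] = cum
    df["start"] = cum - dur
    return EventHistory(df, time_scale="counting_process", validate=False)


def build_risk_set(h: EventHistory, k: int) -> RiskSet:
    """Subjects at risk for the *k*-th event (those with k − 1 observed events)."""
    if not 1 <= k <= h.max_stratum:
        raise ValueError(f"stratum {k} out of range 1..{h.max_stratum}")
    rows = h.table[h.table["k"] == k]
    ids = tuple(rows["id"])
    n_t = int((rows["treatment"] == 1).sum())
    n_c = int((rows["treatment"] == 0).sum())
    return RiskSet(stratum=k, member_ids=ids, n_treated=n_t, n_control=n_c)


def first_event_subset(h: EventHistory) -> EventHistory:
    """Restrict to each subject's first at-risk interval (time to first event)."""
    df = h.table[h.table["k"] == 1].reset_index(drop=True)
    return EventHistory(df, time_scale=h.time_scale, validate=False)


def truncate_strata(h: EventHistory, k_keep: int) -> EventHistory:
    """Drop all records with event number above ``k_keep``."""
    df = h.table[h.table["k"] <= k_keep].reset_index(drop=True)
    return EventHistory(df, h.time_scale, validate=False)


def load_bladder_fixture() -> EventHistory:
    """The VA bladder-tumor recurrence trial (thiotepa vs placebo).

    85 patients (38 thiotepa, 47 placebo) followed up to 64 months after
    excision of superficial bladder tumors; 132 recurrences in total.
    Baseline covariates: ``number`` (initial tumor count) and ``size``
    (diameter of the largest initial tumor, cm).  Counting-process scale.

    The table is derived from the public dataset distributed with the R
    ``survival`` package (``bladder1``), restricted to the placebo and
    thiotepa arms, with the one zero-follow-up subject removed; deaths are
    treated as censoring for recurrence.
    """
    ref = importlib.resources.files("repwp") / "data" / "bladder.csv"
    if not ref.is_file():  # pragma: no cover
        raise FileNotFoundError("bladder fixture missing from package data")
    with importlib.resources.as_file(ref) as p:
        return read_long_table(p, time_scale="counting_process")
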