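"""Cohort containers, delimited-text I/O, summaries, and derived clinical scores.

A :class:`Cohort` is one row per subject of a time-to-event study: a unique
subject id, the right-censored follow-up time (years), the event indicator
(1 = relapse/death observed, 0 = censored), and any number of covariate
columns.  Covariates may contain missing values — in a two-phase study the
"expensive" marker is only measured on the phase-two subsample.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter

__all__ = [
    "Cohort",
    "CohortSummary",
    "CohortValidationError",
    "SchemaError",
    "read_cohort",
    "write_cohort",
    "summarize_cohort",
    "compute_npi",
    "reverse_km_median",
]

#: canonical column names used internally
ID_COL, TIME_COL, EVENT_COL = "id", "time", "event"
_RESERVED = (ID_COL, TIME_COL, EVENT_COL)

_UNIT_TO_YEARS = {"years": 1.0, "months": 1.0 / 12.0, "days": 1.0 / 365.25}


class CohortValidationError(ValueError):
    """Raised when a cohort table violates its invariants."""


class SchemaError(KeyError):
    """Raised when a required column is absent from an input file."""


@dataclass(frozen=True)
class CohortSummary:
    """Descriptive summary of a cohort.

    ``median_followup`` is the reverse Kaplan-Meier estimate: the median of
    the Kaplan-Meier curve fitted to the *censoring* indicator, the standard
    way to quantify follow-up in the presence of events.
    """

    n: int
    n_event: int
    event_fraction: float
    median_followup: float


@dataclass
class Cohort:
    """Validated one-row-per-subject follow-up table.

    Parameters
    ----------
    df : pandas.DataFrame
        Must contain columns ``id``, ``time``, ``event``; every other column
        is treated as a covariate.  Validated (and re-indexed) on
        construction.
    """

    df: pd.DataFrame
    name: str = ""
    truth: dict = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        df = self.df
        for col in _RESERVED:
            if col not in df.columns:
                raise SchemaError(f"cohort table lacks required column {col!r}")
        df = df.reset_index(drop=True).copy()
        df[ID_COL] = df[ID_COL].astype(str)
        if df[ID_COL].duplicated().any():
            dups = df.loc[df[ID_COL].duplicated(), ID_COL].unique()[:5]
            raise CohortValidationError(f"duplicate subject ids: {list(dups)}")
        time = pd.to_numeric(df[TIME_COL], errors="coerce").to_numpy(float)
        bad = ~np.isfinite(time) | (time <= 0)
        if bad.any():
            rows = np.flatnonzero(bad)[:5] + 1
            raise CohortValidationError(
                f"non-positive or non-finite follow-up time in row(s) {list(rows)}"
            )
        df[TIME_COL] = time
        ev = pd.to_numeric(df[EVENT_COL], errors="coerce").to_numpy(float)
        if not np.isin(ev[np.isfinite(ev)], (0.0, 1.0)).all() or not np.isfinite(ev).all():
            raise CohortValidationError("event indicator must be 0 or 1 for every subject")
        df[EVENT_COL] = ev.astype(int)
        object.__setattr__(self, "df", df)

    # -- convenience accessors -------------------------------------------------
    @property
    def n(self) -> int:
        return len(self.df)

    @property
    def n_event(self) -> int:
        return int(self.df[EVENT_COL].sum())

    @property
    def ids(self) -> np.ndarray:
        return self.df[ID_COL].to_numpy()

    @property
    def time(self) -> np.ndarray:
        return self.df[TIME_COL].to_numpy(float)

    @property
    def event(self) -> np.ndarray:
        return self.df[EVENT_COL].to_numpy(int)

    @property
    def covariate_columns(self) -> list[str]:
        return [c for c in self.df.columns if c not in _RESERVED]

    def require_covariates(self, names: list[str]) -> None:
        missing = [c for c in names if c not in self.df.columns]
        if missing:
            raise SchemaError(f"model covariates not present in cohort: {missing}")

    def __len__(self) -> int:  # pragma: no cover - trivial
        return self.n


def read_cohort(
    path,
    schema: dict | None = None,
    *,
    delimiter: str | None = None,
    time_unit: str = "years",
    name: str = "",
) -> Cohort:
    """Read a delimited-text cohort file (header row required).

    Parameters
    ----------
    schema : mapping, optional
        Maps canonical names (``id``, ``time``, ``event``) to the column
        names used in the file, e.g. ``{"time": "rfs_years"}``.
    delimiter : str, optional
        Field separator; auto-detected between comma and tab when omitted.
    time_unit : {"years", "months", "days"}
        Unit of the time column in the *file*; converted to years internally.
    """
    if time_unit not in _UNIT_TO_YEARS:
        raise ValueError(f"unknown time unit {time_unit!r}")
    if delimiter is None:
        with open(path, "rt") as fh:
            header = fh.readline()
        delimiter = "\t" if header.count("\t") >= header.count(",") and "\t" in header else ","
    df = pd.read_csv(path, sep=delimiter)
    schema = schema or {}
    rename = {v: k for k, v in schema.items() if k in _RESERVED}
    for canonical, source in ((k, schema.get(k, k)) for k in _RESERVED):
        if source not in df.columns:
            raise SchemaError(
                f"column {source!r} (mapped to {canonical!r}) not found in {path}"
            )
    df = df.rename(columns=rename)
    df[TIME_COL] = pd.to_numeric(df[TIME_COL]) * _UNIT_TO_YEARS[time_unit]
    return Cohort(df, name=name or str(path))


def write_cohort(cohort: Cohort, path, *, delimiter: str = ",") -> None:
    """Write a cohort back to delimited text (times in years)."""
    cohort.df.to_csv(path, sep=delimiter, index=False)


def reverse_km_median(time: np.ndarray, event: np.ndarray) -> float:
    """Median follow-up by the reverse Kaplan-Meier method.

    Fits Kaplan-Meier to the censoring indicator ``1 - event`` (events censor
    the observation of follow-up) and returns the median of that curve.  When
    the curve hits 0.5 exactly at a drop time the median is the midpoint of
    that time and the next drop time, matching the convention of R's
    ``survfit``.
    """
    kmf = KaplanMeierFitter()
    kmf.fit(time, 1 - np.asarray(event, int))
    sf = kmf.survival_function_.iloc[:, 0]
    drops = sf[sf.diff().fillna(0) < 0]
    below = drops[drops <= 0.5 + 1e-12]
    if below.empty:
        return float("nan")
    t_med = float(below.index[0])
    if abs(below.iloc[0] - 0.5) <= 1e-12 and len(drops.loc[drops.index > t_med]):
        t_next = float(drops.index[drops.index > t_med][0])
        return 0.5 * (t_med + t_next)
    return t_med


def summarize_cohort(cohort: Cohort) -> CohortSummary:
    """Subject/event counts, event fraction, reverse-KM median follow-up."""
    n, n_event = cohort.n, cohort.n_event
    return CohortSummary(
        n=n,
        n_event=n_event,
        event_fraction=n_event / n,
        median_followup=reverse_km_median(cohort.time, cohort.event),
    )


def _node_stage(positive_nodes):
    nodes = np.asarray(positive_nodes)
    if (nodes < 0).any():
        raise ValueError("positive node count must be >= 0")
    return np.where(nodes == 0, 1, np.where(nodes <= 3, 2, 3))


def compute_npi(tumor_size_mm, positive_nodes, grade):
    """Nottingham Prognostic Index: ``0.02 * size(mm) + node stage + grade``.

    Node stage is 1 for node-negative disease, 2 for one to three positive
    nodes and 3 for four or more.  Grade must be 1, 2 or 3.  Accepts scalars
    or arrays; returns the same shape.
    """
    size = np.asarray(tumor_size_mm, float)
    grade_arr = np.asarray(grade)
    if (size < 0).any():
        raise ValueError("tumor size must be >= 0 mm")
    if not np.isin(grade_arr, (1, 2, 3)).all():
        raise ValueError("tumor grade must be 1, 2 or 3")
    npi = 0.02 * size + _node_stage(positive_nodes) + grade_arr
    return float(npi) if np.ndim(npi) == 0 else npi


def cohort_hash(cohort: Cohort) -> str:
    """Short content hash of a cohort table, for provenance metadata.

    Hashes ids, times, events and the covariate column names; cached on the
    cohort instance so repeated draws in resampling loops pay it once.
    """
    import hashlib

    cached = getattr(cohort, "_hash", None)
    if cached is not None:
        return cached
    h = hashlib.sha1()
    h.update("|".join(cohort.df.columns).encode())
    h.update("|".join(cohort.ids).encode())
    h.update(np.ascontiguousarray(cohort.time).tobytes())
    h.update(np.ascontiguousarray(cohort.event).tobytes())
    digest = h.hexdigest()[:12]
    object.__setattr__(cohort, "_hash", digest)
    return digest
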