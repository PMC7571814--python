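"""Outcome-dependent sampling designs for two-phase cohort studies.

Implements six ways of choosing the phase-two subsample on which an
expensive marker is measured, together with the inclusion-probability
weights each design requires for unbiased hazard-ratio estimation:

* ``srs``      — simple random sampling, ignoring event status;
* ``ncc``      — nested case-control with incidence-density sampling:
                 every case, plus ``m`` controls drawn from its risk set;
* ``modncc``   — NCC where only a random portion of cases (probability
                 ``P``, or a fixed count) is included, for cohorts where
                 events are too numerous to sample fully;
* ``cc``       — case-cohort: a random subcohort extended by all cases;
* ``modcc``    — case-cohort with the out-of-subcohort cases thinned
                 (fraction ``r``);
* ``egs``      — extreme-group sampling: only subjects with an event before
                 ``t1`` (cases) and subjects still event-free at ``t2 >= t1``
                 (control pool) are eligible; everyone else is excluded.

NCC-type samples are analysed by a weighted Cox regression that re-uses
controls at all event times where they are at risk; the weights are inverse
marginal inclusion probabilities of the Kaplan-Meier type
(:func:`km_type_weights`).  Case-cohort samples use time-fixed inverse
sampling-probability weights (:func:`ipw_weights`).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .cohort_model import Cohort, ID_COL, TIME_COL, EVENT_COL, cohort_hash

__all__ = [
    "DesignSpec",
    "SampledCohort",
    "DesignError",
    "EmptyStratumError",
    "WeightError",
    "risk_set",
    "draw_srs",
    "draw_ncc",
    "draw_modncc",
    "draw_cc",
    "draw_modcc",
    "draw_egs",
    "draw_design",
    "calibrate_egs_t1",
    "km_type_weights",
    "ipw_weights",
]

logger = logging.getLogger(__name__)

DESIGN_NAMES = ("full", "srs", "ncc", "modncc", "cc", "modcc", "egs")

ROLE_CASE = "case"
ROLE_CONTROL = "control"
ROLE_SUBCOHORT = "subcohort"
ROLE_EGS_CASE = "egs_case"
ROLE_EGS_CONTROL = "egs_control"


class DesignError(ValueError):
    """Invalid design parameters or an unsatisfiable sampling request."""


class EmptyStratumError(DesignError):
    """An EGS stratum (cases or eligible controls) is empty."""


class WeightError(ValueError):
    """An inclusion probability is undefined (degenerate risk set)."""


@dataclass(frozen=True)
class DesignSpec:
    """A named sampling design plus the parameters relevant to it.

    Only the fields relevant to ``name`` may be set; ``validate`` (called on
    construction) rejects anything else.  Probabilities live in (0, 1];
    ``t2 >= t1 > 0`` for extreme-group sampling.
    """

    name: str
    m: int = 1                                # controls per case (ncc-type, egs)
    case_probability: float | None = None     # P, modncc
    case_count: int | None = None             # fixed-count alternative to P
    subcohort_fraction: float | None = None   # q, cc/modcc
    subcohort_size: int | None = None
    extra_case_fraction: float | None = None  # r, modcc
    extra_case_count: int | None = None
    t1: float | None = None                   # egs early-event boundary (years)
    t2: float | None = None                   # egs event-free boundary (years)
    target_n: int | None = None               # srs sample size / egs calibration
    seed: int | None = None

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.name not in DESIGN_NAMES:
            raise DesignError(f"unknown design {self.name!r}; expected one of {DESIGN_NAMES}")
        if self.m < 1:
            raise DesignError("m (controls per case) must be >= 1")
        for label, p in (
            ("case_probability", self.case_probability),
            ("subcohort_fraction", self.subcohort_fraction),
            ("extra_case_fraction", self.extra_case_fraction),
        ):
            if p is not None and not (0 < p <= 1) and not (label == "extra_case_fraction" and p == 0):
                raise DesignError(f"{label} must lie in (0, 1], got {p}")
        relevant = {
            "full": set(),
            "srs": {"target_n"},
            "ncc": {"m"},
            "modncc": {"m", "case_probability", "case_count"},
            "cc": {"subcohort_fraction", "subcohort_size"},
            "modcc": {"subcohort_fraction", "subcohort_size",
                      "extra_case_fraction", "extra_case_count"},
            "egs": {"m", "t1", "t2", "target_n"},
        }[self.name]
        always = {"name", "seed", "m"}
        for key, value in asdict(self).items():
            if key in always or key in relevant:
                continue
            default = type(self).__dataclass_fields__[key].default
            if value != default:
                raise DesignError(f"parameter {key!r} is not used by design {self.name!r}")
        if self.name == "egs":
            if self.t1 is None or self.t2 is None:
                raise DesignError("egs requires t1 and t2")
            if not (0 < self.t1 <= self.t2):
                raise DesignError("egs requires 0 < t1 <= t2")
        if self.name == "modncc" and self.case_probability is None and self.case_count is None:
            raise DesignError("modncc requires case_probability or case_count")
        if self.name in ("cc", "modcc") and self.subcohort_fraction is None and self.subcohort_size is None:
            raise DesignError(f"{self.name} requires subcohort_fraction or subcohort_size")
        if self.name == "modcc" and self.extra_case_fraction is None and self.extra_case_count is None:
            raise DesignError("modcc requires extra_case_fraction or extra_case_count")

    def to_json(self) -> str:
        return json.dumps(asdict(self), sort_keys=True)


@dataclass
class SampledCohort:
    """The phase-two subset: rows, per-subject roles and analysis weights.

    Each subject appears at most once, with ``weight = 1 / pi`` where ``pi``
    is its overall inclusion probability under the design; ``weight >= 1``.
    ``meta`` records the seed, the cohort content hash and design-derived
    quantities (effective P/q/r, the EGS control fraction ``rho``).
    """

    df: pd.DataFrame
    design: DesignSpec
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        df = self.df.reset_index(drop=True)
        if df[ID_COL].duplicated().any():
            raise DesignError("a subject appears more than once in the sample")
        if len(df) and (df["weight"] < 1 - 1e-9).any():
            raise WeightError("analysis weights must be >= 1 (inclusion probability <= 1)")
        self.df = df

    @property
    def n_sample(self) -> int:
        return len(self.df)

    @property
    def n_event(self) -> int:
        return int(self.df[EVENT_COL].sum()) if len(self.df) else 0

    def roles(self) -> pd.Series:
        return self.df["role"]

    def write(self, path, *, delimiter: str = ",") -> None:
        """Serialize rows to delimited text plus a JSON sidecar with the design."""
        self.df.to_csv(path, sep=delimiter, index=False)
        sidecar = {"design": asdict(self.design), "meta": self.meta}
        with open(str(path) + ".json", "wt") as fh:
            json.dump(sidecar, fh, indent=1, default=float)


def _as_rng(rng) -> np.random.Generator:
    if isinstance(rng, np.random.Generator):
        return rng
    return np.random.default_rng(rng)


def _take(cohort: Cohort, idx: np.ndarray, roles: np.ndarray, weights: np.ndarray,
          design: DesignSpec, meta: dict) -> SampledCohort:
    df = cohort.df.iloc[idx].copy()
    df["role"] = roles
    df["weight"] = weights
    meta = {"cohort_hash": cohort_hash(cohort), **meta}
    return SampledCohort(df=df, design=design, meta=meta)


# ---------------------------------------------------------------------------
# simple random sampling
# ---------------------------------------------------------------------------

def draw_srs(cohort: Cohort, n: int, rng) -> SampledCohort:
    """Uniform sample of ``n`` distinct subjects, event status ignored.

    All weights are 1: every subject has inclusion probability n/N and the
    constant cancels from the partial likelihood, so the sample is analysed
    by a standard (unweighted) Cox regression.
    """
    rng = _as_rng(rng)
    if not 1 <= n <= cohort.n:
        raise DesignError(f"srs sample size must satisfy 1 <= n <= N={cohort.n}, got {n}")
    idx = rng.choice(cohort.n, size=n, replace=False)
    idx.sort()
    design = DesignSpec(name="srs", target_n=n)
    roles = np.where(cohort.event[idx] == 1, ROLE_CASE, ROLE_CONTROL)
    return _take(cohort, idx, roles, np.ones(n), design, {"n": n})


# ---------------------------------------------------------------------------
# nested case-control
# ---------------------------------------------------------------------------

def risk_set(cohort: Cohort, t: float) -> set[str]:
    """Subjects still under observation at ``t``: observed time >= t.

    Ties are included (a subject failing or censored exactly at ``t`` counts
    as at risk at ``t``).
    """
    if t <= 0:
        raise ValueError("risk-set time must be positive")
    return set(cohort.ids[cohort.time >= t])


def draw_ncc(cohort: Cohort, m: int = 1, rng=None) -> SampledCohort:
    """Nested case-control: all cases, ``m`` incidence-density controls each."""
    return _draw_ncc_impl(cohort, p=1.0, case_count=None, m=m, rng=rng, name="ncc")


def draw_modncc(
    cohort: Cohort,
    case_probability: float | None = None,
    case_count: int | None = None,
    m: int = 1,
    rng=None,
) -> SampledCohort:
    """Modified NCC: cases thinned by Bernoulli(P) or to a fixed count.

    For each *sampled* case, ``m`` controls are drawn from its risk set
    exactly as in the ordinary NCC design.  Weights are attached by
    :func:`km_type_weights` with the case-inclusion adjustment.
    """
    if case_probability is None and case_count is None:
        raise DesignError("modncc requires case_probability or case_count")
    return _draw_ncc_impl(cohort, p=case_probability, case_count=case_count,
                          m=m, rng=rng, name="modncc")


def _draw_ncc_impl(cohort, p, case_count, m, rng, name) -> SampledCohort:
    rng = _as_rng(rng)
    if m < 1:
        raise DesignError("m must be >= 1")
    time, event, ids = cohort.time, cohort.event, cohort.ids
    case_pos = np.flatnonzero(event == 1)
    if name == "modncc":
        design = DesignSpec(name=name, m=m, case_probability=p, case_count=case_count)
    else:
        design = DesignSpec(name=name, m=m)
    if len(case_pos) == 0:
        logger.warning("cohort contains no events; NCC sample is empty")
        empty = cohort.df.iloc[[]].copy()
        empty["role"] = pd.Series(dtype=str)
        empty["weight"] = pd.Series(dtype=float)
        return SampledCohort(df=empty, design=design,
                             meta={"cohort_hash": cohort_hash(cohort), "P": p})
    if case_count is not None:
        if case_count > len(case_pos):
            raise DesignError(
                f"case_count={case_count} exceeds number of cases {len(case_pos)}")
        sampled_cases = rng.choice(case_pos, size=case_count, replace=False)
        p_eff = case_count / len(case_pos)
    else:
        keep = rng.random(len(case_pos)) < p
        sampled_cases = case_pos[keep]
        p_eff = p

    # controls: for each sampled case, m uniform draws (no replacement) from
    # its risk set minus the case itself; drawn in event-time order
    order = np.argsort(time[sampled_cases], kind="stable")
    control_pos: list[int] = []
    n_empty = 0
    for ci in sampled_cases[order]:
        pool = np.flatnonzero((time >= time[ci]))
        pool = pool[pool != ci]
        if len(pool) == 0:
            n_empty += 1
            continue
        k = min(m, len(pool))
        control_pos.extend(rng.choice(pool, size=k, replace=False))
    if n_empty:
        logger.warning("%d case(s) had an empty risk set; matched 0 controls", n_empty)

    sampled_case_set = set(sampled_cases.tolist())
    all_pos = sorted(sampled_case_set | set(control_pos))
    idx = np.asarray(all_pos, dtype=int)
    roles = np.array([ROLE_CASE if i in sampled_case_set else ROLE_CONTROL for i in idx])
    weights = km_type_weights(cohort, ids[idx], m=m, P=p_eff)
    meta = {"P": p_eff, "m": m, "n_cases_sampled": len(sampled_case_set),
            "n_empty_risk_sets": n_empty}
    return _take(cohort, idx, roles, weights, design, meta)


def km_type_weights(cohort: Cohort, subject_ids, m: int, P: float) -> np.ndarray:
    """Inverse marginal inclusion probabilities for (mod)NCC samples.

    Sampled controls are re-used at every event time where they are at risk,
    so the analysis weight of subject *i* is ``1 / pi_i`` with ``pi_i`` its
    *overall* inclusion probability under the design:

    * non-case: ``p0_i = 1 - prod_{t_j <= time_i} (1 - P * m / (n(t_j) - 1))``
      over the cohort's case event times, with ``n(t) = |risk set(t)|`` —
      the probability of ever being drawn as a control (cases are thinned
      independently with probability ``P``, and given sampling, each of the
      ``n(t_j) - 1`` other at-risk subjects is drawn with probability
      ``m / (n(t_j) - 1)``, capped at 1);
    * case: ``pi_i = P + (1 - P) * p0_i`` where its own event time is
      excluded from the product — a case not sampled as a case remains
      eligible as a control while at risk.

    At ``P = 1`` this reduces to the classical Kaplan-Meier-type weights and
    every case has weight 1.
    """
    time, event, ids = cohort.time, cohort.event, cohort.ids
    pos = pd.Index(ids).get_indexer(np.asarray(subject_ids, dtype=str))
    if (pos < 0).any():
        raise KeyError("subject_ids contain ids not present in the cohort")
    case_pos = np.flatnonzero(event == 1)
    case_times = time[case_pos]
    order = np.argsort(case_times, kind="stable")
    case_pos, case_times = case_pos[order], case_times[order]
    # n(t_j): subjects with time >= t_j
    sorted_times = np.sort(time)
    n_at_risk = len(time) - np.searchsorted(sorted_times, case_times, side="left")
    draw_prob = np.minimum(m / np.maximum(n_at_risk - 1, 1), 1.0)
    applied = n_at_risk <= 1
    log_factors = np.log1p(-P * draw_prob)
    log_factors[applied] = 0.0  # empty pool: nobody can be drawn at this time
    cum = np.concatenate([[0.0], np.cumsum(log_factors)])

    weights = np.empty(len(pos))
    case_rank = {int(cp): k for k, cp in enumerate(case_pos)}
    for out, i in enumerate(pos):
        k = np.searchsorted(case_times, time[i], side="right")
        log_surv = cum[k]
        if event[i] == 1:
            log_surv -= log_factors[case_rank[i]]  # exclude own event time
            p0 = 1.0 - np.exp(log_surv)
            pi = P + (1.0 - P) * p0
        else:
            pi = 1.0 - np.exp(log_surv)
        if pi <= 0:
            raise WeightError(
                f"subject {ids[i]!r} has zero inclusion probability; "
                "it cannot appear in a valid (mod)NCC sample")
        weights[out] = 1.0 / pi
    return weights


# ---------------------------------------------------------------------------
# case-cohort
# ---------------------------------------------------------------------------

def draw_cc(
    cohort: Cohort,
    subcohort_fraction: float | None = None,
    subcohort_size: int | None = None,
    rng=None,
) -> SampledCohort:
    """Case-cohort: a uniform subcohort extended by all remaining cases."""
    return _draw_cc_impl(cohort, subcohort_fraction, subcohort_size,
                         r=1.0, extra_case_count=None, rng=rng, name="cc")


def draw_modcc(
    cohort: Cohort,
    subcohort_fraction: float | None = None,
    subcohort_size: int | None = None,
    extra_case_fraction: float | None = None,
    extra_case_count: int | None = None,
    rng=None,
) -> SampledCohort:
    """Modified case-cohort: out-of-subcohort cases thinned by Bernoulli(r).

    Cases inside the subcohort are always kept; cases outside enter with
    probability ``r`` (or as a uniform fixed-count subset).
    """
    if extra_case_fraction is None and extra_case_count is None:
        raise DesignError("modcc requires extra_case_fraction or extra_case_count")
    return _draw_cc_impl(cohort, subcohort_fraction, subcohort_size,
                         r=extra_case_fraction, extra_case_count=extra_case_count,
                         rng=rng, name="modcc")


def _draw_cc_impl(cohort, q, size, r, extra_case_count, rng, name) -> SampledCohort:
    rng = _as_rng(rng)
    N = cohort.n
    if size is None:
        if q is None:
            raise DesignError("subcohort_fraction or subcohort_size required")
        size = int(round(q * N))
    if not 0 < size <= N:
        raise DesignError(f"subcohort size must satisfy 1 <= size <= N={N}, got {size}")
    q_eff = size / N
    sub = rng.choice(N, size=size, replace=False)
    sub_set = set(sub.tolist())
    in_sub = np.zeros(N, dtype=bool)
    in_sub[sub] = True
    out_cases = np.flatnonzero((cohort.event == 1) & ~in_sub)
    if extra_case_count is not None:
        if extra_case_count > len(out_cases):
            raise DesignError(
                f"extra_case_count={extra_case_count} exceeds out-of-subcohort "
                f"cases {len(out_cases)}")
        extra = rng.choice(out_cases, size=extra_case_count, replace=False)
        r_eff = extra_case_count / len(out_cases) if len(out_cases) else 1.0
    else:
        if r == 0.0:
            extra = out_cases[:0]
        else:
            extra = out_cases[rng.random(len(out_cases)) < r]
        r_eff = r
    idx = np.asarray(sorted(sub_set | set(extra.tolist())), dtype=int)
    roles = np.array([ROLE_SUBCOHORT if i in sub_set else ROLE_CASE for i in idx])
    weights = ipw_weights(cohort, cohort.ids[idx], q=q_eff, r=r_eff)
    if name == "cc":
        design = DesignSpec(name="cc", subcohort_fraction=q, subcohort_size=size)
    else:
        design = DesignSpec(name="modcc", subcohort_fraction=q, subcohort_size=size,
                            extra_case_fraction=r, extra_case_count=extra_case_count)
    meta = {"q": q_eff, "r": r_eff, "subcohort_size": size}
    return _take(cohort, idx, roles, weights, design, meta)


def ipw_weights(cohort: Cohort, subject_ids, q: float, r: float = 1.0) -> np.ndarray:
    """Time-fixed inverse sampling-probability weights for (mod)CC samples.

    Inclusion probabilities: non-case in the subcohort ``q``; case
    ``q + (1 - q) * r`` (kept if in the subcohort, else thinned with
    probability ``r``).  The classical case-cohort design is ``r = 1``,
    giving every case weight 1.
    """
    if not 0 < q <= 1:
        raise DesignError(f"subcohort fraction q must lie in (0, 1], got {q}")
    if not 0 <= r <= 1:
        raise DesignError(f"extra-case fraction r must lie in [0, 1], got {r}")
    pos = pd.Index(cohort.ids).get_indexer(np.asarray(subject_ids, dtype=str))
    if (pos < 0).any():
        raise KeyError("subject_ids contain ids not present in the cohort")
    event = cohort.event[pos]
    pi_case = q + (1 - q) * r
    if pi_case <= 0:
        raise DesignError("case inclusion probability is zero (q=0 with r=0)")
    return np.where(event == 1, 1.0 / pi_case, 1.0 / q)


# ---------------------------------------------------------------------------
# extreme-group sampling
# ---------------------------------------------------------------------------

def draw_egs(
    cohort: Cohort,
    t1: float,
    t2: float,
    controls_per_case: int = 1,
    rng=None,
) -> SampledCohort:
    """Extreme-group sampling with boundaries ``t1 <= t2`` (years).

    Cases: event observed before ``t1``.  Eligible controls: observed time
    at least ``t2`` (event-free at ``t2``; a later event does not disqualify).
    Subjects censored before ``t2`` without an early event, or with an event
    in ``[t1, t2)``, are excluded.  ``controls_per_case * n_cases`` controls
    are drawn uniformly without replacement, capped (with a warning) at the
    eligible count.  Analysis is unweighted (logistic screening test or a
    conditional likelihood); all weights are set to 1.
    """
    rng = _as_rng(rng)
    if not 0 < t1 <= t2:
        raise DesignError(f"egs requires 0 < t1 <= t2, got t1={t1}, t2={t2}")
    time, event = cohort.time, cohort.event
    case_pos = np.flatnonzero((event == 1) & (time < t1))
    elig_pos = np.flatnonzero(time >= t2)
    if len(case_pos) == 0:
        raise EmptyStratumError(f"no events before t1={t1}")
    if len(elig_pos) == 0:
        raise EmptyStratumError(f"no subjects event-free at t2={t2}")
    want = controls_per_case * len(case_pos)
    if want > len(elig_pos):
        logger.warning("requested %d EGS controls but only %d eligible; capping",
                       want, len(elig_pos))
        want = len(elig_pos)
    ctrl = rng.choice(elig_pos, size=want, replace=False)
    idx = np.asarray(sorted(set(case_pos.tolist()) | set(ctrl.tolist())), dtype=int)
    case_set = set(case_pos.tolist())
    roles = np.array([ROLE_EGS_CASE if i in case_set else ROLE_EGS_CONTROL for i in idx])
    design = DesignSpec(name="egs", t1=t1, t2=t2, m=controls_per_case)
    rho = want / len(elig_pos)
    meta = {"rho": rho, "n_cases": len(case_pos), "n_eligible_controls": len(elig_pos)}
    return _take(cohort, idx, roles, np.ones(len(idx)), design, meta)


@dataclass(frozen=True)
class EgsCalibration:
    t1: float
    t2: float
    n_achieved: int
    n_cases: int
    n_eligible: int


def calibrate_egs_t1(
    cohort: Cohort,
    target_n: int,
    t2: float | str = "equal-to-t1",
    controls_per_case: int = 1,
) -> EgsCalibration:
    """Smallest ``t1`` (on the grid just above observed case event times)
    achieving an EGS sample of at least ``target_n`` subjects.

    With 1:1 sampling the achieved size is ``n_cases + min(n_cases,
    n_eligible)``.  Pass ``t2="equal-to-t1"`` to re-tie ``t2`` to each
    candidate ``t1``; ties break toward the smaller ``t1``.
    """
    time, event = cohort.time, cohort.event
    case_times = np.unique(time[event == 1])
    if len(case_times) == 0:
        raise DesignError("cohort has no events; EGS cannot be calibrated")
    best = None
    achievable = []
    for u in case_times:
        t1 = float(np.nextafter(u, np.inf))
        t2_c = t1 if t2 == "equal-to-t1" else float(t2)
        if t2_c < t1:
            continue
        n_cases = int(((event == 1) & (time < t1)).sum())
        n_elig = int((time >= t2_c).sum())
        if n_cases == 0 or n_elig == 0:
            continue
        n_ach = n_cases + min(controls_per_case * n_cases, n_elig)
        achievable.append(n_ach)
        if n_ach >= target_n:
            best = EgsCalibration(t1=t1, t2=t2_c, n_achieved=n_ach,
                                  n_cases=n_cases, n_eligible=n_elig)
            break
    if best is None:
        lo = min(achievable) if achievable else 0
        hi = max(achievable) if achievable else 0
        raise DesignError(
            f"target_n={target_n} not achievable by EGS on this cohort; "
            f"achievable sizes range {lo}..{hi}")
    return best


# ---------------------------------------------------------------------------
# dispatcher
# ---------------------------------------------------------------------------

def draw_design(cohort: Cohort, design: DesignSpec, rng) -> SampledCohort:
    """Draw one sample according to ``design`` (the ``full`` design returns
    every subject with weight 1)."""
    rng = _as_rng(rng)
    name = design.name
    if name == "full":
        idx = np.arange(cohort.n)
        roles = np.where(cohort.event == 1, ROLE_CASE, ROLE_CONTROL)
        return _take(cohort, idx, roles, np.ones(cohort.n), design, {})
    if name == "srs":
        if design.target_n is None:
            raise DesignError("srs requires target_n")
        return draw_srs(cohort, design.target_n, rng)
    if name == "ncc":
        return draw_ncc(cohort, m=design.m, rng=rng)
    if name == "modncc":
        return draw_modncc(cohort, case_probability=design.case_probability,
                           case_count=design.case_count, m=design.m, rng=rng)
    if name == "cc":
        return draw_cc(cohort, subcohort_fraction=design.subcohort_fraction,
                       subcohort_size=design.subcohort_size, rng=rng)
    if name == "modcc":
        return draw_modcc(cohort, subcohort_fraction=design.subcohort_fraction,
                          subcohort_size=design.subcohort_size,
                          extra_case_fraction=design.extra_case_fraction,
                          extra_case_count=design.extra_case_count, rng=rng)
    if name == "egs":
        return draw_egs(cohort, t1=design.t1, t2=design.t2,
                        controls_per_case=design.m, rng=rng)
    raise DesignError(f"unknown design {name!r}")
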