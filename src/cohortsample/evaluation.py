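"""Design-comparison engine: repeated sampling, bootstrap SEs, inflation
factors, relative efficiency and power.

Two complementary resampling experiments quantify what a sampling design
costs in precision:

* **repeated sampling** on one fixed cohort isolates the variability added
  by the design alone (``sampSE``, the SD of the marker coefficient over
  ``M`` independent subsamples) and the fraction of subsamples in which the
  marker is significant (``power``);
* **bootstrap cohorts** — the design applied once to each of ``M``
  with-replacement resamples of the cohort — measure the total variability
  (``totalSE``: cohort sampling + design sampling).

The **inflation factor** ``IF = totalSE(design) / totalSE(full cohort)``
summarizes the precision lost by subsampling; ``(IF_a / IF_b)^2`` is the
approximate factor by which design *a* needs more subjects to match design
*b*.  For a modified NCC design with case-sampling probability ``p`` and
``m`` controls per case a closed-form approximation is available,
``IF ≈ 1 / sqrt(p * m / (m + 1))``, an upper bound when controls are
re-used via the weighted analysis.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cohort_model import Cohort, ID_COL
from .designs import DesignSpec, draw_design
from .estimation import FitResult, fit_cox, egs_logistic_test, egs_conditional_fit

__all__ = [
    "EvaluationResult",
    "repeated_sampling_experiment",
    "bootstrap_experiment",
    "inflation_factor",
    "analytic_inflation_factor",
    "relative_efficiency",
    "fit_for_design",
    "table_report",
]


class ExperimentError(RuntimeError):
    """No repetition of an experiment produced a usable fit."""


@dataclass
class EvaluationResult:
    """Per-design summary over resampling repetitions.

    ``sampSE`` is the SD of the marker log-HR over repeated subsamples of
    the fixed cohort; ``totalSE`` the SD over bootstrap cohorts; ``IF`` the
    ratio to the full-cohort ``totalSE``; ``power`` the rejection fraction
    of the design's Wald test at level ``alpha``.  ``mc_tol(sd)`` gives the
    Monte-Carlo SE of a reported SD, ``sd / sqrt(2 (M - 1))``.
    """

    design: DesignSpec
    term: str
    M: int
    n_sample_mean: float = math.nan
    n_event_mean: float = math.nan
    mean_loghr: float = math.nan
    sampSE: float = math.nan
    totalSE: float = math.nan
    IF: float = math.nan
    power: float = math.nan
    alpha: float = 0.05
    n_failed: int = 0
    coefs: np.ndarray | None = field(default=None, repr=False)

    @property
    def mean_hr(self) -> float:
        return math.exp(self.mean_loghr)

    def mc_tol(self, sd: float) -> float:
        m_ok = self.M - self.n_failed
        return sd / math.sqrt(2 * max(m_ok - 1, 1))


def _rep_rng(seed: int, rep: int) -> np.random.Generator:
    # deterministic per (master seed, repetition); independent of execution order
    return np.random.default_rng(np.random.SeedSequence([int(seed), int(rep)]))


def fit_for_design(
    sample,
    covariates: list[str],
    *,
    egs_estimator: str = "conditional",
    compute_model_se: bool = False,
) -> FitResult:
    """Fit the analysis model appropriate to the design that produced
    ``sample``: unweighted Cox for full/SRS, weighted Cox with robust SE for
    (mod)NCC and (mod)CC, and for EGS either the conditional Weibull
    likelihood (``"conditional"``, hazard-ratio estimation) or the logistic
    screening model (``"logistic"``)."""
    name = sample.design.name
    if name in ("full", "srs"):
        return fit_cox(sample, covariates, use_weights=False, robust=True,
                       compute_model_se=compute_model_se)
    if name in ("ncc", "modncc", "cc", "modcc"):
        return fit_cox(sample, covariates, use_weights=True, robust=True,
                       compute_model_se=compute_model_se)
    if name == "egs":
        if egs_estimator == "conditional":
            return egs_conditional_fit(sample, covariates)
        if egs_estimator == "logistic":
            return egs_logistic_test(sample, covariates)
        if egs_estimator == "naive-cox":
            return fit_cox(sample, covariates, use_weights=False, robust=True,
                           compute_model_se=compute_model_se)
        raise ValueError(f"unknown egs_estimator {egs_estimator!r}")
    raise ValueError(f"no analysis model for design {name!r}")


def repeated_sampling_experiment(
    cohort: Cohort,
    design: DesignSpec,
    covariates: list[str],
    term: str,
    M: int = 1000,
    *,
    alpha: float = 0.05,
    seed: int = 0,
    egs_estimator: str = "conditional",
) -> EvaluationResult:
    """Apply ``design`` to the fixed cohort ``M`` times; summarize the marker
    coefficient (``mean_loghr``, ``sampSE``) and the rejection fraction
    (``power``) of the design's test at level ``alpha``.

    For EGS the coefficient comes from ``egs_estimator`` while the power is
    always that of the logistic screening test.  Non-converged repetitions
    are dropped and counted in ``n_failed``.  The ``full`` design involves
    no sampling randomness: the single full-cohort fit is returned with
    ``sampSE = 0``.
    """
    if M < 1:
        raise ValueError("M must be >= 1")
    if design.name == "full":
        sample = draw_design(cohort, design, _rep_rng(seed, 0))
        fit = fit_for_design(sample, covariates)
        if not fit.converged:
            raise ExperimentError(f"full-cohort fit failed: {fit.message}")
        return EvaluationResult(
            design=design, term=term, M=M, n_sample_mean=cohort.n,
            n_event_mean=cohort.n_event, mean_loghr=fit.coef(term), sampSE=0.0,
            power=float(fit.p(term) < alpha), alpha=alpha,
            coefs=np.full(M, fit.coef(term)))

    coefs, rejects, nss, nes = [], [], [], []
    n_failed = 0
    for rep in range(M):
        rng = _rep_rng(seed, rep)
        sample = draw_design(cohort, design, rng)
        fit = fit_for_design(sample, covariates, egs_estimator=egs_estimator)
        if design.name == "egs" and egs_estimator != "logistic":
            test = egs_logistic_test(sample, [term])
        else:
            test = fit
        if not (fit.converged and test.converged and np.isfinite(fit.coef(term))):
            n_failed += 1
            continue
        coefs.append(fit.coef(term))
        rejects.append(test.p(term) < alpha)
        nss.append(sample.n_sample)
        nes.append(sample.n_event)
    if not coefs:
        raise ExperimentError("all repetitions failed to converge")
    coefs = np.asarray(coefs)
    return EvaluationResult(
        design=design, term=term, M=M,
        n_sample_mean=float(np.mean(nss)), n_event_mean=float(np.mean(nes)),
        mean_loghr=float(np.mean(coefs)),
        sampSE=float(np.std(coefs, ddof=1)) if len(coefs) > 1 else math.nan,
        power=float(np.mean(rejects)), alpha=alpha, n_failed=n_failed,
        coefs=coefs)


def _bootstrap_cohort(cohort: Cohort, rng: np.random.Generator) -> Cohort:
    idx = rng.integers(0, cohort.n, size=cohort.n)
    df = cohort.df.iloc[idx].copy()
    df[ID_COL] = [f"{s}_b{k}" for k, s in enumerate(df[ID_COL])]
    return Cohort(df, name=f"{cohort.name}:boot")


def bootstrap_experiment(
    cohort: Cohort,
    design: DesignSpec,
    covariates: list[str],
    term: str,
    M: int = 1000,
    *,
    seed: int = 0,
    egs_estimator: str = "conditional",
) -> EvaluationResult:
    """Total-SE experiment: draw ``M`` bootstrap cohorts (size N, with
    replacement), apply ``design`` once to each, fit, and report the SD of
    the marker coefficient as ``totalSE``.

    The bootstrap cohort of repetition ``rep`` depends only on
    ``(seed, rep)``, so running different designs with the same master seed
    compares them on *paired* bootstrap cohorts.  ``design="full"`` yields
    the full-cohort empirical SE.
    """
    if M < 2:
        raise ValueError("M must be >= 2 for an SD")
    coefs, nss, nes = [], [], []
    n_failed = 0
    for rep in range(M):
        rng = _rep_rng(seed, rep)
        bcohort = _bootstrap_cohort(cohort, rng)
        try:
            sample = draw_design(bcohort, design, rng)
        except Exception:
            n_failed += 1
            continue
        fit = fit_for_design(sample, covariates, egs_estimator=egs_estimator)
        if not (fit.converged and np.isfinite(fit.coef(term))):
            n_failed += 1
            continue
        coefs.append(fit.coef(term))
        nss.append(sample.n_sample)
        nes.append(sample.n_event)
    if len(coefs) < 2:
        raise ExperimentError("fewer than two bootstrap repetitions converged")
    coefs = np.asarray(coefs)
    return EvaluationResult(
        design=design, term=term, M=M,
        n_sample_mean=float(np.mean(nss)), n_event_mean=float(np.mean(nes)),
        mean_loghr=float(np.mean(coefs)),
        totalSE=float(np.std(coefs, ddof=1)),
        n_failed=n_failed, coefs=coefs)


def inflation_factor(totalSE_design: float, totalSE_full: float) -> float:
    """``IF = totalSE(design) / totalSE(full cohort)``."""
    if not (totalSE_design > 0 and totalSE_full > 0):
        raise ValueError("total SEs must be positive")
    return totalSE_design / totalSE_full


def analytic_inflation_factor(p: float, m: int = 1) -> float:
    """Closed-form approximation ``1 / sqrt(p * m / (m + 1))`` of the
    modified-NCC inflation factor, for case-sampling probability ``p`` and
    ``m`` matched controls per case.  Derived for the stratified (matched
    sets) analysis, hence an upper bound for the weighted analysis that
    re-uses controls.  With the usual ``m = 1`` it reduces to
    ``1 / sqrt(p / 2)``."""
    if not 0 < p <= 1:
        raise ValueError(f"case sampling probability p must lie in (0, 1], got {p}")
    if m < 1:
        raise ValueError("m must be >= 1")
    return 1.0 / math.sqrt(p * m / (m + 1))


def relative_efficiency(if_a: float, if_b: float) -> float:
    """``(IF_a / IF_b)^2`` — the approximate factor by which design *a*
    needs a larger sample to match the precision of design *b*."""
    if not (if_a > 0 and if_b > 0):
        raise ValueError("inflation factors must be positive")
    return (if_a / if_b) ** 2


# ---------------------------------------------------------------------------
# reporting
# ---------------------------------------------------------------------------

_REPORT_COLUMNS = ["design", "n.sample", "n.event", "log(HR)", "HR",
                   "sampSE", "totalSE", "IF", "power"]


def _design_label(design: DesignSpec) -> str:
    if design.name == "egs":
        return f"egs[t1={design.t1:g},t2={design.t2:g}]"
    return design.name


def table_report(results: list[EvaluationResult]) -> pd.DataFrame:
    """Combine evaluation results into a design-comparison table with
    columns design, n.sample, n.event, log(HR), HR, sampSE, totalSE, IF,
    power.  Results for the same design from the repeated-sampling and
    bootstrap experiments are merged on the design label."""
    rows: dict[str, dict] = {}
    for res in results:
        label = _design_label(res.design)
        row = rows.setdefault(label, {c: math.nan for c in _REPORT_COLUMNS})
        row["design"] = label
        for col, val in (("n.sample", res.n_sample_mean), ("n.event", res.n_event_mean),
                         ("log(HR)", res.mean_loghr), ("HR", res.mean_hr),
                         ("sampSE", res.sampSE), ("totalSE", res.totalSE),
                         ("IF", res.IF), ("power", res.power)):
            if isinstance(val, float) and math.isnan(val):
                continue
            row[col] = val
    table = pd.DataFrame(list(rows.values()), columns=_REPORT_COLUMNS)
    full_rows = table.loc[table["design"] == "full", "totalSE"]
    if len(full_rows) == 1 and np.isfinite(full_rows.iloc[0]):
        base = float(full_rows.iloc[0])
        table["IF"] = [
            inflation_factor(t, base) if np.isfinite(t) else math.nan
            for t in table["totalSE"]
        ]
    return table
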