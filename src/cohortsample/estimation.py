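"""Model fitting for sampled cohorts.

Three analysis routes, each matched to the design that produced the sample:

* :func:`fit_cox` — (weighted) Cox proportional-hazards regression.  For
  NCC/modNCC and CC/modCC samples the subject weights attached by the design
  make the weighted partial likelihood an inverse-probability-weighted
  estimating equation; Wald tests then use the robust (score-residual
  sandwich) variance.  SRS and full-cohort data are fitted unweighted.
* :func:`egs_logistic_test` — the screening test for extreme-group samples:
  a plain logistic regression of early-case status on the covariates with
  maximum-likelihood (observed-information) variance.
* :func:`egs_conditional_fit` — hazard-ratio estimation from an EGS sample
  via a parametric conditional likelihood under a Weibull
  proportional-hazards model, conditioning on inclusion in one of the two
  extreme groups.  A naive Cox fit on the extreme groups alone is biased
  because the middle of the follow-up distribution is missing by design.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from lifelines import CoxPHFitter
from lifelines.exceptions import ConvergenceError

from .cohort_model import Cohort, TIME_COL, EVENT_COL
from .designs import SampledCohort, ROLE_EGS_CASE, ROLE_EGS_CONTROL, EmptyStratumError

__all__ = ["FitResult", "fit_cox", "egs_logistic_test", "egs_conditional_fit"]

Z975 = stats.norm.ppf(0.975)


class MissingCovariateError(ValueError):
    """A modelled covariate is missing on rows included in a fit."""


@dataclass
class FitResult:
    """Tidy per-term estimates from one model fit.

    ``table`` has one row per term with columns ``coef`` (log hazard or log
    odds ratio), ``se_model``, ``se_robust``, ``hr``, ``lo95``, ``hi95`` and
    ``p_wald``; the confidence interval and Wald test use ``se_robust`` when
    available, otherwise ``se_model``.
    """

    table: pd.DataFrame
    converged: bool
    n_used: int
    method: str
    message: str = ""
    extra: dict = field(default_factory=dict)

    def coef(self, term: str) -> float:
        return float(self.table.loc[term, "coef"])

    def se(self, term: str) -> float:
        row = self.table.loc[term]
        return float(row["se_robust"] if np.isfinite(row["se_robust"]) else row["se_model"])

    def p(self, term: str) -> float:
        return float(self.table.loc[term, "p_wald"])

    def hr(self, term: str) -> float:
        return float(self.table.loc[term, "hr"])

    def to_frame(self) -> pd.DataFrame:
        return self.table.reset_index(names="term")


def _failed(terms, method, message, n_used=0) -> FitResult:
    tab = pd.DataFrame(
        {c: np.nan for c in ("coef", "se_model", "se_robust", "hr", "lo95", "hi95", "p_wald")},
        index=pd.Index(terms, name="term"),
    )
    return FitResult(table=tab, converged=False, n_used=n_used, method=method,
                     message=message)


def _make_table(terms, coef, se_model, se_robust) -> pd.DataFrame:
    coef = np.asarray(coef, float)
    se_used = np.where(np.isfinite(se_robust), se_robust, se_model)
    z = coef / se_used
    return pd.DataFrame(
        {
            "coef": coef,
            "se_model": se_model,
            "se_robust": se_robust,
            "hr": np.exp(coef),
            "lo95": np.exp(coef - Z975 * se_used),
            "hi95": np.exp(coef + Z975 * se_used),
            "p_wald": 2 * stats.norm.sf(np.abs(z)),
        },
        index=pd.Index(terms, name="term"),
    )


def _fit_frame(data, covariates, drop_missing):
    if isinstance(data, SampledCohort):
        df = data.df
        weights = df["weight"].to_numpy(float)
    elif isinstance(data, Cohort):
        df = data.df
        weights = np.ones(len(df))
    else:
        raise TypeError("data must be a Cohort or SampledCohort")
    missing_cols = [c for c in covariates if c not in df.columns]
    if missing_cols:
        raise MissingCovariateError(f"covariates not in data: {missing_cols}")
    sub = df[[TIME_COL, EVENT_COL, *covariates]].copy()
    sub["_w"] = weights
    na = sub[covariates].isna().any(axis=1)
    if na.any():
        if not drop_missing:
            raise MissingCovariateError(
                f"{int(na.sum())} row(s) have missing values in modelled covariates; "
                "pass drop_missing=True to exclude them explicitly")
        sub = sub.loc[~na]
    return sub


def fit_cox(
    data: Cohort | SampledCohort,
    covariates: list[str],
    *,
    use_weights: bool = True,
    robust: bool = True,
    ties: str = "efron",
    drop_missing: bool = False,
    compute_model_se: bool = True,
) -> FitResult:
    """(Weighted) Cox proportional-hazards regression.

    Maximizes the weight-augmented partial likelihood (Efron tie handling)
    and reports both the model-based SE and, when ``robust=True``, the
    score-residual sandwich SE, which is the one used for Wald tests and
    confidence intervals.  Non-convergence is flagged on the result rather
    than raised.

    ``ties="breslow"`` is available for cross-package comparison on
    *unweighted* fits only (routed through ``statsmodels`` ``PHReg``).
    """
    sub = _fit_frame(data, covariates, drop_missing)
    if sub[EVENT_COL].sum() < 1:
        return _failed(covariates, "cox", "no events in fitting data", len(sub))
    if not use_weights:
        sub["_w"] = 1.0
    if ties == "breslow":
        return _fit_cox_breslow(sub, covariates, robust)
    if ties != "efron":
        raise ValueError("ties must be 'efron' or 'breslow'")

    cph = CoxPHFitter()
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # non-integer-weight advisory; handled via robust
            cph.fit(sub, duration_col=TIME_COL, event_col=EVENT_COL,
                    weights_col="_w", robust=robust,
                    fit_options={"precision": 1e-11})
    except (ConvergenceError, np.linalg.LinAlgError, ValueError) as err:
        return _failed(covariates, "cox", f"did not converge: {err}", len(sub))
    coef = cph.params_.reindex(covariates).to_numpy()
    se_fit = cph.standard_errors_.reindex(covariates).to_numpy()
    if robust:
        se_robust = se_fit
        se_model = np.full_like(se_robust, np.nan)
        if compute_model_se:
            try:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    cph2 = CoxPHFitter()
                    cph2.fit(sub, duration_col=TIME_COL, event_col=EVENT_COL,
                             weights_col="_w", robust=False)
                se_model = cph2.standard_errors_.reindex(covariates).to_numpy()
            except (ConvergenceError, np.linalg.LinAlgError, ValueError):
                pass
    else:
        se_model, se_robust = se_fit, np.full_like(se_fit, np.nan)
    table = _make_table(covariates, coef, se_model, se_robust)
    return FitResult(table=table, converged=True, n_used=len(sub), method="cox",
                     extra={"ties": "efron", "weighted": bool(use_weights),
                            "log_likelihood": float(cph.log_likelihood_)})


def _fit_cox_breslow(sub, covariates, robust) -> FitResult:
    if not np.allclose(sub["_w"], 1.0):
        raise ValueError("ties='breslow' supports unweighted fits only")
    if robust:
        raise ValueError("robust variance with ties='breslow' is not supported; "
                         "use ties='efron'")
    import statsmodels.api as sm

    mod = sm.PHReg(sub[TIME_COL], sub[covariates], status=sub[EVENT_COL],
                   ties="breslow")
    try:
        res = mod.fit(disp=0)
    except (np.linalg.LinAlgError, ValueError) as err:
        return _failed(covariates, "cox-breslow", f"did not converge: {err}", len(sub))
    se = np.asarray(res.bse)
    table = _make_table(covariates, np.asarray(res.params), se,
                        np.full_like(se, np.nan))
    return FitResult(table=table, converged=True, n_used=len(sub),
                     method="cox-breslow", extra={"ties": "breslow"})


# ---------------------------------------------------------------------------
# extreme-group sampling analyses
# ---------------------------------------------------------------------------

def _egs_arrays(sample: SampledCohort, covariates):
    df = sample.df
    roles = df["role"]
    is_case = (roles == ROLE_EGS_CASE).to_numpy()
    is_ctrl = (roles == ROLE_EGS_CONTROL).to_numpy()
    if not is_case.any() or not is_ctrl.any():
        raise EmptyStratumError("EGS sample must contain both cases and controls")
    missing = [c for c in covariates if c not in df.columns]
    if missing:
        raise MissingCovariateError(f"covariates not in sample: {missing}")
    X = df[covariates].to_numpy(float)
    if np.isnan(X).any():
        raise MissingCovariateError("missing covariate values in EGS sample")
    return df, X, is_case


def egs_logistic_test(sample: SampledCohort, covariates: list[str]) -> FitResult:
    """Screening Wald test for an EGS sample: logistic regression of
    early-case status (event before ``t1``) vs event-free-at-``t2`` status
    on the covariates, with maximum-likelihood variance."""
    import statsmodels.api as sm

    df, X, y = _egs_arrays(sample, covariates)
    const_cols = [c for c, x in zip(covariates, X.T) if np.ptp(x) == 0]
    if const_cols:
        return _failed(covariates, "logistic",
                       f"covariate(s) constant across subjects: {const_cols}", len(df))
    Xc = sm.add_constant(pd.DataFrame(X, columns=covariates), has_constant="add")
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = sm.Logit(y.astype(float), Xc).fit(disp=0, maxiter=200)
        if not res.mle_retvals.get("converged", False):
            return _failed(covariates, "logistic", "MLE did not converge", len(df))
    except Exception as err:  # separation, singular design, etc.
        return _failed(covariates, "logistic", f"did not converge: {err}", len(df))
    coef = res.params.reindex(covariates).to_numpy()
    se = res.bse.reindex(covariates).to_numpy()
    if not np.isfinite(se).all() or (se > 1e3).any():
        return _failed(covariates, "logistic", "separation: unbounded estimates", len(df))
    table = _make_table(covariates, coef, se, np.full_like(se, np.nan))
    return FitResult(table=table, converged=True, n_used=len(df), method="logistic",
                     extra={"intercept": float(res.params.iloc[0])})


def _weibull_logsf(t, log_shape, log_scale, lp):
    """log S(t | x) under Weibull PH: -(t/scale)^shape * exp(lp)."""
    return -np.exp(np.exp(log_shape) * (np.log(t) - log_scale) + lp)


def egs_conditional_fit(
    sample: SampledCohort,
    covariates: list[str],
    *,
    t1: float | None = None,
    t2: float | None = None,
    control_fraction: float | None = None,
    tol: float = 1e-8,
) -> FitResult:
    """Hazard-ratio estimation from an EGS sample by a parametric
    conditional likelihood.

    Assumes a Weibull proportional-hazards model with survivor function
    ``S(t|x) = exp(-(t/scale)^shape * exp(x'b))``.  Each subject's
    contribution conditions on having been included in the sample: a case
    contributes ``f(t_i|x_i) / D(x_i)`` and a control
    ``rho * S(t2|x_i) / D(x_i)``, where ``rho`` is the fraction of eligible
    controls actually drawn and ``D(x) = F(t1|x) + rho * S(t2|x)`` is the
    probability of falling into either extreme group.  Maximized over
    ``(log shape, log scale, b)``; SEs come from the inverse observed
    information (numerical Hessian).
    """
    from statsmodels.tools.numdiff import approx_hess1

    df, X, is_case = _egs_arrays(sample, covariates)
    t1 = float(t1 if t1 is not None else sample.design.t1)
    t2 = float(t2 if t2 is not None else sample.design.t2)
    if t2 < t1:
        raise ValueError("t2 must be >= t1")
    rho = float(control_fraction if control_fraction is not None
                else sample.meta.get("rho", 1.0))
    if not 0 < rho <= 1:
        raise ValueError("control_fraction must lie in (0, 1]")
    time = df[TIME_COL].to_numpy(float)
    t_case = time[is_case]
    Xc, Xa = X[is_case], X
    k = len(covariates)

    def negloglik(theta):
        log_shape, log_scale = theta[0], theta[1]
        beta = theta[2:]
        shape = np.exp(log_shape)
        with np.errstate(divide="ignore", over="ignore", invalid="ignore"):
            lp_all = Xa @ beta
            # log f(t) = log h(t) + log S(t)
            logsf_t1 = _weibull_logsf(t1, log_shape, log_scale, lp_all)
            logsf_t2 = _weibull_logsf(t2, log_shape, log_scale, lp_all)
            # D(x) = F(t1|x) + rho * S(t2|x)
            logD = np.logaddexp(np.log1p(-np.exp(np.maximum(logsf_t1, -7e2))),
                                np.log(rho) + logsf_t2)
            lp_case = lp_all[is_case]
            logsf_tc = _weibull_logsf(t_case, log_shape, log_scale, lp_case)
            log_h = (log_shape + (shape - 1) * (np.log(t_case) - log_scale)
                     - log_scale + lp_case)
            ll = np.sum(log_h + logsf_tc) + np.sum((np.log(rho) + logsf_t2)[~is_case])
            ll -= np.sum(logD)
        if not np.isfinite(ll):
            return 1e10
        return -ll

    x0 = np.concatenate([[0.0, np.log(max(t2, 1e-3))], np.zeros(k)])
    res = optimize.minimize(negloglik, x0, method="L-BFGS-B",
                            options={"ftol": tol, "maxiter": 500})
    terms = covariates
    if not res.success and res.status != 0:
        # one Nelder-Mead polish attempt before giving up
        res2 = optimize.minimize(negloglik, res.x, method="Nelder-Mead",
                                 options={"fatol": 1e-9, "maxiter": 2000})
        if res2.fun <= res.fun:
            res = res2
    theta = res.x
    try:
        H = approx_hess1(theta, negloglik)
        cov = np.linalg.inv(H)
        se_all = np.sqrt(np.diag(cov))
    except np.linalg.LinAlgError:
        return _failed(terms, "egs-conditional", "singular information matrix", len(df))
    if not np.isfinite(se_all).all():
        return _failed(terms, "egs-conditional", "unstable variance estimate", len(df))
    coef, se = theta[2:], se_all[2:]
    table = _make_table(terms, coef, se, np.full_like(se, np.nan))
    return FitResult(
        table=table, converged=bool(res.success or res.fun < 1e9),
        n_used=len(df), method="egs-conditional",
        extra={"shape": float(np.exp(theta[0])), "scale": float(np.exp(theta[1])),
               "rho": rho, "t1": t1, "t2": t2,
               "neg_log_likelihood": float(res.fun)},
    )
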