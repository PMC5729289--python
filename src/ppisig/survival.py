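"""Survival statistics: Cox models, the treatment-interaction screen,
Kaplan–Meier curves, log-rank tests, and Yates-corrected chi-square.

The screening step is the package's gatekeeper for *predictive* (as opposed
to prognostic) modules: per module a Cox proportional-hazards model
``h(t) = h0(t) exp(b1 trt + b2 score + b3 trt*score)`` is fitted on
relapse-free survival and the Wald p-value of the interaction coefficient
b3 is adjusted across modules by Benjamini–Hochberg.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.exceptions import ConvergenceError
from lifelines.statistics import logrank_test as _ll_logrank
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .gsva import GsvaProfile
from .prep import ClinicalTable, check_sample_alignment

__all__ = [
    "CoxFit",
    "ScreenResult",
    "SurvivalCurve",
    "LogRankResult",
    "fit_cox",
    "interaction_screen",
    "bh_adjust",
    "km_curve",
    "logrank_test",
    "chisq_yates",
]


@dataclass(frozen=True)
class CoxFit:
    """Efron-tie Cox proportional-hazards fit summary."""

    coefficients: pd.Series
    standard_errors: pd.Series
    z_values: pd.Series
    p_values: pd.Series
    log_likelihood: float
    converged: bool
    ties: str = "efron"

    def hazard_ratios(self) -> pd.Series:
        return np.exp(self.coefficients)


@dataclass(frozen=True)
class ScreenResult:
    """Per-module interaction screen outcome.

    ``table`` columns: beta_interaction, p, q, selected; ``selected`` is
    q < fdr_threshold.
    """

    table: pd.DataFrame
    fdr_threshold: float

    @property
    def selected_modules(self) -> list[str]:
        return [str(i) for i in self.table.index[self.table["selected"]]]

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index_label="module")


@dataclass(frozen=True)
class SurvivalCurve:
    """Kaplan–Meier product-limit estimate on the distinct event-time grid."""

    times: np.ndarray
    survival: np.ndarray
    at_risk: np.ndarray

    def survival_at(self, t: float) -> float:
        past = self.times <= t
        return float(self.survival[past][-1]) if past.any() else 1.0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"time": self.times, "survival": self.survival, "at_risk": self.at_risk}
        )


@dataclass(frozen=True)
class LogRankResult:
    statistic: float
    p_value: float


def _cox_frame(
    clinical: ClinicalTable, design: Sequence[str] | pd.DataFrame, endpoint: str
) -> pd.DataFrame:
    time, event = clinical.endpoint(endpoint)
    if isinstance(design, pd.DataFrame):
        covs = design.loc[clinical.data.index]
    else:
        covs = clinical.data[list(design)]
    df = covs.copy()
    df["_time"], df["_event"] = time, event
    return df


def fit_cox(
    clinical: ClinicalTable,
    design: Sequence[str] | pd.DataFrame,
    endpoint: str = "rfs",
) -> CoxFit:
    """Fit a Cox proportional-hazards model by Efron partial likelihood.

    ``design`` names covariate columns of the clinical table, or is a
    sample-indexed data frame of covariates (e.g. module scores joined with
    treatment).  Monotone-likelihood (separation) cases surface as
    lifelines convergence warnings and are reported via ``converged``.
    """
    df = _cox_frame(clinical, design, endpoint)
    if df["_event"].sum() < 1:
        raise ValueError("Cox fit requires at least one event")
    cph = CoxPHFitter()
    converged = True
    with warnings.catch_warnings():
        warnings.simplefilter("error", category=RuntimeWarning)
        try:
            cph.fit(df, duration_col="_time", event_col="_event")
        except (ConvergenceError, RuntimeWarning, Warning):
            converged = False
    if not converged:  # refit leniently to still report capped estimates
        cph = CoxPHFitter(penalizer=1e-6)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            cph.fit(df, duration_col="_time", event_col="_event")
    summary = cph.summary
    return CoxFit(
        coefficients=summary["coef"],
        standard_errors=summary["se(coef)"],
        z_values=summary["z"],
        p_values=summary["p"],
        log_likelihood=float(cph.log_likelihood_),
        converged=converged,
    )


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values (q-values), input order."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def interaction_screen(
    profile: GsvaProfile,
    clinical: ClinicalTable,
    fdr_threshold: float = 0.05,
    endpoint: str = "rfs",
    score_mode: str = "continuous",
) -> ScreenResult:
    """Screen modules for a treatment x score interaction on survival.

    Per module, fit ``h(t) = h0(t) exp(b1 trt + b2 score + b3 trt*score)``
    and take the Wald p of b3; BH-adjust across all tested modules and flag
    those with q below ``fdr_threshold``.  ``score_mode="dichotomized"``
    replaces the continuous score by its above-median indicator.  Fits that
    fail to converge enter the adjustment with p = 1 (with a warning)
    rather than being dropped.
    """
    if score_mode not in ("continuous", "dichotomized"):
        raise ValueError(f"unknown score_mode {score_mode!r}")
    if len(profile.modules) == 0:
        empty = pd.DataFrame(
            columns=["beta_interaction", "p", "q", "selected"]
        )
        return ScreenResult(table=empty, fdr_threshold=fdr_threshold)
    check_sample_alignment(profile.samples, clinical)
    order = clinical.data.index
    time, event = clinical.endpoint(endpoint)
    trt = clinical.data["treatment"].to_numpy(dtype=float)

    betas, pvals = [], []
    for name in profile.modules:
        score = profile.values.loc[name, order].to_numpy(dtype=float)
        if score_mode == "dichotomized":
            score = (score > np.median(score)).astype(float)
        df = pd.DataFrame(
            {
                "treatment": trt,
                "score": score,
                "trt_score": trt * score,
                "_time": time.to_numpy(dtype=float),
                "_event": event.to_numpy(dtype=float),
            },
            index=order,
        )
        cph = CoxPHFitter()
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                cph.fit(df, duration_col="_time", event_col="_event")
            betas.append(float(cph.summary.loc["trt_score", "coef"]))
            pvals.append(float(cph.summary.loc["trt_score", "p"]))
        except (ConvergenceError, Exception) as exc:  # noqa: BLE001
            warnings.warn(
                f"module {name}: interaction fit failed ({exc}); recording p=1",
                stacklevel=2,
            )
            betas.append(np.nan)
            pvals.append(1.0)

    q = bh_adjust(pvals)
    table = pd.DataFrame(
        {
            "beta_interaction": betas,
            "p": pvals,
            "q": q,
            "selected": q < fdr_threshold,
        },
        index=pd.Index(profile.modules, name="module"),
    )
    return ScreenResult(table=table, fdr_threshold=fdr_threshold)


def km_curve(times, events) -> SurvivalCurve:
    """Kaplan–Meier product-limit estimator over the distinct event times."""
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=int)
    if t.shape != e.shape:
        raise ValueError("times and events must have equal length")
    if (t < 0).any():
        raise ValueError("survival times must be non-negative")
    kmf = KaplanMeierFitter()
    kmf.fit(t, e)
    event_times = np.unique(t[e == 1])
    if event_times.size == 0:
        return SurvivalCurve(
            times=np.array([]), survival=np.array([]), at_risk=np.array([])
        )
    surv = kmf.survival_function_at_times(event_times).to_numpy(dtype=float)
    at_risk = np.array([(t >= u).sum() for u in event_times])
    return SurvivalCurve(times=event_times, survival=surv, at_risk=at_risk)


def logrank_test(times_a, events_a, times_b, events_b) -> LogRankResult:
    """Two-group log-rank chi-square test (1 df)."""
    ta, tb = np.asarray(times_a, float), np.asarray(times_b, float)
    ea, eb = np.asarray(events_a, int), np.asarray(events_b, int)
    if ta.size == 0 or tb.size == 0:
        raise ValueError("both groups must be non-empty")
    if ea.sum() + eb.sum() == 0:
        return LogRankResult(statistic=0.0, p_value=1.0)
    res = _ll_logrank(ta, tb, event_observed_A=ea, event_observed_B=eb)
    return LogRankResult(
        statistic=float(res.test_statistic), p_value=float(res.p_value)
    )


def chisq_yates(table) -> tuple[float, float]:
    """Pearson chi-square with Yates continuity correction on a 2x2 table."""
    arr = np.asarray(table)
    if arr.shape != (2, 2):
        raise ValueError("chisq_yates expects a 2x2 table")
    if (arr < 0).any() or not np.issubdtype(arr.dtype, np.integer):
        arr = arr.astype(float)
        if (arr < 0).any() or not np.allclose(arr, np.round(arr)):
            raise ValueError("counts must be non-negative integers")
    if (arr.sum(axis=0) == 0).any() or (arr.sum(axis=1) == 0).any():
        raise ValueError("all table margins must be positive")
    stat, p, _, _ = stats.chi2_contingency(arr, correction=True)
    return float(stat), float(p)
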