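"""Shared survival statistics: Kaplan-Meier curves and Cox hazard ratios.

Thin wrappers around lifelines that fix the conventions used throughout
the package: survival times in months, Efron tie handling in Cox fits,
hazard ratios with 95% Wald confidence intervals, and a step-function KM
estimate whose median is the first time S(t) drops to 0.5 or below.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter

__all__ = ["KMCurve", "CoxSummary", "km_fit", "hazard_ratio", "cox_fit"]


@dataclass
class KMCurve:
    """Product-limit estimate: step function over the event-time grid."""

    times: np.ndarray            # observed time grid (starts at 0)
    survival: np.ndarray         # S(t) at each grid time, nonincreasing
    median: float                # first t with S(t) <= 0.5; nan if never
    ci_lower: np.ndarray
    ci_upper: np.ndarray

    def at(self, t: float) -> float:
        """S(t) of the step function (right-continuous)."""
        idx = np.searchsorted(self.times, t, side="right") - 1
        return float(self.survival[max(idx, 0)])


@dataclass
class CoxSummary:
    """One Cox proportional-hazards fit (per-covariate table + C-index)."""

    table: pd.DataFrame          # coef, hazard_ratio, ci_lower, ci_upper, p
    c_index: float
    median_risk_cutoff: float    # median training partial-hazard risk score

    def __getitem__(self, covariate: str) -> pd.Series:
        return self.table.loc[covariate]

    @property
    def hazard_ratios(self) -> pd.Series:
        return self.table["hazard_ratio"]


def km_fit(T, delta) -> KMCurve:
    """Kaplan-Meier product-limit estimate with 95% confidence band."""
    T = np.asarray(T, dtype=float)
    delta = np.asarray(delta, dtype=int)
    if len(T) == 0:
        raise ValueError("empty input")
    kmf = KaplanMeierFitter()
    kmf.fit(T, event_observed=delta)
    surv = kmf.survival_function_["KM_estimate"]
    times = surv.index.to_numpy(dtype=float)
    s = surv.to_numpy(dtype=float)
    below = np.flatnonzero(s <= 0.5)
    median = float(times[below[0]]) if len(below) else float("nan")
    ci = kmf.confidence_interval_
    return KMCurve(times=times, survival=s, median=median,
                   ci_lower=ci.iloc[:, 0].to_numpy(),
                   ci_upper=ci.iloc[:, 1].to_numpy())


def cox_fit(df: pd.DataFrame, duration_col: str = "time",
            event_col: str = "event", penalizer: float = 0.0) -> CoxSummary:
    """Cox PH fit (Efron ties) on all non-outcome columns of ``df``."""
    cph = CoxPHFitter(penalizer=penalizer)
    cph.fit(df, duration_col=duration_col, event_col=event_col)
    summ = cph.summary
    table = pd.DataFrame({
        "coef": summ["coef"],
        "hazard_ratio": summ["exp(coef)"],
        "ci_lower": summ["exp(coef) lower 95%"],
        "ci_upper": summ["exp(coef) upper 95%"],
        "p": summ["p"],
    })
    risk = cph.predict_partial_hazard(df).to_numpy(dtype=float)
    return CoxSummary(table=table, c_index=float(cph.concordance_index_),
                      median_risk_cutoff=float(np.median(risk)))


def hazard_ratio(group, T, delta) -> CoxSummary:
    """Univariate Cox HR of a binary group label, with Wald 95% CI/p.

    ``group`` is 0/1 (or boolean); the reported HR is for group 1 vs 0.
    """
    group = np.asarray(group, dtype=float)
    uniq = np.unique(group)
    if len(uniq) < 2:
        raise ValueError("hazard_ratio requires two groups")
    df = pd.DataFrame({"group": group,
                       "time": np.asarray(T, dtype=float),
                       "event": np.asarray(delta, dtype=int)})
    return cox_fit(df)
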