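"""Kaplan-Meier estimation, median survival and log-rank comparisons.

Thin, convention-fixing layer over lifelines.  Times are in months; the
event flag is 1 when the endpoint (death or recurrence) was observed and 0
for censored follow-up.  Median survival uses the first event time where
S(t) <= 0.5 and ``NOT_REACHED`` (infinity) when the curve never drops that
far.  Pairwise log-rank p-values are reported unadjusted.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test as _ll_logrank
from lifelines.statistics import multivariate_logrank_test as _ll_multivariate

log = logging.getLogger(__name__)

NOT_REACHED = float("inf")


@dataclass
class KMCurve:
    """Product-limit survival curve S(t) at the distinct observed times."""

    event_times: np.ndarray
    survival_prob: np.ndarray
    at_risk: np.ndarray

    def survival_at(self, t: float) -> float:
        """Step-function value of S at time t (S = 1 before the first time)."""
        idx = np.searchsorted(self.event_times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival_prob[idx])


def _check_records(time, event) -> tuple[np.ndarray, np.ndarray]:
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    if time.size == 0:
        raise ValueError("no survival records")
    if time.shape != event.shape:
        raise ValueError("time and event must have equal length")
    if np.any(~np.isfinite(time)) or np.any(time <= 0):
        raise ValueError("times must be finite and positive")
    return time, event


def km_estimate(time, event) -> KMCurve:
    """Kaplan-Meier product-limit estimate S(t) = prod (1 - d_i/n_i)."""
    time, event = _check_records(time, event)
    kmf = KaplanMeierFitter()
    kmf.fit(time, event_observed=event)
    table = kmf.event_table.loc[kmf.event_table.index > 0]
    times = table.index.to_numpy(dtype=float)
    surv = kmf.survival_function_at_times(times).to_numpy(dtype=float)
    at_risk = table["at_risk"].to_numpy(dtype=int)
    return KMCurve(event_times=times, survival_prob=surv, at_risk=at_risk)


def median_survival(curve: KMCurve) -> float:
    """Smallest event time t with S(t) <= 0.5, or NOT_REACHED."""
    below = curve.survival_prob <= 0.5
    if not np.any(below):
        return NOT_REACHED
    return float(curve.event_times[np.argmax(below)])


def logrank_test(time, event, group, group_a, group_b) -> tuple[float, float]:
    """Two-group log-rank test; returns (chi-square statistic, p-value).

    Zero total variance (e.g. one group copied from the other with no
    events) degenerates to statistic 0, p = 1.
    """
    time, event = _check_records(time, event)
    group = np.asarray(group)
    mask_a, mask_b = group == group_a, group == group_b
    if not mask_a.any() or not mask_b.any():
        raise ValueError(f"empty group among {group_a!r}, {group_b!r}")
    res = _ll_logrank(time[mask_a], time[mask_b], event[mask_a], event[mask_b])
    stat, p = float(res.test_statistic), float(res.p_value)
    if math.isnan(stat) or math.isnan(p):
        log.info("log-rank variance is zero; reporting statistic 0, p = 1")
        return 0.0, 1.0
    return stat, p


def multigroup_logrank(time, event, group) -> tuple[float, int, float]:
    """k-group log-rank test; returns (statistic, df, p) with df = k - 1."""
    time, event = _check_records(time, event)
    group = np.asarray(group)
    levels = pd.unique(group)
    if len(levels) < 2:
        raise ValueError("need at least two groups")
    res = _ll_multivariate(time, group, event)
    stat, p = float(res.test_statistic), float(res.p_value)
    if math.isnan(stat) or math.isnan(p):
        log.info("log-rank variance is zero; reporting statistic 0, p = 1")
        return 0.0, len(levels) - 1, 1.0
    return stat, len(levels) - 1, p


def survival_summary(clinical: pd.DataFrame, labels: np.ndarray) -> dict:
    """Per-subtype KM medians plus overall and pairwise log-rank tests."""
    time = clinical["time_months"].to_numpy(dtype=float)
    event = clinical["event"].to_numpy(dtype=int)
    labels = np.asarray(labels)
    levels = sorted(pd.unique(labels))
    medians = {}
    for s in levels:
        curve = km_estimate(time[labels == s], event[labels == s])
        med = median_survival(curve)
        medians[int(s)] = None if med == NOT_REACHED else med
    stat, df, p = multigroup_logrank(time, event, labels)
    pairwise = {}
    for i, a in enumerate(levels):
        for b in levels[i + 1 :]:
            s2, p2 = logrank_test(time, event, labels, a, b)
            pairwise[f"{a}_vs_{b}"] = {"statistic": s2, "p": p2}
    return {
        "median_months": medians,
        "logrank": {"statistic": stat, "df": df, "p": p},
        "pairwise_logrank": pairwise,
    }
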