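"""Kaplan-Meier estimation and log-rank comparison of TME groups.

Thin wrappers over lifelines that expose the product-limit curve with
Greenwood variances, and the k-group log-rank chi-square test. Events
precede censorings at tied times (the standard convention).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test


@dataclass
class KMCurve:
    """Product-limit estimate: S(t) = prod(1 - d_i / n_i) over event times."""

    event_times: np.ndarray
    survival: np.ndarray
    at_risk: np.ndarray
    greenwood_var: np.ndarray
    ci_lower: np.ndarray
    ci_upper: np.ndarray

    def median(self) -> float:
        below = self.survival <= 0.5
        return float(self.event_times[below][0]) if below.any() else np.inf


def km_estimate(times, events) -> KMCurve:
    """Kaplan-Meier curve with Greenwood variance and 95% log-scale CI."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    if times.size == 0:
        raise ValueError("empty survival input")
    if (times < 0).any():
        raise ValueError("survival times must be >= 0")
    kmf = KaplanMeierFitter().fit(times, events)
    tab = kmf.event_table
    event_rows = tab[tab["observed"] > 0]
    t = event_rows.index.to_numpy(dtype=float)
    d = event_rows["observed"].to_numpy(dtype=float)
    n = event_rows["at_risk"].to_numpy(dtype=float)
    surv = np.cumprod(1.0 - d / n)
    # Greenwood: Var(S) = S^2 * cumsum(d / (n (n - d)))
    with np.errstate(divide="ignore", invalid="ignore"):
        inner = np.cumsum(np.where(n > d, d / (n * (n - d)), 0.0))
    var = surv**2 * inner
    ci = kmf.confidence_interval_survival_function_
    ci_at = ci.reindex(event_rows.index)
    return KMCurve(
        event_times=t,
        survival=surv,
        at_risk=n,
        greenwood_var=var,
        ci_lower=ci_at.iloc[:, 0].to_numpy(),
        ci_upper=ci_at.iloc[:, 1].to_numpy(),
    )


def logrank(survival_table: pd.DataFrame, group_col: str = "group") -> tuple[float, int, float]:
    """k-group log-rank test: (chi-square statistic, df = k - 1, p)."""
    df = survival_table
    groups = df[group_col].unique()
    res = multivariate_logrank_test(df["time"], df[group_col], df["event"])
    return float(res.test_statistic), len(groups) - 1, float(res.p_value)
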