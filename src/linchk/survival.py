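"""Stage 7: expression-stratified survival analysis.

Patients are split at an expression quantile (default the 75th
percentile: upper quartile vs lower three quartiles), survival curves
are estimated with the Kaplan-Meier product-limit estimator, and the
groups are compared with the log-rank test. Estimation and the test
are delegated to lifelines.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test as _ll_logrank

from .core import StatTestResult


def stratify_by_quantile(expr: pd.Series, q: float = 0.75) -> pd.Series:
    """Label patients 'high' iff expression strictly above the q-quantile.

    Linear-interpolation (type 7) quantile; ties at the threshold go to
    'low'.
    """
    x = expr.astype(float)
    if len(x) < 4:
        raise ValueError("need at least 4 patients to stratify")
    thr = float(np.quantile(x.to_numpy(), q))
    return pd.Series(np.where(x > thr, "high", "low"), index=x.index, name="group")


@dataclass
class KaplanMeierEstimate:
    """Right-continuous survival step function S(t)."""

    times: np.ndarray  # event times where the estimate drops
    survival: np.ndarray  # S(t) just after each time

    def __call__(self, t: float) -> float:
        idx = np.searchsorted(self.times, t, side="right") - 1
        if idx < 0:
            return 1.0
        return float(self.survival[idx])


def kaplan_meier(times, events) -> KaplanMeierEstimate:
    """Product-limit survival estimate.

    Censored subjects leave the risk set without dropping the curve;
    with no censoring the estimate equals empirical survival.
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    if events.sum() < 1:
        # all censored: flat survival at 1
        return KaplanMeierEstimate(np.array([]), np.array([]))
    kmf = KaplanMeierFitter()
    kmf.fit(times, event_observed=events)
    sf = kmf.survival_function_["KM_estimate"]
    t = sf.index.to_numpy(dtype=float)
    s = sf.to_numpy(dtype=float)
    keep = t > 0
    return KaplanMeierEstimate(t[keep], s[keep])


def logrank_test(records: pd.DataFrame, group_col: str = "group") -> StatTestResult:
    """Two-group log-rank test (1 df chi-square).

    ``records`` needs columns time, event and the group column with
    exactly two levels.
    """
    groups = sorted(records[group_col].unique())
    if len(groups) != 2:
        raise ValueError(f"need exactly 2 groups, got {groups}")
    a = records[records[group_col] == groups[0]]
    b = records[records[group_col] == groups[1]]
    if len(a) < 1 or len(b) < 1:
        raise ValueError("each group needs at least one subject")
    res = _ll_logrank(
        a["time"], b["time"], event_observed_A=a["event"], event_observed_B=b["event"]
    )
    return StatTestResult(float(res.test_statistic), float(res.p_value), "log-rank")


def survival_analysis(
    records: pd.DataFrame, expr_col: str = "expression", q: float = 0.75
) -> tuple[pd.Series, dict[str, KaplanMeierEstimate], StatTestResult]:
    """Stratify, estimate per-group KM curves and run the log-rank test."""
    groups = stratify_by_quantile(records[expr_col], q=q)
    df = records.assign(group=groups.to_numpy())
    curves = {
        g: kaplan_meier(sub["time"], sub["event"])
        for g, sub in df.groupby("group")
    }
    return groups, curves, logrank_test(df)
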