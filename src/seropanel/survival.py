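"""Kaplan-Meier estimation and the two-group log-rank test.

Implemented directly from the product-limit and hypergeometric-variance
formulas (the survival claims these support need nothing more).  The
convention for ties between censoring and events at the same time is the
standard one: events first, censored subjects remain at risk through that
time.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class KmCurve:
    """Product-limit estimate over the distinct event times.

    ``survival[i]`` is S(t) just after ``times[i]``; ``greenwood_var`` is
    the Greenwood variance of S at each step.
    """

    times: np.ndarray
    n_at_risk: np.ndarray
    n_events: np.ndarray
    survival: np.ndarray
    greenwood_var: np.ndarray

    def survival_at(self, t: float) -> float:
        """S(t): the step function evaluated at time t (S(0) = 1)."""
        idx = np.searchsorted(self.times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "time": self.times,
            "n_at_risk": self.n_at_risk,
            "n_events": self.n_events,
            "survival": self.survival,
            "greenwood_var": self.greenwood_var,
        })


def km_estimate(time, event) -> KmCurve:
    """Kaplan-Meier product-limit estimator.

    ``time`` are nonnegative follow-up times, ``event`` is 1 for an
    observed event and 0 for censoring.  Tied event times collapse into a
    single step whose event count is the multiplicity.
    """
    t = np.asarray(time, dtype=float)
    e = np.asarray(event, dtype=int)
    if len(t) == 0:
        raise ValueError("need at least one record")
    if (t < 0).any():
        raise ValueError("negative follow-up time")
    if set(np.unique(e)) - {0, 1}:
        raise ValueError("event flags must be 0/1")

    event_times = np.unique(t[e == 1])
    n_at_risk = np.empty(len(event_times), dtype=int)
    n_events = np.empty(len(event_times), dtype=int)
    surv = np.empty(len(event_times))
    gvar = np.empty(len(event_times))
    s = 1.0
    gsum = 0.0
    for i, et in enumerate(event_times):
        n = int((t >= et).sum())          # censored at et stay at risk through it
        d = int(((t == et) & (e == 1)).sum())
        n_at_risk[i] = n
        n_events[i] = d
        s *= 1.0 - d / n
        if n > d:
            gsum += d / (n * (n - d))
        surv[i] = s
        gvar[i] = s * s * gsum if n > d else 0.0
    return KmCurve(event_times, n_at_risk, n_events, surv, gvar)


@dataclass
class LogRankResult:
    observed: dict[str, float]
    expected: dict[str, float]
    variance: float
    statistic: float
    p: float
    flag: str | None = None


def logrank_test(time, event, group) -> LogRankResult:
    """Two-group log-rank test: chi-square on 1 df from the summed
    observed-minus-expected events under the hypergeometric variance."""
    t = np.asarray(time, dtype=float)
    e = np.asarray(event, dtype=int)
    g = np.asarray(group)
    labels = sorted(pd.unique(g).tolist())
    if len(labels) != 2:
        raise ValueError(f"log-rank test needs exactly two groups, got {labels}")
    if (t < 0).any():
        raise ValueError("negative follow-up time")
    in_a = g == labels[0]

    event_times = np.unique(t[e == 1])
    o_a = e_a = var = 0.0
    for et in event_times:
        at_risk = t >= et
        n = int(at_risk.sum())
        n_a = int((at_risk & in_a).sum())
        d = int(((t == et) & (e == 1)).sum())
        d_a = int(((t == et) & (e == 1) & in_a).sum())
        o_a += d_a
        e_a += d * n_a / n
        if n > 1:
            var += d * (n_a / n) * (1 - n_a / n) * (n - d) / (n - 1)

    total_events = float((e == 1).sum())
    observed = {labels[0]: o_a, labels[1]: total_events - o_a}
    expected = {labels[0]: e_a, labels[1]: total_events - e_a}
    if var == 0.0:
        return LogRankResult(observed, expected, 0.0, math.nan, math.nan,
                             flag="zero variance (no informative event times)")
    chi2 = (o_a - e_a) ** 2 / var
    p = float(stats.chi2.sf(chi2, df=1))
    return LogRankResult(observed, expected, var, float(chi2), p)


def dichotomize_expression(values, healthy_mean: float, fold: float = 2.0) -> np.ndarray:
    """Split subjects into "overexpressed" (value > fold x healthy mean)
    vs "normal" groups for survival comparisons."""
    if healthy_mean < 0:
        raise ValueError("healthy-group mean must be nonnegative")
    v = np.asarray(values, dtype=float)
    return np.where(v > fold * healthy_mean, "overexpressed", "normal")
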