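"""Kaplan-Meier estimation, log-rank testing and cutoff-stratified survival.

Follow-up is administratively censored at a fixed horizon (15 months in the
motivating design): subjects alive at the horizon carry ``event=0`` at the
horizon time, and subjects flagged lost to follow-up are excluded before
estimation.  Two hazard-ratio summaries are provided, as both circulate in
the applied literature: the O/E ratio ``(O_a/E_a)/(O_b/E_b)`` (default,
"log-rank HR") and the Mantel-Haenszel one-step estimate
``exp((O_a - E_a)/V)``.  Confidence intervals use the log-scale normal
approximation.

Deaths tied at one event time reduce the same risk set (simultaneous-event
convention); the hypergeometric variance carries the usual ``(n-d)/(n-1)``
tie correction.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .association import youden_cutoff

__all__ = [
    "KMCurve",
    "LogRankResult",
    "km_estimate",
    "median_survival",
    "logrank_test",
    "stratify_by_cutoff",
    "combined_strata",
]


@dataclass
class KMCurve:
    """Product-limit estimate: step function over the distinct event times."""

    times: np.ndarray        # distinct event (death) times, ascending
    survival: np.ndarray     # S(t) just after each event time
    at_risk: np.ndarray      # n_i at each event time
    events: np.ndarray       # d_i at each event time
    n_subjects: int

    def survival_at(self, t: float) -> float:
        """S(t) of the right-continuous step function."""
        s = 1.0
        for ti, si in zip(self.times, self.survival):
            if ti <= t:
                s = si
            else:
                break
        return float(s)


def _validate(times: Sequence[float], events: Sequence[int]) -> tuple[np.ndarray, np.ndarray]:
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=int)
    if t.size == 0:
        raise ValueError("no survival records")
    if t.shape != e.shape:
        raise ValueError("times and events must align")
    if np.any(t <= 0) or np.any(~np.isfinite(t)):
        raise ValueError("survival times must be positive and finite")
    if set(np.unique(e).tolist()) - {0, 1}:
        raise ValueError("event flags must be 0 (censored) or 1 (death)")
    return t, e


def km_estimate(times: Sequence[float], events: Sequence[int]) -> KMCurve:
    """Kaplan-Meier product-limit estimator S(t) = prod (1 - d_i/n_i)."""
    t, e = _validate(times, events)
    event_times = np.unique(t[e == 1])
    surv, at_risk, deaths = [], [], []
    s = 1.0
    for ti in event_times:
        n_i = int((t >= ti).sum())
        d_i = int(((t == ti) & (e == 1)).sum())
        s *= 1.0 - d_i / n_i
        surv.append(s)
        at_risk.append(n_i)
        deaths.append(d_i)
    return KMCurve(
        times=event_times,
        survival=np.asarray(surv, dtype=float),
        at_risk=np.asarray(at_risk, dtype=int),
        events=np.asarray(deaths, dtype=int),
        n_subjects=int(t.size),
    )


def median_survival(curve: KMCurve) -> float | None:
    """Smallest event time with S(t) <= 0.5, or None if never reached."""
    for ti, si in zip(curve.times, curve.survival):
        if si <= 0.5 + 1e-12:
            return float(ti)
    return None


@dataclass
class LogRankResult:
    chi_square: float
    p_value: float
    hazard_ratio: float          # group a vs group b
    ci_lower: float
    ci_upper: float
    observed: tuple[float, float]
    expected: tuple[float, float]
    variance: float
    variant: str                 # "oe" | "mantel-haenszel"


def logrank_test(times_a: Sequence[float], events_a: Sequence[int],
                 times_b: Sequence[float], events_b: Sequence[int],
                 hr_variant: str = "oe") -> LogRankResult:
    """Two-group log-rank test with an O/E or Mantel-Haenszel hazard ratio.

    At each distinct pooled event time a 2x2 table of deaths vs at-risk
    contributes observed minus hypergeometric-expected deaths and the
    matching variance; the chi-square statistic has one degree of freedom.
    """
    from scipy import stats

    ta, ea = _validate(times_a, events_a)
    tb, eb = _validate(times_b, events_b)
    pooled_t = np.concatenate([ta, tb])
    pooled_e = np.concatenate([ea, eb])
    group = np.concatenate([np.zeros(ta.size, dtype=bool), np.ones(tb.size, dtype=bool)])
    event_times = np.unique(pooled_t[pooled_e == 1])
    if event_times.size == 0:
        raise ValueError("no events in either group; log-rank test undefined")

    o_a = e_a = o_b = e_b = var = 0.0
    for ti in event_times:
        at_risk = pooled_t >= ti
        n = int(at_risk.sum())
        n_a = int((at_risk & ~group).sum())
        n_b = n - n_a
        dead = (pooled_t == ti) & (pooled_e == 1)
        d = int(dead.sum())
        d_a = int((dead & ~group).sum())
        o_a += d_a
        o_b += d - d_a
        e_a += d * n_a / n
        e_b += d * n_b / n
        if n > 1:
            var += d * (n_a / n) * (n_b / n) * (n - d) / (n - 1)
    if var == 0.0:
        raise ValueError("log-rank variance is zero; groups indistinguishable")
    chi2 = (o_a - e_a) ** 2 / var
    p = float(stats.chi2.sf(chi2, df=1))

    if hr_variant == "oe":
        if e_a == 0 or e_b == 0 or o_b == 0:
            hr = np.inf if o_a > 0 else np.nan
            lo = hi = np.nan
        else:
            hr = (o_a / e_a) / (o_b / e_b)
            se = np.sqrt(1.0 / e_a + 1.0 / e_b)
            lo, hi = hr * np.exp(-1.96 * se), hr * np.exp(1.96 * se)
    elif hr_variant == "mantel-haenszel":
        hr = float(np.exp((o_a - e_a) / var))
        lo = float(np.exp((o_a - e_a - 1.96 * np.sqrt(var)) / var))
        hi = float(np.exp((o_a - e_a + 1.96 * np.sqrt(var)) / var))
    else:
        raise ValueError("hr_variant must be 'oe' or 'mantel-haenszel'")

    return LogRankResult(
        chi_square=float(chi2), p_value=p, hazard_ratio=float(hr),
        ci_lower=float(lo), ci_upper=float(hi),
        observed=(o_a, o_b), expected=(e_a, e_b), variance=float(var),
        variant=hr_variant,
    )


def stratify_by_cutoff(values: pd.Series, labels: Sequence[int]
                       ) -> tuple[pd.Series, float]:
    """High/low strata at the Youden-optimal ROC cutoff on outcome labels.

    ``labels`` is the binary survival status (1 = died) used to place the
    cutoff; subjects with marker value strictly above the cutoff form the
    "high" stratum.  Returns (stratum labels aligned to ``values``, cutoff).
    """
    cutoff, _, _ = youden_cutoff(values.to_numpy(dtype=float), labels)
    strata = pd.Series(
        np.where(values.to_numpy(dtype=float) > cutoff, "high", "low"),
        index=values.index, name="stratum",
    )
    return strata, cutoff


def combined_strata(strata_1: pd.Series, strata_2: pd.Series) -> pd.Series:
    """Joint high/high vs low/low strata; discordant subjects are dropped.

    Restricting to the concordant extremes sharpens the contrast at the cost
    of sample size; raises if nobody is concordant.
    """
    joined = pd.concat([strata_1, strata_2], axis=1, join="inner")
    concordant = joined.iloc[:, 0] == joined.iloc[:, 1]
    if not bool(concordant.any()):
        raise ValueError("no subjects concordant on both markers")
    out = joined.loc[concordant].iloc[:, 0].map({"high": "high/high", "low": "low/low"})
    out.name = "stratum"
    return out
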