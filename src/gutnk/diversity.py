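"""Within-sample (alpha) diversity metrics for genus count vectors.

The five metrics used to characterise gut-community structure: Shannon
entropy and Simpson's index (diversity proper), Pielou and Simpson evenness,
and Strong's dominance index, which measures how far the cumulative
rank-abundance curve rises above the uniform expectation.

All metrics operate on a single sample's non-negative count vector; richness
``S`` counts only taxa observed (count > 0) in that sample.  Shannon and
Pielou default to log base 2, the q2-diversity convention, so raw values are
comparable with the wider amplicon ecosystem; the base is a parameter and
cancels once values are Z-standardised downstream.
"""

from __future__ import annotations

import math
from typing import Iterable

import numpy as np
import pandas as pd

__all__ = [
    "shannon",
    "simpson",
    "pielou_evenness",
    "simpson_evenness",
    "strong_dominance",
    "alpha_diversity_table",
    "ALPHA_METRICS",
]


def _as_counts(counts: Iterable[float]) -> np.ndarray:
    v = np.asarray(list(counts) if not isinstance(counts, np.ndarray) else counts, dtype=float)
    if v.ndim != 1:
        raise ValueError("count vector must be one-dimensional")
    if v.size == 0 or np.any(v < 0) or not np.all(np.isfinite(v)):
        raise ValueError("counts must be a non-empty vector of finite non-negative numbers")
    if v.sum() == 0:
        raise ValueError("all-zero count vector: diversity undefined")
    return v


def _proportions(counts: Iterable[float]) -> np.ndarray:
    v = _as_counts(counts)
    p = v / v.sum()
    return p[p > 0]


def shannon(counts: Iterable[float], log_base: float = 2.0) -> float:
    """Shannon entropy H = -sum p_i log_b p_i over observed taxa."""
    if log_base <= 1.0:
        raise ValueError("log_base must exceed 1")
    p = _proportions(counts)
    return float(-(p * (np.log(p) / math.log(log_base))).sum())


def simpson(counts: Iterable[float]) -> float:
    """Simpson's diversity D = 1 - sum p_i^2 (probability two draws differ)."""
    p = _proportions(counts)
    return float(1.0 - (p * p).sum())


def pielou_evenness(counts: Iterable[float], log_base: float = 2.0) -> float:
    """Pielou's J = H / log_b(S); undefined for a single observed taxon."""
    p = _proportions(counts)
    s = p.size
    if s < 2:
        raise ValueError("Pielou evenness undefined for richness S < 2")
    return shannon(counts, log_base) / (math.log(s) / math.log(log_base))


def simpson_evenness(counts: Iterable[float]) -> float:
    """Inverse-Simpson divided by richness: (1 / sum p_i^2) / S."""
    p = _proportions(counts)
    return float((1.0 / (p * p).sum()) / p.size)


def strong_dominance(counts: Iterable[float]) -> float:
    """Strong's dominance Dw = max_i (b_i/N - i/S).

    ``b_i`` is the cumulative count of the ``i`` most abundant observed taxa;
    uniform communities score 0, single-taxon dominance approaches 1.  Rank
    ties are irrelevant: cumulative sums are invariant to ordering within a
    tie.
    """
    v = _as_counts(counts)
    v = v[v > 0]
    s = v.size
    n = v.sum()
    b = np.cumsum(np.sort(v)[::-1])
    i = np.arange(1, s + 1)
    return float(np.max(b / n - i / s))


ALPHA_METRICS = ("shannon", "simpson", "pielou", "simpson_evenness", "strong")


def alpha_diversity_table(counts: pd.DataFrame, log_base: float = 2.0) -> pd.DataFrame:
    """Five alpha metrics for every row (sample) of a counts DataFrame."""
    rows = {}
    for sid, row in counts.iterrows():
        v = row.to_numpy(dtype=float)
        rows[sid] = {
            "shannon": shannon(v, log_base),
            "simpson": simpson(v),
            "pielou": pielou_evenness(v, log_base),
            "simpson_evenness": simpson_evenness(v),
            "strong": strong_dominance(v),
        }
    out = pd.DataFrame.from_dict(rows, orient="index")
    out.index.name = counts.index.name or "subject"
    return out[list(ALPHA_METRICS)]
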