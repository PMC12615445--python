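"""Composite percentile-bin scores: per-subset and global NK exhaustion, and
the microbiota dysbiosis score.

Every feature (a checkpoint percent-positive, an alpha-diversity metric, a
CLR abundance) is first Z-scored against the healthy-donor (HD) reference
distribution, then classified into an ordinal bin 1/2/3 by comparing it with
empirical percentile thresholds of that reference:

* ``one_sided`` (exhaustion default): values below the ``cut_lo`` reference
  percentile score 1, between ``cut_lo`` and ``cut_hi`` score 2, above score
  3 — higher receptor expression means a worse bin.
* ``two_sided`` (dysbiosis default): the comparison is applied to |Z|
  against the percentiles of the reference's own |Z| values, so deviation in
  either direction from the HD centre counts.

Bins for the six checkpoints are summed within each NK subset (range 6-18);
the global exhaustion score is the mean of the CD56dim and CD56bright subset
scores.  The dysbiosis score sums two-sided bins over its feature panel
(alpha metrics plus CLR abundances of taxa expanded or depleted in disease),
so it ranges over [k, 3k] for k features; a mean-normalised variant is
available for panels of different sizes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "CHECKPOINT_MARKERS",
    "NK_SUBSETS",
    "ReferenceDistribution",
    "BinRule",
    "fit_reference",
    "z_score",
    "bin_score",
    "subset_exhaustion_score",
    "global_exhaustion_score",
    "exhaustion_scores",
    "dysbiosis_score",
    "dysbiosis_scores",
]

CHECKPOINT_MARKERS = ("PD-1", "LAG-3", "BTLA", "TIM-3", "TIGIT", "NKG2A")
NK_SUBSETS = ("CD56dim", "CD56bright")


@dataclass(frozen=True)
class BinRule:
    """Percentile cuts and sidedness of the 1/2/3 classification."""

    mode: str = "one_sided"
    cut_lo: float = 66.7
    cut_hi: float = 90.0

    def __post_init__(self) -> None:
        if self.mode not in ("one_sided", "two_sided"):
            raise ValueError("mode must be 'one_sided' or 'two_sided'")
        if not (0.0 < self.cut_lo < self.cut_hi < 100.0):
            raise ValueError("require 0 < cut_lo < cut_hi < 100")


@dataclass
class ReferenceDistribution:
    """Per-feature healthy-donor summary: mean, SD (ddof=1), sorted values."""

    mean: Mapping[str, float]
    sd: Mapping[str, float]
    values: Mapping[str, np.ndarray]

    def __contains__(self, feature: str) -> bool:
        return feature in self.mean

    @property
    def features(self) -> list[str]:
        return list(self.mean)

    def n_reference(self, feature: str) -> int:
        return int(len(self.values[feature]))


def fit_reference(hd_values: pd.DataFrame) -> ReferenceDistribution:
    """Fit the HD reference from a subjects x features table of observations.

    Raises on fewer than two observations or on a constant feature: a zero
    HD standard deviation makes the Z-score undefined, and such features
    must be excluded (or jittered upstream) rather than silently floored.
    """
    mean, sd, values = {}, {}, {}
    for feature in hd_values.columns:
        v = np.sort(hd_values[feature].to_numpy(dtype=float))
        if v.size < 2:
            raise ValueError(f"feature {feature!r}: need >= 2 reference observations")
        if np.any(~np.isfinite(v)):
            raise ValueError(f"feature {feature!r}: non-finite reference value")
        s = float(np.std(v, ddof=1))
        if s == 0.0:
            raise ValueError(
                f"feature {feature!r} is constant in the reference; exclude it "
                "from the panel (SD=0 leaves the Z-score undefined)"
            )
        mean[feature] = float(np.mean(v))
        sd[feature] = s
        values[feature] = v
    return ReferenceDistribution(mean=mean, sd=sd, values=values)


def z_score(x: float, ref: ReferenceDistribution, feature: str) -> float:
    if feature not in ref:
        raise KeyError(f"feature {feature!r} not in reference")
    return (float(x) - ref.mean[feature]) / ref.sd[feature]


def _bin_thresholds(ref: ReferenceDistribution, rule: BinRule, feature: str
                    ) -> tuple[float, float]:
    """Z-scale thresholds at the rule's percentiles of the reference."""
    if feature not in ref:
        raise KeyError(f"feature {feature!r} not in reference")
    ref_z = (ref.values[feature] - ref.mean[feature]) / ref.sd[feature]
    if rule.mode == "two_sided":
        ref_z = np.abs(ref_z)
    t_lo = float(np.percentile(ref_z, rule.cut_lo))
    t_hi = float(np.percentile(ref_z, rule.cut_hi))
    return t_lo, t_hi


def bin_score(z: float, ref: ReferenceDistribution, rule: BinRule, feature: str) -> int:
    """Classify a Z-score into bin 1, 2 or 3 against the reference percentiles.

    Thresholds are the linear-interpolation percentiles of the reference
    Z-values (one_sided) or of their absolute values (two_sided); values at
    or below a threshold stay in the lower bin.
    """
    t_lo, t_hi = _bin_thresholds(ref, rule, feature)
    z = abs(float(z)) if rule.mode == "two_sided" else float(z)
    if z <= t_lo:
        return 1
    if z <= t_hi:
        return 2
    return 3


def _bin_column(values: np.ndarray, ref: ReferenceDistribution, rule: BinRule,
                feature: str) -> np.ndarray:
    """Vectorised bin_score over one feature column."""
    t_lo, t_hi = _bin_thresholds(ref, rule, feature)
    z = (np.asarray(values, dtype=float) - ref.mean[feature]) / ref.sd[feature]
    if rule.mode == "two_sided":
        z = np.abs(z)
    return np.where(z <= t_lo, 1, np.where(z <= t_hi, 2, 3))


def subset_exhaustion_score(bins: Mapping[str, int],
                            markers: Sequence[str] = CHECKPOINT_MARKERS) -> int:
    """Sum of the per-marker bins for one NK subset."""
    missing = [m for m in markers if m not in bins]
    if missing:
        raise KeyError(f"missing marker bin for {missing[0]!r}")
    return int(sum(int(bins[m]) for m in markers))


def global_exhaustion_score(s_dim: int, s_bright: int,
                            n_markers: int = len(CHECKPOINT_MARKERS)) -> float:
    """Mean of the two subset scores; inputs must lie in [n, 3n] markers."""
    lo, hi = n_markers, 3 * n_markers
    for s in (s_dim, s_bright):
        if not lo <= s <= hi:
            raise ValueError(f"subset score {s} outside [{lo}, {hi}]")
    return (s_dim + s_bright) / 2.0


def dysbiosis_score(subject_features: Mapping[str, float],
                    ref: ReferenceDistribution,
                    rule: BinRule | None = None,
                    features: Sequence[str] | None = None,
                    aggregate: str = "sum") -> float:
    """Composite dysbiosis score for one subject.

    Two-sided percentile bins over the configured feature panel, aggregated
    by sum (default, range [k, 3k]) or mean (range [1, 3]).
    """
    rule = rule or BinRule(mode="two_sided")
    features = list(features) if features is not None else ref.features
    if not features:
        raise ValueError("empty dysbiosis feature panel")
    bins = []
    for feature in features:
        if feature not in subject_features:
            raise KeyError(f"subject is missing feature {feature!r}")
        z = z_score(subject_features[feature], ref, feature)
        bins.append(bin_score(z, ref, rule, feature))
    if aggregate == "sum":
        return float(sum(bins))
    if aggregate == "mean":
        return float(np.mean(bins))
    raise ValueError("aggregate must be 'sum' or 'mean'")


# ---------------------------------------------------------------------------
# cohort-level conveniences


def _panel_column(marker: str, subset: str) -> str:
    return f"{marker}|{subset}"


def exhaustion_scores(panel: pd.DataFrame, ref: ReferenceDistribution,
                      rule: BinRule | None = None,
                      markers: Sequence[str] = CHECKPOINT_MARKERS) -> pd.DataFrame:
    """Subset and global exhaustion scores for every subject.

    ``panel`` holds percent-positive values in columns named
    ``"<marker>|<subset>"``; the reference must have been fitted on the same
    columns restricted to HD subjects.  Returns columns ``s_dim``,
    ``s_bright`` and ``global_score``.
    """
    rule = rule or BinRule(mode="one_sided")
    subset_sums = {}
    for subset in NK_SUBSETS:
        bins = np.zeros(len(panel), dtype=int)
        for m in markers:
            col = _panel_column(m, subset)
            bins += _bin_column(panel[col].to_numpy(), ref, rule, col)
        subset_sums[subset] = bins
    df = pd.DataFrame(
        {
            "s_dim": subset_sums["CD56dim"],
            "s_bright": subset_sums["CD56bright"],
            "global_score": (subset_sums["CD56dim"] + subset_sums["CD56bright"]) / 2.0,
        },
        index=panel.index,
    )
    df.index.name = panel.index.name or "subject"
    return df


def dysbiosis_scores(features: pd.DataFrame, ref: ReferenceDistribution,
                     rule: BinRule | None = None,
                     panel: Sequence[str] | None = None,
                     aggregate: str = "sum") -> pd.Series:
    """Dysbiosis score for every subject of a subjects x features table."""
    rule = rule or BinRule(mode="two_sided")
    panel = list(panel) if panel is not None else ref.features
    if not panel:
        raise ValueError("empty dysbiosis feature panel")
    missing = [f for f in panel if f not in features.columns]
    if missing:
        raise KeyError(f"subject table is missing feature {missing[0]!r}")
    bins = np.zeros((len(features), len(panel)), dtype=int)
    for j, f in enumerate(panel):
        bins[:, j] = _bin_column(features[f].to_numpy(), ref, rule, f)
    vals = bins.sum(axis=1).astype(float) if aggregate == "sum" else bins.mean(axis=1)
    if aggregate not in ("sum", "mean"):
        raise ValueError("aggregate must be 'sum' or 'mean'")
    s = pd.Series(vals, index=features.index, name="dysbiosis_score")
    s.index.name = features.index.name or "subject"
    return s
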