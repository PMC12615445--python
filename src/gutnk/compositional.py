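"""Compositional handling of taxa count tables: CLR transform, taxonomy
aggregation, and the five-ratio taxonomic panel.

Counts are compositional: only relative information is meaningful.  The
centered log-ratio (CLR) maps each sample's (pseudocounted) abundances to
real coordinates ``ln(x_i) - mean_j ln(x_j)`` that sum to zero, so
differences of CLR coordinates are log-abundance-ratios and are invariant to
sequencing depth.

The ratio panel reports five contrasts repeatedly informative for gut
dysbiosis in cervical cancer: Proteobacteria/Firmicutes and
Bacteroidota/Firmicutes at the phylum level, and Escherichia/Ruminococcus,
Prevotella/Ruminococcus and Escherichia/Erysipelotrichaceae UCG-003 at the
genus level.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

__all__ = [
    "TaxaCountTable",
    "aggregate_taxa",
    "clr_transform",
    "taxon_ratio",
    "ratio_panel",
    "RATIO_PANEL",
]

# (name, numerator, denominator, level); Escherichia is recorded in SILVA
# genus tables as "Escherichia-Shigella", aliased below.
RATIO_PANEL = (
    ("Proteobacteria/Firmicutes", "Proteobacteria", "Firmicutes", "phylum"),
    ("Bacteroidota/Firmicutes", "Bacteroidota", "Firmicutes", "phylum"),
    ("Escherichia/Ruminococcus", "Escherichia", "Ruminococcus", "genus"),
    ("Prevotella/Ruminococcus", "Prevotella", "Ruminococcus", "genus"),
    ("Escherichia/Erysipelotrichaceae UCG-003", "Escherichia",
     "Erysipelotrichaceae UCG-003", "genus"),
)

_ALIASES = {"Escherichia": "Escherichia-Shigella"}


def _norm(name: str) -> str:
    return " ".join(str(name).split())


@dataclass
class TaxaCountTable:
    """Samples x taxa non-negative integer counts plus a genus->phylum map."""

    counts: pd.DataFrame
    taxonomy: Mapping[str, str] = field(default_factory=dict)
    level: str = "genus"

    def __post_init__(self) -> None:
        counts = self.counts
        if counts.index.has_duplicates:
            raise ValueError("duplicate subject IDs in count table")
        if counts.columns.has_duplicates:
            raise ValueError("duplicate taxon names in count table")
        arr = counts.to_numpy()
        if arr.size and (not np.issubdtype(arr.dtype, np.number) or np.any(arr < 0)):
            raise ValueError("counts must be non-negative numbers")
        self.taxonomy = {_norm(g): _norm(p) for g, p in dict(self.taxonomy).items()}

    @property
    def subjects(self) -> list:
        return list(self.counts.index)

    @property
    def taxa(self) -> list[str]:
        return list(self.counts.columns)

    def resolve(self, name: str) -> str:
        """Resolve a taxon name against the table, honouring known aliases."""
        name = _norm(name)
        if name in self.counts.columns:
            return name
        alias = _ALIASES.get(name)
        if alias is not None and alias in self.counts.columns:
            return alias
        raise KeyError(f"taxon {name!r} not present in table")


def aggregate_taxa(table: TaxaCountTable, level: str) -> TaxaCountTable:
    """Sum genus counts into phyla via the taxonomy map; genus is identity."""
    if level == "genus":
        return table
    if level != "phylum":
        raise ValueError(f"unknown aggregation level {level!r}")
    missing = [g for g in table.taxa if _norm(g) not in table.taxonomy]
    if missing:
        raise KeyError(f"genus {missing[0]!r} has no phylum in the taxonomy map")
    phyla = [table.taxonomy[_norm(g)] for g in table.taxa]
    agg = table.counts.T.groupby(pd.Index(phyla, name="phylum"), sort=True).sum().T
    return TaxaCountTable(counts=agg, taxonomy=table.taxonomy, level="phylum")


def clr_transform(table: TaxaCountTable, pseudocount: float = 0.5) -> pd.DataFrame:
    """Row-wise CLR: ln(count+pseudocount) centered by the row mean log.

    With ``pseudocount=0`` every count must be strictly positive.  The
    geometric mean is taken over the full feature set of the table passed in
    (sub-compositional selections change CLR values and are deliberately not
    supported here).
    """
    if pseudocount < 0:
        raise ValueError("pseudocount must be non-negative")
    x = table.counts.to_numpy(dtype=float) + pseudocount
    if np.any(x <= 0):
        raise ValueError("zero counts require a positive pseudocount")
    logs = np.log(x)
    clr = logs - logs.mean(axis=1, keepdims=True)
    return pd.DataFrame(clr, index=table.counts.index, columns=table.counts.columns)


def taxon_ratio(clr: pd.DataFrame, numerator: str, denominator: str) -> pd.Series:
    """CLR difference = ln of the pseudocounted abundance ratio, per subject."""
    for name in (numerator, denominator):
        if name not in clr.columns:
            raise KeyError(f"feature {name!r} not present in CLR table")
    return clr[numerator] - clr[denominator]


def ratio_panel(table: TaxaCountTable, pseudocount: float = 0.5) -> pd.DataFrame:
    """The five named taxonomic ratios, one column each, one row per subject.

    Phylum ratios are computed on the phylum-aggregated CLR, genus ratios on
    the genus-level CLR; either way the geometric mean spans the full table
    at that level.
    """
    genus_clr = clr_transform(table, pseudocount)
    phylum_table = aggregate_taxa(table, "phylum")
    phylum_clr = clr_transform(phylum_table, pseudocount)
    out = {}
    for name, num, den, level in RATIO_PANEL:
        src, tbl = (phylum_clr, phylum_table) if level == "phylum" else (genus_clr, table)
        out[name] = taxon_ratio(src, tbl.resolve(num), tbl.resolve(den))
    return pd.DataFrame(out, index=table.counts.index)
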