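"""Readers and writers for the tabular interchange formats.

TSV for matrices (taxa counts, metadata, scores), long-format CSV for the
NK panel, JSON for nested results.  Writers prepend ``#``-prefixed
provenance comment lines (seed, config hash); readers skip them.  Subject
IDs are opaque strings.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .compositional import TaxaCountTable
from .scoring import NK_SUBSETS

__all__ = [
    "read_taxa_table", "write_taxa_table",
    "read_taxonomy", "write_taxonomy",
    "read_nk_panel", "write_nk_panel",
    "read_metadata", "write_metadata",
    "write_json", "provenance_header", "config_hash",
]


def config_hash(obj) -> str:
    blob = json.dumps(obj, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def provenance_header(seed: int | None = None, extra: Mapping[str, str] | None = None) -> str:
    lines = ["# generated by gutnk"]
    if seed is not None:
        lines.append(f"# seed: {seed}")
    for k, v in (extra or {}).items():
        lines.append(f"# {k}: {v}")
    return "\n".join(lines) + "\n"


def _write_with_header(df: pd.DataFrame, path: Path, sep: str,
                       seed: int | None, extra: Mapping[str, str] | None) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(provenance_header(seed, extra))
        df.to_csv(fh, sep=sep)


def _read_table(path: Path, sep: str) -> pd.DataFrame:
    return pd.read_csv(path, sep=sep, comment="#", index_col=0)


def write_taxa_table(table: TaxaCountTable | pd.DataFrame, path: Path,
                     seed: int | None = None) -> None:
    df = table.counts if isinstance(table, TaxaCountTable) else table
    _write_with_header(df, path, "\t", seed, None)


def read_taxa_table(path: Path, taxonomy: Mapping[str, str] | None = None) -> TaxaCountTable:
    """Read a subjects x genera TSV into a validated count table."""
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            if not line.startswith("#"):
                header = line.rstrip("\n").split("\t")[1:]
                break
        else:
            raise ValueError(f"{path}: empty taxa table")
    if len(header) != len(set(header)):
        raise ValueError(f"{path}: duplicate genus columns")
    df = _read_table(path, "\t")
    if df.index.has_duplicates:
        raise ValueError(f"{path}: duplicate subject IDs")
    arr = df.to_numpy()
    if not np.issubdtype(arr.dtype, np.number):
        bad = df.columns[[not np.issubdtype(df[c].dtype, np.number) for c in df.columns]]
        raise ValueError(f"{path}: non-numeric counts in column {bad[0]!r}")
    if np.any(arr < 0):
        i, j = np.argwhere(arr < 0)[0]
        raise ValueError(
            f"{path}: negative count at row {df.index[i]!r}, column {df.columns[j]!r}")
    return TaxaCountTable(counts=df, taxonomy=taxonomy or {})


def write_taxonomy(taxonomy: Mapping[str, str], path: Path) -> None:
    df = pd.DataFrame(sorted(taxonomy.items()), columns=["genus", "phylum"])
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=False)


def read_taxonomy(path: Path) -> dict[str, str]:
    df = pd.read_csv(path, sep="\t", comment="#")
    if not {"genus", "phylum"} <= set(df.columns):
        raise ValueError(f"{path}: taxonomy file needs 'genus' and 'phylum' columns")
    return dict(zip(df["genus"], df["phylum"]))


def write_nk_panel(panel: pd.DataFrame, path: Path, seed: int | None = None) -> None:
    """Write the wide "marker|subset" panel as a long (subject, subset, marker,
    percent) CSV."""
    records = []
    for sid, row in panel.iterrows():
        for col, val in row.items():
            marker, subset = str(col).rsplit("|", 1)
            records.append((sid, subset, marker, val))
    long = pd.DataFrame(records, columns=["subject", "subset", "marker", "percent"])
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(provenance_header(seed, None))
        long.to_csv(fh, index=False)


def read_nk_panel(path: Path) -> pd.DataFrame:
    """Read a long NK-panel CSV and pivot to wide "marker|subset" columns."""
    long = pd.read_csv(path, comment="#")
    required = {"subject", "subset", "marker", "percent"}
    if not required <= set(long.columns):
        raise ValueError(f"{path}: NK panel needs columns {sorted(required)}")
    bad_subset = set(long["subset"]) - set(NK_SUBSETS)
    if bad_subset:
        raise ValueError(f"{path}: unknown NK subset {sorted(bad_subset)[0]!r}")
    out_of_range = long[(long["percent"] < 0) | (long["percent"] > 100)]
    if len(out_of_range):
        r = out_of_range.iloc[0]
        raise ValueError(
            f"{path}: percent {r['percent']} out of [0,100] for subject "
            f"{r['subject']!r}, marker {r['marker']!r}")
    wide = long.pivot_table(index="subject", columns=["marker", "subset"],
                            values="percent", aggfunc="first", observed=True)
    if wide.isna().any().any():
        col = wide.columns[wide.isna().any()][0]
        sid = wide.index[wide[col].isna()][0]
        raise ValueError(
            f"{path}: subject {sid!r} is missing marker {col[0]!r} for subset {col[1]!r}")
    wide.columns = [f"{m}|{s}" for m, s in wide.columns]
    # preserve first-appearance subject order from the file
    order = list(dict.fromkeys(long["subject"]))
    return wide.loc[order]


def write_metadata(metadata: pd.DataFrame, path: Path, seed: int | None = None) -> None:
    _write_with_header(metadata, path, "\t", seed, None)


def read_metadata(path: Path) -> pd.DataFrame:
    df = _read_table(path, "\t")
    required = {"group", "time_months", "event", "lost_to_followup"}
    if not required <= set(df.columns):
        raise ValueError(f"{path}: metadata needs columns {sorted(required)}")
    return df


def write_json(obj, path: Path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)

    def _default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        raise TypeError(f"not JSON serialisable: {type(o)}")

    path.write_text(json.dumps(obj, indent=2, default=_default) + "\n", encoding="utf-8")
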