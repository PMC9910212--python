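"""Metadata-driven aggregation of IS data and metadata (SQL GROUP BY semantics).

Aggregation collapses PCR replicates into biological samples, samples into
tissues, tissues into whole patients — whatever level of granularity the
analysis needs — by grouping on a list of metadata fields (the *key*,
acting as a superkey for output groups) and reducing quantification values
with registered functions (default: sum).  A clone observed in a single
member of a group is present in the aggregate with that member's value.
"""

from __future__ import annotations

from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd

from .data_model import ANNOTATION_COLUMNS, REPLICATE_ID

#: Sentinel under which rows with a missing key value are grouped (reported,
#: never silently dropped).
MISSING_KEY = "<missing>"

# values are pandas aggregation aliases or callables
REDUCERS: dict[str, Callable | str] = {
    "sum": "sum",
    "mean": "mean",
    "median": "median",
    "sd": "std",
    "min": "min",
    "max": "max",
    "count": "count",
    "distinct_count": "nunique",
}


def register_reducer(name: str, func: Callable) -> None:
    """Attach a user-defined reducer usable by name in aggregation calls."""
    REDUCERS[name] = func


def _resolve_reducers(names: Sequence[str | Callable]) -> list[tuple[str, Callable]]:
    out = []
    for r in names:
        if callable(r):
            out.append((getattr(r, "__name__", "custom"), r))
        elif r in REDUCERS:
            out.append((r, REDUCERS[r]))
        else:
            raise ValueError(f"unknown reducer {r!r}; registered: {sorted(REDUCERS)}")
    return out


def aggregate_values_by_key(
    m: pd.DataFrame,
    meta: pd.DataFrame,
    key: Sequence[str],
    reducers: Mapping[str, Sequence[str | Callable]] | None = None,
    id_col: str = REPLICATE_ID,
) -> pd.DataFrame:
    """Group IS values by metadata key fields and reduce per quantification kind.

    Left-joins the long matrix to metadata on the replicate id, groups by
    (event, key fields) and applies each reducer to each kind's values.
    With a single reducer the output keeps the long layout with the key
    fields replacing the replicate id; with several reducers the value
    column is named ``value_<reducer>``.

    Raises if any matrix replicate id lacks a metadata row, or a key field
    is unknown.
    """
    bad = [k for k in key if k not in meta.columns]
    if bad:
        raise ValueError(f"unknown aggregation key field(s): {bad}")
    orphans = sorted(set(m[id_col]) - set(meta[id_col]))
    if orphans:
        raise ValueError(f"replicate ids missing from metadata: {orphans}")
    if reducers is None:
        reducers = {k: ["sum"] for k in m["kind"].unique()}

    ann = meta[list(dict.fromkeys([id_col] + list(key)))].copy()
    for k in key:
        if k != id_col:
            ann[k] = ann[k].where(ann[k].notna(), MISSING_KEY)
    j = m.merge(ann, on=id_col, how="left", suffixes=("", "_meta"))

    ev_cols = [c for c in ANNOTATION_COLUMNS if c in m.columns]
    pieces = []
    for kind, sub in j.groupby("kind", sort=True):
        funcs = _resolve_reducers(reducers.get(kind, ["sum"]))
        grouped = sub.groupby(ev_cols + list(key), dropna=False)["value"]
        agg = grouped.agg(**{f"value_{name}": func for name, func in funcs}).reset_index()
        agg.insert(len(ev_cols) + len(key), "kind", kind)
        pieces.append(agg)
    out = pd.concat(pieces, ignore_index=True)
    if set(c for c in out.columns if c.startswith("value_")) == {"value_sum"} and all(
        [n for n, _ in _resolve_reducers(v)] == ["sum"] for v in reducers.values()
    ):
        out = out.rename(columns={"value_sum": "value"})
    return out.sort_values(
        ["kind"] + ev_cols[:2] + list(key), kind="mergesort"
    ).reset_index(drop=True)


def default_meta_reducers(meta: pd.DataFrame, key: Sequence[str], id_col: str) -> dict:
    """Defaults: numeric fields -> sum and mean; dates -> min; ids -> distinct count."""
    plan: dict[str, list[str]] = {}
    for col in meta.columns:
        if col in key:
            continue
        series = meta[col]
        if col == id_col:
            plan[col] = ["distinct_count"]
        elif pd.api.types.is_numeric_dtype(series):
            plan[col] = ["sum", "mean"]
        elif pd.api.types.is_datetime64_any_dtype(series) or "date" in col.lower():
            plan[col] = ["min"]
        else:
            plan[col] = ["distinct_count"]
    return plan


def aggregate_metadata(
    meta: pd.DataFrame,
    key: Sequence[str],
    reducers: Mapping[str, Sequence[str | Callable]] | None = None,
    id_col: str = REPLICATE_ID,
) -> pd.DataFrame:
    """One row per key tuple, with each field reduced per the plan.

    Output columns are ``<field>_<reducer>``.  A reducer applied to an
    incompatible field type raises.
    """
    bad = [k for k in key if k not in meta.columns]
    if bad:
        raise ValueError(f"unknown aggregation key field(s): {bad}")
    if meta.empty:
        return pd.DataFrame(columns=list(key))
    if reducers is None:
        reducers = default_meta_reducers(meta, key, id_col)

    grouped = meta.groupby(list(key), dropna=False)
    pieces = {}
    for field, names in reducers.items():
        if field not in meta.columns:
            raise ValueError(f"unknown metadata field {field!r}")
        numeric_only = {"sum", "mean", "median", "sd"}
        for name, func in _resolve_reducers(names):
            if name in numeric_only and not pd.api.types.is_numeric_dtype(meta[field]):
                raise ValueError(f"reducer '{name}' incompatible with non-numeric field '{field}'")
            pieces[f"{field}_{name}"] = grouped[field].agg(func)
    out = pd.DataFrame(pieces).reset_index()
    return out
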