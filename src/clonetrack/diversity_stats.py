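"""Descriptive statistics, diversity/evenness indices and clonal abundance.

Clonal diversity is the standard safety read-out of a gene-therapy graft: a
healthy polyclonal reconstitution shows high Shannon diversity and Pielou
evenness near 1, while a clonal expansion drives both down.  Indices are
computed on the per-group quantification vectors of aggregated matrices
(one value per clone), using natural logarithms by default so that
Pielou's J = H / ln S is consistent.

Relative clonal abundance is each clone's fraction (in percent) of the
group total; the stream-graph convention highlights clones exceeding a
threshold (1% by default) at any time point.
"""

from __future__ import annotations

import math
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .data_model import ANNOTATION_COLUMNS, REPLICATE_ID, event_columns

DIVERSITY_INDICES = ("shannon", "simpson", "invsimpson", "renyi", "pielou", "dominance")

STAT_FUNCTIONS = {
    "count": len,
    "sum": np.sum,
    "mean": np.mean,
    "median": np.median,
    "sd": lambda v: np.std(v, ddof=1) if len(v) > 1 else np.nan,
    "skew": lambda v: sps.skew(v, bias=False) if len(v) > 2 else np.nan,
    "kurtosis": lambda v: sps.kurtosis(v, bias=False) if len(v) > 3 else np.nan,
    "min": np.min,
    "max": np.max,
}


def _proportions(values: Sequence[float]) -> np.ndarray:
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValueError("empty value vector")
    if (v <= 0).any():
        raise ValueError("diversity indices require strictly positive values")
    return v / v.sum()


def diversity_index(
    values: Sequence[float],
    index: str = "shannon",
    q: float | None = None,
    base: float = math.e,
) -> float:
    """Diversity / evenness index of a clone-size vector.

    With p_i = v_i / sum(v):

    * ``shannon``     H = -sum p_i log p_i
    * ``simpson``     1 - sum p_i^2       (complement; probability two cells
      drawn at random belong to different clones)
    * ``dominance``   sum p_i^2
    * ``invsimpson``  1 / sum p_i^2
    * ``renyi``       log(sum p_i^q) / (1 - q) for order ``q`` != 1;
      continuous at q = 1 where it equals H
    * ``pielou``      J = H / log S, undefined (NaN) for S = 1

    Logarithms use ``base`` (natural log by default).
    """
    p = _proportions(values)
    log = lambda x: np.log(x) / np.log(base)
    if index == "shannon":
        return float(-(p * log(p)).sum())
    if index == "simpson":
        return float(1.0 - (p**2).sum())
    if index == "dominance":
        return float((p**2).sum())
    if index == "invsimpson":
        return float(1.0 / (p**2).sum())
    if index == "renyi":
        if q is None:
            raise ValueError("renyi requires an order q")
        if q == 1:
            return float(-(p * log(p)).sum())
        return float(log((p**q).sum()) / (1.0 - q))
    if index == "pielou":
        s = p.size
        if s == 1:
            return float("nan")
        h = -(p * log(p)).sum()
        return float(h / log(s))
    raise ValueError(f"unknown index {index!r}; available: {DIVERSITY_INDICES}")


def sample_statistics(
    m: pd.DataFrame,
    meta: pd.DataFrame,
    key: Sequence[str],
    functions: Sequence[str] = ("count", "sum", "mean", "median", "sd"),
    diversity: Sequence[str] = ("shannon", "simpson"),
    strand_aware: bool = True,
    id_col: str = REPLICATE_ID,
) -> pd.DataFrame:
    """Per-group descriptive statistics plus distinct-IS count.

    One output row per key tuple; per quantification kind, one column per
    requested statistic (``<kind>_<stat>``) and diversity index.  Statistics
    undefined for the group size (e.g. sd of one value) are missing.
    """
    unknown = [f for f in functions if f not in STAT_FUNCTIONS]
    if unknown:
        raise ValueError(f"unknown statistic(s) {unknown}; available: {sorted(STAT_FUNCTIONS)}")
    unknown = [d for d in diversity if d not in DIVERSITY_INDICES]
    if unknown:
        raise ValueError(f"unknown diversity index(es) {unknown}")
    bad = [k for k in key if k not in meta.columns]
    if bad:
        raise ValueError(f"unknown key field(s): {bad}")

    j = m.merge(meta[[id_col] + list(key)], on=id_col, how="left")
    ev_cols = event_columns(strand_aware)
    rows = []
    for kt, grp in j.groupby(list(key), dropna=False):
        kt = kt if isinstance(kt, tuple) else (kt,)
        row = dict(zip(key, kt))
        row["distinct_is"] = int(grp.drop_duplicates(ev_cols).shape[0])
        for kind, sub in grp.groupby("kind"):
            v = sub["value"].to_numpy(dtype=float)
            for fname in functions:
                row[f"{kind}_{fname}"] = STAT_FUNCTIONS[fname](v)
            pos = v[v > 0]
            for dname in diversity:
                row[f"{kind}_{dname}"] = (
                    diversity_index(pos, dname, q=2 if dname == "renyi" else None)
                    if pos.size
                    else np.nan
                )
        rows.append(row)
    return pd.DataFrame(rows)


def compute_abundance(
    m: pd.DataFrame,
    meta: pd.DataFrame | None = None,
    key: Sequence[str] | None = None,
    quantification: str = "seqCount",
    id_col: str = REPLICATE_ID,
) -> pd.DataFrame:
    """Relative clonal abundance per group: 100 * value / group total.

    Groups are key tuples after joining metadata, or the replicate id itself
    when no key is given.  Groups whose total is zero are skipped with a
    warning column in the result's attrs.
    """
    sub = m[m["kind"] == quantification].copy()
    if key:
        if meta is None:
            raise ValueError("metadata required when a key is given")
        sub = sub.merge(meta[[id_col] + list(key)], on=id_col, how="left")
        group_cols = list(key)
    else:
        group_cols = [id_col]
    totals = sub.groupby(group_cols, dropna=False)["value"].transform("sum")
    skipped = sub.loc[totals == 0, group_cols].drop_duplicates()
    sub = sub[totals > 0].copy()
    sub["relative_abundance"] = 100.0 * sub["value"] / totals[totals > 0]
    sub.attrs["skipped_groups"] = skipped.to_dict("records")
    return sub.reset_index(drop=True)


def top_clones(
    abundance: pd.DataFrame,
    threshold_pct: float = 1.0,
    timepoint_col: str = "timepoint",
    strand_aware: bool = True,
) -> pd.DataFrame:
    """Flag clones whose abundance exceeds the threshold at any time point.

    Adds a boolean ``flagged`` column: True for events in the ribbon set
    (relative abundance > ``threshold_pct`` in >= 1 time point), False for
    the background stratum.
    """
    ev_cols = event_columns(strand_aware)
    out = abundance.copy()
    peak = out.groupby(ev_cols, dropna=False)["relative_abundance"].transform("max")
    out["flagged"] = peak > threshold_pct
    return out
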