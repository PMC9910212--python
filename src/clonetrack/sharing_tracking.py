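"""Integration-site sharing across groups and first-source tracking.

Sharing is pure set algebra on event identity: for a tuple of groups it
reports the size of the intersection, the percentage it represents of each
group and of the union, optionally the shared coordinates and a truth table
(one membership vector per union member) for Venn/Euler plotting.

:func:`iss_source` tracks shared clones back to the first time point they
were observed in a reference series, yielding stacked-bar data of how much
each earlier time point contributes to each later one.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations, permutations
from typing import Sequence

import pandas as pd

from .data_model import REPLICATE_ID, event_columns

MAX_VENN_SETS = 5


@dataclass
class SharingRow:
    group_ids: tuple
    shared_count: int
    on_each: dict  # group id -> percent of that group's events shared
    on_union: float
    is_coordinates: list | None = None
    truth_table: pd.DataFrame | None = field(default=None, repr=False)


def group_event_sets(
    m: pd.DataFrame,
    meta: pd.DataFrame | None = None,
    key: Sequence[str] | None = None,
    strand_aware: bool = True,
    id_col: str = REPLICATE_ID,
) -> dict[str, frozenset]:
    """Map each group label to its set of distinct integration events."""
    ev_cols = event_columns(strand_aware)
    if key:
        if meta is None:
            raise ValueError("metadata required when a key is given")
        j = m.merge(meta[[id_col] + list(key)], on=id_col, how="left")
        j["_group"] = j[list(key)].astype(str).agg("|".join, axis=1)
    else:
        j = m.copy()
        j["_group"] = j[id_col].astype(str)
    out = {}
    for g, grp in j.groupby("_group", dropna=False):
        out[str(g)] = frozenset(map(tuple, grp[ev_cols].drop_duplicates().to_numpy()))
    return out


def share_sets(
    sets: dict[str, frozenset],
    group_ids: Sequence[str],
    keep_coords: bool = False,
    make_truth_table: bool = False,
) -> SharingRow:
    """Sharing statistics for one tuple of groups."""
    members = [sets[g] for g in group_ids]
    inter = frozenset.intersection(*members)
    union = frozenset.union(*members)
    row = SharingRow(
        group_ids=tuple(group_ids),
        shared_count=len(inter),
        on_each={
            g: (100.0 * len(inter) / len(s) if len(s) else 0.0)
            for g, s in zip(group_ids, members)
        },
        on_union=100.0 * len(inter) / len(union) if union else 0.0,
    )
    if keep_coords:
        row.is_coordinates = sorted(inter)
    if make_truth_table:
        rows = [
            {"event": ev, **{g: ev in s for g, s in zip(group_ids, members)}}
            for ev in sorted(union)
        ]
        row.truth_table = pd.DataFrame(rows)
    return row


def is_sharing(
    matrices: pd.DataFrame | Sequence[pd.DataFrame],
    meta: pd.DataFrame | Sequence[pd.DataFrame] | None = None,
    keys: Sequence[str] | Sequence[Sequence[str]] | None = None,
    mode: str = "combinations",
    n_way: int = 2,
    keep_coords: bool = False,
    make_truth_tables: bool = False,
    venn: bool = False,
    strand_aware: bool = True,
    id_col: str = REPLICATE_ID,
) -> list[SharingRow]:
    """All pairwise (or n-way) sharing rows over the groups of the inputs.

    One or more matrices can be given, each with its own grouping key;
    group labels are pooled across inputs.  ``mode="permutations"`` emits
    ordered duplicates (needed for square heatmaps); ``"combinations"``
    emits each unordered tuple once.  Self-pairs (g vs g) are included in
    permutations mode only, on the heatmap-diagonal convention.
    """
    if n_way < 2:
        raise ValueError("n_way must be >= 2")
    if venn and n_way > MAX_VENN_SETS:
        raise ValueError(f"Venn plots have a maximum limit of {MAX_VENN_SETS} sets")
    if mode not in ("combinations", "permutations"):
        raise ValueError("mode must be 'combinations' or 'permutations'")

    if isinstance(matrices, pd.DataFrame):
        matrices = [matrices]
        meta = [meta]
        keys = [keys]
    elif meta is None or isinstance(meta, pd.DataFrame):
        meta = [meta] * len(matrices)
    if keys is None or (keys and isinstance(keys[0], str)):
        keys = [keys] * len(matrices)

    sets: dict[str, frozenset] = {}
    for m, mt, k in zip(matrices, meta, keys):
        for g, s in group_event_sets(m, mt, k, strand_aware, id_col).items():
            sets[g] = sets.get(g, frozenset()) | s

    labels = sorted(sets)
    if len(labels) < n_way and mode == "combinations":
        return []
    tuples = (
        permutations(labels, n_way)
        if mode == "permutations"
        else combinations(labels, n_way)
    )
    rows = [
        share_sets(sets, t, keep_coords, make_truth_tables) for t in tuples
    ]
    if mode == "permutations":
        rows += [
            share_sets(sets, (g,) * n_way, keep_coords, make_truth_tables)
            for g in labels
        ]
        rows.sort(key=lambda r: r.group_ids)
    return rows


def sharing_to_frame(rows: list[SharingRow]) -> pd.DataFrame:
    """Flat TSV-ready view: one row per comparison."""
    recs = []
    for r in rows:
        rec = {f"g{i + 1}": g for i, g in enumerate(r.group_ids)}
        rec["shared_count"] = r.shared_count
        for i, g in enumerate(r.group_ids):
            rec[f"on_g{i + 1}_pct"] = r.on_each[g]
        rec["on_union_pct"] = r.on_union
        recs.append(rec)
    return pd.DataFrame(recs)


def sharing_heatmap_matrix(
    rows: list[SharingRow], value: str = "shared_count"
) -> pd.DataFrame:
    """Square matrix (groups x groups) of pairwise sharing, for heatmaps.

    ``value``: ``shared_count``, ``on_row_pct`` (percent of the row group)
    or ``on_union_pct``.  Requires 2-way permutation-mode rows.
    """
    labels = sorted({g for r in rows for g in r.group_ids})
    mat = pd.DataFrame(index=labels, columns=labels, dtype=float)
    for r in rows:
        if len(r.group_ids) != 2:
            raise ValueError("heatmap requires 2-way sharing rows")
        g1, g2 = r.group_ids
        if value == "shared_count":
            mat.loc[g1, g2] = r.shared_count
        elif value == "on_row_pct":
            mat.loc[g1, g2] = r.on_each[g1]
        elif value == "on_union_pct":
            mat.loc[g1, g2] = r.on_union
        else:
            raise ValueError(f"unknown value {value!r}")
    return mat


def iss_source(
    reference: pd.DataFrame,
    meta: pd.DataFrame,
    timepoint_col: str = "timepoint",
    strand_aware: bool = True,
    id_col: str = REPLICATE_ID,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Label each event with the first time point it was observed in.

    Returns (sources, stacked):

    * ``sources`` — one row per distinct event with its ``source_timepoint``
      (the minimum observation time point);
    * ``stacked`` — stacked-bar data: for each observed time point, how many
      events present there trace back to each source time point.
    """
    if timepoint_col not in meta.columns:
        raise ValueError(f"metadata lacks time point field '{timepoint_col}'")
    ev_cols = event_columns(strand_aware)
    j = reference.merge(meta[[id_col, timepoint_col]], on=id_col, how="left")
    j[timepoint_col] = pd.to_numeric(j[timepoint_col])
    obs = j.drop_duplicates(ev_cols + [timepoint_col])
    sources = (
        obs.groupby(ev_cols, dropna=False)[timepoint_col]
        .min()
        .rename("source_timepoint")
        .reset_index()
    )
    stacked = (
        obs.merge(sources, on=ev_cols)
        .groupby([timepoint_col, "source_timepoint"])
        .size()
        .rename("n_events")
        .reset_index()
        .rename(columns={timepoint_col: "observed_timepoint"})
    )
    return sources, stacked
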