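"""Recalibration: merge integration events that wobble within a few bp.

Alignment noise can shift the reported locus of the same true insertion by a
handful of base pairs between sequencing pools, which would break clone
tracking across time points.  Events on the same chromosome (and strand, in
strand-aware mode) whose loci differ by less than a threshold (default 4 bp,
i.e. wobble within +/-3 bp) are condensed into a single event whose
quantifications are the sums over the merged members.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .data_model import ANNOTATION_COLUMNS, REPLICATE_ID, event_columns

DEFAULT_THRESHOLD = 4  # bp; events are "near" iff |locus_x - locus_y| < threshold


def distance(x: int, y: int) -> int:
    """Distance between two loci on the same chromosome (and strand): |x - y|."""
    return abs(int(x) - int(y))


def _cluster_partition(loci: np.ndarray, threshold: int) -> np.ndarray:
    """Anchor clustering of sorted loci.

    The first unclustered event opens a cluster (anchor); following events
    join while their distance *to the anchor* is < threshold.  An event at
    distance >= threshold starts a new anchor.  Returns a cluster id per
    locus (input must be ascending).
    """
    ids = np.empty(len(loci), dtype=np.int64)
    cluster = -1
    anchor = None
    for i, locus in enumerate(loci):
        if anchor is None or locus - anchor >= threshold:
            cluster += 1
            anchor = locus
        ids[i] = cluster
    return ids


def compute_near_integrations(
    m: pd.DataFrame,
    threshold: int = DEFAULT_THRESHOLD,
    criterion: str = "max_value",
    strand_aware: bool = True,
    emit_map: bool = True,
    id_col: str = REPLICATE_ID,
) -> tuple[pd.DataFrame, pd.DataFrame | None]:
    """Merge near events and return (recalibrated matrix, recalibration map).

    Within each (chromosome[, strand]) partition, events sorted by locus are
    clustered with a sliding anchor window (see :func:`_cluster_partition`).
    Each cluster collapses to one representative event; per-replicate,
    per-kind values of the members are summed.

    criterion
        ``"max_value"`` — representative is the member with the largest total
        quantification across replicates and kinds (tie: lowest locus);
        ``"keep_first"`` — the lowest-locus member (the anchor).

    The map (when ``emit_map``) has one row per input event:
    chr/locus/strand before -> after.
    """
    if threshold < 1:
        raise ValueError("threshold must be >= 1")
    if criterion not in ("max_value", "keep_first"):
        raise ValueError(f"unknown criterion {criterion!r}")

    ev_cols = event_columns(strand_aware)
    part_cols = [c for c in ev_cols if c != "integration_locus"]
    if m.empty:
        empty_map = pd.DataFrame(
            columns=[f"{c}_before" for c in ev_cols] + [f"{c}_after" for c in ev_cols]
        )
        return m.copy(), (empty_map if emit_map else None)

    events = m.drop_duplicates(ev_cols)[ev_cols].copy()
    # total support per event, for the max_value representative rule
    support = (
        m.groupby(ev_cols, dropna=False)["value"].sum().rename("_support").reset_index()
    )
    events = events.merge(support, on=ev_cols, how="left")
    events = events.sort_values(part_cols + ["integration_locus"], kind="mergesort")

    reps = []
    for _, part in events.groupby(part_cols, dropna=False, sort=False):
        cl = _cluster_partition(part["integration_locus"].to_numpy(), threshold)
        part = part.assign(_cluster=cl)
        for _, members in part.groupby("_cluster", sort=False):
            if criterion == "keep_first":
                rep = members.iloc[0]
            else:
                best = members["_support"].max()
                cand = members[members["_support"] == best]
                rep = cand.sort_values("integration_locus").iloc[0]
            rec = members[ev_cols].copy()
            for c in ev_cols:
                rec[f"{c}_after"] = rep[c]
            reps.append(rec)

    mapping = pd.concat(reps, ignore_index=True)
    mapping = mapping.rename(columns={c: f"{c}_before" for c in ev_cols})

    after_cols = [f"{c}_after" for c in ev_cols]
    joined = m.merge(
        mapping,
        left_on=ev_cols,
        right_on=[f"{c}_before" for c in ev_cols],
        how="left",
    )
    joined = joined.drop(columns=ev_cols + [f"{c}_before" for c in ev_cols])
    joined = joined.rename(columns={f"{c}_after": c for c in ev_cols})

    # gene annotation is inherited from the representative member
    gene_cols = [c for c in ("GeneName", "GeneStrand") if c in m.columns]
    if gene_cols:
        rep_ann = (
            m.merge(mapping, left_on=ev_cols, right_on=[f"{c}_before" for c in ev_cols])
            .loc[lambda d: np.all(
                [d[c] == d[f"{c}_after"] for c in ev_cols], axis=0
            )]
            .drop_duplicates([f"{c}_after" for c in ev_cols])[after_cols + gene_cols]
            .rename(columns={f"{c}_after": c for c in ev_cols})
        )
        joined = joined.drop(columns=gene_cols).merge(rep_ann, on=ev_cols, how="left")

    group_cols = list(dict.fromkeys(ev_cols + gene_cols))
    out = (
        joined.groupby(group_cols + [id_col, "kind"], dropna=False)["value"]
        .sum()
        .reset_index()
    )
    if not strand_aware and "strand" not in out.columns:
        out["strand"] = pd.NA
    keep = [c for c in ANNOTATION_COLUMNS if c in out.columns] + [id_col, "kind", "value"]
    out = out[keep].sort_values(
        ["kind", "chr", "integration_locus", id_col], kind="mergesort"
    ).reset_index(drop=True)
    return out, (mapping if emit_map else None)


def write_recalibration_map(mapping: pd.DataFrame, path: str | Path) -> None:
    mapping.to_csv(path, sep="\t", index=False)
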