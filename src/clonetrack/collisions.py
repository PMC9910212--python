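"""Collision removal: reassign or discard clones seen in independent subjects.

A *collision* is the same integration site observed in two or more
independent subjects.  Because two independent vector insertions at the very
same base pair are vanishingly unlikely (~3e8 accessible positions), a
collision almost certainly reflects cross-contamination between samples, and
the clone must be attributed to a single source or dropped.

Resolution applies an ordered cascade of criteria per colliding event:

1. **date** — the group treated/collected strictly earliest wins (a clone
   cannot pre-date its own transduction elsewhere);
2. **replicates** — the group observing the event in strictly more distinct
   PCR replicates wins;
3. **ratio** — a group whose summed quantification is at least
   ``reads_ratio`` times (default 10x) that of every other group wins;
4. otherwise the event is discarded from all groups.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .data_model import (
    REPLICATE_ID,
    StageReport,
    event_columns,
    matrix_totals,
)

DEFAULT_INDEPENDENCE_KEY = ("subject_id", "project_id")
DEFAULT_READS_RATIO = 10.0


@dataclass
class CollisionVerdict:
    """Outcome of resolving one colliding event."""

    event: tuple
    winner: str  # independence-group label, or "discarded"
    criterion_used: str  # date | replicates | ratio | unresolved
    diagnostics: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        assert (self.criterion_used == "unresolved") == (self.winner == "discarded")


def remove_collisions(
    m: pd.DataFrame,
    meta: pd.DataFrame,
    independence_key: tuple[str, ...] = DEFAULT_INDEPENDENCE_KEY,
    date_field: str = "treatment_date",
    reads_ratio: float = DEFAULT_READS_RATIO,
    quantification: str = "seqCount",
    strand_aware: bool = True,
    id_col: str = REPLICATE_ID,
    pool_col: str = "pool_id",
) -> tuple[pd.DataFrame, StageReport, list[CollisionVerdict]]:
    """Detect and resolve collisions; returns (matrix, report, verdicts).

    ``independence_key`` metadata fields define the independent groups
    (default: subject within project).  ``date_field`` must parse as a
    calendar date for every replicate in the matrix; ties are evaluated at
    day resolution.  The winner keeps all its rows, losers' rows are deleted;
    unresolved events are removed from every group.
    """
    missing = [c for c in list(independence_key) + [date_field] if c not in meta.columns]
    if missing:
        raise ValueError(f"metadata lacks required fields: {missing}")

    ev_cols = event_columns(strand_aware)
    meta = meta.copy()
    dates = pd.to_datetime(meta[date_field], errors="coerce")
    bad = dates.isna() & meta[date_field].notna()
    if bad.any() or dates.isna().any():
        culprit = meta.loc[dates.isna(), id_col].tolist()
        raise ValueError(f"unparseable {date_field} for replicate(s): {culprit}")
    meta["_date"] = dates.dt.normalize()
    meta["_group"] = meta[list(independence_key)].astype(str).agg("|".join, axis=1)

    before = matrix_totals(m, strand_aware)
    ann = meta[[id_col, "_group", "_date", *( [pool_col] if pool_col in meta.columns else [] )]]
    j = m.merge(ann, on=id_col, how="left")
    if j["_group"].isna().any():
        orphans = sorted(j.loc[j["_group"].isna(), id_col].unique().tolist())
        raise ValueError(f"replicate ids missing from metadata: {orphans}")

    groups_per_event = j.groupby(ev_cols, dropna=False)["_group"].nunique()
    colliding = groups_per_event[groups_per_event > 1].index
    if len(colliding) == 0:
        report = _make_report(m, j, before, before, [], strand_aware, pool_col)
        return m.copy(), report, []

    coll_mask = pd.MultiIndex.from_frame(j[ev_cols]).isin(colliding)
    coll = j[coll_mask]

    # per (event, group) diagnostics, computed once
    qsub = coll[coll["kind"] == quantification]
    diag = (
        coll.groupby(ev_cols + ["_group"], dropna=False)
        .agg(date=("_date", "min"), replicate_count=(id_col, "nunique"))
        .join(
            qsub.groupby(ev_cols + ["_group"], dropna=False)["value"]
            .sum()
            .rename("value_sum"),
            how="left",
        )
        .fillna({"value_sum": 0.0})
        .reset_index()
    )

    verdicts: list[CollisionVerdict] = []
    keep_pairs = []  # (event tuple, winning group)
    for ev, sub in diag.groupby(ev_cols, dropna=False, sort=False):
        ev = ev if isinstance(ev, tuple) else (ev,)
        winner, criterion = _resolve(sub, reads_ratio)
        verdicts.append(
            CollisionVerdict(
                event=ev,
                winner=winner,
                criterion_used=criterion,
                diagnostics={
                    r["_group"]: {
                        "date": str(r["date"].date()),
                        "replicate_count": int(r["replicate_count"]),
                        "value_sum": float(r["value_sum"]),
                    }
                    for r in sub.to_dict("records")
                },
            )
        )
        if winner != "discarded":
            keep_pairs.append(ev + (winner,))

    keep_idx = set(keep_pairs)
    pair_key = pd.MultiIndex.from_frame(j[ev_cols + ["_group"]])
    keep_mask = (~coll_mask) | pair_key.isin(keep_idx)
    out = m[keep_mask].reset_index(drop=True)

    after = matrix_totals(out, strand_aware)
    report = _make_report(out, j[keep_mask], before, after, verdicts, strand_aware, pool_col)
    return out, report, verdicts


def _resolve(sub: pd.DataFrame, reads_ratio: float) -> tuple[str, str]:
    """Apply the date -> replicates -> ratio cascade to one event's groups."""
    earliest = sub["date"].min()
    cand = sub[sub["date"] == earliest]
    if len(cand) == 1:
        return cand["_group"].iloc[0], "date"
    most = sub["replicate_count"].max()
    cand2 = sub[sub["replicate_count"] == most]
    if len(cand2) == 1:
        return cand2["_group"].iloc[0], "replicates"
    sums = sub.set_index("_group")["value_sum"]
    top = sums.idxmax()
    others = sums.drop(top)
    if len(others) and sums[top] > 0 and (sums[top] >= reads_ratio * others).all():
        return top, "ratio"
    return "discarded", "unresolved"


def _make_report(out, joined, before, after, verdicts, strand_aware, pool_col):
    n_coll = len(verdicts)
    n_reassigned = sum(v.winner != "discarded" for v in verdicts)
    per_pool = []
    if pool_col in joined.columns and len(joined):
        for pool, grp in joined.groupby(pool_col, dropna=False):
            per_pool.append(
                {
                    "pool": pool,
                    "distinct_is": int(grp.drop_duplicates(event_columns(strand_aware)).shape[0]),
                    "value_sums": {
                        k: float(v) for k, v in grp.groupby("kind")["value"].sum().items()
                    },
                }
            )
    report = StageReport(
        stage_name="collision_removal",
        totals_before=before,
        totals_after=after,
        per_pool=per_pool,
        flagged_items=[
            {"identifier": v.event, "reason": f"collision:{v.criterion_used}", "winner": v.winner}
            for v in verdicts
        ],
    )
    report.totals_after["collisions_found"] = n_coll
    report.totals_after["collisions_reassigned"] = n_reassigned
    report.totals_after["collisions_discarded"] = n_coll - n_reassigned
    return report


def collision_accounting(
    total_is: int, collisions: int, reassigned: int
) -> dict[str, float]:
    """Summary arithmetic of a collision-removal run.

    From the number of distinct IS before processing, the number identified
    as collisions and the number successfully reassigned, derive the
    discarded count, the final IS count and the headline percentages shown
    in stage reports.
    """
    if not (0 <= reassigned <= collisions <= total_is):
        raise ValueError("need 0 <= reassigned <= collisions <= total_is")
    discarded = collisions - reassigned
    return {
        "total_is": total_is,
        "collisions": collisions,
        "reassigned": reassigned,
        "discarded": discarded,
        "final_is": total_is - discarded,
        "collision_rate_pct": 100.0 * collisions / total_is,
        "reassignment_rate_pct": 100.0 * reassigned / collisions if collisions else 0.0,
        "discard_rate_pct": 100.0 * discarded / total_is,
    }


def verdicts_to_frame(verdicts: list[CollisionVerdict]) -> pd.DataFrame:
    """Tabular view of verdicts for TSV export."""
    rows = []
    for v in verdicts:
        rows.append(
            {
                "event": "|".join(str(x) for x in v.event),
                "winner": v.winner,
                "criterion": v.criterion_used,
                "n_groups": len(v.diagnostics),
            }
        )
    return pd.DataFrame(rows, columns=["event", "winner", "criterion", "n_groups"])
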