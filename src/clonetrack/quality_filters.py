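"""Sample outlier flagging and clone purity filtering.

Two orthogonal quality controls:

* :func:`outliers_by_pool_fragments` flags under-sequenced PCR samples
  within each sequencing pool, testing each sample's (log) raw-read count
  against its pool distribution.
* :func:`purity_filter` removes a clone from groups where its quantification
  is far below the group holding its maximum — the signature of low-level
  intra-subject carry-over between dependent samples (e.g. sorted lineages
  of one patient at one time point).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .data_model import REPLICATE_ID, StageReport, event_columns, matrix_totals


@dataclass
class OutlierFlag:
    replicate_id: str
    pool_id: str
    statistic: float  # z score of the (log) read count within the pool
    p_value: float
    flagged: bool
    reason: str = "undersequenced"


def outliers_by_pool_fragments(
    meta: pd.DataFrame,
    key: str = "raw_reads",
    alpha: float = 0.01,
    log_transform: bool = True,
    min_pool_size: int = 3,
    id_col: str = REPLICATE_ID,
    pool_col: str = "pool_id",
) -> tuple[list[OutlierFlag], StageReport]:
    """Flag under-sequenced samples per pool.

    Per pool with n >= ``min_pool_size`` members: x_i = log2(key_i + 1)
    (or the raw value), z_i = (x_i - mean) / sd, and p_i is the lower tail
    of a Student t with n - 1 degrees of freedom at z_i.  A sample is
    flagged iff p_i < alpha and its value lies below the pool mean.  Pools
    with zero spread produce no flags; samples with a missing key value are
    flagged separately with reason ``missing-data``.
    """
    if pool_col not in meta.columns or key not in meta.columns:
        raise ValueError(f"metadata must provide '{pool_col}' and '{key}'")
    flags: list[OutlierFlag] = []
    for pool, grp in meta.groupby(pool_col, dropna=False):
        vals = pd.to_numeric(grp[key], errors="coerce")
        for rid in grp.loc[vals.isna(), id_col]:
            flags.append(OutlierFlag(rid, pool, np.nan, np.nan, True, "missing-data"))
        ok = grp[vals.notna()]
        x = vals.dropna().to_numpy(dtype=float)
        if log_transform:
            x = np.log2(x + 1.0)
        n = len(x)
        if n < min_pool_size:
            continue
        sd = x.std(ddof=1)
        mean = x.mean()
        if sd == 0:
            continue
        z = (x - mean) / sd
        p = sps.t.cdf(z, df=n - 1)
        for rid, zi, pi, xi in zip(ok[id_col], z, p, x):
            flagged = bool(pi < alpha and xi < mean)
            flags.append(OutlierFlag(str(rid), pool, float(zi), float(pi), flagged))
    n_flagged = sum(f.flagged for f in flags)
    report = StageReport(
        stage_name="outlier_filter",
        totals_before={"n_samples": int(len(meta))},
        totals_after={"n_samples": int(len(meta)) - n_flagged, "n_flagged": n_flagged},
        per_pool=[
            {
                "pool": pool,
                "n_samples": int(len(grp)),
                "n_flagged": sum(f.flagged for f in flags if f.pool_id == pool),
            }
            for pool, grp in meta.groupby(pool_col, dropna=False)
        ],
        flagged_items=[
            {
                "identifier": f.replicate_id,
                "reason": f.reason,
                "pool": f.pool_id,
                "statistic": f.statistic,
                "p_value": f.p_value,
            }
            for f in flags
            if f.flagged
        ],
    )
    return flags, report


def flags_to_frame(flags: list[OutlierFlag]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "replicate_id": f.replicate_id,
                "pool_id": f.pool_id,
                "statistic": f.statistic,
                "p_value": f.p_value,
                "flagged": f.flagged,
                "reason": f.reason,
            }
            for f in flags
        ],
        columns=["replicate_id", "pool_id", "statistic", "p_value", "flagged", "reason"],
    )


def drop_flagged(
    m: pd.DataFrame, flags: list[OutlierFlag], id_col: str = REPLICATE_ID
) -> pd.DataFrame:
    """Remove all rows of flagged replicates from a long matrix."""
    bad = {f.replicate_id for f in flags if f.flagged}
    return m[~m[id_col].isin(bad)].reset_index(drop=True)


def purity_filter(
    m: pd.DataFrame,
    meta: pd.DataFrame,
    group_key: list[str],
    min_value: float = 3,
    impurity_ratio: float = 10,
    quantification: str = "seqCount",
    strand_aware: bool = True,
    id_col: str = REPLICATE_ID,
) -> tuple[pd.DataFrame, StageReport]:
    """Purge low-purity clones across dependent groups.

    Three steps on the selected quantification kind:

    1. rows with value < ``min_value`` are dropped (all kinds, row-wise on
       the selected kind's rows; other kinds' rows for the same
       (event, replicate) are dropped alongside to keep the matrix coherent);
    2. events present in >= 2 groups (as defined by ``group_key`` metadata
       fields) are selected for processing; all others pass through;
    3. for each processed event, with v_max the maximum per-group sum, the
       event is removed from every group i where v_max / v_i > ``impurity_ratio``.
       The group holding the maximum always survives.
    """
    if impurity_ratio <= 1:
        raise ValueError("impurity_ratio must be > 1")
    missing = [c for c in group_key if c not in meta.columns]
    if missing:
        raise ValueError(f"metadata lacks group fields: {missing}")

    before = matrix_totals(m, strand_aware)
    ev_cols = event_columns(strand_aware)

    # step 1: minimum-value pre-filter on the selected kind
    qmask = m["kind"] == quantification
    low_pairs = m.loc[qmask & (m["value"] < min_value), ev_cols + [id_col]]
    low_key = pd.MultiIndex.from_frame(low_pairs)
    pair_key = pd.MultiIndex.from_frame(m[ev_cols + [id_col]])
    step1 = m[~pair_key.isin(low_key)].copy()

    ann = meta[[id_col] + group_key].copy()
    ann["_group"] = ann[group_key].astype(str).agg("|".join, axis=1)
    j = step1.merge(ann[[id_col, "_group"]], on=id_col, how="left")
    if j["_group"].isna().any():
        orphans = sorted(j.loc[j["_group"].isna(), id_col].unique().tolist())
        raise ValueError(f"replicate ids missing from metadata: {orphans}")

    qj = j[j["kind"] == quantification]
    per_group = qj.groupby(ev_cols + ["_group"], dropna=False)["value"].sum().reset_index()
    shared = per_group.groupby(ev_cols, dropna=False)["_group"].nunique()
    shared_events = shared[shared > 1].index

    proc = per_group[pd.MultiIndex.from_frame(per_group[ev_cols]).isin(shared_events)]
    vmax = proc.groupby(ev_cols, dropna=False)["value"].transform("max")
    impure = proc[vmax / proc["value"] > impurity_ratio]

    drop_key = pd.MultiIndex.from_frame(impure[ev_cols + ["_group"]])
    jpair = pd.MultiIndex.from_frame(j[ev_cols + ["_group"]])
    out = j[~jpair.isin(drop_key)].drop(columns="_group").reset_index(drop=True)

    report = StageReport(
        stage_name="purity_filter",
        totals_before=before,
        totals_after=matrix_totals(out, strand_aware),
        flagged_items=[
            {
                "identifier": tuple(r[c] for c in ev_cols),
                "reason": "impurity",
                "group": r["_group"],
                "value": float(r["value"]),
            }
            for r in impure.to_dict("records")
        ],
    )
    report.totals_after["rows_dropped_min_value"] = int(len(m) - len(step1))
    report.totals_after["events_processed"] = int(len(shared_events))
    return out, report
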