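"""Core domain types and I/O for integration-site (IS) matrices and metadata.

An *integration site* is the genomic position (chromosome, locus, strand)
where a viral vector inserted into the host genome; it labels the clone
descending from the transduced cell.  Quantification tools emit one sparse
matrix per sequencing pool: IS in rows, PCR replicates in columns, and cell
values holding either raw read counts (``seqCount``) or sonication-fragment
based genome estimates (``fragmentEstimate``).

Internally everything is tidy/long: one row per observed
(event, replicate, quantification-kind) triple.  Zeros and missing cells are
never stored — absence of a row means "not observed".  Every analytical stage
consumes and produces this long form, joined to a per-replicate metadata
table on a single mandatory identifier column.
"""

from __future__ import annotations

import json
from concurrent.futures import ThreadPoolExecutor
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, NamedTuple, Sequence

import numpy as np
import pandas as pd

#: Default name of the mandatory replicate-identifier column in metadata;
#: must match IS-matrix column headers exactly (case-sensitive).
REPLICATE_ID = "CompleteAmplificationID"

#: Fixed annotation columns of a wide IS matrix; anything else is a sample.
ANNOTATION_COLUMNS = ("chr", "integration_locus", "strand", "GeneName", "GeneStrand")

#: Recognized quantification kinds.
QUANTIFICATION_KINDS = ("seqCount", "fragmentEstimate")

#: Columns of the canonical long-form IS matrix (plus the replicate id column).
LONG_VALUE_COLUMNS = ("kind", "value")


class IntegrationEvent(NamedTuple):
    """The (chromosome, locus, strand) triple identifying a clone.

    ``strand`` is ``None`` in strand-agnostic mode.  Loci are 1-based
    single-base positions (no end coordinate exists for an IS).
    """

    chromosome: str
    locus: int
    strand: str | None = None


def event_columns(strand_aware: bool = True) -> list[str]:
    """Columns that jointly identify an integration event."""
    cols = ["chr", "integration_locus"]
    if strand_aware:
        cols.append("strand")
    return cols


@dataclass
class StageReport:
    """Serializable summary emitted by import / cleaning stages.

    Concretizes the per-stage dashboards as plain data: totals before and
    after the stage, per-pool descriptive statistics and a list of flagged
    items with the reason and supporting numbers.
    """

    stage_name: str
    totals_before: dict = field(default_factory=dict)
    totals_after: dict = field(default_factory=dict)
    per_pool: list = field(default_factory=list)
    flagged_items: list = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "stage_name": self.stage_name,
            "totals_before": self.totals_before,
            "totals_after": self.totals_after,
            "per_pool": self.per_pool,
            "flagged_items": self.flagged_items,
        }

    def to_json(self, path: str | Path | None = None) -> str:
        text = json.dumps(self.to_dict(), indent=2, default=_json_default)
        if path is not None:
            Path(path).write_text(text)
        return text


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, (np.ndarray, tuple, set)):
        return list(obj)
    return str(obj)


def matrix_totals(m: pd.DataFrame, strand_aware: bool = True) -> dict:
    """Distinct-IS count and per-kind value sums of a long matrix."""
    if m.empty:
        return {"distinct_is": 0, "value_sums": {}}
    n_is = m.drop_duplicates(event_columns(strand_aware)).shape[0]
    sums = m.groupby("kind")["value"].sum().to_dict()
    return {"distinct_is": int(n_is), "value_sums": {k: float(v) for k, v in sums.items()}}


# ---------------------------------------------------------------------------
# Sparse matrix reading / writing
# ---------------------------------------------------------------------------

def _normalize_chrom(series: pd.Series) -> pd.Series:
    """Strip a leading 'chr' prefix; chromosomes are stored bare ('1'..'X')."""
    s = series.astype(str).str.strip()
    return s.str.replace(r"^chr", "", regex=True, case=False)


def read_sparse_matrix(
    path: str | Path,
    kind: str = "seqCount",
    strand_aware: bool = True,
    annotation_columns: Sequence[str] = ANNOTATION_COLUMNS,
    id_col: str = REPLICATE_ID,
) -> tuple[pd.DataFrame, dict]:
    """Read a wide sparse IS matrix (TSV) into long form.

    The file holds annotation columns (``chr``, ``integration_locus``,
    ``strand`` and optionally ``GeneName``/``GeneStrand``) followed by one
    column per PCR replicate.  Cells that are zero, empty or NA are dropped:
    the long form stores observed entries only.

    Returns
    -------
    (long_df, stats) where ``stats`` has ``n_rows`` (long rows kept) and
    ``n_dropped_cells`` (zero/NA cells of the sample block).

    Raises
    ------
    ValueError
        on duplicate sample column headers (identifiers must be unique),
        on a file with no sample columns, or on a non-integer locus.
    """
    path = Path(path)
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
    dupes = sorted({h for h in header if header.count(h) > 1})
    if dupes:
        raise ValueError(
            f"{path}: duplicated column header(s) {dupes}; sample identifiers "
            "must be unique (no repetitions allowed)"
        )
    ann_present = [c for c in annotation_columns if c in header]
    sample_cols = [c for c in header if c not in annotation_columns]
    if not sample_cols:
        raise ValueError(f"{path}: no sample columns found besides {ann_present}")
    for required in ("chr", "integration_locus"):
        if required not in ann_present:
            raise ValueError(f"{path}: missing mandatory annotation column '{required}'")

    wide = pd.read_csv(path, sep="\t", dtype={"chr": str})
    loci = pd.to_numeric(wide["integration_locus"], errors="coerce")
    bad = loci.isna() | (loci != loci.round())
    if bad.any():
        row = int(np.flatnonzero(bad.to_numpy())[0])
        raise ValueError(
            f"{path}: malformed integration_locus "
            f"{wide['integration_locus'].iloc[row]!r} at data row {row + 1}"
        )
    wide["integration_locus"] = loci.astype(np.int64)
    wide["chr"] = _normalize_chrom(wide["chr"])
    if "strand" not in wide.columns:
        wide["strand"] = pd.NA

    keep_ann = [c for c in ANNOTATION_COLUMNS if c in wide.columns]
    long = wide.melt(
        id_vars=keep_ann, value_vars=sample_cols, var_name=id_col, value_name="value"
    )
    long["value"] = pd.to_numeric(long["value"], errors="coerce")
    n_cells = len(long)
    long = long[long["value"].notna() & (long["value"] != 0)].copy()
    long["kind"] = kind
    for optional in ("GeneName", "GeneStrand"):
        if optional not in long.columns:
            long[optional] = pd.NA
    long = long[list(ANNOTATION_COLUMNS) + [id_col, "kind", "value"]]
    long = long.reset_index(drop=True)
    stats = {"n_rows": len(long), "n_dropped_cells": int(n_cells - len(long))}
    return long, stats


def write_sparse_matrix(
    m: pd.DataFrame,
    path: str | Path,
    kind: str = "seqCount",
    id_col: str = REPLICATE_ID,
) -> None:
    """Write one quantification kind of a long matrix back to wide TSV.

    Unobserved cells are written empty (round-trip treats empty, NA and zero
    as identical: not observed).
    """
    sub = m[m["kind"] == kind]
    ann = [c for c in ANNOTATION_COLUMNS if c in m.columns]
    # set_index/unstack keeps rows whose annotation (e.g. GeneName) is absent
    wide = sub.set_index(ann + [id_col])["value"].unstack(id_col)
    wide.columns.name = None
    wide.reset_index().to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Metadata
# ---------------------------------------------------------------------------

def read_metadata(path: str | Path, id_col: str = REPLICATE_ID) -> pd.DataFrame:
    """Read the per-replicate metadata TSV and validate the identifier column."""
    meta = pd.read_csv(path, sep="\t", dtype={id_col: str})
    validate_metadata(meta, id_col)
    return meta

def validate_metadata(meta: pd.DataFrame, id_col: str = REPLICATE_ID) -> None:
    if id_col not in meta.columns:
        raise ValueError(f"metadata lacks mandatory identifier column '{id_col}'")
    ids = meta[id_col]
    if ids.isna().any() or (ids.astype(str).str.len() == 0).any():
        raise ValueError("metadata identifier column contains empty values")
    if ids.duplicated().any():
        dupes = sorted(ids[ids.duplicated()].unique().tolist())
        raise ValueError(f"duplicate replicate identifiers in metadata: {dupes}")


def read_vispa2_stats(path: str | Path, id_col: str = REPLICATE_ID) -> pd.DataFrame:
    """Read a per-sample raw-read statistics TSV (replicate id + raw_reads)."""
    stats = pd.read_csv(path, sep="\t", dtype={id_col: str})
    if id_col not in stats.columns:
        raise ValueError(f"stats file lacks key column '{id_col}'")
    if stats[id_col].duplicated().any():
        dupes = sorted(stats.loc[stats[id_col].duplicated(), id_col].unique().tolist())
        raise ValueError(f"duplicate replicate identifiers in stats file: {dupes}")
    return stats


def attach_raw_reads(
    meta: pd.DataFrame,
    stats: pd.DataFrame,
    id_col: str = REPLICATE_ID,
    reads_col: str = "raw_reads",
) -> tuple[pd.DataFrame, list[str]]:
    """Left-join raw read counts onto metadata by replicate id.

    Returns the augmented metadata plus the list of replicate ids for which
    no raw-read value was found (their ``raw_reads`` is left missing).
    """
    cols = [id_col, reads_col]
    if reads_col not in stats.columns:
        raise ValueError(f"stats file lacks column '{reads_col}'")
    merged = meta.drop(columns=[reads_col], errors="ignore").merge(
        stats[cols], on=id_col, how="left"
    )
    unmatched = merged.loc[merged[reads_col].isna(), id_col].tolist()
    return merged, unmatched


# ---------------------------------------------------------------------------
# Metadata-guided import
# ---------------------------------------------------------------------------

def _path_column(kind: str, kinds: Sequence[str]) -> str:
    return "path_to_matrix" if len(kinds) == 1 else f"path_to_matrix_{kind}"


def import_guided(
    meta: pd.DataFrame,
    kinds: Sequence[str] = ("seqCount",),
    workers: int = 1,
    strand_aware: bool = True,
    on_missing_file: str = "error",
    id_col: str = REPLICATE_ID,
    pool_col: str = "pool_id",
) -> tuple[pd.DataFrame, StageReport]:
    """Import IS matrices listed in metadata; only metadata samples are kept.

    Each metadata row carries the path of the matrix file holding its column
    (column ``path_to_matrix``, or ``path_to_matrix_<kind>`` when several
    quantifications are imported).  Matrix columns not present in the
    metadata are discarded and counted.  Files may be read concurrently
    (``workers`` > 1); the output is a deterministic function of the inputs
    regardless of worker count.

    ``on_missing_file``: ``"error"`` raises on a listed file that cannot be
    read; ``"skip"`` records it in the report and continues.
    """
    if workers < 1:
        raise ValueError("workers must be >= 1")
    if on_missing_file not in ("error", "skip"):
        raise ValueError("on_missing_file must be 'error' or 'skip'")
    validate_metadata(meta, id_col)
    wanted = set(meta[id_col])

    jobs: list[tuple[str, str]] = []  # (kind, path), sorted for determinism
    for kind in kinds:
        col = _path_column(kind, kinds)
        if meta.empty:
            continue
        if col not in meta.columns:
            raise ValueError(f"metadata lacks path column '{col}'")
        for p in sorted(meta[col].dropna().unique()):
            jobs.append((kind, p))

    failed: list[dict] = []

    def _read(job):
        kind, p = job
        try:
            long, stats = read_sparse_matrix(
                p, kind=kind, strand_aware=strand_aware, id_col=id_col
            )
        except (OSError, ValueError) as exc:
            return job, None, {"error": str(exc)}
        return job, long, stats

    if workers == 1:
        results = [_read(j) for j in jobs]
    else:
        with ThreadPoolExecutor(max_workers=workers) as pool:
            results = list(pool.map(_read, jobs))

    pieces = []
    per_file = []
    for (kind, p), long, stats in results:
        if long is None:
            failed.append({"path": p, "kind": kind, "reason": stats["error"]})
            if on_missing_file == "error":
                raise ValueError(f"failed to import {p}: {stats['error']}")
            continue
        in_meta = long[id_col].isin(wanted)
        ignored = sorted(long.loc[~in_meta, id_col].unique().tolist())
        kept = long[in_meta]
        pieces.append(kept)
        per_file.append(
            {
                "path": p,
                "kind": kind,
                "imported_samples": int(kept[id_col].nunique()),
                "ignored_samples": len(ignored),
                "ignored_sample_ids": ignored,
                "dropped_cells": stats["n_dropped_cells"],
            }
        )

    if pieces:
        out = pd.concat(pieces, ignore_index=True)
        out = out.sort_values(
            ["kind", "chr", "integration_locus", "strand", id_col],
            kind="mergesort",
            na_position="last",
        ).reset_index(drop=True)
    else:
        out = pd.DataFrame(
            columns=list(ANNOTATION_COLUMNS) + [id_col, "kind", "value"]
        )

    found_ids = set(out[id_col]) if len(out) else set()
    missing_ids = sorted(wanted - found_ids)
    flagged = [{"identifier": i, "reason": "replicate id found in no file"} for i in missing_ids]
    flagged += [
        {"identifier": f["path"], "reason": "file failed",
         "kind": f["kind"], "detail": f["reason"]}
        for f in failed
    ]

    per_pool: list[dict] = []
    if pool_col in meta.columns and not meta.empty:
        for pool, grp in meta.groupby(pool_col, dropna=False):
            ids = set(grp[id_col])
            per_pool.append(
                {
                    "pool": pool,
                    "metadata_samples": len(ids),
                    "imported_samples": len(ids & found_ids),
                    "missing_samples": len(ids - found_ids),
                }
            )

    report = StageReport(
        stage_name="import",
        totals_after=matrix_totals(out, strand_aware),
        per_pool=per_pool,
        flagged_items=flagged,
    )
    report.totals_after["per_file"] = per_file
    return out, report


def check_matrix_metadata_consistency(
    m: pd.DataFrame, meta: pd.DataFrame, id_col: str = REPLICATE_ID
) -> None:
    """Raise if the matrix references replicates absent from the metadata."""
    orphans = sorted(set(m[id_col]) - set(meta[id_col]))
    if orphans:
        raise ValueError(f"replicate ids missing from metadata: {orphans}")


def iter_events(m: pd.DataFrame, strand_aware: bool = True) -> Iterable[IntegrationEvent]:
    """Distinct integration events of a long matrix, in sorted order."""
    cols = event_columns(strand_aware)
    uniq = m.drop_duplicates(cols).sort_values(cols)
    for row in uniq.itertuples(index=False):
        yield IntegrationEvent(
            row.chr, int(row.integration_locus), row.strand if strand_aware else None
        )
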