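"""Synthetic multi-pool, multi-subject clonal-tracking scenarios.

Generates IS matrices, metadata and raw-read statistics emulating a small
gene-therapy trial — several subjects followed over time points, each
sequenced in per-time-point pools with two PCR replicates per sorted cell
marker — together with a ground-truth table of every planted structure:

* **collisions** — clones of one subject leaked at low level into another
  subject's samples (the earlier-treated subject is the true source);
* **under-sequenced samples** — replicates with raw-read depth a fixed
  factor below their pool;
* **an over-targeted gene** — integrations assigned to genes with
  probability proportional to gene length, except one gene boosted by an
  enrichment factor (a planted common-insertion-site signal);
* **wobble pairs** — sibling events 1-3 bp from a true event that
  recalibration must merge;
* **impurity events** — clones with a large value in one marker group and a
  trace value in another at the same time point.

Loci are drawn uniformly with a guaranteed >= 10 bp separation between
distinct clones (so only planted wobble pairs merge at the default 4 bp
threshold); per-replicate counts are log-normal.  The same seed always
yields byte-identical files.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .data_model import ANNOTATION_COLUMNS, REPLICATE_ID

CHROMOSOMES = [str(c) for c in range(1, 23)] + ["X"]


@dataclass
class ScenarioConfig:
    """Knobs of a synthetic scenario; defaults emulate a desk-scale trial."""

    n_subjects: int = 3
    timepoints: tuple = (30, 90, 180, 270)  # days after gene therapy
    clones_per_subject: int = 300
    replicate_count: int = 2
    markers: tuple = ("CD34", "CD3")
    tissue: str = "PB"
    project_id: str = "GT01"
    n_genes: int = 100
    gene_length_range: tuple = (30_000, 80_000)  # bp
    p_detect: float = 0.6  # per-sample clone detection probability
    mean_reads: float = 5e6  # pool-level raw reads per replicate (log-normal)
    seed: int = 0
    # planted ground truth
    planted_collisions: int = 20
    outlier_samples: int = 3
    outlier_depth_factor: float = 1e-3
    cis_gene: str | None = None  # default: middle gene of the annotation
    cis_enrichment: float = 10.0
    wobble_pairs: int = 15
    impurity_events: int = 10


@dataclass
class Scenario:
    config: ScenarioConfig
    metadata: pd.DataFrame
    stats: pd.DataFrame
    gene_lengths: pd.DataFrame
    matrices: dict  # pool id -> wide DataFrame
    truth: dict
    paths: dict = field(default_factory=dict)

    @property
    def long(self) -> pd.DataFrame:
        """All pools melted to the canonical long form (seqCount)."""
        pieces = []
        for pool, wide in self.matrices.items():
            sample_cols = [c for c in wide.columns if c not in ANNOTATION_COLUMNS]
            long = wide.melt(
                id_vars=[c for c in ANNOTATION_COLUMNS if c in wide.columns],
                value_vars=sample_cols,
                var_name=REPLICATE_ID,
                value_name="value",
            )
            long = long[long["value"].notna() & (long["value"] != 0)]
            pieces.append(long)
        out = pd.concat(pieces, ignore_index=True)
        out["kind"] = "seqCount"
        out["integration_locus"] = out["integration_locus"].astype(np.int64)
        return out.sort_values(
            ["chr", "integration_locus", "strand", REPLICATE_ID], kind="mergesort"
        ).reset_index(drop=True)


def _check_feasible(cfg: ScenarioConfig) -> None:
    reserved = cfg.planted_collisions + cfg.wobble_pairs + cfg.impurity_events
    if reserved > cfg.clones_per_subject:
        raise ValueError(
            f"cannot plant {reserved} structures in {cfg.clones_per_subject} "
            "clones per subject"
        )
    if cfg.n_subjects < 2 and cfg.planted_collisions:
        raise ValueError("collisions need >= 2 subjects")
    n_samples_per_pool = cfg.n_subjects * len(cfg.markers) * cfg.replicate_count
    if cfg.outlier_samples > len(cfg.timepoints) * n_samples_per_pool:
        raise ValueError("more planted outliers than samples")
    if cfg.cis_enrichment < 1:
        raise ValueError("cis_enrichment must be >= 1")


def generate_scenario(cfg: ScenarioConfig, out_dir: str | Path | None = None) -> Scenario:
    """Build a scenario; optionally write the TSV files under ``out_dir``.

    Writes one wide IS matrix per pool (``matrix_<pool>.tsv``), the
    metadata (``metadata.tsv``, with ``path_to_matrix`` pointing at the pool
    files) and the raw-read statistics (``stats.tsv``).
    """
    _check_feasible(cfg)
    rng = np.random.default_rng(cfg.seed)

    # gene annotation; planted CIS gene draws integrations cis_enrichment-fold
    # above its length share
    genes = pd.DataFrame(
        {
            "gene_name": [f"GENE{i + 1:04d}" for i in range(cfg.n_genes)],
            "length_bp": rng.integers(*cfg.gene_length_range, size=cfg.n_genes),
        }
    )
    cis_gene = cfg.cis_gene or genes["gene_name"].iloc[cfg.n_genes // 2]
    weights = genes["length_bp"].to_numpy(dtype=float).copy()
    weights[genes["gene_name"] == cis_gene] *= cfg.cis_enrichment
    weights /= weights.sum()

    # distinct clone loci with >= 10 bp global separation (slot sampling)
    n_clones = cfg.n_subjects * cfg.clones_per_subject
    chroms = rng.choice(CHROMOSOMES, size=n_clones)
    slots = rng.choice(20_000_000, size=n_clones, replace=False)
    loci = slots.astype(np.int64) * 10 + 1
    strands = rng.choice(["+", "-"], size=n_clones)
    gene_idx = rng.choice(cfg.n_genes, size=n_clones, p=weights)
    clones = pd.DataFrame(
        {
            "chr": chroms,
            "integration_locus": loci,
            "strand": strands,
            "GeneName": genes["gene_name"].to_numpy()[gene_idx],
            "GeneStrand": rng.choice(["+", "-"], size=n_clones),
            "subject_id": np.repeat(
                [f"PT{i + 1:02d}" for i in range(cfg.n_subjects)],
                cfg.clones_per_subject,
            ),
        }
    )

    subjects = [f"PT{i + 1:02d}" for i in range(cfg.n_subjects)]
    # distinct treatment dates => collisions resolve by the date criterion
    treat_dates = {
        s: (pd.Timestamp("2019-01-15") + pd.Timedelta(days=45 * i)).date().isoformat()
        for i, s in enumerate(subjects)
    }

    # reserve disjoint clone blocks per subject for the planted structures
    truth: dict = {"cis_gene": cis_gene, "collisions": [], "wobble": [], "impurity": [], "outliers": []}
    sub_frames = {s: clones[clones["subject_id"] == s].reset_index(drop=True) for s in subjects}

    collision_plan = []  # (event-row, winner, loser)
    for i in range(cfg.planted_collisions):
        winner_i, loser_i = sorted(rng.choice(cfg.n_subjects, size=2, replace=False))
        winner, loser = subjects[winner_i], subjects[loser_i]
        row = sub_frames[winner].iloc[i]
        collision_plan.append((row, winner, loser))
        truth["collisions"].append(
            {
                "chr": row["chr"],
                "integration_locus": int(row["integration_locus"]),
                "strand": row["strand"],
                "winner": winner,
                "loser": loser,
                "criterion": "date",
            }
        )

    wobble_plan = []
    base = cfg.planted_collisions
    for i in range(cfg.wobble_pairs):
        row = sub_frames[subjects[0]].iloc[base + i]
        offset = int(rng.integers(1, 4))  # sibling 1-3 bp away: merges at < 4
        wobble_plan.append((row, offset))
        truth["wobble"].append(
            {
                "chr": row["chr"],
                "integration_locus": int(row["integration_locus"]),
                "strand": row["strand"],
                "sibling_locus": int(row["integration_locus"]) + offset,
            }
        )

    impurity_plan = []
    base += cfg.wobble_pairs
    for i in range(cfg.impurity_events):
        subject = subjects[int(rng.integers(cfg.n_subjects))]
        row = sub_frames[subject].iloc[base + i]
        tp = int(cfg.timepoints[int(rng.integers(len(cfg.timepoints)))])
        major, minor = (cfg.markers[0], cfg.markers[1]) if len(cfg.markers) > 1 else (cfg.markers[0],) * 2
        impurity_plan.append((row, subject, tp, major, minor))
        truth["impurity"].append(
            {
                "chr": row["chr"],
                "integration_locus": int(row["integration_locus"]),
                "strand": row["strand"],
                "subject": subject,
                "timepoint": tp,
                "major_marker": major,
                "minor_marker": minor,
            }
        )
    impurity_keys = {
        (r["chr"], int(r["integration_locus"]), r["strand"]) for r in truth["impurity"]
    }

    # metadata: one row per PCR replicate; one pool per time point
    meta_rows = []
    for t_i, tp in enumerate(cfg.timepoints):
        pool = f"POOL{t_i + 1:02d}"
        for s in subjects:
            for marker in cfg.markers:
                for r in range(1, cfg.replicate_count + 1):
                    rid = f"{s}_{cfg.tissue}_{marker}_d{tp:03d}_R{r}"
                    meta_rows.append(
                        {
                            REPLICATE_ID: rid,
                            "project_id": cfg.project_id,
                            "subject_id": s,
                            "tissue": cfg.tissue,
                            "cell_marker": marker,
                            "timepoint": tp,
                            "pool_id": pool,
                            "treatment_date": treat_dates[s],
                        }
                    )
    meta = pd.DataFrame(meta_rows)

    # per-sample observations
    obs: dict[str, list] = {rid: [] for rid in meta[REPLICATE_ID]}

    def _emit(row, rid, value):
        obs[rid].append(
            (
                row["chr"],
                int(row["integration_locus"]),
                row["strand"],
                row["GeneName"],
                row["GeneStrand"],
                int(value),
            )
        )

    meta_by = meta.set_index(REPLICATE_ID)
    for s in subjects:
        sub_meta = meta[meta["subject_id"] == s]
        frame = sub_frames[s]
        rids = sub_meta[REPLICATE_ID].tolist()
        present = rng.random((len(frame), len(rids))) < cfg.p_detect
        values = np.maximum(1, np.round(rng.lognormal(2.0, 1.0, (len(frame), len(rids)))))
        for ci in range(len(frame)):
            row = frame.iloc[ci]
            key = (row["chr"], int(row["integration_locus"]), row["strand"])
            if key in impurity_keys:
                continue  # values fully scripted below
            if not present[ci].any():
                present[ci, int(rng.integers(len(rids)))] = True
            for ri, rid in enumerate(rids):
                if present[ci, ri]:
                    _emit(row, rid, values[ci, ri])

    # planted impurity: major marker gets large values, minor a trace value
    for row, subject, tp, major, minor in impurity_plan:
        sel = meta[(meta["subject_id"] == subject) & (meta["timepoint"] == tp)]
        for rid in sel.loc[sel["cell_marker"] == major, REPLICATE_ID]:
            _emit(row, rid, 300)
        minor_ids = sel.loc[sel["cell_marker"] == minor, REPLICATE_ID].tolist()
        _emit(row, minor_ids[0], 5)

    # planted contamination: the loser subject sees the winner's clone at
    # trace level in a single replicate of one random time point
    for row, winner, loser in collision_plan:
        sel = meta[meta["subject_id"] == loser]
        rid = sel[REPLICATE_ID].iloc[int(rng.integers(len(sel)))]
        _emit(row, rid, int(rng.integers(1, 6)))

    # planted wobble siblings: low-count echo of the true event 1-3 bp away
    for row, offset in wobble_plan:
        sib = row.copy()
        sib["integration_locus"] = int(row["integration_locus"]) + offset
        sel = meta[meta["subject_id"] == row["subject_id"]]
        picks = rng.choice(len(sel), size=2, replace=False)
        for p in picks:
            _emit(sib, sel[REPLICATE_ID].iloc[int(p)], int(rng.integers(1, 8)))

    # wide matrix per pool
    matrices = {}
    for t_i, tp in enumerate(cfg.timepoints):
        pool = f"POOL{t_i + 1:02d}"
        pool_ids = meta.loc[meta["pool_id"] == pool, REPLICATE_ID].tolist()
        recs = {}
        for rid in pool_ids:
            for chrom, locus, strand, gene, gstrand, value in obs[rid]:
                key = (chrom, locus, strand, gene, gstrand)
                recs.setdefault(key, {})[rid] = recs.setdefault(key, {}).get(rid, 0) + value
        wide = pd.DataFrame(
            [
                dict(
                    zip(("chr", "integration_locus", "strand", "GeneName", "GeneStrand"), k)
                )
                | v
                for k, v in recs.items()
            ]
        )
        for rid in pool_ids:
            if rid not in wide.columns:
                wide[rid] = np.nan
        wide = wide.sort_values(["chr", "integration_locus", "strand"], kind="mergesort")
        matrices[pool] = wide[
            ["chr", "integration_locus", "strand", "GeneName", "GeneStrand"] + pool_ids
        ].reset_index(drop=True)

    # raw-read statistics; planted outliers are depth_factor below the pool
    raw = np.round(rng.lognormal(np.log(cfg.mean_reads), 0.15, len(meta)))
    stats = pd.DataFrame({REPLICATE_ID: meta[REPLICATE_ID], "raw_reads": raw.astype(np.int64)})
    # one planted outlier per pool at most: two extreme values in one pool
    # would inflate the pool spread and mask each other
    pools = list(matrices)
    if cfg.outlier_samples > len(pools):
        raise ValueError("cannot plant more outliers than pools (one per pool)")
    out_idx = []
    for pool in rng.permutation(pools)[: cfg.outlier_samples]:
        pool_rows = np.flatnonzero((meta["pool_id"] == pool).to_numpy())
        out_idx.append(int(rng.choice(pool_rows)))
    for i in out_idx:
        stats.loc[i, "raw_reads"] = max(1, int(raw[i] * cfg.outlier_depth_factor))
        truth["outliers"].append(
            {"replicate_id": meta[REPLICATE_ID].iloc[i], "pool": meta["pool_id"].iloc[i]}
        )

    scenario = Scenario(
        config=cfg,
        metadata=meta,
        stats=stats,
        gene_lengths=genes,
        matrices=matrices,
        truth=truth,
    )

    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        paths = {}
        pool_paths = {}
        for pool, wide in matrices.items():
            p = out_dir / f"matrix_{pool}.tsv"
            wide.to_csv(p, sep="\t", index=False)
            pool_paths[pool] = str(p)
        meta_out = meta.copy()
        meta_out["path_to_matrix"] = meta_out["pool_id"].map(pool_paths)
        paths["metadata"] = str(out_dir / "metadata.tsv")
        meta_out.to_csv(paths["metadata"], sep="\t", index=False)
        paths["stats"] = str(out_dir / "stats.tsv")
        stats.to_csv(paths["stats"], sep="\t", index=False)
        paths["gene_lengths"] = str(out_dir / "gene_lengths.tsv")
        genes.to_csv(paths["gene_lengths"], sep="\t", index=False)
        paths["matrices"] = pool_paths
        scenario.paths = paths
        scenario.metadata = meta_out
    return scenario
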