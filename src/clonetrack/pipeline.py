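"""End-to-end pipeline: import -> recalibrate -> collisions -> filters ->
aggregate -> analytics, driven by a serializable run configuration.

Each enabled stage writes its tabular outputs (TSV) and a stage report
(JSON); a final plain-HTML summary stitches the stage reports together.
Reports are views: every number they show is recomputable from the TSVs.
"""

from __future__ import annotations

import html
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import (
    aggregation,
    cis_analysis,
    collisions,
    data_model,
    diversity_stats,
    population_size,
    quality_filters,
    recalibration,
    sharing_tracking,
)
from .data_model import REPLICATE_ID, StageReport

log = logging.getLogger("clonetrack")

CANONICAL_STAGES = (
    "import",
    "recalibrate",
    "collisions",
    "filter_outliers",
    "filter_purity",
    "aggregate",
    "stats",
    "abundance",
    "cis",
    "sharing",
    "popsize",
)


@dataclass
class RunConfig:
    """Fully serializable description of one pipeline run."""

    metadata_path: str = ""
    stats_path: str | None = None
    gene_lengths_path: str | None = None
    output_dir: str = "clonetrack_out"
    stages: tuple = CANONICAL_STAGES
    # stage parameters (recalibration window, collision ratio, purity ratio,
    # outlier / CIS significance levels)
    recalibration_threshold: int = 4
    reads_ratio: float = 10.0
    impurity_ratio: float = 10.0
    purity_min_value: float = 3.0
    outlier_alpha: float = 0.01
    cis_alpha: float = 0.05
    strand_aware: bool = True
    quantification: str = "seqCount"
    independence_key: tuple = ("subject_id", "project_id")
    date_field: str = "treatment_date"
    aggregation_key: tuple = ("subject_id", "cell_marker", "tissue", "timepoint")
    purity_group_key: tuple = ("subject_id", "timepoint", "cell_marker")
    popsize_window: int = 3
    id_col: str = REPLICATE_ID
    workers: int = 1
    seed: int = 0
    log_level: str = "INFO"

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        cfg = cls(**data)
        cfg.stages = tuple(cfg.stages)
        cfg.independence_key = tuple(cfg.independence_key)
        cfg.aggregation_key = tuple(cfg.aggregation_key)
        cfg.purity_group_key = tuple(cfg.purity_group_key)
        return cfg


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute the enabled stages in canonical order; returns artifact paths.

    Raises on stage failure after retaining partial artifacts on disk.
    """
    logging.basicConfig(level=cfg.log_level)
    out = Path(cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    enabled = [s for s in CANONICAL_STAGES if s in cfg.stages]
    if list(enabled) != [s for s in cfg.stages if s in CANONICAL_STAGES]:
        log.warning("stages reordered to the canonical pipeline order: %s", enabled)
    artifacts: dict[str, str] = {}
    reports: list[StageReport] = []

    meta = data_model.read_metadata(cfg.metadata_path, cfg.id_col)
    if cfg.stats_path:
        stats = data_model.read_vispa2_stats(cfg.stats_path, cfg.id_col)
        meta, unmatched = data_model.attach_raw_reads(meta, stats, cfg.id_col)
        if unmatched:
            log.warning("no raw reads for %d replicates", len(unmatched))

    m, report = data_model.import_guided(
        meta, workers=cfg.workers, strand_aware=cfg.strand_aware, id_col=cfg.id_col
    )
    _save(m, out / "matrix_imported.tsv", artifacts, "import")
    _save_report(report, out, reports, artifacts)
    log.info("imported %d rows", len(m))

    if "recalibrate" in enabled:
        m, mapping = recalibration.compute_near_integrations(
            m,
            threshold=cfg.recalibration_threshold,
            strand_aware=cfg.strand_aware,
            id_col=cfg.id_col,
        )
        mapping.to_csv(out / "recalibration_map.tsv", sep="\t", index=False)
        artifacts["recalibration_map"] = str(out / "recalibration_map.tsv")
        _save(m, out / "matrix_recalibrated.tsv", artifacts, "recalibrate")

    if "collisions" in enabled:
        m, report, verdicts = collisions.remove_collisions(
            m,
            meta,
            independence_key=cfg.independence_key,
            date_field=cfg.date_field,
            reads_ratio=cfg.reads_ratio,
            quantification=cfg.quantification,
            strand_aware=cfg.strand_aware,
            id_col=cfg.id_col,
        )
        collisions.verdicts_to_frame(verdicts).to_csv(
            out / "collision_verdicts.tsv", sep="\t", index=False
        )
        artifacts["collision_verdicts"] = str(out / "collision_verdicts.tsv")
        _save(m, out / "matrix_no_collisions.tsv", artifacts, "collisions")
        _save_report(report, out, reports, artifacts)

    if "filter_outliers" in enabled and "raw_reads" in meta.columns:
        flags, report = quality_filters.outliers_by_pool_fragments(
            meta, alpha=cfg.outlier_alpha, id_col=cfg.id_col
        )
        quality_filters.flags_to_frame(flags).to_csv(
            out / "outlier_flags.tsv", sep="\t", index=False
        )
        artifacts["outlier_flags"] = str(out / "outlier_flags.tsv")
        m = quality_filters.drop_flagged(m, flags, cfg.id_col)
        _save_report(report, out, reports, artifacts)

    if "filter_purity" in enabled:
        m, report = quality_filters.purity_filter(
            m,
            meta,
            group_key=list(cfg.purity_group_key),
            min_value=cfg.purity_min_value,
            impurity_ratio=cfg.impurity_ratio,
            quantification=cfg.quantification,
            strand_aware=cfg.strand_aware,
            id_col=cfg.id_col,
        )
        _save(m, out / "matrix_pure.tsv", artifacts, "filter_purity")
        _save_report(report, out, reports, artifacts)

    agg = None
    if "aggregate" in enabled:
        agg = aggregation.aggregate_values_by_key(
            m, meta, key=list(cfg.aggregation_key), id_col=cfg.id_col
        )
        _save(agg, out / "matrix_aggregated.tsv", artifacts, "aggregate")

    if "stats" in enabled:
        stats_tab = diversity_stats.sample_statistics(
            m,
            meta,
            key=list(cfg.aggregation_key),
            strand_aware=cfg.strand_aware,
            id_col=cfg.id_col,
        )
        _save(stats_tab, out / "group_statistics.tsv", artifacts, "stats")

    if "abundance" in enabled:
        ab = diversity_stats.compute_abundance(
            m, meta, key=list(cfg.aggregation_key), quantification=cfg.quantification,
            id_col=cfg.id_col,
        )
        _save(ab, out / "abundance.tsv", artifacts, "abundance")

    if "cis" in enabled and cfg.gene_lengths_path:
        genes = pd.read_csv(cfg.gene_lengths_path, sep="\t")
        cis = cis_analysis.cis_grubbs(
            m, genes, alpha=cfg.cis_alpha, strand_aware=cfg.strand_aware
        )
        _save(cis, out / "cis_genes.tsv", artifacts, "cis")

    if "sharing" in enabled:
        rows = sharing_tracking.is_sharing(
            m, meta, keys=["subject_id"], mode="permutations",
            strand_aware=cfg.strand_aware, id_col=cfg.id_col,
        )
        _save(
            sharing_tracking.sharing_to_frame(rows),
            out / "sharing.tsv",
            artifacts,
            "sharing",
        )

    if "popsize" in enabled and "timepoint" in meta.columns:
        frames = []
        for subject in sorted(meta["subject_id"].unique()):
            hists, tps = population_size.build_capture_histories(
                m, meta, subject=subject, strand_aware=cfg.strand_aware, id_col=cfg.id_col
            )
            if len(tps) < 2:
                continue
            ests = population_size.sliding_estimates(hists, tps, window=cfg.popsize_window)
            frames.append(population_size.estimates_to_frame(ests, subject))
        if frames:
            _save(
                pd.concat(frames, ignore_index=True),
                out / "population_size.tsv",
                artifacts,
                "popsize",
            )

    summary = out / "summary.html"
    summary.write_text(_render_summary(reports))
    artifacts["summary_html"] = str(summary)
    (out / "run_config.yaml").write_text(yaml.safe_dump(asdict(cfg), sort_keys=False))
    return artifacts


def _save(df: pd.DataFrame, path: Path, artifacts: dict, key: str) -> None:
    df.to_csv(path, sep="\t", index=False)
    artifacts[key] = str(path)


def _save_report(report: StageReport, out: Path, reports: list, artifacts: dict) -> None:
    p = out / f"report_{report.stage_name}.json"
    report.to_json(p)
    reports.append(report)
    artifacts[f"report_{report.stage_name}"] = str(p)


def _render_summary(reports: list[StageReport]) -> str:
    """Minimal static HTML stitching the stage reports (no templating engine)."""
    parts = ["<html><head><title>clonetrack run summary</title></head><body>"]
    parts.append("<h1>Pipeline run summary</h1>")
    for r in reports:
        parts.append(f"<h2>{html.escape(r.stage_name)}</h2>")
        parts.append("<pre>")
        parts.append(html.escape(json.dumps(r.to_dict(), indent=2, default=str)))
        parts.append("</pre>")
    parts.append("</body></html>")
    return "\n".join(parts)
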