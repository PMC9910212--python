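# clonetrack

Clonal tracking of vector integration sites (IS) for gene-therapy studies.

In hematopoietic stem cell gene therapy, every corrected cell carries the
viral vector integrated at a (chromosome, locus, strand) position that is
inherited by all of its progeny — a natural clonal barcode.  Sequencing the
vector–genome junctions of follow-up samples yields, per sequencing pool, a
sparse matrix of clones (rows) by PCR replicates (columns) whose cells hold
read counts (`seqCount`) or sonication-fragment genome estimates
(`fragmentEstimate`).  Analysts use these matrices to answer the safety and
efficacy questions regulators ask over decade-long follow-ups: is the graft
polyclonal?  Is any clone expanding?  Is any gene over-targeted?  How large
is the active stem-cell pool?

`clonetrack` is a metadata-driven toolkit for this analysis.  A per-replicate
metadata table (subject, tissue, cell marker, time point, pool, treatment
date, …) keyed by the replicate identifier drives every stage:

* **import** — metadata-guided reading of wide sparse matrices into a tidy
  long form (only observed entries are stored; only metadata samples are
  imported), optionally in parallel;
* **recalibration** — events whose loci wobble within a window (default
  4 bp, i.e. ±3 bp) on the same chromosome/strand are merged by a sliding
  anchor scan, summing quantifications and emitting an old→new map;
* **collision removal** — a clone seen in two *independent* subjects is
  almost surely cross-contamination; it is reassigned by an ordered cascade
  (earliest treatment date → most distinct PCR replicates → ≥10× summed
  quantification) or discarded;
* **quality filters** — per-pool flagging of under-sequenced samples
  (lower-tail Student-*t* on log₂ raw reads) and a purity filter removing
  clones whose quantification in one dependent group is >10× below the
  group holding their maximum;
* **aggregation** — SQL-GROUP-BY-style collapsing of replicates to samples,
  tissues or whole patients via any metadata key, with pluggable reducers;
* **analytics** — descriptive statistics; Shannon (H = −Σ pᵢ ln pᵢ),
  Simpson (1 − Σ pᵢ²), inverse Simpson, Rényi of any order and Pielou
  evenness (J = H / ln S); relative clonal abundance with >1 %-at-any-time
  top-clone flagging; Grubbs-style common-insertion-site detection on
  length-normalized gene integration frequencies with BH-FDR; gene-by-gene
  Fisher exact comparison of two integration profiles; set-algebra IS
  sharing with truth tables and first-source time point tracking; and
  capture–recapture (bias-corrected Chao lower bound,
  N̂ = S_obs + (t−1)/t · f₁(f₁−1)/(2(f₂+1))) estimation of the active
  HSPC population size, overall and over sliding time point triplets.

A synthetic-scenario generator (`clonetrack.synthetic_fixtures`) builds
multi-pool, multi-subject, multi-time point datasets with planted
collisions, wobble pairs, under-sequenced samples, impurity events and an
over-targeted gene, so every stage is testable end to end without any
external data.

## Worked example

```python
from clonetrack import ScenarioConfig, generate_scenario, import_guided
from clonetrack import compute_near_integrations, remove_collisions
from clonetrack import build_capture_histories, sliding_estimates

scenario = generate_scenario(ScenarioConfig(seed=1), "scenario_dir")
matrix, report = import_guided(scenario.metadata)
print(f"imported {len(matrix)} observations, "
      f"{report.totals_after['distinct_is']} distinct IS")

matrix, recal_map = compute_near_integrations(matrix, threshold=4)
n_after = recal_map[["chr_after", "integration_locus_after",
                     "strand_after"]].drop_duplicates().shape[0]
print(f"recalibration: {len(recal_map)} events -> {n_after}")

matrix, coll_report, verdicts = remove_collisions(matrix, scenario.metadata)
t = coll_report.totals_after
print(f"collisions: {t['collisions_found']} found, "
      f"{t['collisions_reassigned']} reassigned, {t['collisions_discarded']} discarded")

hists, timepoints = build_capture_histories(matrix, scenario.metadata, subject="PT01")
for est in sliding_estimates(hists, timepoints, window=3):
    label = "overall" if est.overall else "-".join(str(int(t)) for t in est.window)
    print(f"  {label}: S_obs={est.s_obs}  N_hat={est.estimate:.1f} +/- {est.std_err:.1f}")
```

prints

```
imported 8634 observations, 915 distinct IS
recalibration: 915 events -> 900
collisions: 20 found, 20 reassigned, 0 discarded
  30-90-180: S_obs=299  N_hat=299.1 +/- 0.3
  90-180-270: S_obs=300  N_hat=300.2 +/- 0.4
  overall: S_obs=300  N_hat=304.5 +/- 5.7
```

The 15 planted wobble pairs collapse (915 → 900 events), all 20 planted
cross-subject collisions are reassigned to their true source subject by
the treatment-date criterion, and the capture–recapture estimates recover
this subject's simulated clone pool (300 clones): per-window detection is
near-saturating (4 samples per time point), so S_obs is close to N̂, while
the overall estimate adds the clones that escaped some occasions.

The same pipeline runs from the shell:

```sh
clonetrack simulate --seed 1 --out scenario_dir
clonetrack run --config run.yaml   # or stage-by-stage subcommands:
clonetrack recalibrate --matrix long.tsv --out recal.tsv --map-out map.tsv
```

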