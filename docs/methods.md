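# Methods

This note documents the models, procedures and numerical choices behind
`clonetrack`, the assumptions they rest on, and what the synthetic test
scenarios do and do not establish about real data.

## Data model

An integration event is the triple (chromosome, locus, strand); the locus is
a 1-based single-base position with no end coordinate (junction sequencing
resolves insertion points, not intervals).  Strand-aware mode is the
default: events differing only in strand are distinct clones.  Strand can be
ignored (`strand_aware=False`) for protocols that do not resolve it.

Matrices are held long/tidy: one row per observed (event, replicate,
quantification-kind) triple.  Zeros, empty cells and NA in a wide input file
are treated identically — "not observed" — and dropped at melt time; this is
what keeps decade-scale datasets tractable and it means a written matrix
round-trips up to the representation of absence.  Chromosome labels are
stored bare; a leading `chr` prefix is stripped on read.  Any column of a
wide file outside the fixed annotation set (`chr`, `integration_locus`,
`strand`, `GeneName`, `GeneStrand`) is a sample column, and duplicate sample
headers are a hard error because the replicate identifier is the join key to
metadata.  Import is metadata-guided: files listed in the metadata are read
(optionally by a thread pool; output is sorted so worker count cannot change
it), columns absent from the metadata are discarded and counted.

## Recalibration

Alignment noise shifts the reported locus of one true insertion by a few
base pairs between pools, which would split a clone's history.  Events on
one chromosome/strand are sorted by locus and scanned with a sliding anchor
window: the first unclustered event anchors a cluster and absorbs following
events at distance < threshold (default 4 bp, i.e. wobble within ±3 bp); an
event at ≥ threshold from the anchor starts a new anchor.  Because surviving
anchors are pairwise ≥ threshold apart, a later event can only ever be near
the latest anchor, so this scan equals the exhaustive all-anchors clustering
(the property the test-suite oracle checks) and a second pass is a no-op.
Chains are deliberately not followed transitively beyond the anchor: a run
of events each 3 bp apart does not condense into one event spanning tens of
bp.

Cluster members' per-replicate, per-kind values are summed.  The
representative coordinate is a module parameter because junction evidence
does not dictate it: `max_value` (default) keeps the member with the largest
total quantification — the best-supported coordinate — with ties broken
toward the lowest locus; `keep_first` keeps the anchor for strict
positional reproducibility.  Gene annotation is inherited from the
representative.  The old→new map of every input event is emitted for audit.

## Collision removal

A clone observed in two independent subjects is treated as
cross-contamination: with ~3×10⁸ accessible insertion positions,
independent identical insertions are vanishingly rare.  Independence is
purely metadata-defined (default key: subject within project).  Per
colliding event the cascade is:

1. **date** — the group with the strictly earliest date (default field:
   treatment date, compared at day resolution) wins: a clone cannot predate
   its own transduction elsewhere;
2. **replicates** — the group observing the event in strictly the most
   distinct PCR replicates wins;
3. **ratio** — a group whose summed quantification (default kind
   `seqCount`) is at least `reads_ratio` (default 10) times every other
   group's wins;
4. otherwise the event is discarded from all groups.

Each criterion is judged over all competing groups; when a criterion
produces no strict winner the next is tried.  The winner keeps all its
rows.  Verdicts carry per-group diagnostics (date, replicate count, value
sum) for audit, and the stage report exposes the accounting identity
`IS_after = IS_before − discarded` together with reassignment/discard
percentages.

## Quality filters

**Under-sequenced samples.**  Per sequencing pool, raw read counts are
log₂(x+1)-transformed (spanning orders of magnitude), standardized against
the pool mean and SD, and each sample's z-score is referred to the lower
tail of a Student *t* with n−1 df.  A sample is flagged iff p < α (default
0.01) *and* it lies below the pool mean — only under-sequencing distorts
clone recovery.  Pools with fewer than 3 members or zero spread yield no
flags (no meaningful spread estimate); missing read counts are flagged
separately as missing data.  An optional pre-normalization by pool depth is
not applied by default.  With one extreme sample in a pool of ~12 the pool
SD is inflated by the outlier itself, which this test tolerates; two
extreme outliers in one small pool can mask each other — a known limitation
of single-outlier tests.

**Purity filter.**  Within dependent groups (e.g. sorted lineages of one
subject at one time point), a clone's trace presence far below its dominant
group is carry-over.  Steps: (1) rows of the selected kind with value <
`min_value` (default 3) are dropped, together with sibling-kind rows of the
same (event, replicate) to keep kinds coherent; (2) events present in ≥ 2
groups are processed, all others pass; (3) an event is removed from every
group where max-group-value / group-value > `impurity_ratio` (default 10,
strict inequality); the maximum holder always survives.  Raising the ratio
removes monotonically fewer rows; raising `min_value` keeps monotonically
fewer.

## Aggregation

SQL GROUP BY semantics: the long matrix is left-joined to metadata on the
replicate id, grouped by (event, key fields), and each quantification kind
is reduced by registered functions (default sum) — so a clone observed in
one replicate of a group is present in the aggregate with that replicate's
value.  Reducers resolve to pandas aggregation primitives; user callables
can be registered by name.  Missing key values group under an explicit
sentinel rather than being dropped.  Aggregating by a key refinement and
then the coarser key equals aggregating by the coarser key directly (sums
are associative), which the suite verifies.  Metadata aggregates per key
tuple with per-field defaults: numeric → sum and mean, dates → min,
identifiers → distinct count.

## Diversity, abundance, top clones

All indices operate on a group's clone-size vector v with pᵢ = vᵢ/Σv:
Shannon H = −Σ pᵢ ln pᵢ; Simpson reported as the complement 1 − Σ pᵢ² (raw
Σ pᵢ² available as dominance); inverse Simpson 1/Σ pᵢ²; Rényi of order q,
ln(Σ pᵢ^q)/(1−q), continuous at q = 1 where it equals H; Pielou
J = H/ln S, undefined (NaN) at S = 1.  Natural logarithms throughout so
that J is consistent; the base is a parameter.  All indices are invariant
to uniform scaling of counts.  Relative abundance is 100·v/Σv per group;
clones exceeding a threshold (default 1 %) at any time point form the
highlighted "ribbon" set of stream plots, the rest the background stratum.
Descriptive statistics (count, sum, mean, median, SD, skew, kurtosis, …)
are computed per group and kind alongside the distinct-IS count; statistics
undefined at the group size (SD of one value) are reported missing.

## Common insertion sites

Per gene g with length L_g and k_g distinct IS: raw frequency k_g/L_g is
rescaled by the mean gene length (a dimensionless convenience — any
positive constant cancels in the z-standardization and cannot change
significance calls, which is why the exact constant is exposed but
irrelevant), transformed x_g = −log₂(scaled), and standardized
z_g = (mean(x) − x_g)/sd(x) so large z means over-targeted.  The Grubbs
outlier conversion t_g = z_g·√(n−2)/√(n−1−z_g²) (t = +∞ when z² ≥ n−1) is
referred to the upper tail of Student *t* with n−2 df — one-sided, since
only over-targeting is a genotoxicity signal — and Benjamini–Hochberg FDR
is applied (the classical multiply-by-n Grubbs correction is available as
an option).  Genes with zero spread in x yield no calls.  The test needs
≥ 3 genes and a length for every annotated gene.  Fisher track comparison
builds, per gene, the 2×2 table [[k_A, N_A−k_A], [k_B, N_B−k_B]] of
distinct IS in/outside the gene for two profiles and reports the two-sided
exact p (unadjusted by default, matching the convention of significance at
p < 0.05 on scatter comparisons; BH available).

## Sharing and source tracking

Sharing is set algebra on event identity only — quantifications are
ignored, and any minimum-value filtering belongs to the purity filter.
For each group tuple: |∩|, percentages on each group and on the union, and
optionally the shared coordinates and a truth table (membership vector per
union member) for Venn/Euler plotting (capped at 5 sets for Venn).
Permutations mode emits ordered duplicates plus self-pairs for square
heatmaps; combinations mode each unordered tuple once.  `iss_source`
labels every event of a reference series with its earliest observation
time point and emits stacked-bar data of how many events at each observed
time point trace to each source time point.

## Population size

Time points are capture occasions; a clone is captured at a time point if
it has any retained observation there (magnitude ignored) after optional
per-kind thresholds and lineage restriction via a marker→lineage map.  The
estimator is the bias-corrected Chao lower bound on the capture-frequency
counts f₁ (seen once) and f₂ (seen twice):

    N̂ = S_obs + A·f₁(f₁−1)/(2(f₂+1)),   A = (t−1)/t

with the matching standard variance formula on (f₁, f₂).  The (t−1)/t
factor is the standard small-sample correction for incidence data over t
occasions: under homogeneous per-occasion detection it makes the estimator
essentially unbiased (for t = 3, p = 0.3 the uncorrected abundance-style
form overshoots by ~17 % in expectation, the corrected one by < 1 %).
The uncorrected form is available via `occasion_correction=False`.
Assumptions: closed population within the window (no birth/death of
clones), independent occasions; the estimate is a lower bound under
capture heterogeneity and is always ≥ S_obs, with equality at f₁ = 0.
Estimates are produced per sliding window of neighboring time points
(default triplets) plus one overall estimate; a single occasion is refused
(recapture undefined), and occasions emptied by filtering are dropped with
a warning.  Open-population (Jolly–Seber-style) models are intentionally
out of scope; the `model` tag is reserved for them.

## Synthetic scenarios

The generator emulates a desk-scale trial: 3 subjects, 4 time points
(days 30/90/180/270), one pool per time point, 2 cell markers × 2 PCR
replicates per subject and time point, 300 clones per subject.  Loci are
uniform over chromosomes on a 10 bp grid sampled without replacement, so
distinct clones are always ≥ 10 bp apart and only planted wobble siblings
(1–3 bp offsets) fall inside the 4 bp recalibration window.  Per-sample
presence is Bernoulli (p = 0.6) and counts are log-normal (µ = 2, σ = 1 on
the log scale); genes (100, lengths 30–80 kb) are assigned with
probability proportional to length, the planted over-targeted gene 10-fold
above its share.  Planted structures and their intended outcomes are
recorded in a truth table: 20 collisions (subjects have distinct treatment
dates, so the earlier-treated subject is the intended winner), 15 wobble
pairs, 10 impurity events (trace value 5 — above the default min-value
pre-filter, so the ratio step is what removes it), and 3 under-sequenced
samples at 10⁻³ of their pool depth, placed at most one per pool because
two extreme outliers in one small pool mask each other in the pool
statistic.  The same seed yields byte-identical files.

What this does not emulate: integration hotspots beyond the single planted
gene, PCR/sequencing error, fragment-estimate quantification bias,
realistic clone-size dynamics over time, or heterogeneous capture across
clones.  Passing the end-to-end recovery tests therefore shows the
algorithms implement their definitions correctly at realistic desk scale —
not that the default thresholds are optimal for any particular assay.

## Problem sizes and numerics

The test suite and acceptance script use: 200 random instances (≤ 50
events) for the recalibration/brute-force oracle; 100 random count vectors
against the reference diversity implementation (agreement to 1e-9); 100
Monte-Carlo replicates of a closed population (N = 1000, p = 0.3, 3
occasions) for Chao parameter recovery; 200 null datasets (600 IS uniform
over 80 equal-length genes) for FDR control of the CIS test; and the
default synthetic scenario for end-to-end recovery.  Ties in the
`max_value` representative rule break toward the lowest locus; dates are
compared as calendar days; diversity indices reject non-positive values;
degenerate inputs (single clone, single occasion, zero-spread pools,
zero-total groups) return defined missing values or refuse loudly rather
than guessing.
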