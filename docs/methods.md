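# Methods

This note records the models, conventions and numerical choices behind
`omicshape`, in the order the pipeline runs them.

## Data model

Quantification tables are entity × sample grids with explicit sample
metadata (condition N−/N+, timepoint in hours, replicate). `NaN` always
means "not quantified"; in MaxQuant LFQ output a `0` cell is an
unquantified measurement, so zeros are converted to missing at read time,
before anything is counted. Contaminant and reverse-decoy rows are dropped
at read time for the same reason. Sample order is dictated by the
user-supplied sample map (column name → condition/timepoint/replicate),
never by column order on disk, because `proteinGroups` header conventions
vary across MaxQuant versions.

## Preprocessing

**Missingness filter.** A protein is kept if it is quantified in at least
`ceil(min_fraction × n)` samples of *each* condition (default
`min_fraction = 0.5`). Two counting semantics exist in practice — per
sample and per timepoint (a timepoint counts if any replicate is present) —
and both are implemented behind a mode flag; sample-level is the default.
The filter is monotone: lowering `min_fraction` never removes a previously
kept protein.

**Down-shifted normal imputation.** Missing log2 cells in column *j* are
drawn from N(μⱼ − d·σⱼ, (w·σⱼ)²) with defaults d = 1.8, w = 0.3, where
μⱼ/σⱼ are computed from the column's present values (sample SD, ddof = 1).
Columns are imputed independently, in sample order, from a single seeded
`numpy` Generator, so results are bit-reproducible and independent of
entity order. Rationale: LFQ missingness is intensity-dependent (MNAR), so
plausible imputations sit in the low-intensity tail, not at the column
mean. A column with fewer than two present values has no defined SD and is
an error rather than a guess.

**Fold changes.** Replicate means are taken on the log2 scale within each
(condition, timepoint); the fold change is mean(N−) − mean(N+), i.e.
log2 of the intensity ratio. Timepoints present in only one condition are
excluded with a warning (in the reference design the transcriptome lacks
the 10th-day sample, so cross-layer comparison covers 3–48 h).

**Differential testing.** Per entity per timepoint, a Welch
(unequal-variance) two-sample t-test of N− vs N+ replicates; Student's
variant is available via `equal_var=True` and a pooled-across-timepoints
mode via `pooled=True`. Benjamini–Hochberg adjustment is applied across
entities within each timepoint (deterministic, standard; a
permutation-based FDR would depend on an unspecified permutation scheme).
Zero variance in both groups is resolved by convention: equal means → p = 1,
unequal → p = 0, logged.

## Shape-based distance

Series are z-normalized with the population (1/m) variance convention; a
zero-variance series maps to the all-zero vector and is treated as
degenerate. The coefficient-normalized cross-correlation is

NCCc(x, y)[w] = Σₜ x̃ₜ ỹₜ₊w / (‖x̃‖·‖ỹ‖),  w ∈ [−(m−1), m−1],

computed over zero-padded overlaps via FFT (`scipy.signal.correlate`,
verified in the tests against a direct O(m²) sliding-dot-product oracle to
1e−9). All coefficients lie in [−1, 1]; SBD = 1 − max coefficient lies in
[0, 2]. Sign convention: a positive best shift means the second series lags
the first, so for a protein trailing its transcript,
`sbd(transcript, protein)` reports a positive shift.

Tie-break at the maximum: smallest |shift| first, then negative before
positive. Degenerate inputs: flat-vs-flat is distance 0 (identical shapes);
flat-vs-anything-else is 1, the uninformative midpoint — this avoids NaN
propagation while ranking flat pairs sensibly.

The time axis is index rank, not hours: the 3/6/12/24/48 h design is
uneven, but 5–6-point series cannot support continuous-time alignment and
cross-correlation shifts are integer index shifts. Consequently a "shift of
1" means one sampling step, whatever its duration.

**Exactness of shift recovery.** For delayed copies of *localized* shapes
(e.g. a single bump), the zero-padded cross-correlation recovers the
imposed shift exactly for |d| ≤ m/3 (property-tested). For arbitrary
series — including random walks — exact recovery is only statistical: the
truncated overlap at nonzero shifts can let a competing shift win, and a
monotone series' delayed copy correlates almost perfectly at shift 0. This
is a property of zero-padded cross-correlation itself, not of the
implementation.

**Concordance classes.** SBD values of all paired genes form the reference
pool; its 25th/75th percentiles (linear-interpolation quantiles — the
convention is configurable and recorded with the thresholds) split genes
into highly similar (< Q1), highly unsimilar (> Q3) and indistinct.
Inequalities are strict, so degenerate pools classify everything as
indistinct. Per-category fractions are computed against the all-gene pool
by default; a per-subset reference is available.

**k-shape clustering.** Random initial assignment from a seed, then
alternation of (a) per-cluster shape extraction — members aligned to the
current centroid at their optimal SBD shift, centroid taken as the
principal eigenvector of the centered Gram matrix QᵀSQ, sign fixed against
the aligned-member mean, z-normalized — and (b) reassignment of each
profile to its nearest centroid by SBD. Emptied clusters are reseeded with
the profile farthest from its centroid. Iteration stops when assignments
stabilise or after `max_iter` (default 100). The objective Σ SBD(profile,
centroid) is recorded per iteration.

## Cluster and phase structure

Row clustering uses 1 − Spearman ρ (average ranks; range [0, 2]) with
average-linkage agglomeration (complete/ward configurable — the linkage is
recorded in output metadata) cut at k = 8, the reference design's cluster
count; k is a flag, not an inference. A constant profile has undefined ρ
and is assigned distance 1 to everything, flagged. Column (timepoint)
clustering is Euclidean, cut at 3 phases. PCA treats samples as
observations with centered but unscaled features, since log2 LFQ magnitudes
carry signal.

## Functional summaries

Category counts per cluster are ranked descending with alphabetical
tie-break; the top five are flagged as the cluster's primary functions,
with unannotated genes counted as `unknown`. The category-level layer
comparison reports per-category means (median configurable) of LogetT and
LogetP on shared timepoints and their difference LogetT − LogetP; each
layer aggregates over its own detected members by default (the layers'
detected gene sets differ), with an intersection mode available. The
twelve-category vocabulary is configuration, not code.

## Synthetic data

`generate_paired_series` builds base trajectories as random walks
(cumulative Gaussian steps) — irregular monotone/zigzag shapes like
observed fold-change cluster profiles, without committing to a parametric
family. Delayed pairs copy the transcript shifted by 0–2 steps
(edge-padded: the first value is repeated, as biological trajectories have
no natural zero at the boundary), rescaled by a log-uniform factor in
[0.5, 2], plus Gaussian noise (default sd 0.2 in log2-ratio units).
Independent pairs draw a fresh walk. Defaults (400 pairs, half delayed,
5 timepoints) mirror the reference design's paired-gene scale.

`generate_lfq_matrix` draws log2 intensities around per-entity
condition/timepoint means (baseline N(25, 2²) on the log2-LFQ scale, an
N−-specific random-walk treatment effect with step sd 0.5, replicate noise
sd 0.4) and masks cells with probability logistic in negative log2
intensity (defaults: intercept −2, slope 0.8 per log2 unit below the
baseline mean — about 12% missing at the mean, rising steeply below it,
~20% overall). `intercept = −inf` disables missingness.

What the generators do *not* model: replicate correlation beyond i.i.d.
noise, shared regulatory structure across genes, normalization artefacts,
and count-based noise in FPKM. Passing tests on synthetic data therefore
demonstrate correctness of the computations and the detectability of the
planted delay structure, not biological validity on real data.

**A measured limit of the delay-detection setup.** With 5-point series,
delays up to 2 and edge padding, SBD separates delayed from independent
pairs clearly in distribution (median ≈ 0.17 vs ≈ 0.43; rank-sum
p < 10⁻³), but the overall AUC plateaus near 0.8 even without noise:
a delay of 2 leaves only 3 genuine points after padding, and independent
5-point pairs often align well by chance across the 9 candidate shifts
(per-delay AUC ≈ 0.97 / 0.80 / 0.63 for delays 0 / 1 / 2). Short series
limit per-gene delay resolution; the distribution-level contrast is the
robust signal.

## Problem sizes

Tests and examples run on hundreds of entities and 10⁴–10⁵ random draws:
large enough for Monte-Carlo moments to converge to ~1% and for rank-based
separations to be decisive, small enough that the full suite runs in well
under a minute on one core. The pipeline itself is O(n·m²) in SBD stages
and handles the reference design's ~1800 × 6 scale trivially.
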