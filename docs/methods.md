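# Methods

`replitempo` analyses high-temporal-resolution Repli-Seq: sequencing of
BrdU-labelled nascent DNA from cells FACS-sorted into 16 equal S-phase
fractions (S1–S16), binned at 50 kb, with a G1 whole-genome control. This
note records the models, parameter choices, and numerical conventions the
package commits to, and what its synthetic-data validation does and does
not establish.

## Heatmap construction

Per-track counts are scaled to reads per million (RPM) independently for
each fraction and for G1, mirroring the fact that each FACS fraction is
sequenced as its own library. Each bin's signal per fraction is
`max(0, log2(RPM_S / RPM_G1))`: the G1 ratio removes mappability and
copy-number bias, and negative values — bins with less signal than a
non-replicating control — are treated as noise and clipped to zero. Bins
whose G1 RPM is zero or below `g1_floor` (default 0.1) times the
genome-wide median G1 RPM are masked outright; masking is monotone — a bin
masked here stays masked through every later stage, and masked bins split
chromosomes into independent segments for all downstream rules.

The 16 × N matrix is then smoothed with a truncated 2-D Gaussian
(σ = 1 bin, radius 1 — i.e. each bin is averaged with its 8 neighbours in
the fraction × position lattice). Kernel weights follow
`exp(-(x²+y²)/2σ²)` and are renormalised to sum to one: the continuous
Gaussian prefactor does not normalise a truncated discrete kernel, and the
subsequent column scaling removes any constant factor anyway. Padding
replicates the S1 row above and the S16 row below (a bin fully replicated
in S1 stays replicated), and replicates edge bins along the genome axis.
Chromosomes are smoothed independently — a fork cannot cross a chromosome
boundary, so neither does the kernel. Masked columns are excluded from
neighbour sums with weight renormalisation (normalised convolution) rather
than treated as zeros, so mask borders do not acquire artificial dips.

Finally each unmasked column is scaled to a total of 100, on the
assumption that every bin finishes replicating by the end of S phase;
columns with zero mass (never replicated within S) become masked. The
column values are thereafter read as "percent of cells replicating this
bin in this fraction".

An edge-noise QC reports the mean summed signal in the last `edge_window`
(default 4) fractions over the top-decile earliest bins (by the weighted
RT score) and the symmetric quantity for the latest bins; residual
non-specific signal at the extremes of S phase shows up here.

## Feature segmentation

Unmasked columns are clustered with BIRCH: a CF-tree (subclusters
summarised by count / linear-sum / square-sum triples; threshold 0.5,
branching factor 50) followed by global agglomeration of the subcluster
centroids to the requested cluster count. Centroids are ranked temporally:
primary key, the fraction of maximum replication (ascending); secondary
key, the magnitude at that maximum (descending — a sharper peak means a
more synchronously replicating cluster, which we treat as earlier among
ties). Each bin inherits its cluster's rank (1 = earliest), giving the
rank profile that all feature rules read.

The rules, applied per contiguous unmasked segment after run-length
encoding:

* a same-rank run flanked on both sides by later (higher-rank) bins is an
  **initiation zone (IZ)** — replication starts here before its
  surroundings — regardless of run length;
* a same-rank run flanked on both sides by earlier bins is a
  **small termination site** when ≤ 2 bins (≤ 100 kb) and a **late
  constant-timing region (late CTR)** when > 2 bins;
* the remaining runs (earlier flank on one side, later on the other) are
  slope elements; consecutive slope elements are automatically monotone
  and form a chain. Within a chain spanning at least `min_ttr_bins`
  (default 3) bins, single-bin runs are **timing transition region (TTR)**
  bins — rightward if ranks increase with position, leftward if they
  decrease — and multi-bin plateaus are **breakages**, small internal
  initiation zones that locally flatten the slope. A single-bin run at
  the very start or end of a segment joins an adjacent chain (its value
  already defined the chain's flank); every other run that touches a
  segment end stays uncalled, because its classification would require a
  flank that does not exist. Chains shorter than `min_ttr_bins` also stay
  uncalled.

These conventions make the labelling a partition: every unmasked bin
receives exactly one label (a feature or "unlabelled"). An independent
brute-force interpreter of the same rules, written per-position in the
test-suite, agrees exactly with the run-length implementation on random
rank profiles.

**Cluster-count granularity.** The library default is 50 clusters, suited
to genome-scale inputs. The useful granularity is bounded by the
discriminable profile difference of neighbouring bins: at 1.8 kb/min a
fork crosses a 50-kb bin in ~27.8 min, 0.74 of a 37.5-min fraction window,
so profiles of adjacent bins differ by less than one window. When the
number of centroids exceeds the number of temporally distinguishable
profiles (roughly, the S-phase span of the data in fraction windows), rank
assignment dithers between near-identical centroids and produces spurious
one-bin IZ/termination calls. On the package's desk-scale simulations
(tens to hundreds of bins) the analyses therefore use 10–14 clusters; the
rule of thumb is clusters ≈ distinguishable temporal steps, not bins.

IZ timing classes follow the peak fraction of the IZ's mean profile:
early (S1–3), early-mid (S4–6), late-mid (S7–9), late (S10 and beyond;
the S13–16 tail folds into "late").

## Replication kinetics

The column-wise cumulative sum of a normalised column estimates the
fraction of cells that have replicated the bin by the end of each
fraction's time window; the value of fraction f is therefore assigned the
window-END time `f/16 · s_duration` (window midpoints describe the
per-window increments, not the running sum). S-phase duration defaults to
10 h.

A logistic `F(t) = 100 / (1 + e^{-k (t - t0)})` is least-squares fitted to
the 16 (time, cumulative) points. `T_rep = t0` is the time at which 50 %
of cells have replicated the bin; `T_width = 2·ln 3 / k` is the 25 %→75 %
time spread (the identity follows from the logistic quantile function) and
measures cell-to-cell timing variability. Fitting uses bounded
`least_squares` (k ∈ (0, 50] h⁻¹, t0 ∈ [0, s_duration]) with an analytic
Jacobian, initialised from a non-parametric quantile oracle that linearly
interpolates the 25/50/75 crossing times of the cumulative curve. For
near-step columns the bounded problem's tolerances are unreachable on the
flat residual surface; the solver's final iterate is kept (it is already
at the optimum to numerical precision) rather than discarded. Fits with
residual RMSE above `rmse_cap` (default 5 percentage points) are flagged,
never raised.

**Smoothing and kinetics.** The σ = 1 fraction-axis kernel is itself a
temporal filter with standard deviation ~0.74 windows (~28 min at a 10-h
S phase); it inflates an apparent `T_width` in quadrature. Parameter-
recovery analyses therefore run kinetics on a column-scaled but UNsmoothed
heatmap (`normalize_stack(..., smooth=False)`); the smoothed heatmap
remains the default for feature calling, where the kernel suppresses rank
flicker. `T_width` values fitted from smoothed data should be read as
upper bounds.

**Fork speed.** A TTR's slope measures a single uni-directional fork.
Because breakages are small internal initiation zones, same-direction TTR
pieces separated only by breakage calls are treated as one fork traversal
("breakage-free TTR"): the speed is the inverse slope of an ordinary
least-squares regression of fitted `t_rep` (minutes) on bin-centre
position (kb) over the chain's TTR bins, with breakage bins excluded.
This equals dividing the TTR size by the S-phase time it traverses, but
is unbiased for short pieces (bin-centre times span one bin less than the
interval) and noise-robust for fragmented slopes. Estimates are dropped
when the implied span falls below 0.5 fraction widths, the slope sign
contradicts the TTR direction, or fewer than two bins have usable fits.
`fractions_spanned` is defined so that
`speed = size / (fractions_spanned/16 × s_minutes)` holds exactly.

**Weighted RT score.** Per bin,
`log2((S1·8 + S2·7 + … + S8·1 + ε) / (S9·1 + S10·2 + … + S16·8 + ε))`
with ε = 0.01 keeping single-sided bins finite; positive = early. The
allele RT difference is the element-wise difference of two such tracks.

## Biphasic replication

A monotone cumulative curve cannot have two maxima; "two distinct times of
replication" is operationalised on the per-fraction column profile (the
cumulative curve's increments): a bin is biphasic when the profile has two
local maxima, each ≥ `peak_min` (default 20) percentage points, with a run
of at least `min_gap` (default 1) consecutive intermediate fractions all
≤ `trough_max` (default 5) — the intervening temporal interval in which
replication of neither mode is detectable. Requiring *all* intermediate
fractions below the trough threshold would reject essentially every true
biphasic column, because the smoothing kernel leaves shoulders of ~0.27 ×
peak height next to each peak. Contiguous biphasic bins merge into
regions; regional peaks are the modal per-bin peaks.

Note that the per-fraction RPM scaling makes the two modes' heights
depend on how much of the genome co-replicates with each mode (early- or
late-peak bias); `peak_min` is deliberately a configurable threshold.

Annotation overlap follows a ≥ 50 % containment rule: a region overlaps a
fragile site or long gene (> 200 kb) when at least half of its bins are
fully contained in a single annotation interval. Enrichment of gene sizes
is tested against length-matched segments placed uniformly (without
overlap) over the genome, with a Mann-Whitney U rank comparison and an
empirical median-rank p.

Allele classification of a pooled biphasic region: **allele-independent**
when both allele heatmaps are themselves biphasic over the region;
**allele-dependent** when each allele is unimodal, the allele `t_rep`s
differ by ≥ 2 fraction widths (configurable), and one allele peak matches
each pooled peak within one fraction; anything else is **unresolved**.

## The simulator

Each cell draws, per origin, a firing decision (Bernoulli with the
origin's efficiency) and a firing time (Normal(mean, sd) clipped to
[0, S]); bidirectional forks move at constant speed v (default
1.8 kb/min) and the replication time of a bin centre is the minimum over
fired origins of (firing time + distance / v) — passive replication is
the minimum, not a separate mechanism. Cells with no fired origin on a
chromosome redraw until one fires, a conditioning choice reflecting that
chromosomes do finish replicating. S phase (default 600 min) is sliced
into 16 equal windows; the expected read count of bin j in window f is
`read_depth × mappability_j × (share of cells replicating j in f)` plus an
optional uniform background, with Poisson noise; the G1 control is
Poisson around `g1_depth × mappability`. Bimodal loci replace the local
origin's firing-time mode in a configurable share of cells, tied either
to a fixed allele (allele-dependent asynchrony) or to a per-cell coin
flip (allele-independent).

Defaults: `read_depth = 200` expected reads per bin summed over
fractions (hundreds of reads per covered bin-fraction, the regime of deep
Repli-Seq), `n_cells = 1000–2000` per scenario, firing sd 5–15 min for
tightly programmed origins and larger for deliberately heterogeneous
ones. Normal clipping (rather than redrawing) distorts quantiles only
when a mode sits within ~3 sd of an S-phase boundary; no library scenario
does.

Ground truth: IZ intervals are ±1 bin around origin positions (merged
when origins fall within 2 bins); single-fork spans are the maximal
strictly monotone runs of the deterministic (mean-time, all-fire)
replication-time profile; terminations are its local maxima; per-bin
timing quantiles come from the closed form when all sds are zero,
otherwise from a 10,000-cell Monte-Carlo.

Scenario notes:

* `well_separated_izs` — 20 origins, 800-kb spacing, firing times
  zig-zagging 60→420→60 min so neighbouring origins always differ by
  120 min and terminations fall mid-gap; includes a 2-bin mappability
  hole to exercise masking. The origin beside the hole is (correctly) not
  callable: the mask removes its flank and the rules invent none.
* `pure_ttr` — one edge origin per 1-Mb chromosome; a single fork
  traverses the remaining 19 bins, reaching ~S15; a tiny very-late
  chromosome keeps S16 populated genome-wide (a real genome always has
  late mass; per-fraction RPM requires it).
* `biphasic_allelic` / `biphasic_random` — modes at 125 and 425 min
  (mid-window in S4 and S12), sd 8 min, fork speed 3 kb/min, against a
  sawtooth context chromosome whose forks sweep S uniformly so the
  per-fraction RPM scaling does not skew the two modes; mode positions
  mid-window matter because a 50/50 mixture caps each mode's column mass
  at 50 and smoothing retains only ~0.45 of an isolated window's mass,
  so modes straddling window boundaries can fall below the 20-point peak
  threshold. This is a genuine sensitivity limit of the thresholded
  detector, not of the simulation.

## Known limitations

* **Slope quantisation.** At v = 1.8 kb/min, 50-kb bins and 37.5-min
  windows, a fork crosses a bin in less than one window, so roughly every
  fourth pair of neighbouring bins peaks in the same window and forms a
  2-bin same-rank plateau that the rules (faithfully) label breakage even
  inside a pure single-fork span. Fork-speed estimation is immune (the
  breakage-free merging above); consumers of breakage calls should treat
  isolated 2-bin breakages in otherwise clean slopes as a resolution
  artifact. Raising firing heterogeneity does not help: it replaces
  plateaus with noise-driven rank inversions.
* The synthetic data contain no GC or fragment-length bias, no
  replication-independent copy-number variation, and mappability enters
  only as a per-bin multiplier; passing tests demonstrate method
  correctness under the stated generative model, not robustness to every
  artefact of real libraries.
* All-zero fraction tracks are rejected rather than worked around; tiny
  synthetic genomes must carry mass in every fraction, as real genomes do.
* `T_rep`/`T_width` assume all bins finish replicating by the end of S16
  (the column scaling enforces completion); if some cells never finish a
  very late region, its true `T_width` is larger than reported.
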