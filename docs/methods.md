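# Methods

`casim` implements the downstream statistics applied to deconvolved calcium
event trains from one-photon microendoscopy of motor cortex (SMA/M1):
per-cell event descriptors, trial-aligned modulation classification,
pairwise coactivation by the Z-Jaccard statistic, and detection of
precisely timed multi-cell event sequences.  The package consumes the
*outputs* of cell extraction and deconvolution (CNMF-E footprints/traces,
OASIS event trains); image preprocessing, extraction and deconvolution are
out of scope.  A synthetic session generator with known planted structure
stands in for recorded data so that every stage has a parameter-recovery
test.

## Data model

A session holds event trains (continuous times in seconds from recording
start, amplitudes in arbitrary units), fluorescence traces on a 10 Hz frame
grid, cell centroids, and (for task recordings) a behavioral trial table.
All times share one clock; analysis segments are half-open `[t0, t1)` so
that splitting a recording into consecutive windows never double-counts a
boundary event.  Event times stay continuous internally — quantisation to
the 10 Hz frame grid or the 0.2 s coactivation grid happens only at the
point of use, avoiding premature rounding.

## Synthetic sessions

Background activity is an independent homogeneous Poisson process per cell.
On top of it the generator can plant:

* **pairwise synchrony** — a shared Poisson process whose events are copied
  to both member cells with independent uniform jitter on `[0, jitter_s]`
  (default 0.2 s, one coactivation bin: common input at the coincidence
  scale of the Jaccard analysis);
* **ordered motifs** — one event per member cell at cumulative step lags
  from a start time, starts drawn with rejection so occurrences never
  overlap within a cell (ground-truth counts stay unambiguous);
* **direction tuning** — during the response window (default 1 s) after
  target onset of matching successful trials, a tuned cell's rate is
  multiplied by `rate_gain` (default 5); `preferred_direction=None` makes a
  cell responsive to every direction.

Traces are rendered by convolving events with a single-exponential kernel
(`tau` = 0.5 s, a GCaMP6f-like decay) on the 10 Hz grid plus i.i.d.
Gaussian noise (default SD 0.05, emulating denoised traces).  Amplitudes
are log-normal(0, 0.5): positive and right-skewed like deconvolved event
amplitudes.  Trial tables follow the two task designs: a one-target reach
(directions left/center/right) and a two-target reach (left/right, 1 s
center hold, explicit movement onset), with inter-trial intervals uniform
on [2, 3] s.  Everything is deterministic given the config seed
(`SeedSequence` spawning per component).

The generator emulates the *statistical* structure of such recordings —
sparse event trains at 0.01–1 events/s, planted coupling, task tuning.  It
does not model photophysics, motion artifacts, cross-session instability,
bursty (non-Poisson) background firing, or amplitude-dependent detection;
passing recovery tests therefore demonstrates correctness of the analysis
chain on data of known structure, not robustness to every pathology of real
recordings.

## Event descriptors

Per cell and segment: event rate (count/duration — exactly, by
construction), IEI CV (sample SD over mean of consecutive inter-event
intervals, n−1 denominator; undefined below 3 events), and mean event
amplitude (undefined for silent cells; amplitudes are taken from the event
file, never re-estimated from traces).  Condition contrasts on the same
cells (spontaneous vs task) use the two-sided Wilcoxon signed-rank test
with zero differences dropped; region contrasts on disjoint cell sets use
the two-sided rank-sum test.  All-zero difference vectors return p = 1 by
convention, and comparisons with fewer than 5 valid pairs are flagged
underpowered rather than suppressed.  Families of tests are corrected by
Benjamini–Hochberg FDR (step-up; via `statsmodels.multipletests`), applied
within a site's descriptor family.

## Trial alignment and modulation

For each successful trial, the 3-s epoch of raw trace from 1 s before to
2 s after the aligned event (target onset; movement onset for the
two-target task) is Z-scored to that trial's baseline: the first second of
the preceding inter-trial interval.  Event times are mapped to frames by
nearest-frame rounding.  Trials with zero baseline SD or epochs outside the
recording are dropped and counted.  Per cell and direction, the mean Z in
the event window (0–1 s) is compared with the pre-window (−1–0 s) by a
signed-rank test across trials; BH-FDR runs across all cell × condition
tests of the session.  Cells significant in exactly one condition are
direction-related, in two or more non-direction-related, in none not
modulated.  |ΔZ| magnitudes (difference of trial-averaged window means) are
compared between increasing and decreasing cells (rank-sum) and across
target positions (Kruskal–Wallis).

Numerical notes.  Because the baseline is 10 frames, dividing by its sample
SD gives the Z-scores Student-type heavy tails: on stationary white noise
the pooled epoch SD is √((1+1/n)(n−1)/(n−3)) ≈ 1.19, not 1.  This affects
both simulated and real data identically and cancels from the paired
within-trial contrast.  Classification power falls with the expected number
of response events per trial (base rate × gain × window): a cell responding
in only half of its preferred trials is frequently missed at 30
trials/condition, so recovery figures are quoted for task-responsive cells
(base rate 0.5 events/s).

## Coactivation (Z-Jaccard)

Events are binned into 0.2 s intervals (binary occupancy; a trailing
partial bin is dropped), forward-smoothed by OR-ing each bin with the four
bins ahead (events within 1 s count as coincident), and each unordered pair
scored with the Jaccard index of its active-bin sets.  The per-pair null
rotates the second cell's smoothed row circularly — preserving its
autocorrelation, destroying cross-cell coupling — 1,000 times and the
observed index is standardised by the null mean and SD (Z-Jaccard); pairs
with |Z| > 1.96 are synchronized.  The relation between Z and centroid
distance is summarised with a loess smoother (span 1).

Implementation choices: rotation offsets are drawn uniformly from
{1, …, T−1}, excluding the identity rotation (drawing from 1..T would
include a replicate equal to the observation, a small conservative bias);
the null Jaccard for *every* offset is obtained exactly from the circular
cross-correlation of the two rows (FFT, rounded back to integer
intersections — row sums are rotation-invariant), so sampling 1,000 offsets
is a table lookup rather than 1,000 recomputations.  Pairs whose null SD is
zero (silent or saturated rows) have no defined Z; they are excluded from
the synchronized-pair denominator and counted in the run log.  Smoothing is
applied before shifting, matching the statistic's definition (shifting raw
bins and then smoothing differs at the wrap boundary).

## Sequence detection

A sequence is an ordered tuple of ≥2 distinct cells whose events recur in
order with every consecutive step in (0.05, 2] s — the lower bound excludes
simultaneous bursts, the upper bound is the per-step limit.  The gap rule
is applied between consecutive events *within* an occurrence (its stated
purpose targets within-occurrence simultaneity); a between-occurrence
separation variant can be configured instead.  Occurrences are counted
greedily: anchor events in time order, each extended by the earliest unused
event of the next cell in its window, with backtracking (so an anchor
matches whenever a completion exists); matched events are consumed, making
occurrences event-disjoint.  On exhaustive small-instance sweeps this
greedy count equals the maximum number of disjoint occurrences, and that
equality is a tested invariant.

Enumeration counts all ordered pairs, then grows only motifs reaching the
minimum repetition count by one cell at a time up to order 5
(downward-closure pruning: a motif never occurs more often than its
contiguous sub-motifs; the unbounded search is intractable for 100+ cells).
Motifs with repeated cells are excluded.  Significance in a 10-min window
requires ≥4 occurrences *and* strictly exceeding the empirical 95th
percentile (order statistic at ⌈0.95·K⌉) of a 1,000-replicate null in which
every member cell except the first is independently circularly shifted by a
uniform offset — each replicate conserves every cell's event count.  The
minimum-repetition filter applies only to observed data; null counts are
raw.  Significant motifs contained as a contiguous ordered subsequence of a
longer significant motif are flagged subsumed but retained.  Two-cell null
counting is vectorised across replicates (one pointer lane per offset),
which is the dominant cost at realistic rates.

Summaries per window: number of significant sequences (normalised by cell
count), repetition counts, proportion of cells participating, and the
pairwise centroid-distance distribution of member cells against all cells
(two-sample Kolmogorov–Smirnov).

Two behaviours of the published procedure are worth knowing.  First,
common-input synchrony with jitter above 0.05 s *is* a two-cell sequence by
definition — the coactivation and sequence analyses overlap on such pairs;
only near-simultaneous coupling (≤0.05 s) is excluded by the gap rule.
Second, candidate motifs are tested at a per-motif 5% level with no
multiplicity control across motifs, so the absolute number of significant
sequences grows with event density: at 0.05 events/s and 20 cells a 10-min
window yields sequence counts on the scale of tens, at 0.1 events/s the
tested order-3 space is ~10× larger and so is the expected false-positive
count.  The per-motif calibration (~3–5%) is what the tests pin down.

## Pipeline

`run_pipeline` executes simulate/load → describe → align → coactivation →
sequences from one nested config.  One global seed derives per-stage
generators via `SeedSequence.spawn` (scheme echoed in the manifest);
outputs are write-once CSVs plus a JSON manifest recording the parameter
echo, completed stages, and every exclusion (dropped trials, invalid pairs,
skipped windows).  Two runs with the same config are byte-identical.

## Problem sizes

Tests and the acceptance script run on synthetic sessions of 10–30 cells
and 10–20 min at 0.05–0.5 events/s, with 1,000-replicate nulls and 10–20
seeds per Monte-Carlo estimate — the scale at which the null calibrations
(±few %) and recovery probabilities (≥0.8–0.9) quoted in the test suite are
stable.

## Known limitations

* The magnitude comparison uses trial-averaged window means; per-trial
  magnitude distributions are not modelled.
* The baseline second is taken as the *first* second of the preceding
  inter-trial interval; for intervals longer than 2 s other readings exist
  (recorded in the alignment metadata).
* Whether occurrence counting may reuse events across occurrences of the
  same motif is a definitional choice here (disjoint-greedy), validated
  against its own oracle.
* No NWB/DANDI ingestion; sessions are read from the four CSV schemas.
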