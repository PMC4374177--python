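# Methods notes

This note documents the models, conventions and numerical choices behind
`sleepclines`, and what the synthetic-data tests do and do not demonstrate
about real DAM data.

## Data model and conventions

A recording is a per-minute integer beam-cross series per fly, aligned to
Zeitgeber time (ZT00 = lights-on; 12:12 LD by default, lights-on clock time
configurable). A "day" is always a full ZT00 -> ZT24 span; the analysis
window (default days 5–12 of the recording) is cut at ZT-day boundaries, so
every downstream per-day statistic divides by whole days. Timestamps are
naive local time; DST and timezone shifts are ignored.

DAM monitor files are assumed to follow the common 42-column tab-delimited
DAMSystem layout (index, date, time, status, six metadata columns, 32
channel counts); column positions and the OK status code are configurable
via `DamLayout`. Readings flagged not-OK, and missing minutes, are *gaps*.
Two gap policies are offered because upstream practice varies and the
correct choice depends on why readings failed: `zero_fill` (default) sets
the minute to 0 and flags it in `gap_mask`; `drop_day` removes every full
ZT day containing a gap. Zero-filling can only inflate sleep, never
activity; users with substantial gaps should prefer `drop_day`.

## Sleep definitions

* Sleep bout: maximal run of >= `threshold` (default 5) consecutive
  zero-count minutes. Runs touching the series boundary are counted from/to
  the boundary (they are genuinely censored; excluding them would bias bout
  number down and mean duration up in short recordings).
* A bout's phase label (photophase/scotophase) is fixed by its starting
  minute. For bouts spanning the lights-on/off boundary the default
  `split` attribution divides the bout's *minutes* between phases for sleep
  duration, while bout count and full duration go to the starting phase for
  bout number and average bout duration; a `start` policy assigns
  everything to the starting phase. The split keeps per-phase sleep
  durations summing to total sleep, while average bout duration remains a
  property of whole bouts.
* Average sleep-bout duration is the mean over all bouts of the phase
  (pooled across days), not a day-then-bout mean; with near-balanced bout
  counts per day the two coincide, and pooling is the better-conditioned
  estimator at low bout counts.
* Walking speed excludes *all* zero-count minutes, not only minutes inside
  sleep bouts — the plainest reading of "per unit time excluding inactive
  time". Sub-threshold quiescence (1–4 min stills) therefore does not
  dilute speed. The alternative is one flag away in the code.
* Hourly bout-duration profiles bin bouts by the ZT hour of their starting
  minute, consistent with the phase-attribution rule.

The exclusion filter computes every 1440-minute sliding window sum via a
cumulative sum and discards a fly if any window totals <= 24 crosses; the
first triggering window is reported. The threshold is inclusive (exactly
24 crosses discards).

## Aggregation

Strict two-stage unweighted means: flies -> line means -> population means,
with the population s.e.m. the standard deviation of line means over
sqrt(n_lines). Isofemale lines, not flies, are the independent genetic
replicates, so unequal fly counts per line must not reweight lines.
Missing values (e.g. walking speed in a never-active phase) propagate as
means over non-missing units.

## Cline statistics

Population means are the regression units (n = number of populations;
typically 5). OLS via `scipy.stats.linregress`; R² = squared Pearson
correlation; two-sided slope *t*-test with n − 2 df. With n = 5 residual
normality is untestable; OLS is retained as the conventional estimator and
the nonparametric rank-based tests are provided for group comparisons
(`mannwhitneyu` with mid-rank tie handling, `kruskal` for >2 groups).
Hour-by-hour scans run 24 regressions and flag significance at alpha/24
(Bonferroni; reject iff p <= alpha/m, inclusive).

## Ramping (sunrise anticipation)

Activity is summed in 30-minute bins over ZT18.0–23.5 (12 bins), averaged
over days within fly then over flies within line, and min-max normalized
per line over the 12 bins. The averaging order (days -> flies -> line) is
fixed; with balanced days per fly it equals the pooled mean. A line whose
12 bins are all equal has an undefined normalization and is excluded with a
warning. Population curves are unweighted means of line curves; per-bin
regressions on latitude use the normalized population means (the curves are
percentages of each line's own maximum, making amplitudes comparable across
lines of different absolute activity).

## Phase and period (constant-dark data)

Free-running period: Sokolove–Bushell chi-square periodogram. For a
candidate period of P minutes and K complete cycles (N = K·P minutes used),
Q_P = K · Σ_h (M_h − M)² / (Σ_i (X_i − M)²/N) is compared to the
chi-square(P − 1) null; the grid is 20–28 h in 0.1-h steps (rounded to
whole minutes) and the reported period maximizes the margin over the
Bonferroni-corrected critical value at alpha = 0.05. No candidate
exceeding its critical value means no detectable rhythm (NaN). The
statistic is invariant to affine count rescaling; planted grid periods are
recovered within one step.

Peak phase: counts smoothed by a 60-min centered moving average (edge
shrinkage), cut into cycles of the estimated (or supplied) period; the
morning peak is the argmax in [0, period/2) and the evening peak in
[period/2, period) of each cycle, averaged over cycles. The first DD cycle
is skipped by default as an entrainment transient. Flat windows contribute
nothing; ties resolve to the earliest maximum. Because peaks are located
well inside their half-cycles in practice, plain (non-circular) averaging
across cycles is used.

## Enrichment

Coordinates are 1-based closed intervals on both genes and windows
(FlyBase/GFF convention); overlap requires >= 1 shared bp (gene end 199
does not touch window start 200). Outlier flagging takes exactly
ceil(fraction × count) windows of highest mean F_ST — the upper tail only,
since high differentiation is the signature of spatially varying selection
— with ties at the threshold broken by genomic position. Overlap queries
use an interval tree, cross-checked in tests against a quadratic all-pairs
oracle.

Hypergeometric tails are inclusive of the observed count and computed by
log-space summation of `hypergeom.logpmf` point masses (`logsumexp`),
stable for tails of order 1e-25. The enrichment universe is the expressed
gene set (not all annotated genes), matching how the published DE
percentages are expressed. Depletion questions use the inclusive lower
tail. Fold enrichment (k/n)/(K/N) compares the sample DE proportion to the
*genome-wide* proportion; the comparison to genes *outside* the sample
((K−k)/(N−n)) is a different, slightly larger number for an enriched
sample — the genome-average version is what the percent-excess statistic
reports.

## Synthetic data

Behavior: a two-state alternating renewal process on the minute grid. Run
lengths are geometric — the discrete memoryless choice, so a run in
progress at a phase boundary continues with its original parameters, which
forces downstream attribution rules to be exercised exactly as real
boundary-spanning bouts do. A run's parameters are those of the phase of
its starting minute. Sleep minutes record 0; wake minutes draw
Poisson(rate), so awake-but-still minutes (Poisson zeros) occur and
observed inactive runs are not identical to latent sleep runs — the same
ambiguity real beam-cross data carries. Because a 5-min threshold censors
short latent runs, measured average bout durations exceed the geometric
means (memorylessness gives E[L | L >= 5] = mean + 4), and ratios of
measured durations across populations are slightly compressed relative to
the programmed ratio of means.

Defaults (chosen once as the study conditions): day wake rate 2.0 and
night 1.0 crosses/min; wake-bout means 30 (day) / 10 (night) min; sleep-bout
means 10 (day) / 30 (night, temperate) min. The nighttime sleep-bout mean
follows the cline `67.58 − 0.8427 × latitude` min, i.e. 60 min at 9°N and
30 min at 44.6°N — the programmed two-fold equatorial/temperate contrast —
at the five sampled latitudes (44.6, 41.8, 37.5, 30.3, 9.0°N). Daytime
parameters carry no cline, reproducing the observed day/night contrast.
Line effects are multiplicative log-normal (sd 0.12 on the log scale) on
the nighttime sleep-bout mean only. The pre-dawn ramp multiplies the night
wake rate linearly from 1 at ZT21 to 2 at ZT24. Deaths (optional) zero the
series from a uniform random minute. Acceptance-scale runs use the full
design (5 populations × 8 lines × 16 flies × 8 days); null-calibration
replicates use a reduced design (2 lines × 2 flies × 2 days) since only the
type-I error of a 5-point regression is being measured.

Genome fixtures: 1-kb windows tile one chromosome; window mean F_ST ~
Beta(1, 10) (right-skewed on [0, 1], resembling genome-wide F_ST between
closely related populations); top 5% flagged. Genes are placed uniformly
with geometric lengths (mean 2 kb, floor 200 bp) and may overlap each
other. Per-timepoint DE indicators are Bernoulli with odds multiplied by
`de_window_enrichment` for genes overlapping flagged windows; fold changes
are log-normal magnitudes >= 1 with a configurable per-timepoint direction
bias.

What the generator does *not* emulate: temperature-driven activity
modulation, sex differences, age effects, homeostatic rebound after sleep
deprivation, monitor-position effects, linkage/inversion structure among
windows (windows are independent draws), or expression levels (DE is a
flag, not a count model). Passing tests therefore demonstrate correctness
of the measurement and inference machinery under a known generating
process, not that real clines of a given size will be detected under real
noise.

## Numerical and degenerate-input choices

* Bout detection uses vectorized run-length encoding; the test suite pins
  it to a brute-force linear scan on random and hypothesis-generated
  series.
* Zero active minutes -> walking speed NaN; flat ramping line -> excluded;
  flat periodogram input -> NaN period; empty bout set -> NaN average
  duration. NaNs propagate through aggregation as means over non-missing
  values with unit counts reported.
* All randomness flows from `numpy.random.Generator` seeded via
  `SeedSequence` spawning, so population sets are reproducible fly-by-fly
  and results are identical across runs on a given platform.
* Exact rank-sum p-values are used where scipy's automatic policy selects
  them (small, tie-free samples); otherwise the tie-corrected normal
  approximation applies.

## Known limitations

* The DAM reader supports the single common 42-column dialect (configurable
  columns); exotic DAMSystem variants need a custom `DamLayout`.
* Phase estimation assumes one activity peak per searched half-cycle;
  bimodal morning activity within a half-cycle returns the global argmax.
* `drop_day` splices out whole ZT days, which preserves per-day statistics
  but breaks absolute time across the splice; periodogram analysis should
  use gap-free (zero-filled) series.
* The hourly cline scan inherits the low power of 5-point regressions; it
  is a pattern descriptor, not a discovery tool.
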