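# Methods

## The measurement model

`inkstone` analyzes single-character handwriting-to-dictation experiments
recorded on a pressure-sensitive digitizer tablet. The raw signal is a pen
sample stream — rows of (timestamp in ms, x, y, pressure, trial id) at the
tablet's sampling rate (200 Hz, i.e. one sample every 5 ms, by default) —
plus a per-trial event log (audio onset/offset of the spoken prompt,
spacebar press marking completion, and the participant's self-report:
correct / character amnesia / don't know).

Writing is segmented hierarchically into three nested orthographic units:

* **stroke** — a maximal run of consecutive samples with pressure > 0.
  Zero-pressure (pen-in-air, "hover") samples separate strokes; they are kept
  for rendering but contribute to no metric.
* **radical** — a contiguous group of strokes, assigned by consuming a
  character decomposition table (character → ordered per-radical stroke
  counts) in writing order. There is no geometric radical discovery: if the
  detected stroke count disagrees with the table, the trial is flagged
  `decomposition_mismatch` and carries no radical level, while stroke- and
  character-level metrics are still computed.
* **character** — the whole trial's ink.

Per unit the pipeline reports the standard inter-/intra-unit interval and
trajectory measures: writing latency (audio offset → first pen-down for the
character; previous unit's offset → current unit's onset for radicals and
strokes), writing duration (first → last inked sample of the unit),
trajectory length (sum of Euclidean distances between successive ink
samples, summed over member strokes), mean pen pressure over the unit's ink
samples, and — for radicals and strokes — the straight-line distance from
the previous unit's last ink point.

Definitional choices worth making explicit:

* Latency and distance are *inter-unit* intervals, so they are undefined for
  the first radical and the first stroke of a trial (there is no "previous
  unit"); first-unit cells are missing and excluded from aggregates. The
  character latency covers preparation of the first unit.
* A radical's onset/offset are the onset of its first and offset of its last
  stroke; radicals have no pen events of their own.
* Character mean pressure averages over ink samples only. Including
  zero-pressure hover samples would dilute the mean with values that encode
  "no contact", not a pressure.
* Stroke onsets/offsets are the timestamps of the first/last pressure-positive
  sample of the run; no velocity-based onset refinement and no resampling or
  smoothing before length computation. The minimum stroke size is 1 sample
  (`min_stroke_samples` raises it for noisy tablets).
* These definitions force two conservation identities that the test suite
  asserts on every synthetic trial: character length = Σ radical lengths =
  Σ stroke lengths, and character duration = Σ stroke durations + Σ
  inter-stroke latencies (exact on integer timestamps).

Two equivalent implementations exist: a readable per-trial path
(`segmentation` + `metrics.trial_metrics`) and a vectorized batch path
(`metrics.extract_metrics`) used for full experiments; tests hold them to
exact agreement, and both are checked against brute-force enumeration
oracles.

## Quality control

Trial level: raters code each penscript correct/incorrect and flag
revisions; with several raters the majority wins and even ties break
conservatively (toward incorrect / revised). Only rater-correct, unrevised
trials enter latency/duration/pressure analyses. Self-report consistency is
the fraction of coded trials where a correct self-report coincides with a
correct rater code. Inter-rater agreement uses the intraclass correlation,
two-way random effects, absolute agreement, single rater — ICC(2,1) — since
each penscript is coded by the same number of interchangeable raters drawn
from a pool; the variant choice is ours, as is the F-based 95% interval.

Metric level, defaults: character latencies > 10 s removed; character
durations < 1 s or > 10 s removed; radical and stroke latencies and
durations > 2 s removed. Bounds are strict (exactly 10 000 ms survives).
Removal is **per metric**, not per unit: a discarded latency leaves the same
unit's duration in place. This is deliberate — latency and duration exclusion
rates at one level can then differ, which per-trial removal could never
produce. Filters are idempotent and emit an auditable report
(n_before / n_removed / percent per level × metric).

The character-amnesia rate of an item is the proportion of amnesia
self-reports, computed before metric exclusions (an amnesia trial has no
valid character to time). The denominator excludes "don't know" trials by
default (`amnesia_denominator="all"` keeps them); rater codes are binary, so
the exclusion keys on the self-report.

## Item-level statistics

Analyses collapse trials to one row per character: radical/stroke measures
are first averaged within a trial across units (skipping undefined
first-unit cells), then across participants, keeping the character as the
unit of analysis at every level.

* **Split-half reliability**: participants are randomly split into two equal
  halves (odd counts drop one at random, logged), the item-level measure is
  computed per half, Pearson-correlated across items, and corrected with the
  Spearman–Brown prophecy formula 2r/(1+r). The split is seeded and
  reproducible. Note the corrected r estimates the reliability of the *full*
  sample's item means: with item variance σ²ᵢ and trial noise σ²ₑ over N
  participants it converges to σ²ᵢ/(σ²ᵢ + σ²ₑ/N), which is what the
  acceptance suite checks.
* **Correlation matrix**: Pearson r throughout with .05/.01/.001 stars; for
  two sum-coded binary variables this is exactly the phi coefficient.
* **Collinearity screen**: stepwise VIF elimination. VIFⱼ = 1/(1−R²ⱼ) from
  regressing predictor j on the others plus an intercept; while any VIF ≥ 5
  (default threshold) the worst predictor is dropped, ties and perfect
  collinearity (VIF = ∞) breaking toward the alphabetically last name with a
  warning. Every step's table is retained.
* **Regression battery**: OLS of each item-level measure on the 14 lexical
  predictors (phonogram, phonetic radical order, regularity, homophone
  density, number of meanings, imageability, concreteness, frequency, age of
  acquisition, number of strokes, number of radicals, left-right, top-down,
  word familiarity), each z-transformed over the analysis sample after
  exclusions — including the sum-coded binaries, so coefficients are
  per-SD throughout. Some outcomes enter handwriting covariates to absorb
  mechanical confounds (character duration: character length, stroke
  distance, stroke latency; radical latency: radical distance; radical
  duration: radical length, stroke latency; stroke latency: stroke
  distance); covariates are z-scored like the predictors. Multiple-testing
  control is Benjamini–Hochberg FDR at q = .05 per model over the
  14-predictor family; the intercept and covariates are exempt. Raw and
  adjusted p values are both reported. Items are unweighted (plain OLS on
  item means, no trials-per-item weights).
* **Cross-level contrasts**: for each pair of unit levels the two levels'
  item means are stacked in long format, Level is sum-coded ±0.5 (+0.5 for
  the coarser level of the pair under character ⊃ radical ⊃ stroke), and the
  model adds Level and Level × predictor interactions to the main effects.
  Duration contrasts additionally enter the per-level ink Length and
  Level × Length. The FDR family covers the 14 main effects plus all Level ×
  interaction terms; Level itself and the Length covariate are exempt, being
  structural rather than lexical hypotheses.

## The synthetic-experiment generator

`simulate.SimulationConfig` defines a complete generative model so every
stage is testable without real recordings. Defaults emulate the scale of
real adult single-character dictation data: 42 participants × 1200 items,
5 ms sampling, character latency ≈ 1030 ms, within-radical inter-stroke gaps
≈ 100 ms, between-radical gaps ≈ 150 ms, stroke duration ≈ 148 ms, pressure
≈ 12 500 device units, stroke length ≈ 5.1 units in a 40-unit grid cell on
an 8 × 5 sheet. Latencies, gaps, and durations are log-normal
(positive, right-skewed, mean ≪ max, as real pen timing data are); their
parameters are given as mean/SD on the millisecond scale. All realized times
are snapped to the sampling grid, and inter-unit gaps are realized as
zero-pressure hover samples, so detected structure round-trips exactly.

Item-level outcome means are linear in the *z-scored* lexical predictors via
designed effect vectors (`beta_latency`, `beta_duration`, `beta_amnesia`),
plus Gaussian item and participant random intercepts — the minimal structure
that makes split-half reliability nontrivial — and trial-level noise.
Default latency effects (frequency −180, age of acquisition +120, number of
strokes +60 ms per SD) are of realistic sign and order of magnitude; duration
carries no *designed* lexical effect by default because stroke count already
drives duration mechanically (each extra stroke adds its duration plus a
gap). Character-amnesia responses follow a logistic model (intercept −3 ≈
4.7% base rate; frequency and age-of-acquisition slopes by default);
"don't know" trials (1%) produce a single circle stroke, amnesia trials a
scribble with a perturbed stroke count, and 2.7% of correct trials are
marked revised. Rater majorities contradict the self-report on a configured
2.38% of trials, and one of the three raters dissents on 12% (dissent never
flips a 3-rater majority, so the consistency rate stays interpretable while
the ICC drops below 1).

What the generator does *not* emulate — and hence what passing tests cannot
show about real data: genuine glyph shapes (ink is schematic random
polylines; all metrics depend only on coordinates and timestamps), real
stroke-order errors, within-writer learning or fatigue across sessions,
correlated lexical predictors beyond what independent marginals induce, and
revision/crossing-out ink. Geometry is reflected back into the grid cell, so
realized inter-stroke distances can sit slightly below their configured
means for long characters.

## Numerical and design choices

* Times are integer milliseconds on the sampling grid; identities over
  timestamps are asserted exactly, trajectory lengths to 1e-9.
* z-scoring uses the population SD (ddof 0) of the analysis sample; constant
  columns raise rather than silently producing NaNs.
* `spearman_brown` is undefined at r = −1 and raises.
* ICC is undefined for constant ratings and raises.
* Degenerate streams: an empty or all-hover trial yields zero strokes and a
  `no_ink`-flagged character record with missing metrics, not an error.
* Determinism: every stochastic routine (generator, split-half) takes a seed
  or a `numpy.random.Generator`; the same seed yields byte-identical sample
  streams.
* Problem sizes in the test bench: the oracle-equivalence suite uses 1000
  randomized trials, the parameter-recovery study 100 replicates of
  10 participants × 200 items (the full 42 × 1200 design is supported but is
  ~25× that work), and the acceptance script reports a 12 × 300 experiment.

## Known limitations

* Radical grouping requires a decomposition entry; characters missing from
  the table get no radical-level metrics (flagged, logged).
* The amnesia-rate denominator is a convention (see QC above); with very few
  non-don't-know trials per item the rate is noisy.
* Single-radical characters have no radical latency/distance; their item
  cells are missing, and they drop out of radical-latency models as
  incomplete cases.
* The regression battery is item-level OLS; no trial-level mixed-effects
  modeling is attempted.
* Rendering aims at faithful diagnostics, not typography; SVG output embeds
  no date so repeat renders are byte-identical.
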