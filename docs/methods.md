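# Methods

This note documents the models, defaults, and design choices behind
`singacc`: what each statistic assumes, what the cohort simulator does and
does not emulate, and the numerical conventions used throughout.

## Accuracy measures

**TRD.** Unaccompanied singers carry their tuning reference internally; it
cannot be observed directly, only estimated from the sung notes. After
aligning sung notes to the score and subtracting expected from sung pitch
(score normalization, in semitones), a centered moving average of window
`window_n = 5` (the note plus two neighbours either side) estimates the
reference trajectory; TRD is the sample SD of that trajectory. Choices the
window statistic leaves open, and how they are fixed here:

* Windows are unweighted arithmetic means (no tapering is specified
  anywhere for this statistic, and unweighted means keep the
  transposition-invariance and homogeneity properties exact).
* Sample (n−1) SD by default; population SD is selectable via
  `TRDConfig(sd_kind="population")`.
* The trajectory is defined only where a full centered window exists
  (`full_windows_only`); a `shrink` policy (windows shrink symmetrically at
  the edges, one value per note) is available for short excerpts. For a
  sequence of `n` deviations the default trajectory has `n − 4` points.
* Deviations are smoothed in a single windowing pass; no pre-smoothing is
  applied before the window.
* Octave-error snapping (moving a sung pitch by whole octaves to within
  6 st of its expectation) exists for annotation pipelines whose tracker
  makes octave errors, but is **off** by default: annotation tools are
  expected to deliver corrected pitches, and silent correction would mask
  real errors.

Alignment uses explicit `score_index` columns when present (the simulator
always writes them). Without indices, pairing is ordinal — the k-th sung
note against the k-th score note not falling in an audiated span, with
score time mapped at the nominal tempo. Ordinal alignment assumes no
insertions or omissions; with error-prone performances, annotate indices.

**CV.** IOIs are taken within sung segments only and pooled across
segments of one performance; the first onset of each segment is consumed.
CV = 100·SD/mean is reported in percent. The statistic presumes beat-level
annotation: with one onset per beat, a perfectly steady performance has
CV = 0 and CV measures timing dispersion, not rhythmic content. (On
surface rhythms with mixed note values the raw-IOI CV would mostly reflect
the rhythm itself.)

**MB.** Timing during silent (audiated) spans is unobservable; the MB
metric extrapolates the last vocalized tempo through the span:
`mb = |elapsed/beat_period − expected_beats|`, with the anchor at the
onset of the last sung note before the gap and `expected_beats` the
score-beat distance from that note to the resume note. Two normalizations
are computed per performance: the plain mean of per-section |MB|
(`mean_abs`, the headline) and total |MB| per expected beat (`per_beat`),
which weights long sections more; both appear in the measures table.
The beat period is estimated from the mean of the last `k_ioi` IOIs of
the sung run preceding the gap. `k_ioi = 1` is the literal "last beat
vocalized", but a single interval carries the full per-beat timing noise,
which for a 20-beat span extrapolates to ~2 beats of pure measurement
error at a typical 10% timing CV. The pipeline therefore defaults to
`k_ioi = 8` (~5 s of context at typical tempi, within the shortest sing
window), which keeps the anchor error well below the re-entry jitter it
is meant to measure. The anchor window never reaches back across an
earlier silent gap. Performances without audiated spans (Normal task)
have no MB; the value is N/A (NaN), never 0.

## Adjustment scoring

Difference scores, not ratios: adjusted = AAF score − baseline, so 0 means
the same error as control, positive more, negative less (a performer with
control CV 15.43 and 200-ms-DAF CV 3.64 scores −11.79). The headphone
feedback condition (HF) is the control baseline for AAF conditions — the
AAF stimuli are themselves delivered over headphones — while NF vs HF
equivalence is checked separately (paired t per measure, report-only).
Group baselines are always computed from the data at hand, never
hard-coded.

## Inference

* **Median split**: participants above the sample median of their average
  BAIS score are "high", the rest "low"; ties at the median go low
  (deterministic rule; with an even number of distinct scores the split is
  even).
* **Mixed ANOVA**: group (between) × task × condition (within), one
  observation per cell, classical univariate partition. Error strata:
  subjects-within-group for the between effect; effect × subjects for each
  within effect and its interaction with group. The implementation is
  checked against a brute-force cell-means oracle and against R's `aov`
  with `Error(subject/(task*condition))`. The partition is exact for equal
  group sizes; unequal groups use weighted (observed-cell-size) means.
  No sphericity correction is applied by default — with four conditions
  and two tasks the package mirrors conventional uncorrected univariate F
  reporting; `sphericity="greenhouse-geisser"` adds per-stratum epsilon
  and GG-adjusted p values.
* The **four AAF conditions** (200/600 ms delay, quarter/whole-tone shift)
  are the condition levels of the factorial analysis of adjusted scores;
  the two control conditions enter only as baselines. MB analyses drop the
  Normal task, where the measure is undefined.
* **Pairwise tests**: pooled-variance two-sample t per condition, high vs
  low, pooling adjusted scores across tasks within a condition (24 per
  group at the default design). The Bonferroni family is the four
  per-condition comparisons within one measure/adjustment; `family_size`
  is configurable for other groupings of the comparisons.
* **Partial correlation** is computed by residual regression (least-squares
  fits of x and y on the controls, then Pearson on residuals), which
  supports any number of controls and equals the first-order formula
  `(r_xy − r_xz·r_yz)/√((1−r_xz²)(1−r_yz²))` for a single one; p-values
  use t with n − 2 − k df.

## The cohort simulator

The generator produces data with the structure the analysis assumes: 16
singers (8 per imagery group), each completing 3 tasks × 6 conditions,
one self-chosen piece per singer (generated: bounded diatonic random-walk
melodies, isochronous by default, 120 notes at 84–116 BPM).

Per-performance generative model:

* **Pitch**: sung = expected + tonal center + N(0, `note_noise_sd`). The
  center is a random walk (`tonal_drift_bias` −0.003 st/note downward,
  innovation SD 0.035 st/note) plus, under a feedback shift of size *s*,
  a compensation ramp to −`gain`·s across the performance (opposition;
  a matching mode flips the sign). A ramp rather than an instantaneous
  offset is what a windowed reference statistic can register — a permanent
  constant offset disappears from the trajectory SD once the window
  passes.
* **Timing**: onsets are the singer's internal beat grid plus Gaussian
  phase noise scaled so the IOI CV hits `tempo_noise_cv` (default 0.097,
  landing control CVs near 9.5–9.7%). DAF inflates all IOIs by
  `daf_slowing` (4%) and *reduces* the timing CV by 0.025 — performers
  under delay slow down and tighten up, prioritizing timekeeping over
  expression, so adjusted CVs come out slightly negative as observed in
  control-vs-DAF comparisons.
* **Audiation**: the sing/wait screen toggles at uniform 5–15 s intervals;
  notes in wait spans are dropped (not sung). Re-entry is at the predicted
  grid time plus N(0, `audiation_beat_sd` = 0.42) beats, and the singer
  continues from where they resumed (the error is not corrected). The
  resulting envelope — participants averaging ≈0.5 MB per section,
  greatest per-section drift about ±2 beats — matches what singers
  actually do; the TVD task multiplies audiation and tonal noise by 1.25
  for the speech distractor.
* **Participants**: BAIS-V/-C are drawn inside the ranges observed in
  actively performing singers (4.14–6.57 / 3.79–6.43), with group bands
  separated unless `bais_separation = 0`; years of performing is generated
  to correlate strongly (r ≈ 0.6–0.8) with BAIS, years of theory only
  weakly. Per-singer lognormal multipliers (σ = 0.15) on the noise
  parameters give between-participant heterogeneity.

**Planted effect (default config).** Only the shift-response gain differs
between groups: low 1.0 vs high 0.1 of the shift absorbed, with the
quarter-tone response scaled by 0.35 for everyone (small shifts feel like
chorusing and provoke less compensation). The gain gap was deliberately
calibrated, by pilot simulation, so the low–high difference in
individual-adjusted whole-tone TRD is on the order of one pooled SD —
the magnitude implied by the reported group means of the phenomenon being
emulated — and so the quarter-tone response stays mostly undetectable at
n = 16. These are tuned values, not measured ones: the real study reports
no generative effect sizes, only group summaries.

**Null preset** (`null_config`): identical group profiles, no
condition- or task-dependent parameters, common BAIS range. Used for
type-I calibration; all seven ANOVA effects reject at ≈5% over seeded
replicates.

**Seeding**: every participant owns named `numpy` substreams derived from
`(master_seed, participant index)`, so enlarging a cohort never perturbs
existing participants; identical seeds give bit-identical cohorts, and the
pipeline stamps every output with the seed and a config hash.

What the simulator does **not** emulate: real repertoire (no melodic
structure beyond stepwise diatonic motion, no expressive rubato or
phrase-final lengthening, isochronous rhythms by default), sung-note
insertions/omissions/octave errors, annotation noise, or any coupling
between imagery score and baseline (control-condition) accuracy. Passing
tests therefore demonstrate that the pipeline recovers effects of the
assumed generative form at the study's size — not that real singers
behave this way.

## Problem sizes and runtime choices

Monte-Carlo studies use shortened generated pieces as the package's
simulation-size choice: 48-note pieces for the 500-replicate null
calibration and 96-note pieces for the 200-cohort parameter-recovery
study (TRD precision grows with piece length; 96 notes retains the
planted effect's detectability while keeping the full study fast).
Single-cohort examples use the default 120-note piece. The acceptance
script mirrors these sizes with 100 recovery cohorts and 300 null
replicates.

## Numerical conventions and degenerate inputs

Dot-decimal UTF-8 CSV everywhere; numbers written with 12 significant
digits (round trips are lossless to well under 1e-9). Time in seconds,
pitch in MIDI semitones, segment spans half-open `[start, end)` so
adjacent segments share a boundary without overlap. Statistics raise
typed errors rather than returning sentinels: too few notes/IOIs/sections
(`InsufficientDataError`, naming the minimum), unbalanced or incomplete
factorial designs (`DesignError`, no silent imputation), zero-variance
correlations and degenerate (collinear) partial-correlation controls
(`DomainError`). An all-constant ANOVA response yields F = 0 with an
explicit zero-variance flag. A degenerate median split (all BAIS averages
identical) is an error, not an arbitrary grouping.

## Known limitations

* Ordinal score alignment cannot absorb insertions or omissions; explicit
  `score_index` annotation is required for error-prone performances.
* The pairwise t-tests pool three same-participant observations per
  condition and treat them as independent, inflating the nominal df — the
  conventional analysis for this design, but worth remembering when
  reading the printed df.
* The mixed ANOVA applies no sphericity correction by default.
* CV assumes beat-level onset annotation; on surface rhythms it conflates
  rhythm with timing noise.
* MB depends on the tempo-anchor quality; with very short sung runs the
  anchor falls back to fewer IOIs and per-section estimates get noisy.
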