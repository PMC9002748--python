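# Methods

## Problem setting

A player sits on a pressure-instrumented office chair playing a
mission-based serious game while a PPG sensor reports heart activity and
the game logs mouse telemetry, phase boundaries, and sparse
player-triggered events (proximity alarms, catapult launches, monster
clicks). Immediately after play the participant annotates perceived
engagement on a replay, one mouse-wheel sample per second; the normalized
trace serves as a ground-truth proxy. The analysis asks whether the
direction of change of sensor and in-game features between adjacent
observation windows predicts the direction of change of the annotation
features — a deliberately non-parametric, sign-based notion of
association that is robust to per-participant scale differences.

## Posture identification and threshold calibration

Each of the 12 sensors is binarized at an activation threshold (strict
`>`); the active set is matched against six boolean patterns in the
precedence order P1, P5, P6, P4, P2, P3 (most to least specific, first
match wins; ties between overlapping patterns are not otherwise
disambiguated by the pattern table itself). The pattern expressions are
kept verbatim from the published activation table, including the atoms
naming seat sensors 2 and 8 even though middle-seat sensors 1, 2, 5, 6
are excluded from the *gradient* feature ΔΤ; the pattern table is
config-overridable for users who prefer to drop those atoms. Samples
matching no pattern are labelled `none`; they break transition runs but
never count as transitions in μΤ.

Calibration sweeps an integer mV grid. Per threshold, accuracy is the
per-sample fraction of identified postures equal to the displayed
schedule (per-sample rather than per-dwell-interval — the finer of the
two readings), averaged over participants. The *plateau* is the longest
contiguous run of thresholds attaining the maximum (first run on ties)
and the selected threshold is its midpoint rounded to an integer, the
same rule that turns an 86–93 mV plateau into a 90 mV choice. Batches of
50 consecutive thresholds are tested with single-factor ANOVA across
participants; a batch with no between-threshold variance is degenerate
and reported as p = 1 with a flag.

## Heart-rate preprocessing and features

Reported inter-beat intervals are cleaned by a bounded-range rule
(default 300–2000 ms) plus a Malik-style successive-deviation rule: an
interval deviating more than 20% from the last *accepted* interval is
dropped. Both parameters are exposed; the rule is idempotent by
construction. Features follow ultra-short HRV practice for 10–30 s
windows — no detrending, no interpolation: Ĥ is the max−min of the BPM
values in the frame and σH the sample (n−1) standard deviation of the
IBIs. Beats belong to the frame containing their timestamp (half-open
[start, end)). The pipeline derives the BPM series used for Ĥ from the
*cleaned* IBIs (60000/IBI) so that ectopic artifacts cannot inflate the
amplitude. A published results table labels the 10 s-frame IBI
variability column "ΔH" where the text defines σH; the package treats
this as a notational inconsistency and implements only Ĥ and σH.

## Annotation and mouse features

Traces are normalized to [0, 1] per whole-session trace (min/max of that
individual trace); frames inherit normalized values, so all four features
are invariant to any positive affine transformation of the raw wheel
units. A constant trace (degenerate range) maps to 0.5 and is logged. ∫A
uses the composite trapezoid rule divided by the span of the integrated
samples, which keeps ∫A within [0, 1] and makes the triangle example
([0,1,0] over 2 s → 0.5) exact; ΔA is the mean *signed* successive
difference — an unsigned variant would destroy the directionality the
sign analysis needs. μMc counts presses per second of frame duration;
μMm sums Euclidean cursor steps per second. Click duration and idleness
are carried by the raw event stream but not featurized.

## Harmonization and observation frames

The annotation trace (1 Hz by construction) is the timing reference.
Pressure, sampled faster at the source, is smoothed by a centered boxcar
spanning one source-rate second — the published "moving average filter
with a cutoff frequency of 1 Hz" is not realizable as a plain moving
average, and a 1 s boxcar (first spectral null at 1 Hz for a 25 Hz
source) is the closest faithful reading; the window is configurable —
then sampled at integer seconds. All streams are truncated to their
common overlap.

Frames are half-open [start, end); the event sample itself belongs to
the post-frame. Each event yields pre [t−d, t) and post [t, t+d) frames
for d ∈ {10, 30} s, clipped to the containing phase; a clipped frame
shorter than d/2 is dropped (logged). No guard gap is applied before
events. Mission-3 frames are omitted when fewer than `min_mission3`
(default 4) participants reach that mission, reproducing the published
omission with 3 of 26 players. Frames with too few samples for a feature
are excluded from that feature's sign analysis rather than zero-filled.

## Sign agreement, significance, and fusion

A change from x₁ to x₂ is *clear* when |x₂−x₁| > clarity ·
max(|x₁|,|x₂|, floor), default clarity 5% with a tiny absolute floor; the
published analysis excludes unclear pairs but never states its rule, so
the threshold is a package choice exposed in config. Matches over the N
retained pooled pairs give c = (2m−N)/N with the exact two-sided binomial
p-value 2·min(P[Bin(N,½)≥m], P[Bin(N,½)≤m]) capped at 1 (two-sided
because both signs of association occur empirically; the published
choice of tail is unstated). Continuous frames pair consecutively per
participant, truncated at the last phase played; reactive frames pair
pre→post per event; pairs are pooled across participants before N is
counted. μΤ participates in the majority vote V (it is a primary
feature) but its own c^z columns are excluded by default, mirroring the
published post-hoc exclusion; a flag re-admits them. No multiple-testing
correction is applied by default (none was applied in the study);
Benjamini–Hochberg is available behind `multiple_testing: fdr_bh`.
Wilcoxon signed-rank contrasts drop zero differences, use the exact
distribution for n ≤ 25 without ties and the tie-corrected normal
approximation otherwise.

## The synthetic cohort

No public data exist, so the generator emulates the statistical
structure the analysis assumes. Latent engagement is a per-second
process: phase mean (defaults Tutorial 0.30, Gameplay 0.70, Review 0.45,
Mission-2 0.65 — chosen to reproduce the published orderings, Tutorial <
Gameplay, Review < Mission-2) plus AR(1) jitter (ρ = 0.95) whose
innovation scale grows with the phase mean, plus a 0.2-high exponential
bump (τ = 10 s) after each event. Scaling the jitter with the level is
what lets the amplitude feature Â carry engagement signal, mirroring the
study's finding that Â correlates with sensor channels.

Channels couple to the latent level through per-channel strengths in
[−1, 1] (default +0.8): backrest-posture probability decreases with
engagement, posture-switch rate, click rate, and cursor speed increase
with it, and the heart-rate oscillation amplitude grows with it on top
of an engagement-independent 3 bpm baseline oscillation (25 s period, a
respiratory-sinus-arrhythmia stand-in). The baseline matters: without
it, the null (zero-coupling) BPM range would grow with frame duration
purely through extreme-value statistics of measurement noise and bias
the null agreement positive; with it, the within-frame BPM swing
saturates within one period regardless of frame length. About 1% of
reported intervals are corrupted (halved or stretched 1.8×) to exercise
the cleaning stage. The annotation is the latent level plus N(0, 0.02)
noise quantized to 1/50 wheel ticks. Events are Poisson in
Gameplay/Mission-2 (0.6/min) thinned to a 60 s minimum spacing — twice
the longest reactive duration, so reactive frames of distinct events
never overlap. Phase durations (180/300/90/240 s with 5% per-participant
spread) and the 14/26 Mission-2 participation mirror the study protocol;
calibration sessions use active 150±30 mV vs inactive 10±5 mV, which
straddle the published 90 mV threshold with near-separable classes.

All randomness flows from a single seed through a splittable
`SeedSequence`, one stream per participant, so cohorts are bitwise
reproducible and participants are independent.

What the generator does *not* emulate: real pressure-sensor physics
(creep, hysteresis, BMI dependence), PPG waveform morphology (IBIs are
generated directly), annotation reaction lag, calibration-sitter
compliance errors, or correlated multi-channel artifacts. Passing tests
therefore demonstrate that the pipeline recovers the structure it
assumes, not that the published human-subject effect sizes are
reproduced; those depend on the original 26-participant dataset.

## Problem sizes and numerical choices

The repeated-seed recovery analysis runs six-player cohorts (all
reaching Mission-2, event rate 0.8/min) so that 100 seeds per regime
complete in minutes; the cohort drivers default to the full 26
participants. Plateau detection uses a 1e-12 tolerance on the accuracy
maximum; contingency tables include a `none` row/column; sign vectors
use 0 for excluded entries; CSV round-trips rely on repr-formatted
floats parsed back at round-trip precision, which is what makes the
report a bitwise-pure function of (config, seed) through disk.

## Known limitations

- The pattern-table contradiction (sensor-2 atoms vs the middle-seat
  exclusion) is preserved, not resolved; both readings are expressible
  via configuration.
- The clarity threshold is a free parameter; retained-pair counts (the
  Table-2 analogue) should be inspected when changing it.
- The binomial null treats pooled pairs as exchangeable across
  participants, as the published coefficient does; participant-level
  clustering is not modelled.
- Continuous frames differ in duration, so duration-sensitive features
  retain a residual confound in continuous-frame comparisons; reactive
  pre/post pairs are duration-matched by construction.
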