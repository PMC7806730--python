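# Methods

This note records the models behind `demgaze`, the defaults and why they were
chosen, and what the synthetic validation does and does not establish.

## Stimulus geometry

The digitized DEM is encoded from its printed dimensions: numbers 4.9 mm tall
(logMAR 0.71 at the 650 mm viewing distance), 98.2% Michelson contrast,
vertical spacing 14.6 mm everywhere; subtests A/B are two columns of 20
numbers 162.5 mm apart; subtest C is 16 rows of 5 numbers whose first-to-last
horizontal extent is 191.8 mm with per-gap spacing in [19.2, 57.5] mm.  The
exact within-row x-positions are not fully determined by those constraints,
so the default layout draws the four gaps of each row from a fixed-seed
generator and rescales them to the printed extent (rejecting draws that leave
the printed range).  Digit identities are configurable placeholders: nothing
downstream depends on them.  Coordinates are mm from screen center, x
rightward, y upward; gaze angles use the same axes in degrees.

Visual angle uses the exact `2·atan(extent/2d)` form; logMAR takes the
optotype detail as 1/5 of symbol height, the standard optotype convention.

## Signal chain

The order is fixed: 13-sample running median on the irregular stream
(index-wise — at ~500 Hz that is ~26 ms; shrinking windows at the edges),
linear-interpolation resampling to 500 Hz, forward–backward 5th-order 40 Hz
Butterworth per contiguous valid segment (zero net phase; the two passes put
the cutoff at −6 dB), then the length-9 smooth noise-robust central
differentiator (antisymmetric taps (14, 14, 6, 1)/128h; exact through cubic
interior polynomials, one-sided `gradient` fallback on the 4 edge samples of
each segment).

**Gap handling.** Raw-stream gaps longer than 75 ms are never interpolated:
blinks last roughly 100–300 ms and bridging them would fabricate smooth
position sweeps.  Such gaps split the recording into valid segments that all
later stages process independently.  The 75 ms default sits safely above the
worst plausible inter-sample spacing of the merged two-camera stream and
below blink duration.

## Event detection

Thresholds adapt to each recording: 3 × the unscaled median absolute
deviation (no 1.4826 normal-consistency factor — the rule is "3 MADs", not "3
robust SDs") of the track-velocity and track-acceleration magnitudes.  The
estimate is two-pass: a provisional 3 × MAD threshold, then a re-estimate over
the sub-threshold ("noise") samples so the saccades themselves do not inflate
it.  Truncation makes the second pass systematically smaller than the first
(on pure noise by roughly a third to a half); the final velocity threshold is
clamped to [10, 100] deg/s to guard degenerate traces.

A candidate saccade opens where velocity crosses its threshold with
acceleration having crossed its own within the preceding 20 ms, and closes at
the downward velocity crossing.  Candidates closer than 20 ms are merged — a
deterministic stand-in for the original manual inspection step.  Because the
zero-phase low-pass spreads each velocity profile symmetrically by a few
samples, the low-threshold crossings land in the spread tails; onset and
offset are therefore refined to where velocity leaves 5% of the event's peak
(never below the detection threshold), which keeps boundary errors within
about ±10 ms and fixation durations unbiased.  Every candidate must then move
the eye: the mean positions of the 20 ms windows before onset and after
offset must differ by more than 3 × the pooled within-window position MAD
(per-axis deviations of both windows pooled) *and* by more than 0.2 deg, the
instrument's spatial resolution.  The displacement assigned to the event is
the difference of those window means, which is far more noise-robust than
endpoint samples.

Fixations are the inter-saccadic intervals (plus each segment's leading and
trailing interval).  Two kinds of fixations are excluded from duration
statistics but keep contributing their time, so that saccade + fixation time
tiles every valid segment exactly: durations above median + 3 × MAD
(single-pass; blink-bridging artifacts), and fragments abutting a signal-loss
gap, whose true duration is unknowable.

## Epoch segmentation

The verbal definitions — an identification epoch runs from arrival at a
line's beginning until the eye starts moving toward another line; a return
sweep runs from that movement's onset to arrival at the new line's beginning,
intermittent fixations included — are quantified by three parameters:

- **sweep trigger**: an against-reading-direction saccade of at least 0.5 ×
  the line extent (leftward for C; the rightward column jump for A/B),
- **end region**: the gaze must first have fixated within max(2°, 35% of the
  line extent) of the line end,
- **line-start tolerance**: the sweep ends at the first fixation within 2.0°
  of the line-start coordinate.

All lines share their start and end coordinates, so the segmentation's
control flow never consults row labels; labels (nearest row center within
half the inter-row spacing, else unlabeled) are bookkeeping.  This matters in
practice: with ~0.7° slow accuracy drift a nearest-row assignment is
occasionally off by one near row boundaries, and a label-driven state machine
would lose sweeps.  Saccades straddling an epoch boundary belong to the
sweep, which is defined by its initiating saccade.

Backwards saccades are horizontal-class saccades against the reading
direction inside identification epochs (leftward for C, upward vertical-class
for A/B); orthogonal saccades are the perpendicular class there.

## Scoring

Adjusted C time = raw × 80/(80 − omissions + additions); A and B are never
error-adjusted.  If only one vertical subtest is usable its time is doubled
and the record flagged.  Transcripts are aligned to the target sequence by
longest-common-subsequence; equal-length replace-runs are substitutions
(neither omission nor addition, matching the two-term formula).  A fully
skipped line counts 2 omissions — implemented as printed on the score sheet
even though a line holds 5 numbers; the weight is a parameter because the
convention is surprising.  A repeated line naturally yields 5 additions.

Reaction-time cleaning: drop trials < 0.1 s, then iterate the "deviates more
than 3 × MAD from the median" rule to a fixed point within each
subject × task (× optotype size) cell.  Iterating makes cleaning idempotent —
re-cleaning the kept set removes nothing — which a single pass does not
guarantee; with all-equal trials MAD = 0 and the strict inequality keeps
everything.  Subjects whose retained-trial mean deviates more than 3 group
SDs from the group mean are flagged (note the rule cannot fire for groups of
≲ 11, where the maximum attainable z is (n−1)/√n < 3).

## Statistics

Partial correlation is the Pearson correlation of the residuals from the two
covariate regressions, with n − 3 df.  Dependent overlapping correlations are
compared with Williams' t (Steiger's formulation), df = n − 3; a Monte-Carlo
calibration under a trivariate-normal null keeps the type-I error within
[0.035, 0.065] at α = 0.05.  FDR is Benjamini–Hochberg step-up via
statsmodels.

Sample sizes: the paired-t calculator searches the smallest n whose
noncentral-t power (ncp = dz·√n, df = n − 1) reaches the target; at dz = 0.5,
α = 0.05 one-sided, power 0.80 this gives n = 27 (a two-sided test gives 34,
so the one-sided reading is the one consistent with the canonical 27; the
sidedness is always explicit in `PowerQuery`).  The correlation calculator
integrates the exact bivariate-normal sampling density of r (Hotelling's
form, via `hyp2f1`, validated against a Monte-Carlo oracle to < 0.02 in
power) above the t-transform critical r; a Fisher-z mode
(n = ((z_α + z_β)/atanh ρ)² + 3) is provided and labeled as the
approximation.  At ρ = 0.5, one-sided, power 0.80: exact 23, Fisher-z 24.

## Synthetic data generator

The generator emulates a child reading the DEM under a remote stereoscopic
eye tracker.  Behavior: fixation durations are lognormal (shape σ = 0.2)
around a latent processing speed s (ms); s is log-linear in age (480 ms at
age 9, slope −0.055/yr, between-subject σ = 0.12 — chosen to span the
plausible 330–650 ms range over ages 6–12); saccade durations follow the main
sequence (21 ms + 2.2 ms/deg — standard literature values giving 30–60 ms
saccades so that saccade time stays small relative to fixation time) with
raised-cosine velocity profiles (closed-form displacement, exact ground
truth); landing noise 0.15° SD.  Slower readers get more refixations,
regressions, and return-sweep hops (1–3, drawn 1 + Binomial(2, p)); multi-hop
sweeps are one large undershooting saccade (65–85% of the distance) plus
corrective hops with ~160 ms intermittent fixations, the pattern reading
research reports for developing readers.  Rows can be skipped for
omission-error scenarios.

Measurement: white noise 0.03° SD per sample (the tracker's stated < 0.05°),
slow sinusoidal drift with 0.7° peak radial amplitude split √2-wise between
axes (the stated ~0.7° accuracy), blinks (4/min, 100–300 ms) placed inside
sufficiently long fixations — blinking is suppressed during saccades, and
blink-corrupted events are discarded by the analysis anyway — and sampling on
the merged, jittered timestamps of two asynchronous ~250 Hz clocks (mean rate
within 10% of 500 Hz).

Reaction times: speed-acuity RT = 0.25 s + 1.0 × s + subject and trial noise;
detection-task RTs share the latent s with a weaker coupling; 2% attentional
lapses (2–4 s) and 1% anticipations (< 0.1 s) exercise the cleaning rules.

**What passing tests show, and what they do not.**  On this generator the
pipeline attains ≥ 0.95 saccade recall/precision (amplitudes within 0.2°),
recovers the latent speed with a regression slope within 10% of unity across
a 36-child cohort (the intercept estimate at that n has a standard error of
~17 ms and is only sanity-bounded), conserves time exactly, and reproduces
the qualitative cohort structure: negative age–DEM-time correlations, a
positive fixation-duration/reaction-time correlation that survives age
adjustment and FDR, and positive correlations of identification fixation
duration and saccade count with total horizontal time.  The generator does
not model head motion, pupil-size artifacts, vergence, smooth pursuit,
off-task looking, or naming-specific cognition, so these results validate
the *machinery*, not its behavior on any particular clinical population.

## Problem sizes and numerical choices

Default simulations run one ~40 s trial (~19,000 samples) per subtest and 36
subjects per cohort — the eye-tracked subsample size this analysis targets —
which keeps a full cohort analysis under ~10 s.  Monte-Carlo calibrations use
2,000 (Williams) and 20,000 (correlation power) replicates with fixed seeds.
All randomness flows from one seed through per-subject derived generators;
identical seeds reproduce byte-identical outputs.  Degenerate inputs are
handled explicitly: zero-variance correlation inputs and exact functions of
the covariate raise; a zero-variance paired difference returns t = 0 (zero
mean) or an infinite-t flag; empty transcripts score as all lines skipped,
with a warning.
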