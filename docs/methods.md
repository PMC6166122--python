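# Methods

This note documents the models, parameter choices and numerical rules
behind `discomfortlab`: what the synthetic generator emulates, how the
event-locked analysis is defined, and where genuinely open design choices
were resolved.

## Scenario model

One trip is ~180 s of highly automated driving containing three identical
approach situations. The ego car (100 km/h) closes on a lead truck
(80 km/h, closing speed 20 km/h ≈ 5.56 m/s) from a 100 m gap. Automated
braking starts at a 9 m gap; the braking law is modelled as a **constant
deceleration that nulls the relative speed exactly at the configured
minimum gap** (4.2 m): a = v²/(2·(9 − 4.2)). After a 3 s dwell at the
minimum the gap opens at the former closing speed back to 100 m and the
next approach begins. The gap trajectory is piecewise analytic and sampled
at the 60 Hz master clock, so the minimum gap is exact up to tick
quantization (≤ v/60 ≈ 0.09 m). Time-to-contact is gap/closing-speed,
defined only while closing. The braking profile of the original scenario
is not recoverable from its published description (a constant deceleration
cannot reproduce the reported 1.1 s minimum time-to-contact), so the
minimum TTC here is emergent (9/5.56 ≈ 1.62 s at brake onset), not a
calibration target.

## Response generator

The generator's defaults are the study conditions; each is either a
reported value or, where nothing is reported, a fixed choice a
practitioner would call realistic (marked *assumed* below).

| parameter | default | basis |
|---|---|---|
| press probability per approach | 208/240 ≈ 0.867 | reported press count |
| press duration | log-normal, mean 8.10 s, SD 5.52 s, truncated > 0.5 s | reported M/SD; right-skewed law *assumed* |
| press onset | 3 s before brake onset, jitter SD 0.5 s | *assumed* (discomfort builds as the truck looms) |
| blink rates pre/during/post | 0.25 / 0.17 / 0.37 s⁻¹ | reported phase means |
| blink process | Poisson thinning, 120 ms blink duration, pupil missing during blinks | *assumed* renewal model |
| pupil | 3.5 mm baseline, +0.30 mm half-sine dilation during episodes | *assumed* amplitudes |
| HR | 72 bpm baseline, −5 bpm ramp reaching a plateau at mid-episode (150%), held until 5 s after release, 2 s recovery ramp | reported shape; amplitudes *assumed* |
| IBI | per-beat 60/HR(t) plus white HF noise of SD r/√2 (r = 45 ms baseline RMSSD), ×0.5 during episodes; logged at 10 Hz with last-value repetition | device-log convention; values *assumed* |
| SCL | 2 µS + 0.01 µS/s warming drift; step artifacts (2/min, 1.5 s) co-occurring with accelerometer/gyroscope spikes; logged as resistance kΩ = 1000/µS | reported drift + artifact structure; values *assumed* |
| pushback | −15 mm shoulder-z half-sine, +50 au back-sensor pressure | *assumed* |
| channel noise SDs | pupil 0.05 mm, HR 1 bpm, SCL 0.02 µS, shoulder 1 mm, pressure 5 au | *assumed* |

Identical (config, seed) ⇒ bit-identical sessions, including the written
CSV bytes.

### Scene luminance and the pupil confound

Scene luminance (60 Hz, front-camera frame lightness on [0, 1]) is
modelled as an ambient base (0.45) plus a slow AR(1) drift (SD 0.08,
correlation time 20 s) plus a truck component 0.15·s(t), where s(t) is
affine in 1/gap scaled to [0, 1] — the white truck fills more of the view
as it looms. An earlier pure-truck design (luminance = s(t) spanning the
full [0, 1]) was rejected: with luminance ≈ 0 outside approaches, the
within-sequence luminance variance exceeds the whole-trip variance, so
subtracting the trip-level luminance z-score from the per-sequence pupil
z-score *always* over-corrects and inverts the pupil effect, which
contradicts the documented behaviour of this correction (it shrinks but
preserves the dilation).

The pupil–luminance coupling gain is **operational, not photometric**: it
reproduces the empirical observation that the uncorrected pupil effect is
*more pronounced* than the corrected one, which requires a positive
coupling of a scale comparable to the trip-level luminance z. The
correction subtracts luminance·(1/s_trip) in z-units while the pupil
z carries luminance·(g/s_seq); with per-sequence pupil SD s_seq ≈ 0.1 mm
and trip luminance SD s_trip ≈ 0.1, the scale-matched gain is
g ≈ s_seq/s_trip ≈ 1.2 mm per luminance unit; the default 1.5 sits
slightly above it so a mild positive residual survives the correction.

## Synchronization

All channels are joined onto the 60 Hz simulator clock by sample-and-hold:
the value at master tick t is the last native sample with timestamp ≤ t,
missing before the first sample. This mirrors a logger that appends "the
current value" of every device at each simulator timestamp; 120 Hz motion
data are down-joined by the same nearest-previous rule. No value is ever
interpolated or invented. Event streams (blinks) are kept as onset lists
and additionally joined as per-tick onset indicators. Master-clock jitter
tolerance is 1 ms.

## Event-locked analysis

- **Interval extraction**: maximal runs of handset values above 2% of full
  scale (guards quantization noise); runs separated by < 0.3 s merged;
  merged runs shorter than 0.5 s dropped. None of the three constants is
  reported in studies of this design; all are exposed as arguments.
- **Sequences**: interval plus 10 s pre and post windows, clipped at trip
  boundaries with truncation flags; windows overlapping a neighbouring
  press are kept and flagged (three approaches per trip make overlap rare).
- **Percent axis**: all spans are half-open [start, end), partitioning
  [onset − 10 s, offset + 10 s) into 300 slices (1–100 pre at 0.1 s,
  101–200 during at duration/100, 201–300 post at 0.1 s). A slice's value
  is the mean of the non-missing master samples in its span; slices left
  empty (possible when the interval is shorter than 100 master ticks) are
  filled by linear interpolation between the nearest non-empty slices and
  flagged. 300 slices (no extra 0% point) were chosen; the alternative
  301-point reading changes nothing materially.
- **Standardization scopes**: pupil z per sequence, luminance z per whole
  trip, HR / SCL / motion / pressure / interblink timer z per sequence.
  z uses the sample SD; a constant input (SD = 0 up to float fuzz) yields
  all zeros with a degenerate flag.
- **SCL detrending**: residual = value − fitted line, per sequence. (The
  alternative reading fit − value only flips the sign of a flat curve.)
- **Interblink timer**: resets at blink *start*; blink duration is not
  excluded; before the first onset the timer runs from the window start
  and is flagged.
- **RMSSD**: consecutive duplicate entries of the 10 Hz held IBI log are
  collapsed to one value per beat before differencing (the device repeats
  the last beat value between beats). Genuinely identical successive beats
  collapse too — an accepted cost of the log format. Windows with fewer
  than 3 beats yield a missing value.
- **Aggregation**: slice-wise mean across sequences with a pointwise
  t-based 95% CI, mean ± t(0.975, n−1)·s/√n — pointwise, not simultaneous,
  by design: the bands support comparison of individual time points.
  Non-overlap of two slices' closed CIs is read as a significant
  difference; a shared endpoint counts as overlap.

## Online detector

Per monitored channel the current value (after a 0.3 s trailing mean that
bridges blink gaps without breaking causality) is standardized against
trailing baseline windows — 10 s ending 3 s before now and 5 s ending 5 s
before now. A window with fewer than 5 samples yields a missing z; a
zero-SD window yields 0, mirroring the whole-scope z rule. Evidence fires
when any window's z crosses the channel's directional threshold (HR
−0.3 SD; pupil +0.3, shoulder-z −0.3, back pressure +0.3, the expected
directions at the same magnitude). Skin conductance is excluded from the
default channel set (no event-locked change). The weighted vote (equal
weights) forms a score in [0, 1]; a detection triggers when the score has
stayed ≥ 0.5 for 3 s, and the detector re-arms 20 s after a trigger.

Trigger/refractory semantics were chosen over maximal above-threshold
runs because run counts are not monotone in the threshold (lowering the
threshold merges runs); the trigger count is a maximal refractory-spaced
packing of a set that only shrinks as the threshold rises, so raising the
threshold provably never yields more detections. Score threshold,
confirmation time and smoothing span were fixed on a dedicated tuning seed
set disjoint from all test seeds; on held-out sessions the defaults hit
every press episode with ≲0.2 false alarms per 3-minute trip and none on
effect-free sessions. Fusion is a transparent weighted vote; the evidence
interface accepts any per-channel binary series so a richer (e.g.
probabilistic) fuser can be slotted in.

## What the synthetic data do and do not show

The generator reproduces the *structure* of the real recordings —
multi-rate logs, held device values, blink gaps, luminance confound,
movement artifacts, event-locked effect directions and reported magnitudes
where printed — but its effects are stronger and cleaner than real
physiology: noise is Gaussian and stationary, effects are deterministic
templates without between-subject variance, habituation or missing
channels, and the luminance–pupil link is linear. Passing the recovery
tests therefore shows the *pipeline* is correct and directionally
sensitive, not that real-world detection would reach the same hit/false-
alarm rates. Problem sizes used by the test suite (20×2 trips ≈ 100
sequences for full-chain recovery; 600 trips ≈ 1550 sequences in the
acceptance script) were chosen to make the binomial/Poisson sampling error
small against the stated tolerances.

## Known limitations

- Handset magnitude is generated but only its binary on/off is analysed,
  matching the interval definition ("independent of the magnitude").
- No clock-drift modelling or correction (clocks are assumed NTP-synced).
- No frequency-domain or nonlinear HRV (windows are too short), no
  saccade/fixation analysis, no habituation or age-group structure.
- The detector weights are fixed, not learned, and no environment gating
  (e.g. presence of a lead vehicle) is applied.
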