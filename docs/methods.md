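# Methods

This note documents the models, numerical choices and limitations of
`dopplervti`: what the simulator emulates, how the envelope tracer and beat
segmenter are defined, and which design decisions were genuinely open.

## Hemodynamic trajectory model

A virtual subject performs a four-phase Valsalva protocol: baseline,
inspiratory hold (expiratory effort against 20–25 cm H2O), release hold, and
recovery, each 15 s by default (total 60 s; the strain begins at t = 15 s).
Every modelled quantity (per-beat VTI, heart rate, stroke volume, MAP, SBP)
follows a plateau-and-ramp multiplier relative to its baseline value:

- unity through baseline;
- a smoothstep ramp during the first `hold_ramp_s` (default 5 s) of the hold
  up to the quantity's *hold multiplier*;
- a plateau through the end of the hold — so the terminal 5 s of the hold
  (the T2 analysis window) sits exactly at the programmed effect size;
- a smoothstep ramp over `recovery_ramp_s` (default 10 s) after release
  toward a *recovery multiplier*, then a plateau through the end of recovery
  (covering the T3 window).

The default "paper_cohort" preset programs the group-mean effect sizes of the
study cohort: carotid VTI ×0.77 at the hold plateau (−23%) recovering to
×1.0164 (+32% from the hold), aortic VTI ×0.63 (−37%) recovering to ×1.3545
(+115%), SV ×0.74 (−26%), MAP ×1.04 (+4%). Two multipliers are not directly
reported anywhere and are *inferred* from index arithmetic, which we flag
explicitly:

- the heart-rate hold multiplier 1.21 follows from the reported +57% DSI
  rise: 1.21 / 0.77 = 1.571;
- the SBP hold multiplier 1.21/1.20 ≈ 1.0083 follows from the reported +20%
  shock-index rise. A constant-pulse-pressure model (SBP = MAP + offset) was
  considered and rejected: with MAP +4% it forces the SI rise to +17.3%,
  inconsistent with the +20% calibration; a near-constant SBP with a
  narrowing pulse pressure during strain is also the physiologically expected
  behaviour in early phase-II Valsalva.

SV recovery is set to ×1.0 (return to baseline). The reported recovery SV
figures are mutually inconsistent (a 27.5 mL / 26% fall cannot be undone by a
"+37 mL or +10%" rise), so the model follows the qualitative statement that
all values returned to baseline.

## Beat waveform and exact VTI control

Each cardiac cycle uses a normalised morphology: a half-cosine systolic rise
from the end-diastolic velocity (EDV) to the peak systolic velocity (PSV) at
`systolic_rise_fraction` (default 0.15) of the cycle, an exponential
diastolic decay (time constant 0.25 cycles) back to EDV, and an optional
Gaussian dicrotic notch carved into the early decay. A `half_sine` degenerate
mode (`v(t) = Vp sin(πt/T)`, area `2·Vp·T/π`) provides a closed-form oracle
for integration tests.

Per-beat VTI is controlled exactly rather than emerging from amplitude: beat
durations follow the HR trajectory, and each beat's amplitude is scaled so
that its analytic area equals `baseline VTI × VTI-multiplier(onset) ×
jitter`. Because VTI = amplitude × duration × (shape mean), this decouples
the programmed VTI change from the concurrent HR change — without the
compensation, a +21% HR rise would mechanically shave ~17% off every beat's
area and corrupt the calibration. Baseline VTI is the area of the unscaled
shape at the baseline heart rate (≈ 27 cm for the default carotid shape at
72 bpm, within the normal adult range).

Ground-truth per-beat VTIs stored with each track are recomputed from the
generated envelope with the same shared-endpoint trapezoidal rule the
analysis uses, so the self-consistency invariant (truth VTI = envelope
integral over the beat) holds to < 0.1% by construction.

## Audio model

Doppler audio is real-valued, forward-flow only: a sum of `n_scatterers`
(default 64) phase-continuous cosines whose instantaneous frequencies are
fixed fractions `r_k` of the envelope's Doppler shift
(`f = 2 f0 v cos θ / c`; defaults f0 = 4 MHz, c = 1540 m/s, θ = 0°, audio at
44.1 kHz). One scatterer is pinned at `r = 1` (the fastest streamline); the
rest are drawn with density ∝ r⁶ — a blunt, near-plug velocity profile
appropriate for systolic carotid flow at high Womersley number. The exponent
matters: it sets where the spectrum's integrated-power 95% point lies
relative to the true edge, and r⁶ keeps that point within ~2% of the
envelope so the percentile tracer's estimand coincides with the maximum
velocity to within its stated tolerance. Flatter (parabolic-flow-like)
profiles put the 95% point ~3.5% low; the bias cancels in all percent-change
endpoints but would violate the envelope-recovery tolerance stated below.

White Gaussian noise is added at a configurable SNR (default 20 dB relative
to signal RMS). Samples where the envelope is exactly zero carry no signal,
so a zero envelope with infinite SNR yields digital silence. Synthesis is
bit-deterministic for a fixed seed. No wall filter, beam profile, aliasing
or bidirectional-flow physics is modelled.

## Envelope tracer

Spectrograms use a Hann window of 10 ms with a 2.5 ms hop (400 frames/s —
resolving systolic upstrokes at heart rates up to ~180 bpm) and no edge
padding; with `scaling="spectrum"` the per-frame bin sum equals the windowed
mean square, making totals comparable across frames.

Per frame the tracer:

1. estimates the noise floor as the mean power of the top 10% of frequency
   bins (19.8–22.05 kHz at defaults, well above any physiological shift) and
   subtracts it, clipping at zero;
2. masks the frame as signal-absent when the corrected total does not exceed
   the floor-level power summed over all bins (`signal_floor_factor = 1`).
   For white noise the corrected total concentrates near 0.37× that
   reference, so noise-only frames are rejected with a wide margin while any
   frame whose in-band signal rivals the total noise power passes;
3. finds the lowest frequency at which the cumulative corrected power
   reaches `percentile` (default 0.95) of the frame total — first crossing
   bin, lower bin on exact ties, refined by linear interpolation of the
   cumulative inside the crossing bin to remove window-lobe quantisation;
4. median-filters the traced series over 5 frames.

Measured performance at the defaults: on noiseless single-tone audio the
trace is within one bin-equivalent (≈ 1.9 cm/s) of the tone for ≥99% of
frames; on full scatterer audio of a virtual subject at SNR 20 dB the
envelope RMS error is ≈ 2 cm/s against a ~110 cm/s peak (the test suite
asserts < 5% of peak, and within 5% of the true shift on ≥95% of frames at
SNR 30 dB in the systolic range).

## Beat segmentation and per-beat metrics

Systolic peaks are found on a Savitzky–Golay-smoothed envelope (75 ms
window, order 2) with a 0.3 s refractory distance (200 bpm ceiling); peaks
with prominence below 0.25× the median prominence are ignored. The onset is
the foot of the upstroke: the maximum of the smoothed derivative in the
run-up to each peak, backtracked to where the slope first drops below 20% of
that maximum. The smoothing is essential — the raw frame-to-frame gradient
of a traced envelope is dominated by bin noise, and anchoring at the
unsmoothed derivative maximum lands ~half a rise time (~60 ms) after the
foot. With the backtracked foot, detected onsets match ground truth to
within ±50 ms for ≥95% of beats at SNR 20 dB.

Per-beat VTI is the trapezoidal integral of the envelope between consecutive
onsets on the native frame grid (no resampling): each beat spans from the
first frame at/after its onset through the first frame at/after the next
onset, sharing that boundary frame so beat areas telescope exactly to the
envelope integral over the covered span. Boundary quantisation is bounded by
hop × EDV (≈ 0.04 cm, negligible against ~25 cm beats). Beats overlapping
any masked frame are retained in the table but flagged and excluded from all
window statistics; the final partial beat is discarded.

## Protocol windows and indices

For phase durations (d1..d4): T1 is the 5-s baseline window ending 5 s
before the hold (seconds 5–10 at defaults, generalised as
`[min(5, d1−5), …+5)` so it always fits inside baseline), T2 the terminal
5 s of the hold, T3 the terminal 5 s of recovery. Every phase must be ≥5 s.
Beat membership is by onset time in the half-open interval; window values
are unweighted means over kept beats, and a window with no kept beats flags
the subject rather than silently imputing.

Window DSI is window-mean HR over window-mean VTI (the reporting
convention); a per-beat-ratio alternative is exposed via `dsi_mode`. The
slow monitor channel (20-s updates) is windowed by its own rule: T1 = the
sample immediately before protocol onset, T2 = the minimum-SV sample during
the protocol (earliest on ties — the peak Valsalva effect), T3 = the sample
at protocol end; MAP and SBP are read at the same sample indices, and SI
combines Doppler window HR with that SBP.

## Statistics

The paired two-tailed Student t-test is computed from the textbook formula
(`t = mean(d) / (sd(d)/√n)`, sample sd, df = n−1) with the p-value from the
Student-t distribution; zero-variance differences raise a degenerate-test
error rather than returning an infinite statistic. Detection metrics count a
subject as predicted-positive when its percent change crosses the decision
threshold in the predictor's direction (fall for carotid/aortic VTI, rise
for DSI/SI; default threshold 10%). Threshold sweeps evaluate every midpoint
between sorted directional values; the operating point maximises Youden's J
with ties broken toward the larger (more conservative) threshold. The
separation margin — minimum positive-class magnitude minus maximum
negative-class magnitude — is positive exactly when the classes are
perfectly separable. The primary detection interval is T1→T2 (peak effect);
T1→T3 is also computed as a recovery-consistency check since the recovery
windows should show no persistent fall. No multiple-testing correction is
applied.

## Cohort construction

Responders draw their multipliers log-normally (σ = 0.05) around the
calibrated preset, with the aortic hold multiplier capped at 0.85 so every
responder's programmed fall exceeds 15%; per-beat VTI jitter is σ = 3% and
RR jitter σ = 2%. Sham controls draw a true aortic change uniformly within
±8% (a deliberate margin from the 10% decision boundary), with the carotid
change coupled at 0.62× the aortic change — the responders' 23/37
attenuation ratio — rather than drawn independently, so control carotid
readings are physiologically consistent with their aortic truth. Per-subject
seeds are spawned from the master seed via `numpy`'s `SeedSequence`, making
cohorts reproducible subject-by-subject; both Doppler channels of a subject
share one beat-onset sequence (one heart).

Problem sizes used by the shipped analyses: the headline detection run is 8
responders + 8 controls, 60 s of two-channel 44.1 kHz audio each, SNR
20 dB; unit tests use single subjects or a reduced "unit_test"
configuration (8 kHz audio, 1.5 MHz carrier, 12 scatterers).

## What the generator does and does not emulate

It emulates: the four-phase protocol timing, calibrated group-mean effect
sizes with inter-subject spread, beat-to-beat variability, spectral power
filling 0 Hz up to the instantaneous maximum-velocity shift, additive
broadband noise, and the 20-s cadence of a noninvasive pulse-contour
monitor. It does not emulate: probe motion and angle drift, wall-filter
artifacts, venous or reverse flow, arrhythmia, breathing modulation outside
the programmed trajectory, spectral broadening from transit time or beam
geometry, or any internal behaviour of the pulse-contour device (only its
output cadence). Passing tests therefore demonstrate correctness of the
analysis chain under a clean, calibrated signal model — not robustness to
every failure mode of real patch recordings.

## Known limitations

- The percentile tracer carries a small systematic offset relative to the
  true edge that depends on the spectral shape near the edge; absolute VTIs
  inherit it (percent changes do not).
- Sensitivity/specificity on a 16-subject simulated cohort are coarse
  (granularity 1/8); the perfect separation reflects the programmed effect
  sizes and the ±8% sham margin.
- HR above ~180 bpm would not be resolved by the default 0.3 s refractory
  and 10 ms analysis window.
- The SBP channel is a modelled trajectory, not a pulse-contour algorithm;
  SI results should be read as consistency checks of the index arithmetic.
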