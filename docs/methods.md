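# Methods

This note records the model behind `mapgap`, the conventions the detector
uses where the underlying measurement idea leaves them open, the synthetic
data generator's assumptions, and the numerical choices that matter.

## The measurement idea

A monophasic action potential (MAP) is recorded extracellularly when an
electrode presses on electrically viable myocardium; its time course tracks
the local transmembrane action potential. Two facts make MAPs useful for
lesion assessment:

1. a MAP appears only above a site-specific contact force (CF) — firm
   mechanical contact is a precondition for the recording;
2. ablated tissue produces no MAP at any force.

Consequently the *absence* of a MAP is evidence of successful ablation only
when the applied force demonstrably exceeded what viable tissue needs. The
pipeline therefore measures, pre-ablation, the distribution of CF at first
sustained MAP detection on viable tissue (defaults 7.6 ± 4.4 g), and uses it
— or the site's own pre-ablation value, which takes precedence — as the
reference against which post-ablation silence is judged.

## Detection conventions

The acquisition band is 0.1–120 Hz; a MAP is recognised per beat when the
deflection amplitude exceeds 2 mV (strict inequality) and the duration
reaches 100 ms (inclusive). Several operational details are not fixed by
that criterion and are resolved as follows (all configurable through
`DetectorConfig`):

* **Earliest ventricular activation** — QRS onset on the reference ECG,
  located by walking back from the R peak to the first sustained crossing
  of 10% of the R amplitude. All per-beat times (AT, EOR) are measured from
  this fiducial; R peaks themselves come from `scipy.signal.find_peaks`
  with a 0.25 s refractory distance and a 0.3 mV floor (a flat ECG or a
  single beat raises `NoBeatsError`).
* **Local activation** — the maximum-upstroke-velocity sample (largest
  first difference) in the beat window; the standard MAP convention.
* **Amplitude** — peak minus baseline, where the baseline is the median of
  the pre-upstroke segment (robust to the wander the 0.1 Hz high-pass
  leaves behind). A peak-to-peak mode is available (`amplitude_mode`).
* **End of repolarization** — the first post-peak decay past 90% recovery
  toward baseline (APD90-style; `repolarization_fraction`, default 0.9),
  with sub-sample linear interpolation at the crossing. MAPDUR is computed
  as EOR − AT, so the identity holds exactly by construction.
* **"Similar characteristics"** for the 4-consecutive rule — pairwise
  relative difference in amplitude and MAPDUR at most 15%
  (`similarity_tolerance`). The scan returns the lowest qualifying start
  index, so ties cannot arise. The CF credited to a detection is the force
  at the last beat of that first run; the per-beat force is the median of
  the calibrated force channel over the beat window.
* **Beat windows** span from 50 ms before each QRS to 50 ms before the
  next (the last window extends by the median RR interval): interior
  windows partition the trace exactly.

## Filter realization

The band-pass is a second-order Butterworth applied forward and backward
(zero phase, so fiducial timing is unbiased). Two numerical details:

* the design corners are pre-warped by the double-pass factor
  `(√2 − 1)^(1/4) ≈ 0.802` so that 0.1–120 Hz is the −3 dB band of the
  *overall* zero-phase response rather than of a single pass;
* the forward-backward initial conditions use Gustafsson's method with a
  truncated impulse-response length (16 time constants of the high-pass
  pole). The default pad-based initialisation is numerically wrong for a
  0.1 Hz corner at kHz sampling — in testing it leaked a 500 Hz tone at
  −4 dB where the analytic response is −58 dB — while the Gustafsson
  estimate reproduces the analytic |H(f)|² to three significant figures.
  Channel means are removed before filtering.

## Classification rules

Post-ablation, with `ref` the site-matched pre-ablation detection force when
available, else the cohort mean:

| MAP | in pattern | force vs ref | label |
|---|---|---|---|
| yes | yes | — | gap |
| yes | no | — | conductive |
| no | — | > ref (strict) | non-conductive |
| no | — | ≤ ref | indeterminate |

The *indeterminate* label is a deliberate addition: without it, a viable
site probed only below its threshold would be misread as successfully
ablated. Ties (force exactly equal to the reference) fall to indeterminate
for the same reason. Surveys whose silent sites are documented only as
"probed above the reference" (the packaged worked examples print no value)
carry a `supra_reference_force` sentinel that satisfies the force condition
without inventing a number. Reports tally in-pattern and out-of-pattern
sites separately, since whether non-ablated neighbours belong in gap
statistics is a reporting choice.

## FBG calibration

Each fiber is calibrated on a bench: known forces against measured
wavelength shifts, fitted by ordinary least squares on the centred design
(`force = slope·shift + intercept`, free intercept — whether the bench line
passes through the origin is not assumed). The fit equals the closed-form
normal-equations solution to 1e-9 (tested). Calibration is per-fiber and
mandatory; applying a curve to another fiber's series is an error, not a
warning. Negative calibrated forces are clipped to zero (contact force is
non-negative by definition) and the clipping is logged.

## Synthetic data generator

The generator emulates the bench situation, not membrane biophysics:

* **Thresholds** of viable tissue follow a normal truncated below at 0.5 g
  whose *realized* mean/SD equal the configured values (7.6/4.4 g by
  default): the parent parameters of the truncated distribution are solved
  numerically, because naive truncation of N(7.6, 4.4) would shift the
  realized mean to ≈8.1 g and shrink the SD to ≈3.9 g, silently breaking
  the interpretation of the configuration. Elicitation is a hard threshold
  on the instantaneous force (a step, not a sigmoid): the protocol treats
  MAP appearance as a threshold event.
* **Waveforms**: a 2 ms linear rise, a flat plateau over 55% of the MAP
  duration, then an exponential tail whose 90%-recovery crossing falls
  exactly one MAP duration after the upstroke; amplitude 3–6 mV and
  duration 150–250 ms are drawn uniformly per site. These ranges are
  generator conventions — only the detection floor (2 mV / 100 ms) is
  empirically anchored — and are flagged as such in `SimulationConfig`.
  Sub-threshold and non-viable beats carry a ≤0.5 mV far-field bump, so the
  detector sees realistic negatives rather than silence.
* **Timing**: QRS-like complexes (Q/R/S plus a T wave) at the configured
  heart rate (default 80 bpm), the MAP upstroke 20 ms after each R peak;
  1 kHz sampling resolves the 2 ms rise.
* **Respiration**: additive sinusoids (default 0.2 mV on the MAP channel,
  0.3 g on the applied force, 4 s period), suppressed when a breath hold is
  simulated; a per-sample quality flag marks breath-hold windows.
* **Sensor**: the applied force maps through the inverse of a known linear
  calibration (5 g/nm) plus 0.02 nm of sensor noise; additive Gaussian
  noise (0.05 mV) on the electrogram channels.
* **The operator** is closed-loop: the force staircase (start 0.5 g, step
  0.25 g, five beats per level) rises one step after each silent level,
  holds while MAPs are appearing, and stops once four consecutive beats
  elicit one — on silent tissue it stops only after holding a probe force
  above both 12 g and the site's own pre-ablation force. Because the
  operator reacts to elicitation, which depends on the respiratory wobble,
  the staircase and the trace share one respiration phase. The staircase
  step is the quantisation of the measured detection force (upward bias at
  most one step), which is why the recovered reference mean sits within
  ~0.15 g of the configured 7.6 g rather than half a 0.5 g step above it.

What the generator does **not** emulate: membrane kinetics (no
Hodgkin–Huxley dynamics), lesion-growth thermal physics, 3-D anatomy and
catheter mechanics, arrhythmic rhythms (beats are regular with optional
drift only in tests), electrode polarisation artifacts, and MAP amplitude
run-down under sustained pressure. Passing tests therefore demonstrate that
the *analysis* is correct under the stated statistical structure, not that
the detector is robust to every artifact of live recordings.

## Validation problem sizes

The packaged validation runs at desk scale: threshold recovery uses 20
independent surveys of 200 viable sites (pooled mean within ±0.65 g and
pooled SD within ±0.5 g of the configured values; at least 80% of
individual surveys inside those bands — a per-survey "all within ±2 SE"
requirement would be failed ~60% of the time by an ideal unbiased
estimator, since each survey independently lands outside ±2 SE with
probability ≈5%); planted-gap recovery uses 4×4 grids with 0–3 gaps × 20
seeds and requires exact gap-set equality; the consistent-run search is
checked against an exhaustive scan on 100 randomized sequences; the
classification truth table is enumerated exhaustively.

## Known limitations

* The endocardial worked example carries no printed per-site forces; its
  MAP-positive sites are classified as conductive because they are recorded
  as lying off the ablated line itself. If they were instead counted as
  in-pattern, the same rules would report them as gaps.
* The EOR convention (90% recovery) and the 15% similarity tolerance are
  defensible defaults, not measured constants; both are configurable and
  results that depend on them should be reported with the values used.
* The amplitude criterion is implemented peak-to-baseline; peak-to-peak is
  available but changes the effective 2 mV floor.
* `build_reference` summarises detection forces with mean and sample SD
  (n−1 denominator; a singleton reports SD 0), which is adequate for the
  roughly normal threshold distributions simulated here but not robust to
  heavy-tailed real-world force distributions.
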