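# mapgap

Lesion-integrity assessment from co-recorded **monophasic action potentials
(MAPs)** and **fiber-Bragg-grating (FBG) contact forces**.

When a linear radiofrequency ablation lesion (for example across the left
atrial mitral isthmus) is incomplete, residual islands of electrically viable
tissue — *conduction gaps* — let arrhythmias recur. A focal catheter that
records the local MAP while sensing its own tip contact force (CF) can find
those gaps at therapy time: viable myocardium elicits a MAP once the tip is
pressed with sufficient force, while ablated tissue stays electrically silent
at any force. `mapgap` implements that assessment as a reusable, tested
pipeline for electrophysiology signal analysts:

* **synthesis** (`mapgap.synth`) — co-registered MAP/ECG/FBG-sensor
  recordings and whole lesion surveys with planted gaps, with the
  statistical structure the analysis assumes (site-specific elicitation
  thresholds drawn from the viable-tissue distribution N(7.6 g, 4.4 g),
  QRS-locked MAP waveforms, respiration wander, sensor noise);
* **calibration** (`mapgap.calibration`) — per-fiber ordinary-least-squares
  wavelength-shift → grams conversion, `force = slope·shift + intercept`,
  with clipping at zero force;
* **detection** (`mapgap.detection`) — zero-phase 0.1–120 Hz band-pass,
  QRS references on the ECG channel, per-beat MAP criteria and metrics
  (see below), and the four-consecutive-similar-waveform rule that fixes
  the contact force credited to a detection;
* **classification** (`mapgap.classify`) — the site decision rules and the
  survey report;
* **fixtures / CLI** (`mapgap.fixtures`, `mapgap.cli`) — transcribed
  worked-example surveys and a thin `mapgap` command-line wrapper.

## The measurement model

Per beat, with the earliest ventricular activation (QRS onset on the
reference ECG) as time zero:

| metric | definition |
|---|---|
| AT | earliest ventricular activation → local activation (maximum MAP upstroke velocity) |
| EOR | earliest ventricular activation → local end of repolarization (first decay past 90% recovery toward baseline) |
| MAPDUR | local activation → local EOR, so MAPDUR = EOR − AT |

A beat counts as MAP-positive when its deflection amplitude exceeds **2 mV
(strictly)** and its duration reaches **100 ms (inclusively)**. A site counts
as MAP-positive only after **4 consecutive** beats with similar waveform
characteristics (pairwise amplitude and MAPDUR within 15%); the CF at the
**last** beat of that first run is the site's detection force. Post-ablation,
each site is labelled:

* **gap** — MAP present at a site inside the intended lesion pattern;
* **conductive** — MAP present outside the pattern (non-ablated myocardium);
* **non-conductive** — no MAP although the applied CF strictly exceeded the
  reference force (the site's own pre-ablation detection force when known,
  else the viable-tissue cohort mean of 7.6 g);
* **indeterminate** — no MAP but sufficient contact was never demonstrated,
  so electrical death cannot be claimed.

## Worked example

`examples/` holds one short script per capability. Running
`python examples/05_survey_end_to_end.py` simulates a 4×4 epicardial-style
grid with a lesion line on rows B–C and a planted gap at B3, then runs the
whole chain (calibration fit, filtering, detection, site-matched references,
classification):

```
site    label            ref CF (g)  evidence (g)
A1      conductive             11.3         11.27
B1      non_conductive         10.4         12.52
B2      non_conductive          3.1         12.29
B3      gap                     2.1          2.07
B4      non_conductive         10.2         12.54
...
counts: conductive=8, gap=1, non_conductive=7
gaps: B3

planted gap: B3; recovered gap set: ['B3']
```

Each row shows the reference force the rule compared against and the
evidence force (the detection CF for MAP-positive sites, the maximum probe
force for silent ones): the ablated line reads non-conductive, tissue off
the line stays conductive, and the planted gap is recovered exactly.
`examples/04_classify_fixture.py` reproduces the packaged worked-example
surveys, e.g. the first epicardial set (2 MAP-positive sites of 6; the
in-pattern positive B3 at 7.3 g is the gap, D1 at 8.9 g outside the pattern
is conductive) and the endocardial mitral-isthmus survey (4 non-conductive,
5 conductive of 9).

## Command line

```bash
mapgap simulate --pattern layout.json --seed 1 --out survey/
mapgap calibrate --bench bench.csv --fiber F1 --out cal.json
mapgap detect   --trace survey/B3_post_ablation.csv --calibration cal.json --out det/
mapgap classify --survey survey/ --reference auto --out out/
mapgap run      --input set1 --out out/
```

YAML configuration (validated, unknown keys rejected) follows
`mapgap.config.PipelineConfig`: a `detector:` section (band edges, amplitude
and duration criteria, run length, similarity tolerance, repolarization
fraction), a `simulation:` section (sample rate, heart rate, threshold
distribution, noise and respiration levels, seed) and `reference_mode:
site_matched_first | cohort_only`.

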