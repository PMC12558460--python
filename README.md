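# pupilsacc

Analysis toolbox for **fixational-saccade rate and pupil dynamics around
self-paced limb movements**, together with a synthetic eye-tracking session
generator that provides ground truth for every analysis stage.

## The scientific problem

During steady fixation the eyes keep producing small ballistic movements
(fixational saccades, typically < 1° in amplitude). Their rate is not
constant: it drops in the second or so leading up to a self-initiated motor
action (a key or pedal press), rebounds briefly above baseline right after,
and then returns to baseline. The pupil shows a mirrored pattern on the same
timescale — gradual dilation ahead of the action, rapid re-constriction
after — and the amplitudes of the two modulations covary across individual
movements, suggesting a shared neural drive.

Quantifying these effects from binocular 1000-Hz eye-tracker recordings
requires a chain of non-trivial steps, each implemented here as a module:

| module | what it does |
|---|---|
| `simulate` | synthetic sessions: truncated-exponential press intervals, inhomogeneous-Poisson saccades with event-locked suppression/rebound, linearly superposed pupil kernels, shared per-event amplitude factors, blinks |
| `io` | plain-text session dialect (samples TSV + events CSV), lossless round-trip |
| `preprocess` | binocular blink detection, median-anchored linear interpolation, 25-Hz zero-phase Butterworth change-rate signal (mm/s) |
| `saccades` | Engbert-style velocity-threshold detection (5-point derivative, median-based spread, λ·σ elliptic threshold, binocularity, 8–200-ms duration gate) |
| `event_rate` | peri-event rate curves in 25-ms bins over [−2.5, +3] s with mutual overlap exclusion, 250-ms boxcar smoothing, per-event suppression/rebound metrics |
| `pupil_glm` | FIR deconvolution of event-locked pupil change-rate kernels at 1/30-s resolution, solved by cross-validated ridge regression, with nuisance event types |
| `cluster_stats` | cluster-mass sign-flip (baseline-mirroring) Monte Carlo test |
| `covariation` | per-event table (rate modulation, pupil modulation, tonic pupil, inter-press intervals), standardized per-participant regression, group t-tests |
| `latency` | extremum-timing lags between the rate and pupil curves; pupil light-reflex latency |
| `pipeline` / `cli` | end-to-end orchestration from a single YAML config |

## The core quantities

For each motor event at time *t* = 0:

* **rate curve** — r(b) = Σ counts(b) / (0.025 · Σ valid(b)) over 25-ms bins
  b spanning [−2.5, +3] s, where a bin is excluded from both neighbors
  whenever two events' windows overlap;
* **per-event rate modulation** — saccades/s in [+0.2, +1.2) s minus
  saccades/s in [−0.8, 0) s;
* **pupil kernel** — the coefficients β of the ridge-penalized model
  y = Xβ + ε, where y is the 30-Hz pupil change-rate signal (mm/s) and X a
  staggered impulse (Toeplitz-like) design with one column per 1/30-s offset
  per event type;
* **per-event pupil modulation** — mean change rate in [−0.6, +0.2) s minus
  mean in [+0.6, +1.6) s;
* **cluster statistics** — pointwise one-sample t against each participant's
  baseline, cluster mass = Σt over consecutive same-signed p < .05 points,
  null distribution from 1000 random baseline-mirrorings;
* **covariation** — per participant, z-scored OLS of rate modulation on
  pupil modulation, tonic pupil size, and the two flanking inter-press
  intervals; group-level two-tailed one-sample t on the coefficients.

## Worked example

```python
import pupilsacc as ps

cfg = ps.SimulationConfig(n_runs=4, seed=7, blink_rate=6.0)
blocks, events, truth = ps.render_session(cfg)
res = ps.analyze_session(blocks, events)

print(len(res["saccades"]), "saccades detected")
print("baseline rate", round(res["rate_curve"].baseline, 2), "saccades/s")
k = res["kernels"]["press"]
print("kernel peak", round(k.value.max(), 3), "mm/s,",
      "trough", round(k.value.min(), 3), "mm/s")
```

prints (seed 7):

```
151 saccades detected
baseline rate 0.84 saccades/s
kernel peak 0.092 mm/s, trough -0.075 mm/s
```

i.e. the detector recovered the session's fixational saccades (the injected
ground truth contains 159; baseline rate was simulated at 0.89 saccades/s),
and the deconvolved press kernel shows the dilation-then-constriction shape
(injected lobes: +0.12 / −0.10 mm/s, shrunk slightly by the ridge penalty
and per-event amplitude variability).

The same chain runs from a shell:

```sh
pupilsacc simulate -o session/ --seed 7     # writes samples.tsv, events.csv
pupilsacc all -o results/ --seed 7          # full cohort pipeline
```

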