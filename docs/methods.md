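# Methods

This note documents the models implemented in `pupilsacc`, the defaults and
why they were chosen, the numerical decisions, and what the synthetic
validation does and does not establish.

## Synthetic sessions (`simulate`)

The generator emulates a self-paced movement experiment: a session is a set
of 45-s runs during which "presses" occur at truncated-exponential
intervals, while binocular gaze and pupil traces are sampled at 1000 Hz.

**Inter-press intervals.** Exponential with scale 4.6 s conditioned on
[3, 8] s, drawn by inverse-CDF sampling. The closed-form mean of this law is
lo + s − w·e^(−w/s)/(1 − e^(−w/s)) ≈ 5.056 s, so a 45-s run carries ≈ 8–9
events on average.

**Saccade times.** An inhomogeneous Poisson process realized by thinning.
The intensity is a baseline rate (default 0.89 saccades/s) multiplied by an
event-locked modulation around every press: a linear ramp from 1 down to
(1 − depth·aᵢ) over the second before the press and a boxcar at
(1 + gain·aᵢ) over [0.2, 1.2] s after it (defaults depth 0.5, gain 0.4).
Overlapping events combine multiplicatively, floored at zero. The profile is
piecewise linear and non-increasing between its knots, so the thinning bound
is exact at the knots. Time-rescaled inter-saccade intervals pass an Exp(1)
KS test, which validates the simulator itself.

**Saccade waveforms.** Each saccade is rendered as a minimum-jerk
displacement (smooth, velocity peaked mid-flight). Amplitudes are log-normal
with median 21.3 arcmin and log-SD 0.58 (matching a 17-arcmin interquartile
range); durations scale weakly with amplitude around a 19-ms median;
directions deviate from horizontal by N(0, 8°), putting ≈ 78% within 10° of
horizontal. Direction sign re-centers gaze when it strays beyond 0.4°, so
traces stay near fixation without an explicit drift model.

**Pupil trace.** Baseline (default 4 mm) plus the time-integral of linearly
superposed per-event change-rate kernels. The default kernel has a dilation
lobe (+0.12 mm/s, σ 0.45 s, peaking 0.1 s before the press) and a
re-constriction lobe (−0.10 mm/s, σ 0.5 s, peaking 0.9 s after); `delay`
rigidly shifts the kernel, which the latency validation exploits.
Luminance-alternation runs use a separate light-reflex kernel whose
constriction minimum sits exactly 0.4 s after onset.

**Coupling.** One log-normal amplitude factor per event (log-SD
`coupling_sd`, mean 1) scales both that event's rate modulation and its
pupil kernel. This creates the positive per-event association between
saccade and pupil modulation that the covariation stage is designed to
recover; switching `coupling_sd` to 0 removes it without changing either
marginal signal, which provides the matched null condition.

The amplitude distribution of the factor is a modeling choice, not an
inference: only the *existence* of per-event covariation is a property the
analysis targets; log-normal keeps intensities positive.

**Noise and blinks.** Both eyes carry the same true signals plus
independent white noise (gaze 0.005° RMS, pupil 0.002 mm RMS — the level of
a well-calibrated video tracker). Blinks are binocular artifacts: a 30-ms
pupil collapse, a 100-ms signal gap, and a 30-ms recovery, never crossing
run boundaries. Real sessions additionally contain drift, tremor, 1/f pupil
noise, tracker-specific artifacts and non-stationary press behavior; none
of these are modeled, so passing the synthetic validation shows the
*pipeline* is correct under its stated assumptions, not that the
assumptions hold for any particular recording.

## Preprocessing (`preprocess`)

Blink candidates per eye are maximal spans where |Δpupil| exceeds
25 mm/s (a physiologically impossible change rate) or the pupil is absent,
with gaps under 50 ms bridged; only candidates that overlap between the
eyes become blinks, the rest become a missing-data mask. Blinks (±20 ms
padding) are bridged by the line joining the medians of 50-ms flanking
windows; the line is anchored at the window *centers*, so a linear pupil
trend is reproduced exactly. A blink abutting a run edge is left missing
rather than extrapolated. These four widths are defaults exposed in the
API — the detection *criteria* (rate + absence + binocular overlap) are the
fixed part of the design, the thresholds are tunable.

The analysis signal is the first difference of the mean-of-eyes pupil
(falling back to the valid eye when one is missing), scaled to mm/s and
filtered with a third-order Butterworth low-pass at 25 Hz. Filtering is
zero-phase (forward–backward), which preserves event-locked timing — the
latency analysis depends on this. Each run is filtered separately; runs
shorter than the filter warm-up raise an error. Residual missing samples
are bridged before filtering and re-masked afterwards so transients do not
leak while gaps stay flagged.

## Saccade detection (`saccades`)

A 5-point moving derivative (exact for linear motion) feeds a per-run,
per-component robust spread estimate σ² = median(v²) − median(v)²; the
threshold is the ellipse (v_x/λσ_x)² + (v_y/λσ_y)² = 1 with λ = 6, the
conservative literature-standard choice. Candidates need ≥ 6 supra-threshold
ms. Both eyes' candidate periods are pooled; periods ≤ 5 ms apart merge, and
a merged period survives only if it has contributions from both eyes, lasts
8–200 ms, and is not within 10 ms of a blink. Kinematics (amplitude,
direction, peak velocity) are measured on the mean-of-eyes trace, and the
saccade's single timestamp is the midpoint of start and end. Computing σ
per run rather than per session makes the detector robust to slow noise
non-stationarity; a zero-variance run is skipped with a warning rather than
dividing by zero.

## Event-locked rate (`event_rate`)

Raw presses under 300 ms apart collapse (chained: each press is compared to
the previous *raw* press) into one motor event at the first press — this
targets pedal-bounce artifacts. Rates are tallied per 25-ms bin over
[−2.5, +3] s; a bin is excluded (from numerator *and* denominator) when any
part of it lies inside another event's peri-event window — the exclusion is
mutual, so no saccade is ever credited to two events — or outside the run.
Smoothing is a 250-ms boxcar implemented as the mean over bins b−5 … b+4
(exact 250 ms on a 25-ms grid; the half-bin asymmetry is unavoidable and
constant). Zero-denominator bins are excluded from each local average, and
edges use the available bins.

The curve baseline is the time-weighted mean over the window's first 500 ms
and last 1000 ms (weights 0.5 : 1). Per-event modulation is the rate in
[+0.2, +1.2) s minus the rate in [−0.8, 0) s, each divided by its actual
width; events with a neighbor within 2.5 s are invalid for this metric.

## Pupil deconvolution (`pupil_glm`)

Overlap is the reason for deconvolution: pupil responses outlast the
inter-press interval, so naive event-locked averaging mixes neighboring
responses, while under linear superposition a staggered-impulse (FIR)
design separates them. Both the design and the response live on a 30-Hz
frame grid — the response as per-run block means of the 1-kHz change-rate
signal, the impulses at the frame nearest each event time plus offset
(offsets 1/30 s apart; the press window is [−2, +5.5] s). Down-sampling both
sides keeps the system well-conditioned and matches the kernel resolution.

The system is solved with scikit-learn's `RidgeCV` at its default penalty
grid {0.1, 1, 10} and efficient leave-one-out cross-validation on frames
(folds do not respect run boundaries; with ≈ 10⁴ frames per session the
difference is negligible). Frames whose samples are all missing are dropped
row-wise, not interpolated — interpolation already handled blinks, and
residual gaps are rare. Run starts are always modeled as a nuisance event
type so onset transients cannot bias the press kernel; an optional variant
adds blinks and detected saccades as further nuisance types (both variants
are exposed because regressing out oculomotor events can remove genuine
shared signal — the package computes either, the choice is the user's).
Kernels integrate to pupil-size curves by Riemann sum (value 0 at the
window start).

## Cluster statistics (`cluster_stats`)

Pointwise one-sample t of curve-minus-own-baseline across participants;
clusters are maximal runs of consecutive points with p < .05 and constant
sign, with mass = Σt. The null mirrors each participant's curve in their
baseline (2·baseline − curve) independently with probability ½ per
iteration (1000 by default) and keeps the most extreme |mass|; a cluster's
Monte Carlo p is the fraction of null masses strictly exceeding its |mass|.
Pooling both signs through the absolute value makes the test two-sided.
Zero-variance timepoints are defined as t = 0, p = 1 so degenerate inputs
cannot crash the machinery. For rate curves the baseline is the
per-participant window baseline above; for change-rate kernels it is 0 mm/s.
The sign-flip sums are vectorized over iterations, exploiting the fact that
Σd² is invariant under sign flips.

## Covariation (`covariation`)

Tonic pupil size is a 30-s centered boxcar mean of the interpolated pupil,
restricted to the run and to non-missing samples (implemented with
cumulative sums). When the exact event sample is missing, the nearest
non-missing tonic value within 1 s is used. The per-event table keeps
events that are isolated (no neighbor within 2.5 s), not first or last of
their run (their flanking intervals are undefined), and fully finite.
Participants with fewer than 10 remaining events are excluded. All five
columns are z-scored with the sample SD (ddof = 1) and the regression has
no intercept — z-scoring makes the intercept exactly zero and the
coefficients dimensionless standardized betas. Group inference is a
two-tailed one-sample t per predictor, reported with the median, IQR and
proportion-positive descriptives.

## Latencies (`latency`)

Lags are differences of extremum times on the across-participant *average*
curves (not per participant): rate minimum in [−1, +0.2] s → pupil
change-rate peak in [−1, +0.5] s, and rate peak in [0, +1.2] s → pupil
change-rate minimum in [0, +2] s. The search windows bracket the features
the curves show and are config-exposed defaults; ties take the earliest
offset, and an extremum sitting on a window boundary sets a truncation
flag. The light-reflex latency is the interior minimum of the
luminance-increment kernel within [0, 1.5] s; estimates are quantized to
the 25-ms (rate) and 33-ms (pupil) grids, so lag comparisons carry a
±35-ms grid tolerance.

## Validation problem sizes

The validation suite (`scripts/acceptance.py`, mirrored by
`tests/test_acceptance.py`) uses: 10⁶ interval draws; 3 sessions of 8 runs
for detector recovery (hit window ±20 ms); 30 participants × 8 runs for
rate-curve recovery, compared against the boxcar-smoothed injected profile
(the estimator smooths, so the oracle must too); 6-run sessions for kernel
recovery (the well-separated case pins intervals near 8 s; the overlap case
uses the study spacing, both at zero noise with a near-zero penalty so the
measured error is the method's, not the noise's); 200 null datasets of 20
participants with 200 Monte-Carlo iterations each for type-I calibration;
30 participants per covariation cohort with 40 null suites, where the
calibration check is per predictor (each predictor non-significant at
α = .01 in ≥ 95% of suites); and 6-participant cohorts for the 300-ms
lag-shift recovery plus 4 luminance sessions for the 400-ms light-reflex
latency. Recovery runs that only exercise post-detection stages feed the
generator's ground-truth saccade times into the analysis, isolating the
stage under test from detector variance.

## Known limitations

* The generator's white measurement noise and blink model are deliberately
  minimal; detector performance numbers do not transfer to noisy clinical
  recordings.
* Multiplicative combination of overlapping rate modulations and exact
  linear superposition of pupil responses are assumptions of the analysis,
  built into the generator by design — the validation cannot detect their
  violation in real data.
* The covariation model is the two-stage (per-participant OLS, then group
  t) procedure; no hierarchical/mixed-effects alternative is provided.
* Tonic pupil, interpolation-window, and nuisance-window widths are
  conventions exposed as parameters, not estimated quantities.
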