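"""Synthetic binocular eye-tracking sessions with known ground truth.

The generator emulates the statistical structure that the downstream analysis
assumes, so that every stage can be validated against injected truth:

* self-paced motor events with truncated-exponential inter-press intervals;
* fixational saccades as an inhomogeneous Poisson process whose intensity is
  a baseline rate multiplied by an event-locked modulation profile
  (pre-event linear ramp-down, post-event boxcar rebound);
* saccades rendered into the gaze traces as minimum-jerk ballistic
  displacements with field-typical kinematics (median amplitude near
  21 arcmin, duration near 19 ms, predominantly horizontal);
* a pupil trace that is a baseline plus the time-integral of linearly
  superposed per-event change-rate kernels (dilation then re-constriction);
* one shared log-normal amplitude factor per motor event that scales both
  the saccade-rate modulation and the pupil kernel — the per-event coupling
  the covariation stage is designed to recover;
* blinks as binocular signal-loss artifacts flanked by rapid pupil collapse
  and recovery;
* optional luminance-alternation runs driving a pupil light/dark reflex.

Both eyes carry the same true signals plus independent white measurement
noise.  All output is bit-deterministic given the configuration and seed.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .io import EventLog, SampleBlock, EVENT_COLUMNS

RUN_GAP_MS = 5000  # inter-run rest gap in session time


# ---------------------------------------------------------------------------
# configuration

@dataclass
class PupilKernelSpec:
    """Parametric event-locked pupil change-rate kernel (mm/s).

    Two Gaussian lobes: a dilation lobe peaking just before the event and a
    re-constriction lobe after it.  ``delay`` rigidly shifts the whole kernel
    (used to probe latency recovery).
    """

    dilation_amp: float = 0.12        # mm/s
    dilation_peak: float = -0.1       # s relative to event
    dilation_width: float = 0.45      # Gaussian sigma, s
    constriction_amp: float = -0.10   # mm/s
    constriction_peak: float = 0.9    # s
    constriction_width: float = 0.5   # s
    delay: float = 0.0                # s, rigid shift
    support: tuple[float, float] = (-2.0, 3.5)

    def evaluate(self, tau: np.ndarray) -> np.ndarray:
        tau = np.asarray(tau, dtype=float) - self.delay
        v = (self.dilation_amp
             * np.exp(-0.5 * ((tau - self.dilation_peak)
                              / self.dilation_width) ** 2)
             + self.constriction_amp
             * np.exp(-0.5 * ((tau - self.constriction_peak)
                              / self.constriction_width) ** 2))
        lo, hi = self.support
        v = np.where((tau + self.delay >= lo) & (tau + self.delay <= hi), v, 0.0)
        return v


@dataclass
class PlrKernelSpec:
    """Pupil light-reflex change-rate kernel for a luminance step.

    A constriction lobe whose minimum sits ``latency`` seconds after light
    onset, followed by a slow recovery lobe.  The dark reflex (luminance
    decrement) uses the sign-flipped kernel.
    """

    amp: float = -0.8          # mm/s at the constriction peak
    latency: float = 0.4       # s, onset -> fastest constriction
    width: float = 0.12        # s
    recovery_amp: float = 0.12
    recovery_peak: float = 1.4
    recovery_width: float = 0.6
    support: tuple[float, float] = (0.0, 3.5)

    def evaluate(self, tau: np.ndarray) -> np.ndarray:
        tau = np.asarray(tau, dtype=float)
        v = (self.amp * np.exp(-0.5 * ((tau - self.latency) / self.width) ** 2)
             + self.recovery_amp
             * np.exp(-0.5 * ((tau - self.recovery_peak)
                              / self.recovery_width) ** 2))
        lo, hi = self.support
        return np.where((tau >= lo) & (tau <= hi), v, 0.0)


@dataclass
class SimulationConfig:
    """Study-condition parameters of one simulated session."""

    sampling_rate: float = 1000.0        # Hz
    run_duration: float = 45.0           # s
    n_runs: int = 10
    effector: str = "hand"
    interval_scale: float = 4.6          # s, exponential scale of intervals
    interval_lo: float = 3.0             # s, truncation range
    interval_hi: float = 8.0
    baseline_saccade_rate: float = 0.89  # saccades / s
    suppression_depth: float = 0.5       # fractional rate drop at the event
    rebound_gain: float = 0.4            # fractional rate gain post-event
    rate_mod_shape: str = "ramp_boxcar"
    pupil_baseline: float = 4.0          # mm
    pupil_kernel_spec: PupilKernelSpec = field(default_factory=PupilKernelSpec)
    coupling_sd: float = 0.5             # sigma of log-normal per-event factor
    noise_sd_gaze: float = 0.005         # deg, per-sample white noise per eye
    noise_sd_pupil: float = 0.002        # mm
    blink_rate: float = 0.0              # blinks / min
    saccade_amp_median: float = 21.3     # arcmin
    saccade_amp_log_sd: float = 0.58     # lognormal sigma (IQR 17.1 arcmin)
    saccade_dir_sd: float = 8.0          # deg from horizontal (78.5% < 10 deg)
    n_plr_runs: int = 0
    plr_kernel_spec: PlrKernelSpec = field(default_factory=PlrKernelSpec)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.interval_lo >= self.interval_hi:
            raise ValueError("interval_lo must be < interval_hi")
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be > 0")
        for name in ("baseline_saccade_rate", "rebound_gain", "blink_rate",
                     "coupling_sd", "noise_sd_gaze", "noise_sd_pupil"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not 0.0 <= self.suppression_depth <= 1.0:
            raise ValueError("suppression_depth must lie in [0, 1]")
        if self.rate_mod_shape != "ramp_boxcar":
            raise ValueError(f"unknown rate_mod_shape {self.rate_mod_shape!r}")


@dataclass
class GroundTruth:
    """Per-session injected truth, keyed by run id where per-run."""

    saccade_times: dict[str, list[float]] = field(default_factory=dict)
    event_times: dict[str, list[float]] = field(default_factory=dict)
    per_event_amplitude: dict[str, list[float]] = field(default_factory=dict)
    blink_intervals: dict[str, list[tuple[float, float]]] = field(
        default_factory=dict)
    rate_profile_offsets: list[float] = field(default_factory=list)
    rate_profile_values: list[float] = field(default_factory=list)
    pupil_kernel_offsets: list[float] = field(default_factory=list)
    pupil_kernel_values: list[float] = field(default_factory=list)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "GroundTruth":
        d = json.loads(Path(path).read_text())
        gt = cls(**d)
        gt.blink_intervals = {k: [tuple(iv) for iv in v]
                              for k, v in gt.blink_intervals.items()}
        return gt


def _rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


# ---------------------------------------------------------------------------
# inter-press intervals

def truncated_exponential_mean(scale: float, lo: float, hi: float) -> float:
    """Closed-form mean of an exponential conditioned on [lo, hi]."""
    w = hi - lo
    q = math.exp(-w / scale)
    return lo + scale - w * q / (1.0 - q)


def sample_intervals(scale: float, lo: float, hi: float, n: int,
                     seed) -> np.ndarray:
    """Draw inter-event intervals from a range-truncated exponential.

    Inverse-CDF sampling of the exponential with the given scale conditioned
    on lying within [lo, hi].
    """
    if lo >= hi:
        raise ValueError("invalid range: lo must be < hi")
    if scale <= 0:
        raise ValueError("scale must be > 0")
    if n < 0:
        raise ValueError("n must be >= 0")
    rng = _rng(seed)
    u = rng.random(n)
    mass = 1.0 - math.exp(-(hi - lo) / scale)
    return lo - scale * np.log1p(-u * mass)


# ---------------------------------------------------------------------------
# event-locked rate modulation and saccade-time simulation

def ramp_boxcar_profile(suppression_depth: float, rebound_gain: float
                        ) -> Callable[[np.ndarray, float], np.ndarray]:
    """Event-locked multiplicative rate-modulation profile.

    Linear ramp from 1 down to (1 − depth·a) over the second before the
    event, boxcar at (1 + gain·a) over [0.2, 1.2] s after it, 1 elsewhere;
    ``a`` is the per-event amplitude factor.
    """

    def profile(tau: np.ndarray, a: float = 1.0) -> np.ndarray:
        tau = np.asarray(tau, dtype=float)
        mod = np.ones_like(tau)
        ramp = (tau >= -1.0) & (tau < 0.0)
        mod = np.where(ramp, 1.0 - suppression_depth * a * (tau + 1.0), mod)
        box = (tau >= 0.2) & (tau < 1.2)
        mod = np.where(box, 1.0 + rebound_gain * a, mod)
        return mod

    profile.knot_offsets = (-1.0, 0.0, 0.2, 1.2)  # type: ignore[attr-defined]
    return profile


def modulated_intensity(t: np.ndarray, rate_profile, event_times: np.ndarray,
                        baseline_rate: float,
                        amplitudes: np.ndarray | None = None) -> np.ndarray:
    """Intensity = baseline × product of per-event modulations, floored at 0."""
    t = np.atleast_1d(np.asarray(t, dtype=float))
    event_times = np.asarray(event_times, dtype=float)
    if amplitudes is None:
        amplitudes = np.ones_like(event_times)
    lam = np.full(t.shape, float(baseline_rate))
    for e, a in zip(event_times, amplitudes):
        lam *= rate_profile(t - e, a)
    return np.maximum(lam, 0.0)


def simulate_saccade_times(rate_profile, event_times: Sequence[float],
                           run_duration: float, baseline_rate: float,
                           seed, amplitudes: Sequence[float] | None = None
                           ) -> np.ndarray:
    """Realize an inhomogeneous Poisson process by thinning.

    The intensity is ``baseline_rate`` multiplied by the product of the
    event-locked modulation around every event (clipped at 0).
    """
    if baseline_rate < 0:
        raise ValueError("negative intensity: baseline_rate must be >= 0")
    rng = _rng(seed)
    event_times = np.asarray(event_times, dtype=float)
    if amplitudes is not None:
        amplitudes = np.asarray(amplitudes, dtype=float)
    if run_duration <= 0 or baseline_rate == 0:
        return np.empty(0)

    # Upper bound for thinning: evaluate on a 1-ms grid plus the profile's
    # knots shifted to each event (the default profile is piecewise linear
    # and non-increasing between knots, so knots carry the maxima).
    grid = np.arange(0.0, run_duration, 1e-3)
    knots = getattr(rate_profile, "knot_offsets", ())
    if len(knots) and len(event_times):
        extra = (event_times[:, None] + np.asarray(knots)[None, :]).ravel()
        extra = extra[(extra >= 0) & (extra < run_duration)]
        grid = np.concatenate([grid, extra])
    lam_grid = modulated_intensity(grid, rate_profile, event_times,
                                   baseline_rate, amplitudes)
    if np.any(~np.isfinite(lam_grid)):
        raise ValueError("non-finite intensity")
    lam_max = float(lam_grid.max()) * 1.01 + 1e-12
    if lam_max <= 0:
        return np.empty(0)

    n_cand = rng.poisson(lam_max * run_duration)
    cand = np.sort(rng.random(n_cand) * run_duration)
    lam_c = modulated_intensity(cand, rate_profile, event_times,
                                baseline_rate, amplitudes)
    keep = rng.random(n_cand) * lam_max < lam_c
    return cand[keep]


# ---------------------------------------------------------------------------
# waveform rendering

def minimum_jerk(n: int) -> np.ndarray:
    """Normalized minimum-jerk displacement profile on n samples (0 -> 1)."""
    s = np.linspace(0.0, 1.0, n)
    return 10 * s ** 3 - 15 * s ** 4 + 6 * s ** 5


def _kernel_lookup(kernel, fs: float) -> tuple[np.ndarray, float]:
    """Tabulated cumulative integral of a change-rate kernel at 1/fs steps."""
    lo, hi = kernel.support
    delay = getattr(kernel, "delay", 0.0)
    grid = np.arange(lo, hi + delay + 1.0 / fs, 1.0 / fs)
    k = kernel.evaluate(grid)
    kint = np.cumsum(k) / fs
    return kint, lo


def _superpose_pupil(n: int, fs: float, run_events_s: np.ndarray,
                     amplitudes: np.ndarray, kernel) -> np.ndarray:
    """Sum of per-event integrated kernels, sampled on the run's 1/fs grid."""
    out = np.zeros(n)
    if len(run_events_s) == 0:
        return out
    kint, lo = _kernel_lookup(kernel, fs)
    m = len(kint)
    for e, a in zip(run_events_s, amplitudes):
        start = int(round((e + lo) * fs))
        i0, i1 = max(start, 0), min(start + m, n)
        if i0 < i1:
            out[i0:i1] += a * kint[i0 - start:i1 - start]
        if start + m < n:  # kernel fully elapsed: hold the net integral
            out[start + m:] += a * kint[-1]
        if start < 0:  # event precedes the grid (cannot happen for in-run events)
            out[:i0] += 0.0
    return out


def _draw_saccade_kinematics(rng, config, n, x_offset):
    amp_arcmin = config.saccade_amp_median * np.exp(
        rng.normal(0.0, config.saccade_amp_log_sd, n))
    angle = np.deg2rad(rng.normal(0.0, config.saccade_dir_sd, n))
    # keep gaze near fixation: move back toward 0 when displaced
    side = np.where(np.abs(x_offset) > 0.4, -np.sign(x_offset),
                    rng.choice([-1.0, 1.0], n))
    amp_deg = amp_arcmin / 60.0
    dx = amp_deg * np.cos(angle) * side
    dy = amp_deg * np.sin(angle)
    dur_ms = np.clip(np.round(19.0 * (amp_arcmin / 21.3) ** 0.3), 10, 60)
    return dx, dy, dur_ms.astype(int)


def render_session(config: SimulationConfig
                   ) -> tuple[list[SampleBlock], EventLog, GroundTruth]:
    """Render a full synthetic session on the integer-ms session clock.

    Motor runs are laid out back to back with rest gaps; optional
    luminance-alternation runs follow.  Returns the sample blocks, the event
    log (run boundaries, presses, luminance steps) and the injected truth.
    """
    rng = np.random.default_rng(config.seed)
    fs = config.sampling_rate
    n_samp = int(round(config.run_duration * fs))
    profile = ramp_boxcar_profile(config.suppression_depth,
                                  config.rebound_gain)

    blocks: list[SampleBlock] = []
    event_rows: list[tuple] = []
    gt = GroundTruth()
    offs = np.round(np.arange(-2.5, 3.0 + 1e-9, 0.025), 6)
    gt.rate_profile_offsets = offs.tolist()
    gt.rate_profile_values = (config.baseline_saccade_rate
                              * profile(offs, 1.0)).tolist()
    koffs = np.arange(-2.0, 5.5 + 1e-9, 1.0 / 30.0)
    gt.pupil_kernel_offsets = koffs.tolist()
    gt.pupil_kernel_values = config.pupil_kernel_spec.evaluate(koffs).tolist()

    t0 = 0
    for r in range(config.n_runs + config.n_plr_runs):
        is_plr = r >= config.n_runs
        run_id = (f"plr{r - config.n_runs + 1:02d}" if is_plr
                  else f"run{r + 1:02d}")
        # -- events
        n_draw = max(4, int(config.run_duration / config.interval_lo) + 2)
        ivals = sample_intervals(config.interval_scale, config.interval_lo,
                                 config.interval_hi, n_draw, rng)
        times = np.cumsum(ivals)
        times = times[times < config.run_duration - 0.25]
        if config.coupling_sd > 0:
            amps = np.exp(rng.normal(-config.coupling_sd ** 2 / 2.0,
                                     config.coupling_sd, len(times)))
        else:
            amps = np.ones(len(times))

        if is_plr:
            kinds = np.where(np.arange(len(times)) % 2 == 0,
                             "lum_increment", "lum_decrement")
            sacc = simulate_saccade_times(
                profile, [], config.run_duration,
                config.baseline_saccade_rate, rng)
            plr_signs = np.where(kinds == "lum_increment", 1.0, -1.0)
            pupil_sig = _superpose_pupil(n_samp, fs, times, plr_signs,
                                         config.plr_kernel_spec)
        else:
            kinds = np.full(len(times), "press")
            sacc = simulate_saccade_times(
                profile, times, config.run_duration,
                config.baseline_saccade_rate, rng, amplitudes=amps)
            pupil_sig = _superpose_pupil(n_samp, fs, times, amps,
                                         config.pupil_kernel_spec)

        # -- gaze with ballistic saccade displacements
        x = np.zeros(n_samp)
        y = np.zeros(n_samp)
        kept_sacc: list[float] = []
        cur_x = 0.0
        dxs, dys, durs = _draw_saccade_kinematics(rng, config, len(sacc),
                                                  np.zeros(len(sacc)))
        for i, mid_s in enumerate(sacc):
            dur = int(durs[i])
            start = int(round(mid_s * 1000.0)) - dur // 2
            end = start + dur
            if start < 5 or end > n_samp - 5:
                continue
            side = -np.sign(cur_x) if abs(cur_x) > 0.4 else np.sign(dxs[i]) or 1.0
            dx = abs(dxs[i]) * side
            prof = minimum_jerk(dur + 1)
            x[start:end + 1] += dx * prof
            x[end + 1:] += dx
            y[start:end + 1] += dys[i] * prof
            y[end + 1:] += dys[i]
            cur_x += dx
            kept_sacc.append((start + end) / 2.0 / 1000.0)

        pupil = config.pupil_baseline + pupil_sig
        t = t0 + np.arange(n_samp, dtype=np.int64)
        noise = rng.normal(0.0, 1.0, (6, n_samp))
        block = SampleBlock(
            run_id=run_id, t=t,
            xL=x + config.noise_sd_gaze * noise[0],
            yL=y + config.noise_sd_gaze * noise[1],
            pL=pupil + config.noise_sd_pupil * noise[2],
            validL=np.ones(n_samp, dtype=bool),
            xR=x + config.noise_sd_gaze * noise[3],
            yR=y + config.noise_sd_gaze * noise[4],
            pR=pupil + config.noise_sd_pupil * noise[5],
            validR=np.ones(n_samp, dtype=bool))
        blocks.append(block)

        run_t0_s = t0 / 1000.0
        event_rows.append((t0, run_id, "run_start", "none"))
        for kt, kind in zip(times, kinds):
            eff = config.effector if kind == "press" else "none"
            event_rows.append((t0 + int(round(kt * 1000)), run_id, kind, eff))
        event_rows.append((t0 + n_samp - 1, run_id, "run_end", "none"))

        gt.saccade_times[run_id] = [run_t0_s + s for s in kept_sacc]
        if not is_plr:
            gt.event_times[run_id] = (run_t0_s + times).tolist()
            gt.per_event_amplitude[run_id] = amps.tolist()
        gt.blink_intervals[run_id] = []
        t0 += n_samp + RUN_GAP_MS

    events = EventLog(pd.DataFrame(event_rows, columns=EVENT_COLUMNS))
    if config.blink_rate > 0:
        blocks, blink_iv = inject_blinks(blocks, config.blink_rate, rng)
        for run_id, ivs in blink_iv.items():
            gt.blink_intervals[run_id] = ivs
    return blocks, events, gt


# ---------------------------------------------------------------------------
# blink artifacts

def inject_blinks(blocks: list[SampleBlock], blink_rate: float, seed,
                  close_ms: int = 30, gap_ms: int = 100, reopen_ms: int = 30
                  ) -> tuple[list[SampleBlock], dict[str, list[tuple[float, float]]]]:
    """Insert binocular blink artifacts into sample blocks.

    Each blink is a rapid pupil collapse to zero over ``close_ms``, a span of
    missing samples (``gap_ms``), and a rapid recovery, time-locked across
    both eyes.  Gaze is lost during the gap.  Returns the modified blocks and
    the inserted [start, end] intervals in session seconds, per run.
    """
    if blink_rate < 0:
        raise ValueError("blink_rate must be >= 0")
    rng = _rng(seed)
    total = close_ms + gap_ms + reopen_ms
    intervals: dict[str, list[tuple[float, float]]] = {}
    if blink_rate == 0:
        return blocks, {b.run_id: [] for b in blocks}

    out_blocks = []
    for b in blocks:
        n = b.n
        dur_s = n / 1000.0
        k = rng.poisson(blink_rate * dur_s / 60.0)
        starts: list[int] = []
        margin = 400
        for _ in range(k):
            for _attempt in range(20):
                s = int(rng.integers(margin, n - total - margin))
                if all(abs(s - s2) > total + 500 for s2 in starts):
                    starts.append(s)
                    break
        starts.sort()
        new = SampleBlock(run_id=b.run_id, t=b.t.copy(),
                          xL=b.xL.copy(), yL=b.yL.copy(), pL=b.pL.copy(),
                          validL=b.validL.copy(),
                          xR=b.xR.copy(), yR=b.yR.copy(), pR=b.pR.copy(),
                          validR=b.validR.copy())
        ivs = []
        for s in starts:
            g0, g1 = s + close_ms, s + close_ms + gap_ms
            e = s + total
            down = np.linspace(1.0, 0.0, close_ms)
            up = np.linspace(0.0, 1.0, reopen_ms)
            for p, valid, gx, gy in ((new.pL, new.validL, new.xL, new.yL),
                                     (new.pR, new.validR, new.xR, new.yR)):
                p[s:g0] *= down
                p[g0:g1] = np.nan
                p[g1:e] = p[e] * up if e < n else np.nan
                gx[g0:g1] = np.nan
                gy[g0:g1] = np.nan
                valid[g0:g1] = False
            ivs.append((float(new.t[s]) / 1000.0, float(new.t[min(e, n - 1)]) / 1000.0))
        intervals[b.run_id] = ivs
        out_blocks.append(new)
    return out_blocks, intervals
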