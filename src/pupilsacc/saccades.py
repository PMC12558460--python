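"""Binocular velocity-threshold detection of fixational saccades.

The detector follows the Engbert–Mergenthaler family: a 5-point moving
derivative of each eye's gaze, a median-based robust estimate of the
velocity spread per component, an elliptic threshold at ``lambda`` spreads,
and a binocularity requirement.  Candidate periods from the two eyes that
are separated by 5 ms or less are merged; merged periods are kept only if
both eyes contributed, the duration lies within 8–200 ms, and the period is
not within 10 ms of a detected blink (video trackers produce artifactual
gaze excursions around blinks).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .io import SampleBlock
from .preprocess import BlinkInterval

LAMBDA_DEFAULT = 6.0
MIN_SPAN_MS = 6
MERGE_GAP_MS = 5
BLINK_MARGIN_MS = 10
DUR_MIN_MS = 8
DUR_MAX_MS = 200


@dataclass
class SaccadeEvent:
    """A retained (binocular) fixational saccade.

    ``timestamp`` is the midpoint of start/end — the single time the rate
    analysis assigns the saccade to.  Amplitude/direction describe the
    mean-of-eyes gaze displacement from start to end; direction is the
    absolute deviation from horizontal in degrees (0 = horizontal).
    """

    start: float          # ms, session time
    end: float            # ms
    amplitude: float      # arcmin
    direction: float      # deg from horizontal, in [0, 90]
    peak_velocity: float  # deg/s
    binocular: bool
    run_id: str = ""

    @property
    def timestamp(self) -> float:
        return (self.start + self.end) / 2.0

    @property
    def duration(self) -> float:
        return self.end - self.start


def velocity_trace(x: np.ndarray, dt: float) -> np.ndarray:
    """5-point moving-window derivative (deg/s).

    v_n = (x_{n+2} + x_{n+1} − x_{n−1} − x_{n−2}) / (6 dt); exact for linear
    motion.  The two edge samples on each side are NaN (undefined).
    """
    x = np.asarray(x, dtype=float)
    if len(x) < 5:
        raise ValueError("need at least 5 samples for the moving derivative")
    v = np.full(len(x), np.nan)
    v[2:-2] = (x[4:] + x[3:-1] - x[1:-3] - x[:-4]) / (6.0 * dt)
    return v


def median_spread(v: np.ndarray) -> float:
    """Median-based velocity spread: sqrt(median(v²) − median(v)²)."""
    v = v[np.isfinite(v)]
    if len(v) == 0:
        return 0.0
    var = np.median(v ** 2) - np.median(v) ** 2
    return float(np.sqrt(max(var, 0.0)))


def detect_monocular(vx: np.ndarray, vy: np.ndarray,
                     lam: float = LAMBDA_DEFAULT,
                     min_span: int = MIN_SPAN_MS) -> list[tuple[int, int]]:
    """Candidate saccade periods of one eye, as [start, end] sample indices.

    A sample is supra-threshold when (vx/ηx)² + (vy/ηy)² > 1 with
    η = λ·spread per component; candidates are maximal supra-threshold spans
    of at least ``min_span`` samples.  A zero-variance trace yields no
    candidates (threshold undefined).
    """
    if lam <= 0:
        raise ValueError("lambda must be > 0")
    sx, sy = median_spread(vx), median_spread(vy)
    if sx == 0.0 or sy == 0.0:
        warnings.warn("zero velocity spread; skipping run", stacklevel=2)
        return []
    with np.errstate(invalid="ignore"):
        crit = (vx / (lam * sx)) ** 2 + (vy / (lam * sy)) ** 2 > 1.0
    crit = np.nan_to_num(crit).astype(bool)
    spans = []
    idx = np.flatnonzero(crit)
    if len(idx) == 0:
        return []
    breaks = np.flatnonzero(np.diff(idx) > 1)
    starts = np.concatenate([[idx[0]], idx[breaks + 1]])
    ends = np.concatenate([idx[breaks], [idx[-1]]])
    for s, e in zip(starts, ends):
        if e - s + 1 >= min_span:
            spans.append((int(s), int(e)))
    return spans


def _merge_pooled(periods: list[tuple[int, int, str]],
                  gap: int) -> list[tuple[int, int, set]]:
    """Merge time periods (from either eye) separated by <= gap ms."""
    if not periods:
        return []
    periods = sorted(periods)
    merged: list[list] = [[periods[0][0], periods[0][1], {periods[0][2]}]]
    for s, e, eye in periods[1:]:
        if s - merged[-1][1] <= gap:
            merged[-1][1] = max(merged[-1][1], e)
            merged[-1][2].add(eye)
        else:
            merged.append([s, e, {eye}])
    return [(s, e, eyes) for s, e, eyes in merged]


def merge_and_filter(candL: list[tuple[int, int]],
                     candR: list[tuple[int, int]],
                     blinks: list[BlinkInterval],
                     block: SampleBlock,
                     merge_gap: int = MERGE_GAP_MS,
                     blink_margin: int = BLINK_MARGIN_MS
                     ) -> list[SaccadeEvent]:
    """Pool both eyes' candidate periods into retained saccades.

    Applies the merge (≤5 ms gaps), binocularity, duration (8–200 ms) and
    blink-proximity (10 ms) rules, and measures kinematics on the
    mean-of-eyes gaze trace.
    """
    pooled = ([(s, e, "L") for s, e in candL]
              + [(s, e, "R") for s, e in candR])
    merged = _merge_pooled(pooled, merge_gap)

    mx = (block.xL + block.xR) / 2.0
    my = (block.yL + block.yR) / 2.0
    dt = block.dt_ms / 1000.0
    if block.n >= 5:
        vx, vy = velocity_trace(mx, dt), velocity_trace(my, dt)
        speed = np.hypot(vx, vy)
    else:
        speed = np.zeros(block.n)

    out: list[SaccadeEvent] = []
    for s, e, eyes in merged:
        dur = e - s  # ms between first and last supra-threshold sample
        if not ({"L", "R"} <= eyes):
            continue
        if dur < DUR_MIN_MS or dur > DUR_MAX_MS:
            continue
        near_blink = any(s <= b.end + blink_margin and e >= b.start - blink_margin
                         for b in blinks)
        if near_blink:
            continue
        dx, dy = mx[e] - mx[s], my[e] - my[s]
        ang = abs(np.degrees(np.arctan2(dy, dx)))
        direction = min(ang, 180.0 - ang)
        pv = float(np.nanmax(speed[s:e + 1])) if e > s else 0.0
        t0 = float(block.t[s])
        out.append(SaccadeEvent(
            start=t0, end=float(block.t[e]),
            amplitude=60.0 * float(np.hypot(dx, dy)),
            direction=float(direction), peak_velocity=pv,
            binocular=True, run_id=block.run_id))
    return out


def detect_saccades(block: SampleBlock, blinks: list[BlinkInterval] | None = None,
                    lam: float = LAMBDA_DEFAULT) -> list[SaccadeEvent]:
    """Full per-run detection: velocities, per-eye candidates, merge rules."""
    if blinks is None:
        blinks = []
    dt = block.dt_ms / 1000.0
    candL = detect_monocular(velocity_trace(block.xL, dt),
                             velocity_trace(block.yL, dt), lam)
    candR = detect_monocular(velocity_trace(block.xR, dt),
                             velocity_trace(block.yR, dt), lam)
    return merge_and_filter(candL, candR, blinks, block)


def saccades_to_frame(saccades: list[SaccadeEvent]):
    """Tidy per-saccade table (one row per retained saccade)."""
    import pandas as pd
    return pd.DataFrame([{
        "run_id": s.run_id, "start_ms": s.start, "end_ms": s.end,
        "timestamp_ms": s.timestamp, "amplitude_arcmin": s.amplitude,
        "direction_deg": s.direction, "peak_velocity_deg_s": s.peak_velocity,
        "binocular": s.binocular} for s in saccades])
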