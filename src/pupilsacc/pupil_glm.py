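"""Deconvolution of event-locked pupil change-rate kernels (FIR GLM).

The pupil change-rate signal is down-sampled to a 30-Hz frame grid
(block means per run).  For each event type, the design matrix holds a
staggered set of impulse columns — column k of a type carries ones at the
frame nearest (event time + k/30 s) for every event of that type — so the
fitted coefficients are the event-locked response estimates at 1/30-s
offsets, with overlapping responses separated under linear superposition.
The system is solved by ridge regression with the penalty chosen by
efficient leave-one-out cross-validation over a small grid.

Nuisance event types (run starts, optionally blinks and saccades) can be
added so their overlapping responses do not bias the press kernel.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.linear_model import RidgeCV

from .io import EventLog

FRAME_RATE = 30.0
PENALTY_GRID = (0.1, 1.0, 10.0)

#: per-event-type estimation windows, s relative to the event
DEFAULT_WINDOWS = {
    "press": (-2.0, 5.5),
    "run_start": (0.0, 5.5),
    "blink": (0.0, 4.0),
    "saccade": (0.0, 2.0),
    "lum_increment": (0.0, 4.0),
    "lum_decrement": (0.0, 4.0),
}


@dataclass
class DeconvolutionSpec:
    """Which event types to model and over which windows."""

    windows: dict[str, tuple[float, float]] = field(
        default_factory=lambda: {"press": DEFAULT_WINDOWS["press"],
                                 "run_start": DEFAULT_WINDOWS["run_start"]})
    frame_rate: float = FRAME_RATE
    penalty_grid: tuple = PENALTY_GRID

    def n_frames_of(self, event_type: str) -> int:
        a, b = self.windows[event_type]
        if not (np.isfinite(a) and np.isfinite(b)) or b < a:
            raise ValueError(f"invalid window for {event_type!r}")
        return int(np.floor((b - a) * self.frame_rate + 1e-9)) + 1

    def offsets_of(self, event_type: str) -> np.ndarray:
        a, _ = self.windows[event_type]
        return a + np.arange(self.n_frames_of(event_type)) / self.frame_rate


@dataclass
class PupilKernel:
    """Deconvolved event-locked change-rate estimates at 1/30-s offsets."""

    event_type: str
    offsets: np.ndarray  # s relative to the event
    value: np.ndarray    # mm/s


@dataclass
class FrameGrid:
    """30-Hz frame times per run (frame centers, session seconds)."""

    times: np.ndarray    # s
    run_ids: np.ndarray  # str per frame

    def __len__(self) -> int:
        return len(self.times)


def frame_grid(run_bounds: dict[str, tuple[int, int]],
               frame_rate: float = FRAME_RATE) -> FrameGrid:
    times, rids = [], []
    for run_id in sorted(run_bounds):
        s_ms, e_ms = run_bounds[run_id]
        n = int(np.floor((e_ms - s_ms + 1) / 1000.0 * frame_rate))
        t = s_ms / 1000.0 + (np.arange(n) + 0.5) / frame_rate
        times.append(t)
        rids.append(np.full(n, run_id, dtype=object))
    if not times:
        raise ValueError("empty frame grid: no runs")
    return FrameGrid(np.concatenate(times), np.concatenate(rids))


def downsample_frames(change_rate: dict[str, np.ndarray],
                      run_bounds: dict[str, tuple[int, int]],
                      frame_rate: float = FRAME_RATE
                      ) -> tuple[np.ndarray, FrameGrid]:
    """Block-mean the 1-kHz change-rate signal onto the 30-Hz frame grid.

    ``change_rate`` maps run_id to the run's 1-kHz mm/s series.  Frames with
    no finite sample are NaN (missing).
    """
    grid = frame_grid(run_bounds, frame_rate)
    out = np.full(len(grid), np.nan)
    pos = 0
    for run_id in sorted(run_bounds):
        v = np.asarray(change_rate[run_id], dtype=float)
        n = int(np.floor(len(v) / 1000.0 * frame_rate))
        edges = np.round(np.arange(n + 1) * 1000.0 / frame_rate).astype(int)
        for k in range(n):
            seg = v[edges[k]:edges[k + 1]]
            seg = seg[np.isfinite(seg)]
            if len(seg):
                out[pos + k] = seg.mean()
        pos += n
    return out, grid


def build_design(events: EventLog, spec: DeconvolutionSpec,
                 grid: FrameGrid) -> tuple[np.ndarray, dict[str, slice]]:
    """Staggered impulse design matrix (frames × Σ kernel lengths).

    Returns the matrix and the column slice of each event type.  Impulses
    whose shifted time falls outside the event's run are dropped.
    """
    if len(grid) == 0:
        raise ValueError("empty frame grid")
    n = len(grid)
    cols: list[np.ndarray] = []
    slices: dict[str, slice] = {}
    # per-run frame index ranges for in-run placement
    run_frames: dict[str, tuple[int, int]] = {}
    for rid in np.unique(grid.run_ids):
        w = np.flatnonzero(grid.run_ids == rid)
        run_frames[str(rid)] = (int(w[0]), int(w[-1]))
    half = 0.5 / spec.frame_rate
    start_col = 0
    for etype in spec.windows:
        K = spec.n_frames_of(etype)
        offs = spec.offsets_of(etype)
        X = np.zeros((n, K))
        sub = events.df[events.df["type"] == etype]
        for _, row in sub.iterrows():
            rid = str(row["run_id"])
            if rid not in run_frames:
                continue
            f0, f1 = run_frames[rid]
            for k in range(K):
                target = row["t_ms"] / 1000.0 + offs[k]
                # nearest frame within the run
                j = f0 + int(np.round((target - grid.times[f0])
                                      * spec.frame_rate))
                if j < f0 or j > f1:
                    continue
                if abs(grid.times[j] - target) <= half + 1e-9:
                    X[j, k] += 1.0
        cols.append(X)
        slices[etype] = slice(start_col, start_col + K)
        start_col += K
    return np.hstack(cols), slices


def fit_deconvolution(design: np.ndarray, response: np.ndarray,
                      spec: DeconvolutionSpec,
                      slices: dict[str, slice] | None = None,
                      penalty_grid=None) -> dict[str, PupilKernel]:
    """Solve the FIR GLM by cross-validated ridge regression.

    Rows with a missing response are dropped.  Returns one kernel per event
    type in the spec.
    """
    y = np.asarray(response, dtype=float)
    keep = np.isfinite(y)
    if not keep.any():
        raise ValueError("all frames missing")
    X = design[keep]
    y = y[keep]
    alphas = list(penalty_grid if penalty_grid is not None
                  else spec.penalty_grid)
    model = RidgeCV(alphas=alphas)
    model.fit(X, y)
    coefs = model.coef_
    if slices is None:
        # single event type occupying all columns
        (etype,) = spec.windows
        slices = {etype: slice(0, design.shape[1])}
    out = {}
    for etype, sl in slices.items():
        out[etype] = PupilKernel(event_type=etype,
                                 offsets=spec.offsets_of(etype),
                                 value=coefs[sl])
    return out


def deconvolve(events: EventLog, change_rate: dict[str, np.ndarray],
               run_bounds: dict[str, tuple[int, int]] | None = None,
               spec: DeconvolutionSpec | None = None
               ) -> dict[str, PupilKernel]:
    """End-to-end deconvolution: frames, design, ridge fit."""
    if run_bounds is None:
        run_bounds = events.run_bounds()
    if spec is None:
        spec = DeconvolutionSpec()
    y, grid = downsample_frames(change_rate, run_bounds, spec.frame_rate)
    X, slices = build_design(events, spec, grid)
    return fit_deconvolution(X, y, spec, slices)


def integrate_kernel(kernel: PupilKernel,
                     frame_rate: float = FRAME_RATE) -> np.ndarray:
    """Riemann-sum integration of a change-rate kernel to a size curve (mm).

    The value at the window start is 0; each step adds value × (1/30 s).
    """
    v = np.asarray(kernel.value, dtype=float)
    return np.concatenate([[0.0], np.cumsum(v[:-1])]) / frame_rate


DILATION_WIN = (-0.6, 0.2)       # s relative to event
CONSTRICTION_WIN = (0.6, 1.6)


def per_event_pupil_metric(change_rate: np.ndarray, t_ms: np.ndarray,
                           event) -> float:
    """Dilation-minus-constriction change-rate difference for one event.

    Mean change rate in [−0.6, +0.2) s minus mean in [+0.6, +1.6) s; more
    positive = stronger dilation-then-reconstriction modulation.  Events
    that are not isolated (neighbor < 2.5 s) are invalid (NaN).
    """
    if not event.isolated:
        return np.nan
    rel = (np.asarray(t_ms, dtype=float) - event.t) / 1000.0
    v = np.asarray(change_rate, dtype=float)
    dil = v[(rel >= DILATION_WIN[0]) & (rel < DILATION_WIN[1])]
    con = v[(rel >= CONSTRICTION_WIN[0]) & (rel < CONSTRICTION_WIN[1])]
    dil, con = dil[np.isfinite(dil)], con[np.isfinite(con)]
    if len(dil) == 0 or len(con) == 0:
        return np.nan
    return float(dil.mean() - con.mean())
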