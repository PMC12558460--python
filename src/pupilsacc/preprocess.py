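"""Pupil preprocessing: blink detection, interpolation, change-rate signal.

Blinks in video-based trackers register as a rapid apparent change in pupil
size as the eyelid closes/opens, with a span of signal absence in between.
Candidates are found per eye as maximal spans of (|pupil change| above a
rate threshold OR pupil absent), bridging short gaps; a candidate is
accepted as a blink only if the two eyes' candidates overlap in time.
Monocular or quiet signal-absence spans become a missing-data mask instead.

The analysis signal is the pupil *change rate*: the first difference of the
mean-of-eyes pupil diameter (mm/s), low-pass filtered with a zero-phase
third-order Butterworth filter at a 25-Hz critical frequency, computed per
run so no sample outside a run influences samples within it.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import butter, filtfilt

from .io import SampleBlock

#: defaults (config-exposed): flag physiologically impossible change rates
CHANGE_THRESHOLD_MM_S = 25.0
MERGE_GAP_MS = 50
INTERP_PAD_MS = 20
INTERP_WIN_MS = 50


@dataclass
class BlinkInterval:
    """Accepted (binocular) blink span, in run-local sample indices/ms."""

    start: int  # ms index of first affected sample
    end: int    # ms index of last affected sample (inclusive)
    binocular: bool = True

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError("blink interval must have start < end")


def _spans_from_mask(mask: np.ndarray) -> list[tuple[int, int]]:
    """Maximal [start, end] (inclusive) spans of True."""
    if not mask.any():
        return []
    idx = np.flatnonzero(mask)
    breaks = np.flatnonzero(np.diff(idx) > 1)
    starts = np.concatenate([[idx[0]], idx[breaks + 1]])
    ends = np.concatenate([idx[breaks], [idx[-1]]])
    return list(zip(starts.tolist(), ends.tolist()))


def _bridge_gaps(spans: list[tuple[int, int]], gap: int) -> list[tuple[int, int]]:
    if not spans:
        return []
    merged = [list(spans[0])]
    for s, e in spans[1:]:
        if s - merged[-1][1] < gap:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return [(s, e) for s, e in merged]


def _eye_candidates(p: np.ndarray, valid: np.ndarray, thr: float,
                    merge_gap: int) -> list[tuple[int, int]]:
    absent = ~valid | ~np.isfinite(p)
    dp = np.abs(np.diff(p)) * 1000.0  # mm/s at 1 kHz
    rapid = np.zeros_like(absent)
    fast = np.flatnonzero(np.nan_to_num(dp) > thr)
    rapid[fast] = True
    rapid[fast + 1] = True
    return _bridge_gaps(_spans_from_mask(absent | rapid), merge_gap)


def _overlaps(a: tuple[int, int], b: tuple[int, int]) -> bool:
    return a[0] <= b[1] and b[0] <= a[1]


def detect_blinks(block: SampleBlock,
                  change_threshold: float = CHANGE_THRESHOLD_MM_S,
                  merge_gap: int = MERGE_GAP_MS
                  ) -> tuple[list[BlinkInterval], np.ndarray]:
    """Detect binocular blinks and label residual missing data.

    Returns accepted blink intervals (run-local sample indices) and a
    boolean missing-data mask over the run's samples covering candidate
    spans that were *not* accepted as blinks.
    """
    if change_threshold <= 0 or merge_gap <= 0:
        raise ValueError("thresholds must be > 0")
    candL = _eye_candidates(block.pL, block.validL, change_threshold, merge_gap)
    candR = _eye_candidates(block.pR, block.validR, change_threshold, merge_gap)

    blinks: list[BlinkInterval] = []
    usedL, usedR = set(), set()
    for i, a in enumerate(candL):
        for j, b in enumerate(candR):
            if _overlaps(a, b):
                s, e = min(a[0], b[0]), max(a[1], b[1])
                if e > s:
                    blinks.append(BlinkInterval(start=s, end=e))
                usedL.add(i)
                usedR.add(j)
    # merge blinks that themselves overlap (several pairings can coalesce)
    blinks.sort(key=lambda b: b.start)
    merged: list[BlinkInterval] = []
    for b in blinks:
        if merged and b.start <= merged[-1].end:
            merged[-1].end = max(merged[-1].end, b.end)
        else:
            merged.append(b)

    missing = np.zeros(block.n, dtype=bool)
    for i, a in enumerate(candL):
        if i not in usedL:
            missing[a[0]:a[1] + 1] = True
    for j, b in enumerate(candR):
        if j not in usedR:
            missing[b[0]:b[1] + 1] = True
    for b in merged:
        missing[b.start:b.end + 1] = False
    return merged, missing


def mean_pupil(block: SampleBlock) -> np.ndarray:
    """Mean-of-eyes pupil diameter (mm); falls back to the valid eye."""
    pL = np.where(block.validL, block.pL, np.nan)
    pR = np.where(block.validR, block.pR, np.nan)
    both = np.stack([pL, pR])
    import warnings as _w
    with _w.catch_warnings():
        _w.simplefilter("ignore", RuntimeWarning)  # all-NaN sample pairs
        return np.nanmean(both, axis=0)


def interpolate_blinks(pupil: np.ndarray, blinks: list[BlinkInterval],
                       pad: int = INTERP_PAD_MS,
                       win: int = INTERP_WIN_MS) -> np.ndarray:
    """Linearly bridge each blink (± pad ms) between flanking medians.

    The line joins the median pupil size of a ``win``-wide window ending
    just before the padded blink to the median of the window starting just
    after it.  A blink abutting the run edge (no full flanking window) is
    left as missing rather than extrapolated.
    """
    out = np.asarray(pupil, dtype=float).copy()
    n = len(out)
    for b in blinks:
        s, e = b.start - pad, b.end + pad
        pre_lo, post_hi = s - win, e + 1 + win
        if pre_lo < 0 or post_hi > n:
            out[max(s, 0):min(e + 1, n)] = np.nan
            continue
        pre = out[pre_lo:s]
        post = out[e + 1:post_hi]
        if np.all(np.isnan(pre)) or np.all(np.isnan(post)):
            out[s:e + 1] = np.nan
            continue
        m0, m1 = np.nanmedian(pre), np.nanmedian(post)
        # anchor the line at the window centers so a linear trend is preserved
        t0 = (pre_lo + s - 1) / 2.0
        t1 = (e + 1 + post_hi - 1) / 2.0
        tt = np.arange(s, e + 1)
        out[s:e + 1] = m0 + (m1 - m0) * (tt - t0) / (t1 - t0)
    return out


def pupil_change_rate(pupil: np.ndarray, fs: float = 1000.0,
                      cutoff_hz: float = 25.0, order: int = 3) -> np.ndarray:
    """First difference scaled to mm/s, zero-phase Butterworth low-passed.

    Residual missing samples are linearly bridged before filtering and
    re-masked (NaN) afterwards, so gaps do not leak filter transients of
    arbitrary magnitude while remaining flagged as missing.
    """
    p = np.asarray(pupil, dtype=float)
    n = len(p)
    padlen = 3 * (order + 1)
    if n <= padlen + 2:
        raise ValueError(f"run of {n} samples is shorter than the filter "
                         "warm-up; cannot compute change rate")
    nan_mask = ~np.isfinite(p)
    if nan_mask.any():
        if nan_mask.all():
            return np.full(n, np.nan)
        idx = np.arange(n)
        p = p.copy()
        p[nan_mask] = np.interp(idx[nan_mask], idx[~nan_mask], p[~nan_mask])
    v = np.empty(n)
    v[1:] = np.diff(p) * fs
    v[0] = v[1]
    b, a = butter(order, cutoff_hz, btype="low", fs=fs)
    v = filtfilt(b, a, v)
    v[nan_mask] = np.nan
    return v


def preprocess_block(block: SampleBlock,
                     change_threshold: float = CHANGE_THRESHOLD_MM_S,
                     merge_gap: int = MERGE_GAP_MS,
                     pad: int = INTERP_PAD_MS, win: int = INTERP_WIN_MS
                     ) -> dict:
    """Run the full pupil preprocessing chain for one run.

    Returns a dict with blink intervals, the missing mask, the interpolated
    mean-of-eyes pupil (mm) and the change-rate signal (mm/s).
    """
    blinks, missing = detect_blinks(block, change_threshold, merge_gap)
    pupil = interpolate_blinks(mean_pupil(block), blinks, pad, win)
    pupil[missing] = np.nan
    rate = pupil_change_rate(pupil)
    return {"blinks": blinks, "missing": missing,
            "pupil": pupil, "change_rate": rate}
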