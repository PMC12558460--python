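"""Temporal lags between the saccade-rate and pupil change-rate patterns.

The pupil modulation around a self-paced movement trails the saccade-rate
modulation; the lags are read off the across-participant average curves as
differences between extremum times (rate minimum → pupil change-rate peak
before the event; rate peak → pupil change-rate minimum after it).  The
pupil light-reflex latency is the delay between a luminance increment and
the moment of most rapid constriction (the minimum of the deconvolved
change-rate kernel), for comparison with the movement-locked lags.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .event_rate import RateCurve
from .pupil_glm import PupilKernel

#: default extremum search windows, s relative to the motor event
RATE_MIN_WIN = (-1.0, 0.2)
PUPIL_PEAK_WIN = (-1.0, 0.5)
RATE_PEAK_WIN = (0.0, 1.2)
PUPIL_MIN_WIN = (0.0, 2.0)
PLR_WIN = (0.0, 1.5)


@dataclass
class LagReport:
    pre_lag: float = np.nan       # ms, rate minimum -> pupil change-rate peak
    post_lag: float = np.nan      # ms, rate peak -> pupil change-rate minimum
    plr_latency: float = np.nan   # ms, light onset -> fastest constriction
    truncated: bool = False       # an extremum sat on a window boundary


def curve_extremum(offsets: np.ndarray, values: np.ndarray,
                   window: tuple[float, float], kind: str) -> float:
    """Offset (s) of the window-restricted extremum; earliest wins ties."""
    offsets = np.asarray(offsets, dtype=float)
    values = np.asarray(values, dtype=float)
    sel = (offsets >= window[0]) & (offsets <= window[1]) & np.isfinite(values)
    if not sel.any():
        raise ValueError("empty extremum window")
    sub_off, sub_val = offsets[sel], values[sel]
    idx = int(np.argmin(sub_val)) if kind == "min" else int(np.argmax(sub_val))
    return float(sub_off[idx])


def _on_boundary(offsets, values, window, at: float) -> bool:
    sel = (np.asarray(offsets) >= window[0]) & (np.asarray(offsets) <= window[1])
    inwin = np.asarray(offsets)[sel]
    return bool(len(inwin)) and (at == inwin[0] or at == inwin[-1])


def modulation_lag(rate_curve: RateCurve, pupil_kernel: PupilKernel
                   ) -> LagReport:
    """Pre- and post-event lags between the two across-participant curves."""
    r_off, r_val = rate_curve.centers, rate_curve.rate
    p_off, p_val = pupil_kernel.offsets, pupil_kernel.value

    rate_min = curve_extremum(r_off, r_val, RATE_MIN_WIN, "min")
    pupil_peak = curve_extremum(p_off, p_val, PUPIL_PEAK_WIN, "max")
    rate_peak = curve_extremum(r_off, r_val, RATE_PEAK_WIN, "max")
    pupil_min = curve_extremum(p_off, p_val, PUPIL_MIN_WIN, "min")

    trunc = any((
        _on_boundary(r_off, r_val, RATE_MIN_WIN, rate_min),
        _on_boundary(p_off, p_val, PUPIL_PEAK_WIN, pupil_peak),
        _on_boundary(r_off, r_val, RATE_PEAK_WIN, rate_peak),
        _on_boundary(p_off, p_val, PUPIL_MIN_WIN, pupil_min)))
    if trunc:
        warnings.warn("extremum on a search-window boundary (possible "
                      "truncation)", stacklevel=2)
    return LagReport(pre_lag=(pupil_peak - rate_min) * 1000.0,
                     post_lag=(pupil_min - rate_peak) * 1000.0,
                     truncated=trunc)


def plr_latency(kernel: PupilKernel,
                window: tuple[float, float] = PLR_WIN) -> float:
    """Latency (ms) from light onset to the fastest constriction.

    The minimum of the luminance-increment change-rate kernel within the
    search window; a kernel with no interior minimum (monotone or flat) is
    an error.
    """
    off = np.asarray(kernel.offsets, dtype=float)
    val = np.asarray(kernel.value, dtype=float)
    sel = (off >= window[0]) & (off <= window[1]) & np.isfinite(val)
    if not sel.any():
        raise ValueError("empty PLR window")
    sub_off, sub_val = off[sel], val[sel]
    if np.allclose(sub_val, sub_val[0]):
        raise ValueError("flat kernel: no constriction minimum")
    i = int(np.argmin(sub_val))
    if i == 0 or i == len(sub_val) - 1:
        raise ValueError("no interior constriction minimum in the window")
    return float(sub_off[i] * 1000.0)
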