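"""Event-locked fixational saccade rate: curves, smoothing, per-event metrics.

Rates are tallied in 25-ms bins spanning [−2.5, +3] s around each motor
event.  Where two consecutive events' peri-event windows overlap, the
overlapping span is excluded from *both* windows (neither count nor
denominator), so no saccade is ever attributed to two events.  Bins that
extend beyond the run are likewise excluded.  The per-bin rate is the summed
count divided by (bin width × number of events contributing to that bin).

Closely spaced raw presses (< 300 ms, e.g. pedal bounce) are first collapsed
into a single motor event at the time of the first press.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io import EventLog

BIN_MS = 25
WIN_PRE_S = 2.5
WIN_POST_S = 3.0
N_BINS = int(round((WIN_PRE_S + WIN_POST_S) * 1000)) // BIN_MS  # 220
MERGE_GAP_MS = 300
ISOLATION_S = 2.5
SUPPRESS_WIN = (-0.8, 0.0)   # s relative to event
REBOUND_WIN = (0.2, 1.2)
SMOOTH_MS = 250


@dataclass
class MotorEvent:
    """One (merged) motor action with neighborhood bookkeeping."""

    t: float                    # ms, session time
    run_id: str
    effector: str = "hand"
    interval_pre: float = np.nan   # s to previous merged event (NaN if first)
    interval_post: float = np.nan  # s to next merged event
    first_or_last_of_run: bool = False

    @property
    def isolated(self) -> bool:
        """True when no neighboring event lies within 2.5 s."""
        pre_ok = np.isnan(self.interval_pre) or self.interval_pre >= ISOLATION_S
        post_ok = np.isnan(self.interval_post) or self.interval_post >= ISOLATION_S
        return bool(pre_ok and post_ok)


@dataclass
class RateCurve:
    """Event-locked rate per 25-ms bin with effective denominators."""

    offsets: np.ndarray        # s, left bin edges spanning [-2.5, 3)
    rate: np.ndarray           # saccades/s; NaN where denom == 0
    denom: np.ndarray          # effective event count per bin
    baseline: float = np.nan   # saccades/s

    @property
    def centers(self) -> np.ndarray:
        return self.offsets + BIN_MS / 2000.0

    def copy(self) -> "RateCurve":
        return RateCurve(self.offsets.copy(), self.rate.copy(),
                         self.denom.copy(), self.baseline)


def bin_offsets() -> np.ndarray:
    return np.round(-WIN_PRE_S + np.arange(N_BINS) * BIN_MS / 1000.0, 6)


def merge_presses(presses: np.ndarray, run_id: str = "",
                  effector: str = "hand",
                  gap: float = MERGE_GAP_MS) -> list[MotorEvent]:
    """Collapse chained presses (< gap ms after the previous raw press).

    Each group becomes one MotorEvent timestamped at its first press;
    inter-event intervals and first/last flags are computed between the
    merged events of the run.
    """
    presses = np.sort(np.asarray(presses, dtype=float))
    merged: list[float] = []
    for t in presses:
        if merged and t - _last_raw < gap:
            _last_raw = t  # extend the chain, keep the group's first time
        else:
            merged.append(t)
            _last_raw = t
    events = []
    for i, t in enumerate(merged):
        pre = (t - merged[i - 1]) / 1000.0 if i > 0 else np.nan
        post = (merged[i + 1] - t) / 1000.0 if i < len(merged) - 1 else np.nan
        events.append(MotorEvent(
            t=t, run_id=run_id, effector=effector,
            interval_pre=pre, interval_post=post,
            first_or_last_of_run=(i == 0 or i == len(merged) - 1)))
    return events


def motor_events_from_log(events: EventLog, effector: str | None = None
                          ) -> list[MotorEvent]:
    """Merged motor events for every run of a session log."""
    out: list[MotorEvent] = []
    for run_id in events.run_bounds():
        presses = events.events_of("press", run_id=run_id, effector=effector)
        if len(presses):
            eff = effector or str(
                events.df[(events.df.run_id == run_id)
                          & (events.df.type == "press")]["effector"].iloc[0])
            out.extend(merge_presses(presses, run_id, eff))
    return out


def _valid_bins(event: MotorEvent, neighbors: np.ndarray,
                run_bounds: tuple[int, int]) -> np.ndarray:
    """Bin validity mask for one event (overlap + run-boundary exclusion).

    ``neighbors`` holds the times of every *other* motor event in the run;
    a bin is invalid when any part of it lies inside another event's
    peri-event window or outside the run.
    """
    lo = event.t + bin_offsets() * 1000.0          # absolute bin starts, ms
    hi = lo + BIN_MS
    valid = (lo >= run_bounds[0]) & (hi <= run_bounds[1] + 1)
    for nb in neighbors:
        nb_lo, nb_hi = nb - WIN_PRE_S * 1000.0, nb + WIN_POST_S * 1000.0
        valid &= (hi <= nb_lo) | (lo >= nb_hi)
    return valid


def event_rate_curve(saccade_ts: np.ndarray, events: list[MotorEvent],
                     run_bounds: dict[str, tuple[int, int]]) -> RateCurve:
    """Aggregate event-locked rate curve over all motor events.

    ``saccade_ts`` are saccade midpoint timestamps in session ms.  Each
    saccade is assigned to exactly one bin of one event; mutual overlap
    exclusion removes contested spans from both neighbors.
    """
    if not events:
        raise ValueError("no motor events; cannot form a rate curve")
    saccade_ts = np.asarray(saccade_ts, dtype=float)
    counts = np.zeros(N_BINS)
    denom = np.zeros(N_BINS)
    by_run: dict[str, list[MotorEvent]] = {}
    for ev in events:
        by_run.setdefault(ev.run_id, []).append(ev)
    for run_id, evs in by_run.items():
        evs = sorted(evs, key=lambda e: e.t)
        rb = run_bounds[run_id]
        times = np.array([e.t for e in evs])
        for i, ev in enumerate(evs):
            others = np.delete(times, i)
            valid = _valid_bins(ev, others, rb)
            denom += valid
            rel = saccade_ts - ev.t
            sel = (rel >= -WIN_PRE_S * 1000.0) & (rel < WIN_POST_S * 1000.0)
            if sel.any():
                idx = ((rel[sel] + WIN_PRE_S * 1000.0) // BIN_MS).astype(int)
                idx = idx[(idx >= 0) & (idx < N_BINS)]
                idx = idx[valid[idx]]
                np.add.at(counts, idx, 1.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        rate = np.where(denom > 0, counts / (BIN_MS / 1000.0 * denom), np.nan)
    curve = RateCurve(bin_offsets(), rate, denom)
    curve.baseline = curve_baseline(curve)
    return curve


def curve_baseline(curve: RateCurve) -> float:
    """Time-weighted mean rate over the window's first 500 ms + last 1000 ms."""
    off = curve.offsets
    first = off < -WIN_PRE_S + 0.5
    last = off >= WIN_POST_S - 1.0
    m_first = np.nanmean(curve.rate[first])
    m_last = np.nanmean(curve.rate[last])
    return float((0.5 * m_first + 1.0 * m_last) / 1.5)


def smooth_curve(curve: RateCurve, width: int = SMOOTH_MS) -> RateCurve:
    """Sliding-boxcar smoothing over ``width`` ms (10 bins: b−5 … b+4).

    Bins with zero denominator are excluded from each local average; at the
    curve edges only the available bins enter.
    """
    if width % BIN_MS != 0:
        raise ValueError("width must be a multiple of the bin size")
    half = width // BIN_MS // 2
    n = len(curve.rate)
    sm = np.full(n, np.nan)
    ok = curve.denom > 0
    for b in range(n):
        lo, hi = max(b - half, 0), min(b + half, n)
        sel = ok[lo:hi]
        if sel.any():
            sm[b] = np.nanmean(curve.rate[lo:hi][sel])
    out = RateCurve(curve.offsets.copy(), sm, curve.denom.copy(),
                    curve.baseline)
    return out


def per_event_rate_metric(saccade_ts: np.ndarray, event: MotorEvent
                          ) -> float:
    """Rebound-minus-suppression rate difference for one isolated event.

    Count in [+0.2, +1.2) s divided by 1.0 s, minus count in [−0.8, 0) s
    divided by 0.8 s.  Non-isolated events are invalid (NaN).
    """
    if not event.isolated:
        return np.nan
    rel = (np.asarray(saccade_ts, dtype=float) - event.t) / 1000.0
    post = np.count_nonzero((rel >= REBOUND_WIN[0]) & (rel < REBOUND_WIN[1]))
    pre = np.count_nonzero((rel >= SUPPRESS_WIN[0]) & (rel < SUPPRESS_WIN[1]))
    w_post = REBOUND_WIN[1] - REBOUND_WIN[0]
    w_pre = SUPPRESS_WIN[1] - SUPPRESS_WIN[0]
    return post / w_post - pre / w_pre


def participant_modulation_index(metrics: np.ndarray) -> float:
    """Mean per-event modulation metric across a participant's valid events."""
    metrics = np.asarray(metrics, dtype=float)
    metrics = metrics[np.isfinite(metrics)]
    if len(metrics) == 0:
        raise ValueError("no valid per-event metrics")
    return float(np.mean(metrics))
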