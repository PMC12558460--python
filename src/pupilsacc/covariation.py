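"""Per-event covariation of saccade-rate and pupil modulation.

Within each participant, every valid motor action contributes one row:
its saccade-rate modulation metric (response), its pupil modulation metric,
the tonic pupil size at the action, and the intervals to the previous and
next action (confounds).  Actions with a neighbor closer than 2.5 s and the
first/last action of each run are excluded.  All five columns are z-scored
per participant and the response is regressed on the four predictors by
ordinary least squares without an intercept (z-scoring forces it to zero),
yielding standardized coefficients.  Group-level inference is a two-tailed
one-sample t-test of each coefficient's across-participant distribution
against zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .event_rate import MotorEvent

PREDICTORS = ("pupil_mod", "tonic_pupil", "interval_pre", "interval_post")
MIN_EVENTS = 10
TONIC_WIDTH_S = 30.0
TONIC_FALLBACK_MS = 1000


def tonic_pupil(pupil: np.ndarray, width_s: float = TONIC_WIDTH_S,
                fs: float = 1000.0) -> np.ndarray:
    """Slow-varying pupil size: centered boxcar mean within the run.

    At each sample, the mean of the ``width_s``-wide window clipped to the
    run and to non-missing data; NaN where the whole window is missing.
    ``pupil`` is one run's (interpolated) mm trace.
    """
    p = np.asarray(pupil, dtype=float)
    n = len(p)
    half = int(round(width_s * fs / 2.0))
    finite = np.isfinite(p)
    vals = np.where(finite, p, 0.0)
    csum = np.concatenate([[0.0], np.cumsum(vals)])
    ccnt = np.concatenate([[0], np.cumsum(finite)])
    i = np.arange(n)
    lo = np.maximum(i - half, 0)
    hi = np.minimum(i + half + 1, n)
    cnt = ccnt[hi] - ccnt[lo]
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(cnt > 0, (csum[hi] - csum[lo]) / cnt, np.nan)
    return out


def tonic_at(tonic: np.ndarray, t0_ms: int, t_ms: float,
             fallback_ms: int = TONIC_FALLBACK_MS) -> float:
    """Tonic value at an event time; nearest non-missing within 1 s fallback."""
    i = int(round(t_ms - t0_ms))
    if 0 <= i < len(tonic) and np.isfinite(tonic[i]):
        return float(tonic[i])
    lo, hi = max(i - fallback_ms, 0), min(i + fallback_ms + 1, len(tonic))
    seg = tonic[lo:hi]
    ok = np.flatnonzero(np.isfinite(seg))
    if len(ok) == 0:
        return np.nan
    j = ok[np.argmin(np.abs(ok + lo - i))]
    return float(seg[j])


def build_event_table(events: list[MotorEvent], rate_metrics: np.ndarray,
                      pupil_metrics: np.ndarray,
                      tonic_values: np.ndarray) -> pd.DataFrame:
    """Per-event table after the exclusion rules.

    Inputs are aligned per event.  Keeps events that are isolated (no
    neighbor within 2.5 s), not the first or last of their run, and have all
    five values finite.  An empty result is allowed (the participant is
    later flagged as excluded).
    """
    rows = []
    for ev, rm, pm, tp in zip(events, rate_metrics, pupil_metrics,
                              tonic_values):
        if not ev.isolated or ev.first_or_last_of_run:
            continue
        row = {"t_ms": ev.t, "run_id": ev.run_id, "rate_mod": rm,
               "pupil_mod": pm, "tonic_pupil": tp,
               "interval_pre": ev.interval_pre,
               "interval_post": ev.interval_post}
        if all(np.isfinite(v) for k, v in row.items()
               if k not in ("run_id",)):
            rows.append(row)
    cols = ["t_ms", "run_id", "rate_mod", "pupil_mod", "tonic_pupil",
            "interval_pre", "interval_post"]
    return pd.DataFrame(rows, columns=cols)


@dataclass
class ParticipantFit:
    coefficients: dict[str, float] = field(default_factory=dict)
    n_events: int = 0
    excluded: bool = False


def zscore(x: np.ndarray) -> np.ndarray:
    """Sample z-score (ddof=1)."""
    x = np.asarray(x, dtype=float)
    sd = np.std(x, ddof=1)
    if sd == 0:
        raise ValueError("zero-variance column cannot be z-scored")
    return (x - np.mean(x)) / sd


def fit_participant_regression(table: pd.DataFrame) -> ParticipantFit:
    """Standardized multiple regression of rate_mod on the four predictors.

    Participants with fewer than 10 valid events are flagged excluded.
    """
    n = len(table)
    if n < MIN_EVENTS:
        return ParticipantFit(n_events=n, excluded=True)
    y = zscore(table["rate_mod"].to_numpy())
    X = np.column_stack([zscore(table[p].to_numpy()) for p in PREDICTORS])
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    return ParticipantFit(
        coefficients=dict(zip(PREDICTORS, beta.tolist())), n_events=n)


@dataclass
class GroupResult:
    per_predictor: dict[str, dict] = field(default_factory=dict)
    n_participants: int = 0


def group_test(fits: list[ParticipantFit]) -> GroupResult:
    """Two-tailed one-sample t-test of each coefficient vs 0 across
    participants, plus the descriptives (median, IQR, proportion > 0)."""
    used = [f for f in fits if not f.excluded]
    if len(used) < 2:
        raise ValueError("need at least 2 included participants")
    res = GroupResult(n_participants=len(used))
    for p in PREDICTORS:
        vals = np.array([f.coefficients[p] for f in used])
        if np.std(vals, ddof=1) == 0:
            t, pval = (0.0, 1.0) if vals.mean() == 0 else (np.inf, 0.0)
        else:
            t, pval = stats.ttest_1samp(vals, 0.0)
        q1, q3 = np.percentile(vals, [25, 75])
        res.per_predictor[p] = {
            "mean": float(vals.mean()), "t": float(t),
            "df": len(vals) - 1, "p": float(pval),
            "median": float(np.median(vals)), "iqr": float(q3 - q1),
            "prop_positive": float(np.mean(vals > 0))}
    return res
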