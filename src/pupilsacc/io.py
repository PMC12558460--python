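"""On-disk session representation: binocular sample blocks and event logs.

A session is stored as two plain-text files:

* a samples TSV with one row per 1-ms sample, columns
  ``run_id, t_ms, xL, yL, pL, validL, xR, yR, pR, validR`` (gaze in degrees
  of visual angle, pupil diameter in mm, validity as 0/1);
* an events CSV with columns ``t_ms, run_id, type, effector`` where type is
  one of ``press, run_start, run_end, lum_increment, lum_decrement`` and
  effector one of ``hand, foot, none``.

Time is integer milliseconds, zero-based within the session, so that a 1-kHz
grid can be represented without floating-point drift.  Missing values are the
literal token ``NA``.  Both files begin with a dialect-version header line.
"""

from __future__ import annotations

import io as _io
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

SAMPLES_DIALECT = "pupilsacc-samples v1"
EVENTS_DIALECT = "pupilsacc-events v1"
NA_TOKEN = "NA"

EVENT_TYPES = ("press", "run_start", "run_end", "lum_increment",
               "lum_decrement", "blink", "saccade")
EFFECTORS = ("hand", "foot", "none")

SAMPLE_COLUMNS = ["run_id", "t_ms", "xL", "yL", "pL", "validL",
                  "xR", "yR", "pR", "validR"]
EVENT_COLUMNS = ["t_ms", "run_id", "type", "effector"]


class SessionFormatError(ValueError):
    """Raised when an on-disk session violates the dialect."""


@dataclass
class SampleBlock:
    """One run's uniformly sampled binocular record.

    ``t`` is an int64 array on a strict 1-ms grid (session time); gaze is in
    degrees, pupil diameter in mm; invalid samples carry NaN gaze/pupil.
    """

    run_id: str
    t: np.ndarray
    xL: np.ndarray
    yL: np.ndarray
    pL: np.ndarray
    validL: np.ndarray
    xR: np.ndarray
    yR: np.ndarray
    pR: np.ndarray
    validR: np.ndarray

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=np.int64)
        for name in ("xL", "yL", "pL", "xR", "yR", "pR"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))
        for name in ("validL", "validR"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=bool))
        n = len(self.t)
        for name in ("xL", "yL", "pL", "validL", "xR", "yR", "pR", "validR"):
            if len(getattr(self, name)) != n:
                raise SessionFormatError(
                    f"column {name} length {len(getattr(self, name))} != {n}")
        if n > 1:
            dt = np.diff(self.t)
            if not np.all(dt == dt[0]) or dt[0] <= 0:
                raise SessionFormatError(
                    f"run {self.run_id}: timestamps not on a uniform "
                    "increasing grid")

    @property
    def n(self) -> int:
        return len(self.t)

    @property
    def dt_ms(self) -> int:
        return int(self.t[1] - self.t[0]) if self.n > 1 else 1

    @property
    def start_ms(self) -> int:
        return int(self.t[0])

    @property
    def end_ms(self) -> int:
        """Exclusive end of the run (last sample time + one step)."""
        return int(self.t[-1]) + self.dt_ms


@dataclass
class EventLog:
    """Typed point events of one session, stored as a tidy DataFrame."""

    df: pd.DataFrame = field(default_factory=lambda: pd.DataFrame(
        columns=EVENT_COLUMNS))

    def __post_init__(self) -> None:
        df = self.df.copy()
        if list(df.columns) != EVENT_COLUMNS:
            raise SessionFormatError(
                f"event columns must be {EVENT_COLUMNS}, got {list(df.columns)}")
        if len(df):
            df["t_ms"] = df["t_ms"].astype(np.int64)
            df["run_id"] = df["run_id"].astype(str)
            bad_type = set(df["type"]) - set(EVENT_TYPES)
            if bad_type:
                raise SessionFormatError(f"unknown event types: {bad_type}")
            bad_eff = set(df["effector"]) - set(EFFECTORS)
            if bad_eff:
                raise SessionFormatError(f"unknown effectors: {bad_eff}")
            df = df.sort_values(["t_ms", "run_id", "type"],
                                kind="stable").reset_index(drop=True)
        self.df = df
        self._validate_runs()

    def _validate_runs(self) -> None:
        bounds = self.run_bounds()
        # run intervals must not overlap
        spans = sorted(bounds.values())
        for (s0, e0), (s1, _) in zip(spans, spans[1:]):
            if s1 < e0:
                raise SessionFormatError("run intervals overlap")
        presses = self.df[self.df["type"] == "press"]
        for _, row in presses.iterrows():
            rb = bounds.get(row["run_id"])
            if rb is None or not (rb[0] <= row["t_ms"] <= rb[1]):
                raise SessionFormatError(
                    f"press at {row['t_ms']} ms outside run "
                    f"{row['run_id']!r} bounds")

    def run_bounds(self) -> dict[str, tuple[int, int]]:
        """Map run_id -> (start_ms, end_ms) from run_start/run_end entries."""
        out: dict[str, tuple[int, int]] = {}
        starts = self.df[self.df["type"] == "run_start"]
        ends = self.df[self.df["type"] == "run_end"]
        for _, row in starts.iterrows():
            e = ends[ends["run_id"] == row["run_id"]]
            if len(e) != 1:
                raise SessionFormatError(
                    f"run {row['run_id']!r} lacks a unique run_end")
            out[row["run_id"]] = (int(row["t_ms"]), int(e["t_ms"].iloc[0]))
        return out

    def events_of(self, type_: str, run_id: str | None = None,
                  effector: str | None = None) -> np.ndarray:
        """Event times (ms) of one type, optionally restricted."""
        sel = self.df["type"] == type_
        if run_id is not None:
            sel &= self.df["run_id"] == run_id
        if effector is not None:
            sel &= self.df["effector"] == effector
        return self.df.loc[sel, "t_ms"].to_numpy(dtype=np.int64)

    def __len__(self) -> int:
        return len(self.df)


def _blocks_to_frame(blocks: list[SampleBlock]) -> pd.DataFrame:
    parts = []
    for b in blocks:
        parts.append(pd.DataFrame({
            "run_id": b.run_id, "t_ms": b.t,
            "xL": b.xL, "yL": b.yL, "pL": b.pL,
            "validL": b.validL.astype(int),
            "xR": b.xR, "yR": b.yR, "pR": b.pR,
            "validR": b.validR.astype(int),
        }))
    if not parts:
        return pd.DataFrame(columns=SAMPLE_COLUMNS)
    return pd.concat(parts, ignore_index=True)[SAMPLE_COLUMNS]


def write_session(blocks: list[SampleBlock], events: EventLog,
                  samples_path: str | Path, events_path: str | Path) -> None:
    """Write a session in the canonical dialect (deterministic bytes)."""
    sdf = _blocks_to_frame(blocks)
    buf = _io.StringIO()
    buf.write(f"# {SAMPLES_DIALECT}\n")
    sdf.to_csv(buf, sep="\t", index=False, na_rep=NA_TOKEN,
               lineterminator="\n")
    Path(samples_path).write_text(buf.getvalue())

    buf = _io.StringIO()
    buf.write(f"# {EVENTS_DIALECT}\n")
    events.df.to_csv(buf, index=False, na_rep=NA_TOKEN, lineterminator="\n")
    Path(events_path).write_text(buf.getvalue())


def _check_header(path: Path, expected: str) -> None:
    with open(path) as fh:
        first = fh.readline().strip()
    if first != f"# {expected}":
        raise SessionFormatError(
            f"{path}: expected header '# {expected}', got {first!r}")


def read_session(samples_path: str | Path,
                 events_path: str | Path) -> tuple[list[SampleBlock], EventLog]:
    """Read a session written by :func:`write_session`."""
    samples_path, events_path = Path(samples_path), Path(events_path)
    _check_header(samples_path, SAMPLES_DIALECT)
    _check_header(events_path, EVENTS_DIALECT)

    sdf = pd.read_csv(samples_path, sep="\t", comment="#",
                      na_values=[NA_TOKEN], keep_default_na=False,
                      dtype={"run_id": str}, float_precision="round_trip")
    if list(sdf.columns) != SAMPLE_COLUMNS:
        raise SessionFormatError(
            f"{samples_path}: malformed header columns {list(sdf.columns)}")
    blocks = []
    if len(sdf):
        for run_id, g in sdf.groupby("run_id", sort=False):
            blocks.append(SampleBlock(
                run_id=str(run_id), t=g["t_ms"].to_numpy(),
                xL=g["xL"].to_numpy(), yL=g["yL"].to_numpy(),
                pL=g["pL"].to_numpy(), validL=g["validL"].to_numpy() > 0,
                xR=g["xR"].to_numpy(), yR=g["yR"].to_numpy(),
                pR=g["pR"].to_numpy(), validR=g["validR"].to_numpy() > 0))

    edf = pd.read_csv(events_path, comment="#", na_values=[NA_TOKEN],
                      keep_default_na=False, dtype={"run_id": str})
    if len(edf) == 0:
        edf = pd.DataFrame(columns=EVENT_COLUMNS)
    if list(edf.columns) != EVENT_COLUMNS:
        raise SessionFormatError(
            f"{events_path}: malformed header columns {list(edf.columns)}")
    return blocks, EventLog(edf)
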