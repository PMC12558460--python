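"""End-to-end orchestration: simulate → preprocess → detect → analyze.

``analyze_session`` runs the per-participant chain on one session;
``run_pipeline`` simulates a cohort, analyzes every participant, and runs
the group-level statistics (cluster Monte Carlo, covariation regression,
extremum lags), writing a results bundle of CSV/JSON artifacts stamped with
the configuration hash and seed.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import cluster_stats, covariation, event_rate, latency, preprocess
from . import pupil_glm, saccades as sacc_mod, simulate
from .io import EventLog, EVENT_COLUMNS, SampleBlock, write_session


@dataclass
class PipelineConfig:
    """Schema-validated configuration of a full pipeline run."""

    out_dir: str = "results"
    seed: int = 0
    n_participants: int = 12
    nuisance: str = "runstart"       # or "runstart+oculomotor" (S-variant)
    lam: float = sacc_mod.LAMBDA_DEFAULT
    n_iterations: int = cluster_stats.N_ITER
    write_sessions: bool = False
    stages: tuple = ("simulate", "preprocess", "saccades", "rate",
                     "pupil", "stats", "covary", "latency")
    simulation: simulate.SimulationConfig = field(
        default_factory=simulate.SimulationConfig)

    def __post_init__(self) -> None:
        if self.nuisance not in ("runstart", "runstart+oculomotor"):
            raise ValueError(f"unknown nuisance model {self.nuisance!r}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        own = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - own
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        sim_raw = raw.pop("simulation", {})
        if sim_raw is not None and not isinstance(sim_raw, dict):
            raise ValueError("'simulation' must be a mapping")
        sim_fields = {f.name for f in
                      dataclasses.fields(simulate.SimulationConfig)}
        unknown = set(sim_raw or {}) - sim_fields
        if unknown:
            raise ValueError(f"unknown simulation keys: {sorted(unknown)}")
        sim = simulate.SimulationConfig(**(sim_raw or {}))
        return cls(simulation=sim, **raw)

    def content_hash(self) -> str:
        d = dataclasses.asdict(self)
        blob = json.dumps(d, sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def participant_seeds(seed: int, n: int) -> np.ndarray:
    """Derived per-participant integer seeds (deterministic, < 2^31)."""
    return np.random.SeedSequence(seed).generate_state(n) % (2 ** 31)


def analyze_session(blocks: list[SampleBlock], events: EventLog,
                    lam: float = sacc_mod.LAMBDA_DEFAULT,
                    nuisance: str = "runstart",
                    saccade_times_ms: np.ndarray | None = None,
                    run_glm: bool = True) -> dict:
    """Per-participant analysis chain for one session.

    Runs pupil preprocessing, saccade detection (or uses supplied saccade
    midpoint timestamps, e.g. ground truth), the event-locked rate curve,
    the pupil deconvolution, and the per-event metric table.
    """
    run_bounds = events.run_bounds()
    pre: dict[str, dict] = {}
    detected: list[sacc_mod.SaccadeEvent] = []
    blink_rows, sacc_rows = [], []
    for b in blocks:
        res = preprocess.preprocess_block(b)
        pre[b.run_id] = res
        if saccade_times_ms is None:
            detected.extend(sacc_mod.detect_saccades(b, res["blinks"], lam))
        for bl in res["blinks"]:
            blink_rows.append((int(b.t[bl.start]), b.run_id, "blink", "none"))

    if saccade_times_ms is None:
        sacc_ts = np.array([s.timestamp for s in detected])
    else:
        sacc_ts = np.asarray(saccade_times_ms, dtype=float)
    for ts in sacc_ts:
        rid = _run_of(ts, run_bounds)
        if rid is not None:
            sacc_rows.append((int(round(ts)), rid, "saccade", "none"))

    events_motor = event_rate.motor_events_from_log(events)
    curve = smoothed = None
    if events_motor:
        curve = event_rate.event_rate_curve(sacc_ts, events_motor, run_bounds)
        smoothed = event_rate.smooth_curve(curve)

    # deconvolution (press + nuisance model); PLR regressors when present
    kernels: dict = {}
    windows = {}
    if events_motor:
        windows["press"] = pupil_glm.DEFAULT_WINDOWS["press"]
    windows["run_start"] = pupil_glm.DEFAULT_WINDOWS["run_start"]
    if len(events.events_of("lum_increment")):
        windows["lum_increment"] = pupil_glm.DEFAULT_WINDOWS["lum_increment"]
        windows["lum_decrement"] = pupil_glm.DEFAULT_WINDOWS["lum_decrement"]
    glm_events = events.df
    if nuisance == "runstart+oculomotor":
        extra = pd.DataFrame(blink_rows + sacc_rows, columns=EVENT_COLUMNS)
        glm_events = pd.concat([events.df, extra], ignore_index=True)
        windows["blink"] = pupil_glm.DEFAULT_WINDOWS["blink"]
        windows["saccade"] = pupil_glm.DEFAULT_WINDOWS["saccade"]
    if run_glm:
        spec = pupil_glm.DeconvolutionSpec(windows=windows)
        change_rate = {rid: pre[rid]["change_rate"] for rid in pre}
        kernels = pupil_glm.deconvolve(EventLog(glm_events), change_rate,
                                       run_bounds, spec)

    # per-event metrics + tonic pupil
    rate_metrics, pupil_metrics, tonic_vals = [], [], []
    tonic = {rid: covariation.tonic_pupil(pre[rid]["pupil"]) for rid in pre}
    for ev in events_motor:
        rate_metrics.append(event_rate.per_event_rate_metric(sacc_ts, ev))
        rid = ev.run_id
        t0 = run_bounds[rid][0]
        blk_t = np.arange(len(pre[rid]["change_rate"])) + t0
        pupil_metrics.append(pupil_glm.per_event_pupil_metric(
            pre[rid]["change_rate"], blk_t, ev))
        tonic_vals.append(covariation.tonic_at(tonic[rid], t0, ev.t))
    table = covariation.build_event_table(
        events_motor, np.array(rate_metrics), np.array(pupil_metrics),
        np.array(tonic_vals))

    return {"preprocessed": pre, "saccades": detected,
            "saccade_timestamps": sacc_ts, "motor_events": events_motor,
            "rate_curve": curve, "smoothed_curve": smoothed,
            "kernels": kernels, "event_table": table,
            "rate_metrics": np.array(rate_metrics),
            "pupil_metrics": np.array(pupil_metrics)}


def _run_of(t_ms: float, run_bounds: dict) -> str | None:
    for rid, (s, e) in run_bounds.items():
        if s <= t_ms <= e:
            return rid
    return None


def run_pipeline(config: PipelineConfig) -> dict:
    """Simulate a cohort, analyze each participant, run group statistics.

    Returns the results dict and writes the artifact bundle to
    ``config.out_dir``.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = participant_seeds(config.seed, config.n_participants)
    stages = set(config.stages)
    need_glm = bool(stages & {"pupil", "stats", "latency"})

    per_part = []
    for i, s in enumerate(seeds):
        sim = dataclasses.replace(config.simulation, seed=int(s))
        blocks, events, gt = simulate.render_session(sim)
        if config.write_sessions:
            pdir = out / f"participant{i + 1:02d}"
            pdir.mkdir(exist_ok=True)
            write_session(blocks, events, pdir / "samples.tsv",
                          pdir / "events.csv")
            gt.to_json(pdir / "ground_truth.json")
        per_part.append(analyze_session(blocks, events, lam=config.lam,
                                        nuisance=config.nuisance,
                                        run_glm=need_glm))

    results: dict = {"config_hash": config.content_hash(),
                     "seed": config.seed,
                     "n_participants": config.n_participants}

    offs = event_rate.bin_offsets()
    curves = np.vstack([p["smoothed_curve"].rate for p in per_part])
    baselines = np.array([p["rate_curve"].baseline for p in per_part])
    koffs = kvals = None
    if need_glm:
        koffs = per_part[0]["kernels"]["press"].offsets
        kvals = np.vstack([p["kernels"]["press"].value for p in per_part])

    if "stats" in stages:
        # rate curves against per-participant baselines
        rate_mc = cluster_stats.monte_carlo_p(
            curves, baselines, offs + event_rate.BIN_MS / 2000.0,
            n_iter=config.n_iterations, seed=config.seed)
        results["rate_clusters"] = _clusters_dict(rate_mc)
        # change-rate kernels against 0 mm/s
        pupil_mc = cluster_stats.monte_carlo_p(
            kvals, np.zeros(len(per_part)), koffs,
            n_iter=config.n_iterations, seed=config.seed + 1)
        results["pupil_clusters"] = _clusters_dict(pupil_mc)

    if "covary" in stages:
        fits = [covariation.fit_participant_regression(p["event_table"])
                for p in per_part]
        group = covariation.group_test(fits)
        results["covariation"] = {"n_participants": group.n_participants,
                                  "per_predictor": group.per_predictor}

    if "latency" in stages:
        # lags on across-participant mean curves
        mean_curve = event_rate.RateCurve(
            offs, np.nanmean(curves, axis=0),
            np.sum([p["smoothed_curve"].denom for p in per_part], axis=0),
            float(np.mean(baselines)))
        mean_kernel = pupil_glm.PupilKernel("press", koffs,
                                            np.nanmean(kvals, axis=0))
        lag = latency.modulation_lag(mean_curve, mean_kernel)
        results["lags"] = {"pre_lag_ms": lag.pre_lag,
                           "post_lag_ms": lag.post_lag,
                           "truncated": lag.truncated}
        if config.simulation.n_plr_runs > 0:
            plr_vals = np.vstack([p["kernels"]["lum_increment"].value
                                  for p in per_part])
            plr_kernel = pupil_glm.PupilKernel(
                "lum_increment",
                per_part[0]["kernels"]["lum_increment"].offsets,
                np.nanmean(plr_vals, axis=0))
            results["lags"]["plr_latency_ms"] = latency.plr_latency(
                plr_kernel)

    _write_bundle(out, config, per_part, results, offs, koffs)
    return results


def _clusters_dict(mc) -> dict:
    return {"n_iterations": mc.n_iterations,
            "clusters": [{"start_s": c.start, "end_s": c.end,
                          "sign": c.sign, "mass": c.mass, "mc_p": c.mc_p}
                         for c in mc.clusters]}


def _write_bundle(out: Path, config: PipelineConfig, per_part, results,
                  offs, koffs) -> None:
    stamp = {"config_hash": results["config_hash"], "seed": config.seed}
    curves = pd.DataFrame(
        np.vstack([p["smoothed_curve"].rate for p in per_part]),
        columns=[f"{o:+.3f}" for o in offs])
    curves.insert(0, "participant", np.arange(1, len(per_part) + 1))
    curves.to_csv(out / "rate_curves.csv", index=False)
    if koffs is not None and per_part[0]["kernels"]:
        kern = pd.DataFrame(
            np.vstack([p["kernels"]["press"].value for p in per_part]),
            columns=[f"{o:+.4f}" for o in koffs])
        kern.insert(0, "participant", np.arange(1, len(per_part) + 1))
        kern.to_csv(out / "press_kernels.csv", index=False)
    tables = []
    for i, p in enumerate(per_part):
        t = p["event_table"].copy()
        t.insert(0, "participant", i + 1)
        tables.append(t)
    pd.concat(tables, ignore_index=True).to_csv(
        out / "event_tables.csv", index=False)
    (out / "results.json").write_text(
        json.dumps({**stamp, **{k: v for k, v in results.items()
                                if k not in ("config_hash", "seed")}},
                   indent=1, default=float))
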