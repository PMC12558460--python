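"""Ground-truth generator: interval law, Poisson structure, superposition."""

import dataclasses
import math

import numpy as np
import pytest
from scipy import stats

import pupilsacc as ps
from pupilsacc import simulate
from conftest import truth_timestamps_ms


class TestSampleIntervals:
    def test_mean_matches_closed_form(self):
        # E[X | 3 <= X <= 8], X ~ Exp(scale 4.6): lo + s - w q/(1-q)
        w, s = 5.0, 4.6
        q = math.exp(-w / s)
        expected = 3.0 + s - w * q / (1.0 - q)
        x = ps.sample_intervals(4.6, 3.0, 8.0, 10 ** 6, seed=0)
        assert abs(expected - 5.057) < 2e-3
        assert abs(x.mean() - expected) < 0.02

    def test_degenerate_range(self):
        x = ps.sample_intervals(4.6, 3.0, 3.0 + 1e-9, 100, seed=0)
        assert np.allclose(x, 3.0, atol=1e-8)

    def test_ks_distance_to_truncated_cdf(self):
        x = ps.sample_intervals(4.6, 3.0, 8.0, 10 ** 5, seed=1)
        mass = 1.0 - math.exp(-5.0 / 4.6)

        def cdf(v):
            return (1.0 - np.exp(-(v - 3.0) / 4.6)) / mass

        d, _ = stats.kstest(x, cdf)
        assert d < 0.01

    def test_support_respected(self):
        x = ps.sample_intervals(4.6, 3.0, 8.0, 10 ** 4, seed=2)
        assert x.min() >= 3.0 and x.max() <= 8.0

    def test_invalid_range_raises(self):
        with pytest.raises(ValueError, match="range"):
            ps.sample_intervals(4.6, 8.0, 3.0, 10, seed=0)


class TestSaccadeProcess:
    def test_zero_modulation_yields_no_saccades(self):
        zero = lambda tau, a=1.0: np.zeros_like(np.asarray(tau, float))
        out = ps.simulate_saccade_times(zero, [10.0], 45.0, 0.89, seed=0)
        assert len(out) == 0

    def test_constant_intensity_count(self):
        flat = lambda tau, a=1.0: np.ones_like(np.asarray(tau, float))
        out = ps.simulate_saccade_times(flat, [], 1000.0, 0.89, seed=3)
        assert abs(len(out) - 890) < 3 * math.sqrt(890)

    def test_time_rescaling_gives_unit_exponential(self):
        # time-rescaling theorem: integrated intensity between consecutive
        # points of an inhomogeneous Poisson process is Exp(1)
        prof = simulate.ramp_boxcar_profile(0.5, 0.4)
        events = np.arange(5.0, 195.0, 6.0)
        out = ps.simulate_saccade_times(prof, events, 200.0, 2.0, seed=4)
        grid = np.arange(0.0, 200.0, 5e-4)
        lam = simulate.modulated_intensity(grid, prof, events, 2.0)
        cum = np.concatenate([[0.0], np.cumsum(lam) * 5e-4])
        rescaled = np.interp(out, np.arange(len(cum)) * 5e-4, cum)
        d, p = stats.kstest(np.diff(rescaled), "expon")
        assert p > 0.01

    def test_negative_baseline_raises(self):
        flat = lambda tau, a=1.0: np.ones_like(np.asarray(tau, float))
        with pytest.raises(ValueError, match="negative intensity"):
            ps.simulate_saccade_times(flat, [], 10.0, -1.0, seed=0)


class TestRenderSession:
    def test_zero_runs_empty_outputs(self):
        cfg = ps.SimulationConfig(n_runs=0, seed=0)
        blocks, events, gt = ps.render_session(cfg)
        assert blocks == [] and len(events) == 0
        assert gt.saccade_times == {} and gt.event_times == {}

    def test_determinism_bit_identical(self):
        cfg = ps.SimulationConfig(n_runs=2, seed=99, blink_rate=5.0)
        b1, e1, g1 = ps.render_session(cfg)
        b2, e2, g2 = ps.render_session(cfg)
        for x, y in zip(b1, b2):
            np.testing.assert_array_equal(x.xL, y.xL)
            np.testing.assert_array_equal(x.pR, y.pR)
        assert e1.df.equals(e2.df)
        assert g1.saccade_times == g2.saccade_times

    def test_event_count_per_run_band(self):
        cfg = ps.SimulationConfig(n_runs=20, seed=5)
        _, _, gt = ps.render_session(cfg)
        counts = [len(v) for v in gt.event_times.values()]
        # mean interval ~5.06 s over 45 s -> roughly 8-9 events per run
        assert 7.5 <= np.mean(counts) <= 9.5

    def test_saccades_inside_runs_and_amplitudes_coupled(self):
        cfg = ps.SimulationConfig(n_runs=2, seed=6)
        blocks, events, gt = ps.render_session(cfg)
        bounds = events.run_bounds()
        for rid, times in gt.saccade_times.items():
            s, e = bounds[rid]
            assert all(s / 1000.0 <= t <= e / 1000.0 for t in times)
        for rid in gt.event_times:
            assert len(gt.per_event_amplitude[rid]) == len(gt.event_times[rid])

    def test_zero_integral_kernel_returns_to_baseline(self):
        kspec = ps.PupilKernelSpec(dilation_amp=0.1, dilation_width=0.3,
                                   constriction_amp=-0.1,
                                   constriction_width=0.3)
        sig = simulate._superpose_pupil(
            20000, 1000.0, np.array([5.0]), np.array([1.0]), kspec)
        assert abs(sig[-1]) < 1e-3  # net integral ~0 -> back to baseline

    def test_superposition_linearity(self):
        kspec = ps.PupilKernelSpec()
        both = simulate._superpose_pupil(
            30000, 1000.0, np.array([5.0, 20.0]), np.array([1.0, 2.0]), kspec)
        one = simulate._superpose_pupil(
            30000, 1000.0, np.array([5.0]), np.array([1.0]), kspec)
        two = simulate._superpose_pupil(
            30000, 1000.0, np.array([20.0]), np.array([2.0]), kspec)
        np.testing.assert_allclose(both, one + two, atol=1e-12)

    def test_render_superposition_of_rendered_traces(self):
        # pupil trace of a k-event run equals the sum of the per-event
        # contributions plus one baseline, exactly, at zero noise
        cfg = ps.SimulationConfig(n_runs=1, seed=8, noise_sd_pupil=0.0,
                                  noise_sd_gaze=0.0,
                                  baseline_saccade_rate=0.0)
        blocks, events, gt = ps.render_session(cfg)
        ev = np.array(gt.event_times["run01"])
        amps = np.array(gt.per_event_amplitude["run01"])
        parts = [simulate._superpose_pupil(blocks[0].n, 1000.0,
                                           np.array([e]), np.array([a]),
                                           cfg.pupil_kernel_spec)
                 for e, a in zip(ev, amps)]
        np.testing.assert_allclose(
            blocks[0].pL, cfg.pupil_baseline + np.sum(parts, axis=0),
            atol=1e-10)


class TestInjectBlinks:
    def test_zero_rate_is_identity(self, clean_session):
        blocks, _, _ = clean_session
        out, iv = ps.inject_blinks(blocks, 0.0, seed=0)
        assert out is blocks
        assert all(len(v) == 0 for v in iv.values())

    def test_blinks_recovered_by_detector(self):
        cfg = ps.SimulationConfig(n_runs=3, seed=10, blink_rate=10.0)
        blocks, _, gt = ps.render_session(cfg)
        n_eval = 0
        for b in blocks:
            truth = gt.blink_intervals[b.run_id]
            found, _ = ps.detect_blinks(b)
            for ts, te in truth:
                s, e = ts * 1000 - b.t[0], te * 1000 - b.t[0]
                best = 0.0
                for f in found:
                    inter = min(e, f.end) - max(s, f.start)
                    union = max(e, f.end) - min(s, f.start)
                    best = max(best, inter / union)
                assert best >= 0.9
                n_eval += 1
        assert n_eval >= 3

    def test_blinks_inside_run_bounds(self):
        cfg = ps.SimulationConfig(n_runs=4, seed=11, blink_rate=20.0)
        blocks, events, gt = ps.render_session(cfg)
        bounds = events.run_bounds()
        for rid, ivs in gt.blink_intervals.items():
            s, e = bounds[rid]
            for ts, te in ivs:
                assert s / 1000.0 < ts < te < e / 1000.0
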