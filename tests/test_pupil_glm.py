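"""FIR-GLM deconvolution: frames, design, ridge fit, metrics."""

import numpy as np
import pandas as pd
import pytest

import pupilsacc as ps
from pupilsacc.event_rate import MotorEvent
from pupilsacc.io import EVENT_COLUMNS, EventLog
from pupilsacc.pupil_glm import (DeconvolutionSpec, build_design,
                                 downsample_frames, fit_deconvolution,
                                 frame_grid, integrate_kernel,
                                 per_event_pupil_metric, PupilKernel)


def _log(rows):
    return EventLog(pd.DataFrame(rows, columns=EVENT_COLUMNS))


RB = {"r1": (0, 9_999)}
LOG = _log([(0, "r1", "run_start", "none"),
            (9_999, "r1", "run_end", "none")])


class TestDownsample:
    def test_constant_preserved(self):
        y, grid = downsample_frames({"r1": np.full(10_000, 0.3)}, RB)
        np.testing.assert_allclose(y, 0.3)

    def test_one_second_run_gives_30_frames(self):
        rb = {"r1": (0, 999)}
        y, grid = downsample_frames({"r1": np.zeros(1000)}, rb)
        assert len(y) == 30 and len(grid) == 30

    def test_matches_blockwise_mean_oracle(self, rng):
        v = rng.normal(size=3000)
        y, _ = downsample_frames({"r1": v}, {"r1": (0, 2999)})
        edges = np.round(np.arange(91) * 1000.0 / 30.0).astype(int)
        exp = [v[edges[k]:edges[k + 1]].mean() for k in range(90)]
        np.testing.assert_allclose(y, exp)

    def test_all_missing_frame_is_nan(self):
        v = np.zeros(2000)
        v[:40] = np.nan
        y, _ = downsample_frames({"r1": v}, {"r1": (0, 1999)})
        assert np.isnan(y[0]) and np.isfinite(y[2:]).all()


class TestBuildDesign:
    def test_no_events_all_zero(self):
        spec = DeconvolutionSpec(windows={"press": (-2.0, 5.5)})
        grid = frame_grid(RB)
        X, sl = build_design(LOG, spec, grid)
        assert X.shape == (len(grid), spec.n_frames_of("press"))
        assert not X.any()

    def test_staggered_ones_at_consecutive_frames(self):
        spec = DeconvolutionSpec(windows={"press": (0.0, 2.0 / 30.0)})
        grid = frame_grid(RB)
        t_ms = int(grid.times[100] * 1000)  # event exactly at frame 100
        log = _log([(0, "r1", "run_start", "none"),
                    (t_ms, "r1", "press", "hand"),
                    (9_999, "r1", "run_end", "none")])
        X, _ = build_design(log, spec, grid)
        assert X[100, 0] == 1 and X[101, 1] == 1 and X[102, 2] == 1
        assert X.sum() == 3

    def test_column_sums_count_inbounds_events(self):
        spec = DeconvolutionSpec(windows={"press": (-2.0, 5.5)})
        grid = frame_grid(RB)
        rows = [(0, "r1", "run_start", "none"), (9_999, "r1", "run_end", "none")]
        times = [1000, 5000, 9000]
        rows += [(t, "r1", "press", "hand") for t in times]
        X, _ = build_design(_log(rows), spec, grid)
        offs = spec.offsets_of("press")
        for k in (0, 60, len(offs) - 1):
            expect = sum(1 for t in times
                         if 0 <= t / 1000.0 + offs[k] <= 9.999 + 1 / 60)
            assert X[:, k].sum() == pytest.approx(expect, abs=1)

    def test_empty_grid_raises(self):
        with pytest.raises(ValueError):
            frame_grid({})


class TestFitDeconvolution:
    def test_zero_response_zero_kernels(self):
        spec = DeconvolutionSpec(windows={"press": (-1.0, 1.0)})
        grid = frame_grid(RB)
        log = _log([(0, "r1", "run_start", "none"),
                    (5000, "r1", "press", "hand"),
                    (9_999, "r1", "run_end", "none")])
        X, sl = build_design(log, spec, grid)
        k = fit_deconvolution(X, np.zeros(len(grid)), spec, sl)["press"]
        np.testing.assert_allclose(k.value, 0.0, atol=1e-12)

    def test_all_missing_raises(self):
        spec = DeconvolutionSpec(windows={"press": (-1.0, 1.0)})
        grid = frame_grid(RB)
        X, sl = build_design(LOG, spec, grid)
        with pytest.raises(ValueError, match="missing"):
            fit_deconvolution(X, np.full(len(grid), np.nan), spec, sl)

    def test_nuisance_type_with_no_events_is_inert(self):
        rng = np.random.default_rng(3)
        spec1 = DeconvolutionSpec(windows={"press": (-1.0, 2.0)})
        spec2 = DeconvolutionSpec(windows={"press": (-1.0, 2.0),
                                           "blink": (0.0, 2.0)})
        rb = {"r1": (0, 59_999)}
        rows = [(0, "r1", "run_start", "none"), (59_999, "r1", "run_end", "none")]
        rows += [(t, "r1", "press", "hand")
                 for t in range(3000, 57_000, 6000)]
        log = _log(rows)
        grid = frame_grid(rb)
        y = rng.normal(0, 0.1, len(grid))
        X1, sl1 = build_design(log, spec1, grid)
        X2, sl2 = build_design(log, spec2, grid)
        k1 = fit_deconvolution(X1, y, spec1, sl1)["press"]
        k2 = fit_deconvolution(X2, y, spec2, sl2)["press"]
        np.testing.assert_allclose(k1.value, k2.value, atol=1e-9)

    def test_run_start_transient_absorbed_by_nuisance(self):
        # forward-simulate press + run-onset responses; the press kernel
        # must come back unbiased when run_start is modeled
        spec = DeconvolutionSpec(windows={"press": (-2.0, 5.5),
                                          "run_start": (0.0, 5.5)})
        rb = {f"r{i}": (i * 50_000, i * 50_000 + 44_999) for i in range(4)}
        rows = []
        press_t = []
        for i in range(4):
            s, e = rb[f"r{i}"]
            rows += [(s, f"r{i}", "run_start", "none"),
                     (e, f"r{i}", "run_end", "none")]
            for t in range(s + 4000, e - 6000, 7000):
                rows.append((t, f"r{i}", "press", "hand"))
                press_t.append(t)
        log = _log(rows)
        grid = frame_grid(rb)
        X, sl = build_design(log, spec, grid)
        offs = spec.offsets_of("press")
        k_press = ps.PupilKernelSpec().evaluate(offs)
        k_onset = 0.3 * np.exp(-spec.offsets_of("run_start") / 1.5)
        beta = np.concatenate([k_press, k_onset])
        y = X @ beta
        fit = fit_deconvolution(X, y, spec, sl, penalty_grid=(1e-8,))
        err = np.abs(fit["press"].value - k_press).max()
        assert err < 0.05 * np.abs(k_press).max()


class TestIntegrateKernel:
    def test_zero_kernel_zero_curve(self):
        k = PupilKernel("press", np.arange(5) / 30.0, np.zeros(5))
        np.testing.assert_allclose(integrate_kernel(k), 0.0)

    def test_constant_rate_integrates_to_product(self):
        n = 61  # 2 s at 30 Hz
        k = PupilKernel("press", np.arange(n) / 30.0, np.full(n, 0.3))
        curve = integrate_kernel(k)
        assert curve[0] == 0.0
        assert curve[-1] == pytest.approx(0.3 * 2.0)

    def test_round_trips_known_size_curve(self):
        offs = np.arange(0, 91) / 30.0
        size = 0.2 * np.sin(offs)  # known pupil-size curve
        rate = np.gradient(size, 1.0 / 30.0)
        k = PupilKernel("press", offs, rate)
        rec = integrate_kernel(k)
        np.testing.assert_allclose(rec, size - size[0], atol=0.02)


class TestPerEventPupilMetric:
    EVENT = MotorEvent(t=10_000.0, run_id="r", interval_pre=5.0,
                       interval_post=5.0)

    def test_zero_signal(self):
        t = np.arange(20_000)
        assert per_event_pupil_metric(np.zeros(20_000), t, self.EVENT) == 0.0

    def test_window_difference(self):
        t = np.arange(20_000)
        v = np.zeros(20_000)
        v[9_400:10_200] = 0.1     # dilation window [-0.6, +0.2)
        v[10_600:11_600] = -0.1   # constriction window [+0.6, +1.6)
        m = per_event_pupil_metric(v, t, self.EVENT)
        assert m == pytest.approx(0.2)

    def test_matches_windowed_mean_oracle(self, rng):
        t = np.arange(20_000)
        v = rng.normal(size=20_000)
        m = per_event_pupil_metric(v, t, self.EVENT)
        exp = v[9_400:10_200].mean() - v[10_600:11_600].mean()
        assert m == pytest.approx(exp)

    def test_non_isolated_invalid(self):
        ev = MotorEvent(t=10_000.0, run_id="r", interval_pre=1.0,
                        interval_post=5.0)
        t = np.arange(20_000)
        assert np.isnan(per_event_pupil_metric(np.zeros(20_000), t, ev))


def test_s2_variant_keeps_sign_structure():
    """Adding blink+saccade nuisance regressors preserves the
    dilation-then-constriction shape of the press kernel."""
    cfg = ps.SimulationConfig(n_runs=4, seed=21, blink_rate=6.0)
    blocks, events, gt = ps.render_session(cfg)
    res = ps.analyze_session(blocks, events, nuisance="runstart+oculomotor")
    k = res["kernels"]["press"]
    early = (k.offsets >= -0.6) & (k.offsets < 0.2)
    late = (k.offsets >= 0.6) & (k.offsets < 1.6)
    assert k.value[early].mean() > 0
    assert k.value[late].mean() < 0
    assert {"blink", "saccade"} <= set(res["kernels"])
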