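import numpy as np
import pytest

import pupilsacc as ps


@pytest.fixture(scope="session")
def small_session():
    """Two-run session with blinks, shared by read-only tests."""
    cfg = ps.SimulationConfig(n_runs=2, seed=42, blink_rate=6.0)
    return ps.render_session(cfg)


@pytest.fixture(scope="session")
def clean_session():
    """Blink-free low-noise session for detector round-trips."""
    cfg = ps.SimulationConfig(n_runs=3, seed=7)
    return ps.render_session(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def truth_timestamps_ms(gt: ps.GroundTruth) -> np.ndarray:
    if not gt.saccade_times:
        return np.array([])
    return np.concatenate(
        [np.asarray(v) * 1000.0 for v in gt.saccade_times.values()])
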