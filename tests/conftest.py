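import numpy as np
import pytest

from ensembla.simulate import SimConfig, simulate_session
from ensembla.traces import BoutList, TraceMatrix, make_behavior_vector, zscore_traces


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_raw():
    """Tiny deterministic raw trace matrix (3 neurons × 10 frames)."""
    act = np.array(
        [
            [0.0, 1, 2, 3, 2, 1, 0, 0, 1, 2],
            [5.0, 5, 5, 5, 5, 5, 5, 5, 5, 5],  # constant row
            [2.0, 0, 1, 0, 3, 1, 0, 2, 0, 1],
        ]
    )
    return TraceMatrix(
        session_id="toy", neuron_ids=("n0", "n1", "n2"),
        frame_rate_hz=10.0, activity=act,
    )


@pytest.fixture
def sim_session():
    """Default-config synthetic session at reduced size, with ground truth."""
    cfg = SimConfig(n_neurons=30, n_frames=3000, seed=7)
    tm, bouts, gt = simulate_session(cfg)
    b = make_behavior_vector(bouts, cfg.frame_rate_hz, cfg.n_frames)
    return {"cfg": cfg, "traces": tm, "bouts": bouts, "truth": gt, "behavior": b}


@pytest.fixture
def bouts_10s():
    return BoutList(intervals=((1.0, 2.0), (5.0, 7.5)), session_duration_s=10.0)
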