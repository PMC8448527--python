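import numpy as np
import pytest

from sparklet.gating_sim import GatingParams, RenderParams, render_trace, simulate_open_counts
from sparklet.trace_ops import FluorescenceTrace


@pytest.fixture
def flat_trace() -> FluorescenceTrace:
    return FluorescenceTrace(np.ones(300), frame_rate=30.0)


@pytest.fixture
def pulse_trace() -> FluorescenceTrace:
    """20 baseline frames, 31-frame rectangular pulse of amplitude 0.29, 20 baseline."""
    v = np.ones(71)
    v[20:51] = 1.29
    return FluorescenceTrace(v, frame_rate=30.0)


@pytest.fixture
def noisefree_site():
    """A rendered noise-free 4-channel site plus its ground truth."""
    params = GatingParams(n_channels=4, k_open=1.5, k_close=8.5, duration=60.0, seed=7)
    truth = simulate_open_counts(params)
    trace = render_trace(truth, RenderParams(noise_sd=0.0), seed=11)
    return truth, trace


@pytest.fixture
def noisy_site():
    """Same site with additive Gaussian noise of SD q/6."""
    params = GatingParams(n_channels=4, k_open=1.5, k_close=8.5, duration=60.0, seed=7)
    truth = simulate_open_counts(params)
    trace = render_trace(truth, RenderParams(noise_sd=0.29 / 6), seed=11)
    return truth, trace
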