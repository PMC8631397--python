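import numpy as np
import pytest

from oculonet.datasets import load_paper_tables
from oculonet.events import DetectionParams, GazeRecording
from oculonet.network import CorrelationNetworkResults


@pytest.fixture(scope="session")
def paper_tables():
    return load_paper_tables()


@pytest.fixture(scope="session")
def printed_results():
    """Network results built from the packaged published tables."""
    return CorrelationNetworkResults.from_printed_tables()


@pytest.fixture
def detection_params():
    return DetectionParams()


def make_recording(x, y=None, sampling_rate=250.0, valid=None, **kwargs):
    """Recording from position arrays with uniform timestamps."""
    x = np.asarray(x, dtype=float)
    y = np.zeros_like(x) if y is None else np.asarray(y, dtype=float)
    t = np.arange(x.size) * (1000.0 / sampling_rate)
    return GazeRecording(
        subject_id=kwargs.get("subject_id", "s0"),
        trial_id=kwargs.get("trial_id", "t0"),
        sampling_rate=sampling_rate,
        t_ms=t,
        x_deg=x,
        y_deg=y,
        valid=valid,
    )


def raised_cosine_trace(
    amplitude=15.0,
    duration_ms=54.0,
    onset_ms=400.0,
    total_ms=1200.0,
    sampling_rate=250.0,
    noise_sd=0.0,
    seed=0,
):
    """Fixation - raised-cosine saccade - fixation, optionally noisy."""
    rng = np.random.default_rng(seed)
    t = np.arange(0.0, total_ms, 1000.0 / sampling_rate)
    u = np.clip((t - onset_ms) / duration_ms, 0.0, 1.0)
    x = amplitude * 0.5 * (1 - np.cos(np.pi * u))
    if noise_sd:
        x = x + rng.normal(0, noise_sd, t.size)
    return make_recording(x, sampling_rate=sampling_rate)
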