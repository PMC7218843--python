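import numpy as np
import pytest

from neurovad.io_core import EventTable, Recording, epoch_trials
from neurovad.preprocess import extract_production_window
from neurovad.synthetic import SimulationConfig, make_worked_example, simulate_session


@pytest.fixture(scope="session")
def worked_example():
    """The 2 s production-window trial with voicing at ms 402-931."""
    return make_worked_example()


@pytest.fixture(scope="session")
def small_session():
    """A small clean session (no artifacts) with its ground truth."""
    cfg = SimulationConfig(
        n_sensors=40, n_trials_per_stimulus=4, snr_db=10, artifact_trial_rate=0.0, seed=11
    )
    return cfg, *simulate_session(cfg)


@pytest.fixture(scope="session")
def small_production_epochs(small_session):
    """Production-window epochs of the small session, unpreprocessed."""
    _, recording, events, truth = small_session
    epochs = [extract_production_window(e) for e in epoch_trials(recording, events)]
    return epochs, truth


@pytest.fixture
def tiny_recording():
    rng = np.random.default_rng(0)
    data = rng.standard_normal((3, 8000))
    return Recording(
        data,
        1000.0,
        ["GRAD000", "GRAD001", "AUDIO"],
        ["gradiometer", "gradiometer", "acoustic"],
    )


@pytest.fixture
def tiny_events():
    return EventTable([700, 3000], [1, 2], ["S01", "S01"])
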