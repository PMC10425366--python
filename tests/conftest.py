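import numpy as np
import pytest

from fearframe.behavior_io import VelocityTrace, build_session_design, epoch_trace
from fearframe.behavior_scoring import ScoringParams


@pytest.fixture(scope="session")
def conditioning_design():
    return build_session_design("conditioning")


@pytest.fixture(scope="session")
def extinction_design():
    return build_session_design("extinction")


@pytest.fixture
def default_params():
    return ScoringParams()


def make_trace(velocity, rate=30.0, animal_id="t", label="conditioning"):
    velocity = np.asarray(velocity, dtype=float)
    return VelocityTrace(
        animal_id=animal_id,
        sampling_rate=rate,
        time=np.arange(len(velocity)) / rate,
        velocity=velocity,
        session_label=label,
    )


@pytest.fixture
def small_design():
    """A compact design for hand-constructed traces: 3 CS of 5 s at 10 Hz scale."""
    return build_session_design(
        "conditioning", cs_duration=5.0, iti=8.0, lead_in=6.0, n_cs=3
    )


@pytest.fixture
def small_epoched_factory(small_design):
    def factory(velocity, rate=10.0):
        return epoch_trace(make_trace(velocity, rate=rate), small_design)

    return factory
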