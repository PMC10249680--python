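import numpy as np
import pytest

from vrsft import (
    NoiseParams,
    SubjectParams,
    build_protocol,
    schedule_events,
    simulate_session,
)


@pytest.fixture(scope="session")
def protocol1_schedule():
    return schedule_events(build_protocol(1))


@pytest.fixture(scope="session")
def protocol3_schedule():
    return schedule_events(build_protocol(3))


@pytest.fixture(scope="session")
def noiseless():
    return NoiseParams.none()


@pytest.fixture
def make_subject():
    """Subject with a signed induced RAPD delta (log units)."""

    def _make(delta: float = 0.0, **kwargs) -> SubjectParams:
        return SubjectParams(
            deficit_right=max(delta, 0.0), deficit_left=max(-delta, 0.0), **kwargs
        )

    return _make


@pytest.fixture
def noiseless_trace(protocol1_schedule, noiseless, make_subject):
    """Deterministic noiseless protocol-1 recording of a symmetric subject."""
    return simulate_session(protocol1_schedule, make_subject(0.0), noiseless, seed=0)
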