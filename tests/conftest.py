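import dataclasses

import pytest

from engagesense import SessionConfig
from engagesense.config import StudyConfig
from engagesense.framing import ObservationFrame


@pytest.fixture
def frame():
    """Factory for bare continuous observation frames."""

    def make(start: float, end: float) -> ObservationFrame:
        return ObservationFrame("continuous", "test", start, end)

    return make


@pytest.fixture
def small_session_config() -> SessionConfig:
    """A short cohort for fast end-to-end pipeline tests."""
    return SessionConfig(
        n_participants=3,
        phase_durations={
            "Tutorial": 60.0,
            "Gameplay": 150.0,
            "Review": 40.0,
            "Mission-2": 90.0,
        },
        event_rate=1.0,
        mission2_fraction=1.0,
        pressure_rate=10.0,
        seed=7,
    )


@pytest.fixture
def small_study_config(small_session_config) -> StudyConfig:
    return dataclasses.replace(
        StudyConfig(seed=7, threshold=90.0), session=small_session_config
    )
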