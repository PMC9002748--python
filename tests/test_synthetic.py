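"""Properties of the synthetic calibration and play-session generators."""

import numpy as np
import pytest

from engagesense import (
    CalibrationConfig,
    CouplingConfig,
    SessionConfig,
    generate_calibration_session,
    generate_play_session,
    transition_cover_sequence,
)
from engagesense.chair import SENSOR_LABELS
from engagesense.errors import InvalidArgumentError
from engagesense.synthetic import BACKREST_POSTURES, CANONICAL_ACTIVATIONS, _posture_walk


@pytest.mark.parametrize("n", [2, 3, 4, 5, 6])
def test_transition_cover_is_eulerian(n):
    """The display order covers each of the n(n−1) ordered transitions once."""
    seq = transition_cover_sequence(n, seed=n)
    assert len(seq) == n * (n - 1) + 1
    pairs = list(zip(seq[:-1], seq[1:]))
    assert len(pairs) == n * (n - 1)
    assert len(set(pairs)) == n * (n - 1)
    assert all(a != b for a, b in pairs)
    assert seq[0] == seq[-1]  # a circuit


def test_transition_cover_n2_is_rotation_of_unique_circuit():
    seq = transition_cover_sequence(2, seed=0)
    assert seq in (["P1", "P2", "P1"], ["P2", "P1", "P2"])


def test_transition_cover_rejects_single_posture():
    with pytest.raises(InvalidArgumentError):
        transition_cover_sequence(1)


def test_calibration_session_structure():
    cfg = CalibrationConfig(seed=5)
    stream, schedule = generate_calibration_session(cfg, 0)
    assert len(stream) == 31 * 10  # 31 displayed postures × 10 s at 1 Hz
    # P1 intervals: canonical sensors near the active level, the rest inactive
    rows = schedule.labels == "P1"
    for k, lab in enumerate(SENSOR_LABELS):
        mean = stream.values[rows, k].mean()
        if lab in CANONICAL_ACTIVATIONS["P1"]:
            assert mean == pytest.approx(150.0, abs=15.0)
        else:
            assert mean == pytest.approx(10.0, abs=5.0)
    assert np.all(stream.values >= 0)


def test_calibration_session_deterministic():
    cfg = CalibrationConfig(seed=9)
    s1, _ = generate_calibration_session(cfg, 2)
    s2, _ = generate_calibration_session(cfg, 2)
    s3, _ = generate_calibration_session(cfg, 3)
    np.testing.assert_array_equal(s1.values, s2.values)
    assert not np.array_equal(s1.values, s3.values)


def test_play_session_deterministic_and_participant_split(small_session_config):
    b1 = generate_play_session(small_session_config, 0)
    b2 = generate_play_session(small_session_config, 0)
    b3 = generate_play_session(small_session_config, 1)
    np.testing.assert_array_equal(b1.pressure.values, b2.pressure.values)
    np.testing.assert_array_equal(b1.ibi.intervals, b2.ibi.intervals)
    np.testing.assert_array_equal(b1.annotation.values, b2.annotation.values)
    assert not np.array_equal(b1.pressure.values[: len(b3.pressure)], b3.pressure.values[: len(b1.pressure)])


def test_events_confined_and_spaced(small_session_config):
    for i in range(4):
        b = generate_play_session(small_session_config, i)
        for t in b.events.times:
            phase = b.phases.containing(float(t))
            assert phase is not None and phase.name in ("Gameplay", "Mission-2")
        if len(b.events) > 1:
            assert np.all(np.diff(b.events.times) >= small_session_config.event_min_spacing)


def test_truth_is_per_second_in_unit_interval(small_session_config):
    b = generate_play_session(small_session_config, 0)
    total = int(b.phases.phases[-1].end)
    assert len(b.truth) == total
    np.testing.assert_array_equal(b.truth.times, np.arange(total, dtype=float))
    assert b.truth.values.min() >= 0 and b.truth.values.max() <= 1


def test_backrest_use_decreases_with_engagement():
    """Positive posture coupling: less backrest in (engaged) Gameplay than Tutorial."""
    rng = np.random.default_rng(0)
    cfg = SessionConfig(coupling=CouplingConfig(posture=0.8, mobility=0.0, heart=0, mouse=0))
    e = np.concatenate([np.full(2000, 0.2), np.full(2000, 0.8)])
    labels = _posture_walk(cfg, rng, e)
    back = np.array([lab in BACKREST_POSTURES for lab in labels])
    assert back[:2000].mean() > back[2000:].mean()


def test_zero_coupling_decouples_channels(small_session_config):
    """With all couplings zero, per-second click counts are uncorrelated
    with the latent engagement; with strong coupling they correlate."""
    import dataclasses

    def click_corr(cfg):
        r = []
        for i in range(3):
            b = generate_play_session(cfg, i)
            total = len(b.truth)
            press = b.mouse.events.query("event_type == 'press'")["time_s"].to_numpy()
            counts = np.bincount(np.floor(press).astype(int), minlength=total)[:total]
            r.append(np.corrcoef(b.truth.values, counts)[0, 1])
        return np.mean(r)

    null_cfg = dataclasses.replace(
        small_session_config, coupling=CouplingConfig(0, 0, 0, 0)
    )
    r_null = click_corr(null_cfg)
    r_coupled = click_corr(small_session_config)
    assert abs(r_null) < 0.08
    assert r_coupled > r_null + 0.08


def test_event_rate_scales_with_gameplay_duration():
    """Thinned Poisson events: counts grow with rate but respect spacing."""
    cfg = SessionConfig(
        n_participants=1,
        phase_durations={"Tutorial": 30.0, "Gameplay": 600.0, "Review": 30.0, "Mission-2": 60.0},
        event_rate=1.0,
        mission2_fraction=0.0,
        pressure_rate=2.0,
    )
    counts = [len(generate_play_session(cfg, i).events) for i in range(20)]
    # 10 expected before thinning over 600 s; spacing caps the mean below that
    assert 2.0 <= np.mean(counts) <= 10.0


def test_invalid_configs_rejected():
    with pytest.raises(InvalidArgumentError):
        CalibrationConfig(active_mv=(10.0, 1.0), inactive_mv=(50.0, 1.0))
    with pytest.raises(InvalidArgumentError):
        SessionConfig(event_rate=-1.0)
    with pytest.raises(InvalidArgumentError):
        SessionConfig(engagement_levels={"Tutorial": 1.5})
    with pytest.raises(InvalidArgumentError):
        SessionConfig(coupling=CouplingConfig(posture=2.0))
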