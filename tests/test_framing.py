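"""Harmonization to 1 Hz and observation-frame construction."""

import numpy as np
import pytest

from engagesense import (
    AnnotationTrace,
    EventLog,
    Phase,
    PhaseLog,
    PressureStream,
    build_frames,
    harmonize_streams,
)
from engagesense.framing import CONTINUOUS, REACTIVE_POST, REACTIVE_PRE
from engagesense.synthetic import generate_play_session


def annotation(n, t0=0.0):
    return AnnotationTrace(t0 + np.arange(n, dtype=float), np.zeros(n))


def test_constant_pressure_passes_through():
    t = np.arange(0, 60, 1 / 25)
    stream = PressureStream(t, np.full((len(t), 12), 100.0))
    p1hz, table = harmonize_streams(stream, annotation(60))
    assert np.allclose(p1hz.values, 100.0)
    assert len(p1hz) == 60


def test_overlap_truncation():
    t = np.arange(0, 301, 1 / 25)  # pressure spans 301 s
    stream = PressureStream(t, np.full((len(t), 12), 50.0))
    p1hz, table = harmonize_streams(stream, annotation(300))  # annotation 0..299
    assert len(table) == 300


def test_impulse_spreads_over_boxcar_window():
    """One 25 Hz sample at 250 mV amid zeros → 250/25 = 10 mV at that second."""
    t = np.arange(0, 20, 1 / 25)
    vals = np.zeros((len(t), 12))
    hit = np.argmin(np.abs(t - 10.0))
    vals[hit, :] = 250.0
    p1hz, _ = harmonize_streams(PressureStream(t, vals), annotation(20))
    sec10 = int(np.where(p1hz.times == 10.0)[0][0])
    assert p1hz.values[sec10, 0] == pytest.approx(10.0)


def test_two_phases_no_events():
    phases = PhaseLog((Phase("Tutorial", 0, 120), Phase("Gameplay", 120, 420)))
    frames = build_frames(phases, EventLog(np.array([]), np.array([], dtype=object)))
    assert [f.kind for f in frames] == [CONTINUOUS, CONTINUOUS]
    assert [(f.start, f.end) for f in frames] == [(0, 120), (120, 420)]


def test_event_frames_are_half_open_around_event():
    phases = PhaseLog((Phase("Tutorial", 0, 120), Phase("Gameplay", 120, 420)))
    events = EventLog(np.array([200.0]), np.array(["catapult-launch"], dtype=object))
    frames = build_frames(phases, events, reactive_durations=(10.0,))
    reactive = [f for f in frames if f.kind != CONTINUOUS]
    assert [(f.kind, f.start, f.end) for f in reactive] == [
        (REACTIVE_PRE, 190.0, 200.0),
        (REACTIVE_POST, 200.0, 210.0),
    ]


def test_clip_and_drop_rule():
    """A 30 s pre-frame crossing into the previous phase is clipped to 5 s
    (< 15 s) and dropped; the post-frame survives."""
    phases = PhaseLog((Phase("Tutorial", 0, 120), Phase("Gameplay", 120, 420)))
    events = EventLog(np.array([125.0]), np.array(["proximity-alarm"], dtype=object))
    frames = build_frames(phases, events, reactive_durations=(30.0,))
    reactive = [f for f in frames if f.kind != CONTINUOUS]
    assert len(reactive) == 1
    assert reactive[0].kind == REACTIVE_POST
    assert (reactive[0].start, reactive[0].end) == (125.0, 155.0)


def test_clipped_but_long_enough_frame_kept():
    phases = PhaseLog((Phase("Gameplay", 120, 420),))
    events = EventLog(np.array([140.0]), np.array(["monster-click"], dtype=object))
    frames = build_frames(phases, events, reactive_durations=(30.0,))
    pre = [f for f in frames if f.kind == REACTIVE_PRE]
    assert len(pre) == 1
    assert (pre[0].start, pre[0].end) == (120.0, 140.0)  # 20 s ≥ 15 s


def test_event_outside_phases_rejected():
    phases = PhaseLog((Phase("Gameplay", 0, 100),))
    events = EventLog(np.array([500.0]), np.array(["monster-click"], dtype=object))
    frames = build_frames(phases, events)
    assert all(f.kind == CONTINUOUS for f in frames)


def test_mission3_omitted_by_default():
    phases = PhaseLog(
        (Phase("Tutorial", 0, 60), Phase("Gameplay", 60, 200), Phase("Mission-3", 200, 260))
    )
    frames = build_frames(phases, EventLog(np.array([]), np.array([], dtype=object)))
    assert [f.label for f in frames] == ["Tutorial", "Gameplay"]


def test_continuous_frames_partition_session(small_session_config):
    b = generate_play_session(small_session_config, 0)
    frames = build_frames(b.phases, EventLog(np.array([]), np.array([], dtype=object)))
    cont = sorted((f for f in frames if f.kind == CONTINUOUS), key=lambda f: f.start)
    assert cont[0].start == 0.0
    for a, b_ in zip(cont[:-1], cont[1:]):
        assert a.end == b_.start


def test_generator_spacing_keeps_event_frames_disjoint(small_session_config):
    """With ≥30 s event spacing, reactive frames of distinct events and the
    pre/post frames of one event never overlap (per duration class)."""
    for i in range(4):
        b = generate_play_session(small_session_config, i)
        frames = build_frames(b.phases, b.events)
        for d in (10.0, 30.0):
            rx = sorted(
                (f for f in frames if f.nominal_duration == d), key=lambda f: f.start
            )
            for f1, f2 in zip(rx[:-1], rx[1:]):
                assert f1.end <= f2.start
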