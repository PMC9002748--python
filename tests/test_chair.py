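"""Posture identification, threshold calibration, and mobility features."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from engagesense import (
    CalibrationConfig,
    PatternTable,
    PostureSeries,
    PressureStream,
    calibrate_threshold,
    classify_stream,
    identify_posture,
    posture_features,
    transition_contingency,
)
from engagesense.chair import NO_POSTURE, SENSOR_LABELS
from engagesense.errors import (
    ConfigurationError,
    InvalidArgumentError,
    UndefinedFeatureError,
)
from engagesense.framing import ObservationFrame
from engagesense.synthetic import generate_calibration_session


def mv(active: set[str], high: float = 150.0, low: float = 10.0) -> list[float]:
    return [high if lab in active else low for lab in SENSOR_LABELS]


# Independent brute-force evaluators for the six activation patterns,
# hand-transcribed as plain predicates over the active-sensor set.
_ORACLE = [
    ("P1", lambda s: ("3" in s or "7" in s) and ("4" in s or "8" in s)
        and ("a" in s or "d" in s) and ("b" in s or "c" in s)),
    ("P5", lambda s: ("3" in s or "7" in s) and ("2" in s or "8" in s)
        and ("a" in s or "c" in s)),
    ("P6", lambda s: ("3" in s or "7" in s) and ("2" in s or "8" in s)
        and ("b" in s or "d" in s)),
    ("P4", lambda s: ("3" in s or "4" in s)
        and ("a" in s or "b" in s or "c" in s or "d" in s)),
    ("P2", lambda s: ("3" in s or "7" in s) and ("2" in s or "d" in s)),
    ("P3", lambda s: ("3" in s or "4" in s)),
]


def oracle_label(active: set[str]) -> str:
    for label, pred in _ORACLE:
        if pred(active):
            return label
    return NO_POSTURE


@pytest.mark.parametrize(
    "active, expected",
    [
        ({"3", "4", "a", "b"}, "P1"),  # upright with backrest
        (set(), NO_POSTURE),
        ({"7", "d"}, "P2"),  # fails P1/P5/P6/P4, satisfies (3 or 7) and (2 or d)
        ({"3", "4"}, "P3"),
        ({"3", "4", "c"}, "P4"),
        ({"2", "3", "7", "a", "c"}, "P5"),
        ({"2", "3", "7", "b", "d"}, "P6"),
    ],
)
def test_identify_posture_examples(active, expected):
    assert identify_posture(mv(active), threshold=90.0) == expected


def test_identify_posture_matches_exhaustive_oracle():
    """All 2^12 activation sets agree with the hand-coded evaluators."""
    table = PatternTable()
    sets = list(itertools.product([False, True], repeat=len(SENSOR_LABELS)))
    A = np.array(sets, dtype=bool)
    got = table.match(A)
    for row, lab in zip(sets, got):
        active = {s for s, on in zip(SENSOR_LABELS, row) if on}
        assert lab == oracle_label(active)


def test_precedence_returns_most_specific_on_overlap():
    """Activation sets satisfying several patterns (e.g. P1 together with
    P4 or P2) resolve to the most specific one, P1 first."""
    p1 = dict(_ORACLE)["P1"]
    others = [(lab, fn) for lab, fn in _ORACLE if lab != "P1"]
    overlaps = 0
    for row in itertools.product([False, True], repeat=12):
        active = {s for s, on in zip(SENSOR_LABELS, row) if on}
        if p1(active):
            if any(fn(active) for _, fn in others):
                overlaps += 1
            assert identify_posture(mv(active), 90.0) == "P1"
    assert overlaps > 0


def test_unknown_sensor_label_is_configuration_error():
    with pytest.raises(ConfigurationError):
        PatternTable([("PX", "(3 or 9) and (a or b)")])


def test_threshold_is_strict_inequality():
    v = mv({"3", "4"}, high=90.0, low=10.0)
    assert identify_posture(v, 90.0) == NO_POSTURE  # 90 is not > 90
    assert identify_posture(v, 89.9) == "P3"


def test_classify_stream_constant_and_alternating():
    n = 10
    stream = PressureStream(np.arange(n), np.array([mv({"3", "4", "a", "b"})] * n))
    series = classify_stream(stream, 90.0)
    assert list(series.labels) == ["P1"] * n

    vals = [mv({"3", "4", "a", "b"}) if t % 2 == 0 else mv({"2", "3", "4", "7", "8"})
            for t in range(6)]
    series = classify_stream(PressureStream(np.arange(6), np.array(vals)), 90.0)
    assert list(series.labels) == ["P1", "P2", "P1", "P2", "P1", "P2"]


def test_classify_empty_stream_rejected():
    stream = PressureStream(np.array([]), np.empty((0, 12)))
    with pytest.raises(InvalidArgumentError):
        classify_stream(stream, 90.0)


def test_calibration_noiseless_perfect_separation():
    """Exact 150/10 mV outputs give accuracy 1.0 on every threshold in (10, 150)."""
    cfg = CalibrationConfig(active_mv=(150.0, 0.0), inactive_mv=(10.0, 0.0), seed=3)
    sessions = [generate_calibration_session(cfg, i) for i in range(2)]
    res = calibrate_threshold(sessions, grid=np.arange(1, 301))
    inside = (res.thresholds > 10) & (res.thresholds < 150)
    assert np.all(res.mean_accuracy[inside] == 1.0)
    assert res.plateau[0] <= 11 and res.plateau[1] >= 149
    assert res.plateau[0] <= res.selected_threshold <= res.plateau[1]


def test_calibration_synthetic_high_accuracy_at_selected_threshold():
    """Stochastic default generator: classification at the selected threshold
    recovers the displayed schedule on ≥95% of samples."""
    cfg = CalibrationConfig(seed=11)
    stream, schedule = generate_calibration_session(cfg, 0)
    res = calibrate_threshold([(stream, schedule)], grid=np.arange(1, 301))
    series = classify_stream(stream, float(res.selected_threshold))
    acc = np.mean(series.labels == schedule.labels)
    assert acc >= 0.95


def test_calibration_anova_degenerate_flagged():
    cfg = CalibrationConfig(active_mv=(150.0, 0.0), inactive_mv=(10.0, 0.0), seed=0)
    sessions = [generate_calibration_session(cfg, 0)]
    res = calibrate_threshold(sessions, grid=np.arange(20, 60), batch=40)
    assert bool(res.anova["degenerate"].iloc[0])
    assert res.anova["p_value"].iloc[0] == 1.0


@pytest.mark.parametrize(
    "labels, expected",
    [
        (["P1", "P1", "P2"], {("P1", "P1"): 1, ("P1", "P2"): 1}),
        (["P1", "P2", "P1", "P2"], {("P1", "P2"): 2, ("P2", "P1"): 1}),
    ],
)
def test_transition_contingency_counts(labels, expected, frame):
    series = PostureSeries(np.arange(len(labels), dtype=float), np.array(labels, dtype=object))
    tab = transition_contingency(series, frame(0, len(labels)))
    for (a, b), n in expected.items():
        assert tab.loc[a, b] == n
    assert tab.to_numpy().sum() == len(labels) - 1


def test_contingency_single_sample_is_empty(frame):
    series = PostureSeries(np.array([0.0]), np.array(["P1"], dtype=object))
    tab = transition_contingency(series, frame(0, 1))
    assert tab.to_numpy().sum() == 0


def test_posture_features_transition_rate(frame):
    labels = ["P1", "P1", "P2", "P2", "P1"]
    series = PostureSeries(np.arange(5, dtype=float), np.array(labels, dtype=object))
    stream = PressureStream(np.arange(5, dtype=float), np.full((5, 12), 50.0))
    f = posture_features(series, stream, frame(0, 5))
    assert f.transitions_per_second == pytest.approx(0.4)
    assert f.mean_gradient == 0.0  # constant stream


def test_posture_features_single_ramp_gradient(frame):
    """One detection sensor ramping 2 mV/s over 8 detection sensors → 0.25."""
    vals = np.full((5, 12), 50.0)
    ramp_col = SENSOR_LABELS.index("3")
    vals[:, ramp_col] = 50.0 + 2.0 * np.arange(5)
    series = PostureSeries(np.arange(5, dtype=float), np.array(["P1"] * 5, dtype=object))
    f = posture_features(series, PressureStream(np.arange(5, dtype=float), vals), frame(0, 5))
    assert f.mean_gradient == pytest.approx(2.0 / 8.0)


def test_posture_features_too_few_samples(frame):
    series = PostureSeries(np.array([0.0]), np.array(["P1"], dtype=object))
    stream = PressureStream(np.array([0.0]), np.full((1, 12), 50.0))
    with pytest.raises(UndefinedFeatureError):
        posture_features(series, stream, frame(0, 1))


def test_none_breaks_runs_without_counting(frame):
    labels = ["P1", "none", "P2", "P2"]
    series = PostureSeries(np.arange(4, dtype=float), np.array(labels, dtype=object))
    stream = PressureStream(np.arange(4, dtype=float), np.full((4, 12), 50.0))
    f = posture_features(series, stream, frame(0, 4))
    assert f.transitions_per_second == 0.0


@settings(deadline=None, derandomize=True)
@given(
    st.lists(st.sampled_from(["P1", "P2", "P3", "P4", "P5", "P6"]), min_size=2, max_size=40)
)
def test_offdiagonal_total_equals_transition_count(labels):
    """Without none-labels, contingency off-diagonal mass = μΤ × duration."""
    fr = ObservationFrame("continuous", "t", 0, len(labels))
    series = PostureSeries(np.arange(len(labels), dtype=float), np.array(labels, dtype=object))
    stream = PressureStream(np.arange(len(labels), dtype=float), np.full((len(labels), 12), 1.0))
    tab = transition_contingency(series, fr)
    off = tab.to_numpy().sum() - np.trace(tab.to_numpy())
    f = posture_features(series, stream, fr)
    assert off == pytest.approx(f.transitions_per_second * fr.duration)
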