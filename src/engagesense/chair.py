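"""Sitting-posture identification from a pressure-sensor chair.

Twelve force-sensitive resistors are strapped to an office chair: eight on
the seat (labels ``1``–``8``, four under each thigh) and four on the
backrest (labels ``a``–``d``, two per side).  A sensor counts as *active*
when its output exceeds an activation threshold (mV).  Postures P1–P6 are
recognised by matching the set of active sensors against boolean activation
patterns; the activation threshold itself is estimated by a calibration
experiment in which known postures are displayed to a seated participant
and the identification accuracy is swept over a threshold grid.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import ConfigurationError, InvalidArgumentError, UndefinedFeatureError

#: Canonical sensor labels, column order of every pressure matrix.
SENSOR_LABELS: tuple[str, ...] = (
    "1", "2", "3", "4", "5", "6", "7", "8", "a", "b", "c", "d",
)

#: Sensors used for posture detection; middle-seat sensors 1, 2, 5, 6 are
#: excluded (they are loaded in every seated posture and carry no signal).
DETECTION_SENSORS: tuple[str, ...] = ("3", "4", "7", "8", "a", "b", "c", "d")

#: Posture label for samples matching no pattern.
NO_POSTURE = "none"

POSTURE_LABELS: tuple[str, ...] = ("P1", "P2", "P3", "P4", "P5", "P6")

#: Activation patterns, listed in matching precedence (most specific
#: first).  P1 upright with backrest; P2 upright without backrest; P3 front
#: sitting; P4 front sitting with backrest; P5/P6 upright with right/left
#: backrest.  First satisfied pattern wins.
DEFAULT_PATTERNS: tuple[tuple[str, str], ...] = (
    ("P1", "(3 or 7) and (4 or 8) and (a or d) and (b or c)"),
    ("P5", "(3 or 7) and (2 or 8) and (a or c)"),
    ("P6", "(3 or 7) and (2 or 8) and (b or d)"),
    ("P4", "(3 or 4) and (a or b or c or d)"),
    ("P2", "(3 or 7) and (2 or d)"),
    ("P3", "(3 or 4)"),
)

_TOKEN_RE = re.compile(r"\(|\)|\band\b|\bor\b|[0-9a-zA-Z]+")


@dataclass(frozen=True)
class PressureStream:
    """Timestamped 12-channel chair-sensor outputs in mV."""

    times: np.ndarray  # seconds from session start, strictly increasing
    values: np.ndarray  # shape (n_samples, 12), mV, >= 0

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[1] != len(SENSOR_LABELS):
            raise InvalidArgumentError(
                f"pressure values must have {len(SENSOR_LABELS)} channels"
            )
        if len(t) != len(v):
            raise InvalidArgumentError("times and values length mismatch")
        if len(t) > 1 and np.any(np.diff(t) <= 0):
            raise InvalidArgumentError("timestamps must be strictly increasing")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "values", v)

    def __len__(self) -> int:
        return len(self.times)

    def slice(self, start: float, end: float) -> "PressureStream":
        """Samples with timestamp in the half-open window [start, end)."""
        m = (self.times >= start) & (self.times < end)
        return PressureStream(self.times[m], self.values[m])

    def to_frame(self) -> pd.DataFrame:
        cols = {"time_s": self.times}
        for k, lab in enumerate(SENSOR_LABELS):
            name = f"s{lab}" if lab.isdigit() else f"b{lab}"
            cols[name] = self.values[:, k]
        return pd.DataFrame(cols)


@dataclass(frozen=True)
class PostureSeries:
    """Per-sample posture labels (P1–P6 or ``none``)."""

    times: np.ndarray
    labels: np.ndarray  # dtype str

    def __post_init__(self) -> None:
        object.__setattr__(self, "times", np.asarray(self.times, dtype=float))
        object.__setattr__(self, "labels", np.asarray(self.labels, dtype=object))
        if len(self.times) != len(self.labels):
            raise InvalidArgumentError("times and labels length mismatch")

    def __len__(self) -> int:
        return len(self.times)

    def slice(self, start: float, end: float) -> "PostureSeries":
        m = (self.times >= start) & (self.times < end)
        return PostureSeries(self.times[m], self.labels[m])


class PatternTable:
    """Ordered posture activation patterns.

    Each pattern is a boolean expression over sensor labels, e.g.
    ``"(3 or 7) and (2 or d)"``; a label atom is true when that sensor is
    active.  Order defines matching precedence.  Expressions are compiled
    once into vectorised evaluators over boolean activation matrices.
    """

    def __init__(self, patterns: Sequence[tuple[str, str]] = DEFAULT_PATTERNS):
        self.patterns: list[tuple[str, str]] = [(p, e) for p, e in patterns]
        self._evaluators: list[Callable[[np.ndarray], np.ndarray]] = [
            _compile_expression(expr) for _, expr in self.patterns
        ]

    @property
    def labels(self) -> list[str]:
        return [p for p, _ in self.patterns]

    def match(self, active: np.ndarray) -> np.ndarray:
        """Label each row of a boolean (n, 12) activation matrix.

        Returns an object array of posture labels; rows matching no
        pattern get :data:`NO_POSTURE`.
        """
        active = np.atleast_2d(np.asarray(active, dtype=bool))
        out = np.full(len(active), NO_POSTURE, dtype=object)
        unassigned = np.ones(len(active), dtype=bool)
        for (label, _), fn in zip(self.patterns, self._evaluators):
            hit = unassigned & fn(active)
            out[hit] = label
            unassigned &= ~hit
            if not unassigned.any():
                break
        return out

    @classmethod
    def from_mapping(cls, mapping: Sequence[dict] | dict) -> "PatternTable":
        """Build from YAML-style input: ordered list of one-entry mappings
        or a (Python 3.7+ insertion-ordered) dict of label -> expression."""
        pairs: list[tuple[str, str]] = []
        if isinstance(mapping, dict):
            pairs = list(mapping.items())
        else:
            for item in mapping:
                if not isinstance(item, dict) or len(item) != 1:
                    raise ConfigurationError(
                        "pattern list entries must be single-key mappings"
                    )
                pairs.extend(item.items())
        return cls(pairs)


def _compile_expression(expr: str) -> Callable[[np.ndarray], np.ndarray]:
    """Compile a sensor-label boolean expression into a vectorised check.

    Translated to a numpy expression with ``&``/``|``; relative operator
    precedence matches ``and``/``or`` so the token substitution is exact.
    """
    index = {lab: k for k, lab in enumerate(SENSOR_LABELS)}
    pieces: list[str] = []
    for tok in _TOKEN_RE.findall(expr):
        if tok == "and":
            pieces.append("&")
        elif tok == "or":
            pieces.append("|")
        elif tok in "()":
            pieces.append(tok)
        elif tok in index:
            pieces.append(f"A[:, {index[tok]}]")
        else:
            raise ConfigurationError(f"unknown sensor label {tok!r} in pattern {expr!r}")
    leftover = _TOKEN_RE.sub("", expr).strip()
    if leftover:
        raise ConfigurationError(f"unparseable characters {leftover!r} in {expr!r}")
    code = compile(" ".join(pieces), "<pattern>", "eval")

    def evaluate(A: np.ndarray) -> np.ndarray:
        return eval(code, {"__builtins__": {}}, {"A": A})  # noqa: S307 - sanitised tokens

    return evaluate


def identify_posture(
    sensor_vector: Sequence[float] | np.ndarray,
    threshold: float,
    patterns: PatternTable | None = None,
) -> str:
    """Identify the posture for one 12-sensor reading.

    A sensor is active when its output strictly exceeds ``threshold`` (mV).
    Returns the first pattern (precedence order) satisfied by the active
    set, or :data:`NO_POSTURE`.
    """
    if threshold <= 0:
        raise InvalidArgumentError("threshold must be positive")
    patterns = patterns or PatternTable()
    v = np.asarray(sensor_vector, dtype=float)
    if v.shape != (len(SENSOR_LABELS),):
        raise InvalidArgumentError("sensor_vector must have 12 entries")
    return str(patterns.match((v > threshold)[None, :])[0])


def classify_stream(
    stream: PressureStream,
    threshold: float,
    patterns: PatternTable | None = None,
) -> PostureSeries:
    """Label every sample of a (harmonized, 1 Hz) pressure stream."""
    if threshold <= 0:
        raise InvalidArgumentError("threshold must be positive")
    if len(stream) == 0:
        raise InvalidArgumentError("cannot classify an empty stream")
    patterns = patterns or PatternTable()
    labels = patterns.match(stream.values > threshold)
    return PostureSeries(stream.times, labels)


@dataclass
class CalibrationResult:
    """Threshold sweep outcome of the calibration experiment."""

    thresholds: np.ndarray  # mV grid
    mean_accuracy: np.ndarray  # across participants, per threshold
    per_participant: np.ndarray  # shape (n_thresholds, n_participants)
    plateau: tuple[float, float]  # contiguous argmax interval (inclusive)
    selected_threshold: int  # rounded plateau midpoint, mV
    anova: pd.DataFrame = field(default_factory=pd.DataFrame)
    # columns: batch_start, batch_end, p_value, degenerate

    @property
    def max_accuracy(self) -> float:
        return float(self.mean_accuracy.max())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"threshold_mv": self.thresholds, "mean_accuracy": self.mean_accuracy}
        )


def calibrate_threshold(
    sessions: Sequence[tuple[PressureStream, PostureSeries]],
    grid: Sequence[float] | np.ndarray = np.arange(1, 301),
    batch: int = 50,
    patterns: PatternTable | None = None,
) -> CalibrationResult:
    """Sweep the activation threshold against displayed-posture schedules.

    Parameters
    ----------
    sessions
        One ``(pressure, schedule)`` pair per calibration participant; the
        schedule gives the displayed posture for every pressure sample.
    grid
        Candidate thresholds in mV (default 1–300, integer steps).
    batch
        Size of the consecutive-threshold batches on which single-factor
        ANOVA across participants is run.

    Accuracy per threshold and participant is the fraction of samples whose
    identified posture equals the displayed one.  The plateau is the
    longest contiguous run of thresholds attaining the maximum mean
    accuracy, and the selected threshold is its midpoint rounded to the
    nearest integer mV.
    """
    grid = np.asarray(grid, dtype=float)
    if grid.size == 0:
        raise InvalidArgumentError("threshold grid is empty")
    if len(sessions) == 0:
        raise InvalidArgumentError("at least one calibration session required")
    patterns = patterns or PatternTable()
    max_mv = max(float(s.values.max()) for s, _ in sessions)
    if grid.min() <= 0 or grid.min() > max_mv:
        raise InvalidArgumentError("grid outside the sensor output range")

    acc = np.empty((grid.size, len(sessions)))
    for j, (stream, schedule) in enumerate(sessions):
        if len(stream) != len(schedule):
            raise InvalidArgumentError("schedule and stream lengths differ")
        truth = np.asarray(schedule.labels, dtype=object)
        for i, thr in enumerate(grid):
            labels = patterns.match(stream.values > thr)
            acc[i, j] = np.mean(labels == truth)
    mean_acc = acc.mean(axis=1)

    top = mean_acc.max()
    is_max = mean_acc >= top - 1e-12
    lo, hi = _longest_run(is_max)
    plateau = (float(grid[lo]), float(grid[hi]))
    selected = int(round((plateau[0] + plateau[1]) / 2.0))

    rows = []
    for start in range(0, grid.size, batch):
        stop = min(start + batch, grid.size)
        groups = [acc[i] for i in range(start, stop)]
        degenerate = len(groups) < 2 or all(np.ptp(g) == 0 for g in groups)
        if degenerate:
            p = 1.0
        else:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                stat, p = sps.f_oneway(*groups)
            if np.isnan(p):
                p, degenerate = 1.0, True
        rows.append(
            {
                "batch_start": float(grid[start]),
                "batch_end": float(grid[stop - 1]),
                "p_value": float(p),
                "degenerate": degenerate,
            }
        )
    return CalibrationResult(
        thresholds=grid,
        mean_accuracy=mean_acc,
        per_participant=acc,
        plateau=plateau,
        selected_threshold=selected,
        anova=pd.DataFrame(rows),
    )


def _longest_run(mask: np.ndarray) -> tuple[int, int]:
    """Start/end indices (inclusive) of the longest True run; first on ties."""
    best = (0, 0)
    best_len = 0
    i = 0
    n = len(mask)
    while i < n:
        if mask[i]:
            j = i
            while j + 1 < n and mask[j + 1]:
                j += 1
            if j - i + 1 > best_len:
                best, best_len = (i, j), j - i + 1
            i = j + 1
        else:
            i += 1
    return best


ALL_POSTURE_STATES: tuple[str, ...] = POSTURE_LABELS + (NO_POSTURE,)


def transition_contingency(series: PostureSeries, frame) -> pd.DataFrame:
    """Posture-transition contingency table within an observation frame.

    Element (Px, Py) counts adjacent sample pairs labelled Px then Py
    inside the frame, including self-transitions on the diagonal.  Frames
    with fewer than two samples yield an all-zero table.
    """
    sub = series.slice(frame.start, frame.end)
    table = pd.DataFrame(
        0, index=list(ALL_POSTURE_STATES), columns=list(ALL_POSTURE_STATES), dtype=int
    )
    labels = sub.labels
    for a, b in zip(labels[:-1], labels[1:]):
        table.loc[a, b] += 1
    return table


@dataclass(frozen=True)
class PostureFeatures:
    """Mobility features of one observation frame."""

    transitions_per_second: float  # μΤ, 1/s
    mean_gradient: float  # ΔΤ, mV/s over the detection sensors


def posture_features(
    series: PostureSeries, stream: PressureStream, frame
) -> PostureFeatures:
    """Compute μΤ and ΔΤ for one frame.

    μΤ counts adjacent label changes (samples labelled ``none`` break runs
    but never count as changes) divided by the frame duration.  ΔΤ is the
    mean, over the eight posture-detection sensors, of the mean absolute
    first difference of sensor output inside the frame.
    """
    duration = frame.end - frame.start
    if duration <= 0:
        raise InvalidArgumentError("frame duration must be positive")
    labels = series.slice(frame.start, frame.end).labels
    sub = stream.slice(frame.start, frame.end)
    if len(labels) < 2 or len(sub) < 2:
        raise UndefinedFeatureError("frame has fewer than 2 samples")
    changes = sum(
        1
        for a, b in zip(labels[:-1], labels[1:])
        if a != NO_POSTURE and b != NO_POSTURE and a != b
    )
    det_idx = [SENSOR_LABELS.index(s) for s in DETECTION_SENSORS]
    dt = np.diff(sub.times)
    dv = np.abs(np.diff(sub.values[:, det_idx], axis=0)) / dt[:, None]
    return PostureFeatures(
        transitions_per_second=changes / duration,
        mean_gradient=float(dv.mean()),
    )
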