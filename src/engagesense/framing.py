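"""Stream harmonization and observation-frame construction.

All sources are brought onto a common 1 Hz integer-second grid, with the
annotation trace as the timing reference.  Pressure signals (sampled
faster at the source) are smoothed by a centered one-second boxcar before
decimation.  Two kinds of observation frames are then built: *continuous*
frames spanning whole game phases (Tutorial, Gameplay, Review, Mission-2,
Mission-3) and *reactive* frames of fixed duration anchored before and
after sparse in-game events.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .biosignals import BpmSeries, IbiSeries
from .chair import SENSOR_LABELS, PressureStream
from .errors import AlignmentError, InvalidArgumentError
from .traces import AnnotationTrace, MouseStream

log = logging.getLogger(__name__)

PHASE_NAMES = ("Tutorial", "Gameplay", "Review", "Mission-2", "Mission-3")
EVENT_KINDS = ("proximity-alarm", "catapult-launch", "monster-click")

CONTINUOUS = "continuous"
REACTIVE_PRE = "reactive-pre"
REACTIVE_POST = "reactive-post"


@dataclass(frozen=True)
class Phase:
    name: str
    start: float
    end: float


@dataclass(frozen=True)
class PhaseLog:
    """Ordered, non-overlapping game phases."""

    phases: tuple[Phase, ...]

    def __post_init__(self) -> None:
        prev_end = -np.inf
        for p in self.phases:
            if p.end <= p.start:
                raise InvalidArgumentError(f"phase {p.name}: end must exceed start")
            if p.start < prev_end:
                raise InvalidArgumentError("phases overlap or are out of order")
            prev_end = p.end

    def containing(self, t: float) -> Phase | None:
        for p in self.phases:
            if p.start <= t < p.end:
                return p
        return None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "phase": [p.name for p in self.phases],
                "start_s": [p.start for p in self.phases],
                "end_s": [p.end for p in self.phases],
            }
        )


@dataclass(frozen=True)
class EventLog:
    """Sparse player-triggered in-game events."""

    times: np.ndarray
    kinds: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        k = np.asarray(self.kinds, dtype=object)
        if len(t) != len(k):
            raise InvalidArgumentError("times and kinds length mismatch")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "kinds", k)

    def __len__(self) -> int:
        return len(self.times)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"time_s": self.times, "kind": self.kinds})


@dataclass(frozen=True)
class ObservationFrame:
    """A half-open time window [start, end) over which features are computed."""

    kind: str  # continuous | reactive-pre | reactive-post
    label: str  # phase name, or event id
    start: float
    end: float
    nominal_duration: float | None = None  # reactive frames: 10 or 30 s

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise InvalidArgumentError("frame end must exceed start")

    @property
    def duration(self) -> float:
        return self.end - self.start


def harmonize_streams(
    pressure: PressureStream,
    annotation: AnnotationTrace,
    ibi: IbiSeries | None = None,
    bpm: BpmSeries | None = None,
    mouse: MouseStream | None = None,
    truth: AnnotationTrace | None = None,
    smooth_window_s: float = 1.0,
    max_clock_skew_s: float = 1.0,
) -> tuple[PressureStream, pd.DataFrame]:
    """Align all streams onto the integer-second grid of the annotation.

    Pressure is smoothed with a centered boxcar spanning one source-rate
    second (window configurable) and sampled at the grid seconds.  BPM and
    IBI columns carry the last value at or before each second; mouse
    columns aggregate clicks and cursor distance per second.  Streams are
    truncated to their common overlap.

    Returns the 1 Hz pressure stream plus the wide harmonized table.
    """
    if len(pressure) == 0 or len(annotation) == 0:
        raise InvalidArgumentError("pressure and annotation streams required")
    grid = np.round(annotation.times).astype(int)
    if np.any(np.abs(annotation.times - grid) > 0.5):
        raise AlignmentError("annotation trace is not on a 1 Hz grid")

    start = max(float(grid[0]), float(np.ceil(pressure.times[0])))
    end = min(float(grid[-1]), float(np.floor(pressure.times[-1])))
    if end - start < -max_clock_skew_s:
        raise AlignmentError("streams do not overlap within clock tolerance")
    sec = np.arange(int(start), int(end) + 1, dtype=float)

    smoothed = _boxcar_smooth(pressure, smooth_window_s)
    idx = np.searchsorted(pressure.times, sec)
    idx = np.clip(idx, 0, len(pressure) - 1)
    # snap to nearest source sample
    left = np.clip(idx - 1, 0, len(pressure) - 1)
    use_left = np.abs(pressure.times[left] - sec) < np.abs(pressure.times[idx] - sec)
    idx = np.where(use_left, left, idx)
    p1hz = PressureStream(sec, smoothed[idx])

    table: dict[str, np.ndarray] = {"time_s": sec}
    for k, lab in enumerate(SENSOR_LABELS):
        name = f"s{lab}" if lab.isdigit() else f"b{lab}"
        table[name] = p1hz.values[:, k]
    if bpm is not None and len(bpm):
        table["bpm"] = _sample_previous(bpm.times, bpm.bpm, sec)
    if ibi is not None and len(ibi):
        table["ibi_ms"] = _sample_previous(ibi.times, ibi.intervals, sec)
    if mouse is not None:
        clicks = np.zeros(len(sec))
        move = np.zeros(len(sec))
        e = mouse.events
        press_t = e.loc[e["event_type"] == "press", "time_s"].to_numpy(dtype=float)
        np.add.at(clicks, _bin_index(press_t, sec), 1)
        moves = e[e["event_type"] == "move"]
        if len(moves) > 1:
            mt = moves["time_s"].to_numpy(dtype=float)
            d = np.hypot(
                np.diff(moves["x_px"].to_numpy(dtype=float)),
                np.diff(moves["y_px"].to_numpy(dtype=float)),
            )
            np.add.at(move, _bin_index(mt[1:], sec), d)
        table["clicks"] = clicks
        table["move_px"] = move
    ann = np.interp(sec, annotation.times, annotation.values)
    table["annotation"] = ann
    if truth is not None and len(truth):
        table["truth"] = np.interp(sec, truth.times, truth.values)
    return p1hz, pd.DataFrame(table)


def _boxcar_smooth(pressure: PressureStream, window_s: float) -> np.ndarray:
    """Centered moving average over one source-rate second per channel."""
    t = pressure.times
    if len(t) < 3:
        return pressure.values
    rate = 1.0 / float(np.median(np.diff(t)))
    w = max(1, int(round(rate * window_s)))
    if w == 1:
        return pressure.values
    kernel = np.ones(w) / w
    pad = w // 2
    out = np.empty_like(pressure.values)
    for k in range(pressure.values.shape[1]):
        padded = np.pad(pressure.values[:, k], pad, mode="edge")
        sm = np.convolve(padded, kernel, mode="same")[pad:pad + len(t)]
        out[:, k] = sm
    return out


def _sample_previous(times: np.ndarray, values: np.ndarray, grid: np.ndarray) -> np.ndarray:
    """Step (last-observation-carried-forward) sampling onto the grid."""
    idx = np.searchsorted(times, grid, side="right") - 1
    idx = np.clip(idx, 0, len(times) - 1)
    return np.asarray(values, dtype=float)[idx]


def _bin_index(t: np.ndarray, sec: np.ndarray) -> np.ndarray:
    idx = np.floor(t - sec[0]).astype(int)
    return np.clip(idx, 0, len(sec) - 1)


def build_frames(
    phases: PhaseLog,
    events: EventLog,
    reactive_durations: Sequence[float] = (10.0, 30.0),
    omit_phases: Iterable[str] = ("Mission-3",),
) -> list[ObservationFrame]:
    """Construct continuous and reactive observation frames.

    One continuous frame per phase (phases in ``omit_phases`` are skipped).
    Each event at time t yields, per duration d, a pre-frame [t−d, t) and a
    post-frame [t, t+d); the event sample itself belongs to the post-frame.
    Reactive frames are clipped to their containing phase; a clipped frame
    shorter than d/2 is dropped (logged).  Events falling outside every
    phase are rejected with a warning.
    """
    omit = set(omit_phases)
    frames: list[ObservationFrame] = [
        ObservationFrame(CONTINUOUS, p.name, p.start, p.end)
        for p in phases.phases
        if p.name not in omit
    ]
    for ev_i, (t, kind) in enumerate(zip(events.times, events.kinds)):
        phase = phases.containing(float(t))
        if phase is None:
            log.warning("event %s at t=%.1f outside all phases: rejected", kind, t)
            continue
        if phase.name in omit:
            log.info("event at t=%.1f in omitted phase %s: skipped", t, phase.name)
            continue
        for d in reactive_durations:
            for fk, lo, hi in (
                (REACTIVE_PRE, t - d, t),
                (REACTIVE_POST, t, t + d),
            ):
                clipped_lo = max(lo, phase.start)
                clipped_hi = min(hi, phase.end)
                if clipped_hi - clipped_lo < d / 2.0:
                    log.info(
                        "reactive frame [%.1f, %.1f) clipped below %.1f s: dropped",
                        lo, hi, d / 2.0,
                    )
                    continue
                frames.append(
                    ObservationFrame(
                        fk,
                        f"event{ev_i}:{kind}",
                        clipped_lo,
                        clipped_hi,
                        nominal_duration=float(d),
                    )
                )
    return frames
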