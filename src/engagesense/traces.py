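"""Engagement annotation traces and mouse-interaction features.

Players annotate their perceived engagement continuously (one mouse-wheel
sample per second) while replaying their session; the raw, unbounded trace
is normalized to [0, 1] with the min and max of that individual trace.
Four statistical features are extracted per observation frame — mean μA,
duration-normalized trapezoidal area ∫A, amplitude Â (max − min), and the
signed average gradient ΔA — alongside two in-game interaction features:
average clicks per second μMc and cursor distance travelled per second μMm.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import InvalidArgumentError, UndefinedFeatureError

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class AnnotationTrace:
    """Per-second perceived-engagement values."""

    times: np.ndarray
    values: np.ndarray
    normalized: bool = False

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        v = np.asarray(self.values, dtype=float)
        if len(t) != len(v):
            raise InvalidArgumentError("times and values length mismatch")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "values", v)

    def __len__(self) -> int:
        return len(self.times)

    def slice(self, start: float, end: float) -> "AnnotationTrace":
        m = (self.times >= start) & (self.times < end)
        return AnnotationTrace(self.times[m], self.values[m], self.normalized)


def normalize_trace(raw: AnnotationTrace) -> AnnotationTrace:
    """Rescale a whole-session trace to [0, 1] by its own min and max.

    A constant trace maps to 0.5 everywhere (degenerate range); this keeps
    μA defined without poisoning downstream sign analysis, and is logged.
    """
    if len(raw) == 0:
        raise InvalidArgumentError("empty annotation trace")
    lo, hi = float(raw.values.min()), float(raw.values.max())
    if hi == lo:
        log.warning("constant annotation trace: normalizing to 0.5")
        vals = np.full_like(raw.values, 0.5)
    else:
        vals = (raw.values - lo) / (hi - lo)
    return AnnotationTrace(raw.times, vals, normalized=True)


@dataclass(frozen=True)
class AnnotationFeatures:
    mean: float  # μA
    area: float  # ∫A, trapezoidal integral / span
    amplitude: float  # Â = max − min
    gradient: float  # ΔA, mean signed successive difference per second


def annotation_features(trace: AnnotationTrace, frame) -> AnnotationFeatures:
    """μA, ∫A, Â, ΔA of the trace samples inside one frame.

    ∫A integrates with the composite trapezoid rule and divides by the
    span of the integrated samples, so a trace bounded in [0, 1] yields
    ∫A in [0, 1].  ΔA is the mean *signed* successive difference — a
    reversed trace flips its sign.
    """
    sub = trace.slice(frame.start, frame.end)
    if len(sub) < 2:
        raise UndefinedFeatureError("frame has fewer than 2 annotation samples")
    t, v = sub.times, sub.values
    span = t[-1] - t[0]
    return AnnotationFeatures(
        mean=float(v.mean()),
        area=float(np.trapezoid(v, t) / span),
        amplitude=float(v.max() - v.min()),
        gradient=float(np.mean(np.diff(v) / np.diff(t))),
    )


@dataclass(frozen=True)
class MouseStream:
    """Mouse telemetry: press/release click events and cursor positions.

    ``events`` has columns time_s, event_type ∈ {move, press, release},
    x_px, y_px.  Click duration and idleness are carried by the raw events
    but not featurized.
    """

    events: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"time_s", "event_type", "x_px", "y_px"}
        if not required.issubset(self.events.columns):
            raise InvalidArgumentError(f"mouse events need columns {sorted(required)}")

    def slice(self, start: float, end: float) -> "MouseStream":
        e = self.events
        return MouseStream(
            e[(e["time_s"] >= start) & (e["time_s"] < end)].reset_index(drop=True)
        )


@dataclass(frozen=True)
class MouseFeatures:
    clicks_per_second: float  # μMc, 1/s
    movement: float  # μMm, px/s


def mouse_features(mouse: MouseStream, frame) -> MouseFeatures:
    """μMc and μMm within one frame (normalized by frame duration)."""
    duration = frame.end - frame.start
    if duration <= 0:
        raise InvalidArgumentError("frame duration must be positive")
    sub = mouse.slice(frame.start, frame.end).events
    clicks = int((sub["event_type"] == "press").sum())
    moves = sub[sub["event_type"] == "move"]
    if len(moves) == 0:
        warnings.warn("no cursor samples in frame; movement set to 0", stacklevel=2)
        dist = 0.0
    else:
        dx = np.diff(moves["x_px"].to_numpy(dtype=float))
        dy = np.diff(moves["y_px"].to_numpy(dtype=float))
        dist = float(np.hypot(dx, dy).sum())
    return MouseFeatures(clicks_per_second=clicks / duration, movement=dist / duration)
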