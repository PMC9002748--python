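"""Inter-beat-interval cleaning and ultra-short heart-rate features.

A PPG ear-lobe sensor reports inter-beat intervals (IBI, ms) and beats per
minute.  IBIs are cleaned of ectopic beats and outliers with a
bounded-range plus successive-relative-deviation rule, then two features
are computed per observation frame: the BPM amplitude Ĥ (max − min heart
rate) and σH, the sample standard deviation of the IBIs.  Frames of 10 s
and 30 s follow ultra-short HRV practice: no detrending, no interpolation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .errors import EmptyOutputError, InvalidArgumentError, UndefinedFeatureError


@dataclass(frozen=True)
class IbiSeries:
    """Inter-beat intervals in ms, stamped with the beat time in seconds."""

    times: np.ndarray
    intervals: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        v = np.asarray(self.intervals, dtype=float)
        if len(t) != len(v):
            raise InvalidArgumentError("times and intervals length mismatch")
        if np.any(v <= 0):
            raise InvalidArgumentError("inter-beat intervals must be positive")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "intervals", v)

    def __len__(self) -> int:
        return len(self.times)

    def slice(self, start: float, end: float) -> "IbiSeries":
        m = (self.times >= start) & (self.times < end)
        return IbiSeries(self.times[m], self.intervals[m])


@dataclass(frozen=True)
class BpmSeries:
    """Beats-per-minute values, one per detected beat."""

    times: np.ndarray
    bpm: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        v = np.asarray(self.bpm, dtype=float)
        if len(t) != len(v):
            raise InvalidArgumentError("times and bpm length mismatch")
        if np.any(v <= 0):
            raise InvalidArgumentError("bpm must be positive")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "bpm", v)

    def __len__(self) -> int:
        return len(self.times)

    def slice(self, start: float, end: float) -> "BpmSeries":
        m = (self.times >= start) & (self.times < end)
        return BpmSeries(self.times[m], self.bpm[m])


@dataclass(frozen=True)
class HeartFeatures:
    bpm_amplitude: float  # Ĥ, bpm
    ibi_sd: float  # σH, ms


def clean_ibi(
    raw: IbiSeries,
    rel_tol: float = 0.2,
    bounds: tuple[float, float] = (300.0, 2000.0),
) -> IbiSeries:
    """Remove ectopic beats and outliers from an IBI series.

    An interval is rejected when it falls outside ``bounds`` (ms) or when
    it deviates by more than ``rel_tol`` (fraction) from the last accepted
    interval.  Order is preserved; the rule is idempotent because the
    reference is always the last *accepted* interval.
    """
    if len(raw) == 0:
        raise InvalidArgumentError("empty IBI series")
    lo, hi = bounds
    keep = np.zeros(len(raw), dtype=bool)
    last: float | None = None
    for i, x in enumerate(raw.intervals):
        if x < lo or x > hi:
            continue
        if last is not None and abs(x - last) > rel_tol * last:
            continue
        keep[i] = True
        last = x
    if not keep.any():
        raise EmptyOutputError("all inter-beat intervals rejected")
    return IbiSeries(raw.times[keep], raw.intervals[keep])


def bpm_from_ibi(ibi: IbiSeries) -> BpmSeries:
    """Instantaneous heart rate (60000 / IBI) at each accepted beat."""
    return BpmSeries(ibi.times, 60000.0 / ibi.intervals)


def heart_features(ibi: IbiSeries, bpm: BpmSeries, frame) -> HeartFeatures:
    """Ĥ and σH within one observation frame.

    Beats belong to the frame containing their timestamp (half-open
    [start, end)).  σH uses the n−1 (sample) denominator.
    """
    b = bpm.slice(frame.start, frame.end)
    v = ibi.slice(frame.start, frame.end)
    if len(b) < 2 or len(v) < 2:
        raise UndefinedFeatureError("frame has fewer than 2 heart samples")
    return HeartFeatures(
        bpm_amplitude=float(b.bpm.max() - b.bpm.min()),
        ibi_sd=float(np.std(v.intervals, ddof=1)),
    )


def _warn(msg: str) -> None:
    warnings.warn(msg, stacklevel=3)
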