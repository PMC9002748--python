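"""Study configuration: YAML-loadable settings for end-to-end runs."""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .errors import ConfigurationError
from .synthetic import CalibrationConfig, CouplingConfig, NoiseConfig, SessionConfig


@dataclass
class StudyConfig:
    """Everything a full analysis run needs.

    ``threshold`` is either a numeric activation threshold in mV or the
    string ``"calibrate"``, in which case the threshold is selected from
    calibration sessions.  ``min_mission3`` is the minimum number of
    participants that must reach Mission-3 for its frames to enter the
    analysis (below it, the phase is omitted).
    """

    mode: str = "synthetic"  # synthetic | csv-dir
    input_dir: str | None = None  # csv-dir mode: per-participant bundles
    session: SessionConfig = field(default_factory=SessionConfig)
    calibration: CalibrationConfig = field(default_factory=CalibrationConfig)
    threshold: float | str = "calibrate"
    clarity: float = 0.05  # relative-change clarity threshold
    reactive_durations: tuple[float, ...] = (10.0, 30.0)
    min_mission3: int = 4
    include_transition_rate: bool = False  # re-admit μΤ into the c^z analysis
    multiple_testing: str | None = None  # e.g. "fdr_bh"; None mirrors the study
    output_dir: str = "results"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mode not in ("synthetic", "csv-dir"):
            raise ConfigurationError(f"unknown mode {self.mode!r}")
        if self.mode == "csv-dir" and not self.input_dir:
            raise ConfigurationError("csv-dir mode requires input_dir")
        if isinstance(self.threshold, (int, float)) and self.threshold <= 0:
            raise ConfigurationError("numeric threshold must be positive")
        if isinstance(self.threshold, str) and self.threshold != "calibrate":
            raise ConfigurationError("threshold must be numeric or 'calibrate'")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, data: dict) -> "StudyConfig":
        data = dict(data)
        if "session" in data and isinstance(data["session"], dict):
            s = dict(data["session"])
            if isinstance(s.get("coupling"), dict):
                s["coupling"] = CouplingConfig(**s["coupling"])
            if isinstance(s.get("noise"), dict):
                s["noise"] = NoiseConfig(**s["noise"])
            for key in ("active_mv", "inactive_mv"):
                if key in s:
                    s[key] = tuple(s[key])
            data["session"] = SessionConfig(**s)
        if "calibration" in data and isinstance(data["calibration"], dict):
            c = dict(data["calibration"])
            for key in ("active_mv", "inactive_mv"):
                if key in c:
                    c[key] = tuple(c[key])
            data["calibration"] = CalibrationConfig(**c)
        if "reactive_durations" in data:
            data["reactive_durations"] = tuple(data["reactive_durations"])
        return cls(**data)

    @classmethod
    def from_yaml(cls, path: Path | str) -> "StudyConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)
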