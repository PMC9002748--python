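"""CSV serialization of all session streams.

One directory per participant (``p00``, ``p01``, ...), one file per
stream, plain uncompressed CSV:

==============  ==========================================
pressure.csv    time_s, s1..s8, ba..bd (mV)
ibi.csv         time_s, ibi_ms
bpm.csv         time_s, bpm
mouse.csv       time_s, event_type(move|press|release), x_px, y_px
phases.csv      phase, start_s, end_s
events.csv      time_s, kind
annotation.csv  time_s, value
truth.csv       time_s, value   (synthetic sessions only)
==============  ==========================================

Floats are written with pandas' default repr formatting and parsed back
with round-trip precision, so a written-and-reread bundle reproduces the
analysis bitwise.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .biosignals import BpmSeries, IbiSeries
from .chair import SENSOR_LABELS, PatternTable, PressureStream
from .errors import InvalidArgumentError
from .framing import EventLog, Phase, PhaseLog
from .synthetic import SessionBundle
from .traces import AnnotationTrace, MouseStream

PRESSURE_COLUMNS = ["time_s"] + [
    f"s{lab}" if lab.isdigit() else f"b{lab}" for lab in SENSOR_LABELS
]


def write_pressure(stream: PressureStream, path: Path) -> None:
    stream.to_frame().to_csv(path, index=False)


def read_pressure(path: Path) -> PressureStream:
    df = pd.read_csv(path, float_precision="round_trip")
    missing = set(PRESSURE_COLUMNS) - set(df.columns)
    if missing:
        raise InvalidArgumentError(f"{path}: missing columns {sorted(missing)}")
    return PressureStream(
        df["time_s"].to_numpy(float), df[PRESSURE_COLUMNS[1:]].to_numpy(float)
    )


def write_ibi(series: IbiSeries, path: Path) -> None:
    pd.DataFrame({"time_s": series.times, "ibi_ms": series.intervals}).to_csv(
        path, index=False
    )


def read_ibi(path: Path) -> IbiSeries:
    df = pd.read_csv(path, float_precision="round_trip")
    return IbiSeries(df["time_s"].to_numpy(float), df["ibi_ms"].to_numpy(float))


def write_bpm(series: BpmSeries, path: Path) -> None:
    pd.DataFrame({"time_s": series.times, "bpm": series.bpm}).to_csv(path, index=False)


def read_bpm(path: Path) -> BpmSeries:
    df = pd.read_csv(path, float_precision="round_trip")
    return BpmSeries(df["time_s"].to_numpy(float), df["bpm"].to_numpy(float))


def write_mouse(stream: MouseStream, path: Path) -> None:
    stream.events.to_csv(path, index=False)


def read_mouse(path: Path) -> MouseStream:
    return MouseStream(pd.read_csv(path, float_precision="round_trip"))


def write_annotation(trace: AnnotationTrace, path: Path) -> None:
    pd.DataFrame({"time_s": trace.times, "value": trace.values}).to_csv(
        path, index=False
    )


def read_annotation(path: Path) -> AnnotationTrace:
    df = pd.read_csv(path, float_precision="round_trip")
    return AnnotationTrace(df["time_s"].to_numpy(float), df["value"].to_numpy(float))


def write_phases(log: PhaseLog, path: Path) -> None:
    log.to_frame().to_csv(path, index=False)


def read_phases(path: Path) -> PhaseLog:
    df = pd.read_csv(path, float_precision="round_trip")
    return PhaseLog(
        tuple(
            Phase(str(r.phase), float(r.start_s), float(r.end_s))
            for r in df.itertuples()
        )
    )


def write_events(log: EventLog, path: Path) -> None:
    log.to_frame().to_csv(path, index=False)


def read_events(path: Path) -> EventLog:
    df = pd.read_csv(path, float_precision="round_trip")
    if len(df) == 0:
        return EventLog(np.array([]), np.array([], dtype=object))
    return EventLog(df["time_s"].to_numpy(float), df["kind"].to_numpy(object))


_STREAM_FILES = {
    "pressure": "pressure.csv",
    "ibi": "ibi.csv",
    "bpm": "bpm.csv",
    "mouse": "mouse.csv",
    "phases": "phases.csv",
    "events": "events.csv",
    "annotation": "annotation.csv",
}


def write_bundle(bundle: SessionBundle, directory: Path) -> Path:
    """Write one participant's streams under ``directory/pNN``."""
    d = Path(directory) / f"p{bundle.participant:02d}"
    d.mkdir(parents=True, exist_ok=True)
    write_pressure(bundle.pressure, d / "pressure.csv")
    write_ibi(bundle.ibi, d / "ibi.csv")
    write_bpm(bundle.bpm, d / "bpm.csv")
    write_mouse(bundle.mouse, d / "mouse.csv")
    write_phases(bundle.phases, d / "phases.csv")
    write_events(bundle.events, d / "events.csv")
    write_annotation(bundle.annotation, d / "annotation.csv")
    if bundle.truth is not None:
        write_annotation(bundle.truth, d / "truth.csv")
    return d


def read_bundle(directory: Path, participant: int) -> SessionBundle:
    """Read one participant's bundle; raises naming the missing stream."""
    d = Path(directory) / f"p{participant:02d}"
    for stream, fname in _STREAM_FILES.items():
        if not (d / fname).exists():
            raise InvalidArgumentError(
                f"participant p{participant:02d}: missing stream file {fname}"
            )
    truth_path = d / "truth.csv"
    return SessionBundle(
        participant=participant,
        pressure=read_pressure(d / "pressure.csv"),
        ibi=read_ibi(d / "ibi.csv"),
        bpm=read_bpm(d / "bpm.csv"),
        mouse=read_mouse(d / "mouse.csv"),
        phases=read_phases(d / "phases.csv"),
        events=read_events(d / "events.csv"),
        annotation=read_annotation(d / "annotation.csv"),
        truth=read_annotation(truth_path) if truth_path.exists() else None,
    )


def list_participants(directory: Path) -> list[int]:
    """Participant indices present as ``pNN`` subdirectories."""
    out = []
    for d in sorted(Path(directory).glob("p[0-9][0-9]")):
        if d.is_dir():
            out.append(int(d.name[1:]))
    return out


def read_pattern_table(path: Path) -> PatternTable:
    """Pattern table from YAML: an ordered list of one-entry mappings."""
    with open(path) as fh:
        data = yaml.safe_load(fh)
    return PatternTable.from_mapping(data)
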