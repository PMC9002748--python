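"""Synthetic calibration and play sessions for the engagement pipeline.

No public dataset exists for the seated serious-game study this package
analyses, so every downstream stage is exercised against generated
sessions that carry the statistical structure the analysis assumes:

* a latent per-second engagement level, piecewise-smooth around per-phase
  means (Tutorial < Gameplay), with AR(1) jitter whose scale grows with
  the level and a transient exponential bump after each in-game event;
* sitting postures whose backrest use decreases — and switching rate
  increases — with engagement (for positive couplings);
* heart-rate amplitude, mouse click rate, and cursor speed that scale
  with engagement through per-channel coupling strengths;
* a 1 Hz annotation trace equal to the latent engagement plus Gaussian
  noise, quantized to mouse-wheel ticks;
* sparse player-triggered events confined to Gameplay/Mission-2 and
  spaced at least 60 s apart (twice the longest reactive-frame duration)
  so reactive frames of distinct events never overlap.

All randomness flows from one seed through a splittable ``SeedSequence``,
one stream per participant: the same seed reproduces a session bitwise,
different participant indices give independent streams.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import networkx as nx
import numpy as np
import pandas as pd

from .biosignals import BpmSeries, IbiSeries
from .chair import SENSOR_LABELS, PostureSeries, PressureStream
from .errors import InvalidArgumentError
from .framing import EVENT_KINDS, EventLog, Phase, PhaseLog
from .traces import AnnotationTrace, MouseStream

#: Sensor sets a compliant sitter activates in each displayed posture.
#: Each set identifies uniquely under the default pattern precedence.
CANONICAL_ACTIVATIONS: dict[str, frozenset[str]] = {
    "P1": frozenset({"3", "4", "a", "b"}),
    "P2": frozenset({"2", "3", "4", "7", "8"}),
    "P3": frozenset({"3", "4"}),
    "P4": frozenset({"3", "4", "c"}),
    "P5": frozenset({"2", "3", "7", "a", "c"}),
    "P6": frozenset({"2", "3", "7", "b", "d"}),
}

BACKREST_POSTURES = ("P1", "P4", "P5", "P6")
FRONT_POSTURES = ("P2", "P3")
_BACK_WEIGHTS = (0.55, 0.20, 0.15, 0.10)
_FRONT_WEIGHTS = (0.97, 0.03)  # front sitting without backrest dominates

SCREEN_W, SCREEN_H = 1920.0, 1080.0


@dataclass(frozen=True)
class CalibrationConfig:
    """Parameters of the activation-threshold calibration experiment."""

    n_participants: int = 6
    dwell: float = 10.0  # seconds each displayed posture is held
    sample_rate: float = 1.0  # Hz
    active_mv: tuple[float, float] = (150.0, 30.0)  # mean, sd
    inactive_mv: tuple[float, float] = (10.0, 5.0)
    n_postures: int = 6
    seed: int = 0

    def __post_init__(self) -> None:
        if self.dwell <= 0 or self.sample_rate <= 0:
            raise InvalidArgumentError("dwell and sample_rate must be positive")
        if self.active_mv[0] <= self.inactive_mv[0]:
            raise InvalidArgumentError("active mean must exceed inactive mean")


@dataclass(frozen=True)
class CouplingConfig:
    """Per-channel strength in [−1, 1] linking latent engagement to signals."""

    posture: float = 0.8  # + → less backrest use when engaged
    mobility: float = 0.8  # + → more posture switching when engaged
    heart: float = 0.8  # + → larger BPM swings when engaged
    mouse: float = 0.8  # + → more clicks / faster cursor when engaged

    def validate(self) -> None:
        for name in ("posture", "mobility", "heart", "mouse"):
            if not -1 <= getattr(self, name) <= 1:
                raise InvalidArgumentError(f"coupling.{name} outside [-1, 1]")

    def all_zero(self) -> "CouplingConfig":
        return CouplingConfig(0.0, 0.0, 0.0, 0.0)


@dataclass(frozen=True)
class NoiseConfig:
    annotation: float = 0.02  # sd added to latent engagement, [0,1] units
    engagement_jitter: float = 0.05  # AR(1) innovation scale
    ibi_ms: float = 5.0  # beat-timing jitter, ms
    artifact_prob: float = 0.01  # ectopic / missed-beat probability per beat


@dataclass(frozen=True)
class SessionConfig:
    """Study conditions for one synthetic cohort."""

    n_participants: int = 26
    phase_durations: dict = field(
        default_factory=lambda: {
            "Tutorial": 180.0,
            "Gameplay": 300.0,
            "Review": 90.0,
            "Mission-2": 240.0,
        }
    )
    engagement_levels: dict = field(
        default_factory=lambda: {
            "Tutorial": 0.30,
            "Gameplay": 0.70,
            "Review": 0.45,
            "Mission-2": 0.65,
        }
    )
    coupling: CouplingConfig = field(default_factory=CouplingConfig)
    noise: NoiseConfig = field(default_factory=NoiseConfig)
    event_rate: float = 0.6  # expected events per minute of Gameplay
    event_min_spacing: float = 60.0  # s; ≥ 2× max reactive duration keeps frames disjoint
    event_bump: float = 0.20  # engagement bump height after an event
    bump_tau: float = 10.0  # s, exponential decay constant
    mission2_fraction: float = 14.0 / 26.0  # share of players reaching Mission-2
    pressure_rate: float = 25.0  # Hz, raw chair-sensor sampling
    active_mv: tuple[float, float] = (150.0, 30.0)
    inactive_mv: tuple[float, float] = (10.0, 5.0)
    ar_rho: float = 0.95  # AR(1) persistence of the engagement jitter
    base_switch: float = 0.03  # posture switch probability per second
    bpm_base: float = 70.0
    bpm_level_gain: float = 4.0  # bpm shift for full engagement swing
    bpm_amp_base: float = 3.0  # engagement-independent oscillation amplitude, bpm
    bpm_amp_max: float = 8.0  # additional oscillation amplitude at e = 1
    bpm_osc_period: float = 25.0  # s
    click_rate: float = 0.3  # baseline clicks per second
    move_speed: float = 120.0  # baseline cursor speed scale, px/s
    seed: int = 0

    def __post_init__(self) -> None:
        for name, d in self.phase_durations.items():
            if d <= 0:
                raise InvalidArgumentError(f"duration of {name} must be positive")
        for name, e in self.engagement_levels.items():
            if not 0 <= e <= 1:
                raise InvalidArgumentError(f"engagement level of {name} outside [0,1]")
        if self.event_rate < 0:
            raise InvalidArgumentError("event_rate must be non-negative")
        self.coupling.validate()


@dataclass(frozen=True)
class SessionBundle:
    """All raw streams of one participant's synthetic playthrough."""

    participant: int
    pressure: PressureStream
    ibi: IbiSeries
    bpm: BpmSeries
    mouse: MouseStream
    phases: PhaseLog
    events: EventLog
    annotation: AnnotationTrace
    truth: AnnotationTrace  # latent engagement, one value per second


def transition_cover_sequence(
    n_postures: int, seed: int | np.random.Generator = 0
) -> list[str]:
    """Posture display order covering every ordered transition exactly once.

    The complete digraph on n postures is Eulerian (in-degree equals
    out-degree at every node), so a circuit traversing each of the
    n·(n−1) ordered pairs exactly once exists; its vertex sequence has
    length n·(n−1)+1.  Edge insertion order and the start node are
    shuffled by the seed.
    """
    if n_postures < 2:
        raise InvalidArgumentError("need at least 2 postures")
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    edges = [(i, j) for i in range(n_postures) for j in range(n_postures) if i != j]
    order = rng.permutation(len(edges))
    g = nx.DiGraph()
    g.add_nodes_from(range(n_postures))
    g.add_edges_from(edges[k] for k in order)
    start = int(rng.integers(n_postures))
    circuit = list(nx.eulerian_circuit(g, source=start))
    nodes = [circuit[0][0]] + [v for _, v in circuit]
    return [f"P{i + 1}" for i in nodes]


def generate_calibration_session(
    config: CalibrationConfig, participant_index: int = 0
) -> tuple[PressureStream, PostureSeries]:
    """One participant's calibration recording plus the displayed schedule.

    Sensors in the displayed posture's canonical activation set emit
    active-level noise, all others inactive-level noise; outputs are
    clipped at 0 mV.
    """
    ss = np.random.SeedSequence([config.seed, 1000 + participant_index])
    rng = np.random.default_rng(ss)
    schedule = transition_cover_sequence(config.n_postures, rng)
    per = int(round(config.dwell * config.sample_rate))
    labels = np.repeat(schedule, per)
    n = len(labels)
    times = np.arange(n) / config.sample_rate
    values = rng.normal(
        config.inactive_mv[0], config.inactive_mv[1], size=(n, len(SENSOR_LABELS))
    )
    active_draw = rng.normal(config.active_mv[0], config.active_mv[1], size=(n, len(SENSOR_LABELS)))
    for posture, active_set in CANONICAL_ACTIVATIONS.items():
        rows = labels == posture
        for k, lab in enumerate(SENSOR_LABELS):
            if lab in active_set:
                values[rows, k] = active_draw[rows, k]
    values = np.clip(values, 0.0, None)
    return PressureStream(times, values), PostureSeries(times, labels)


def generate_calibration_cohort(
    config: CalibrationConfig,
) -> list[tuple[PressureStream, PostureSeries]]:
    """All calibration participants' sessions."""
    return [
        generate_calibration_session(config, i) for i in range(config.n_participants)
    ]


def _phase_log(config: SessionConfig, rng: np.random.Generator, plays_m2: bool) -> PhaseLog:
    names = ["Tutorial", "Gameplay", "Review"] + (["Mission-2"] if plays_m2 else [])
    t = 0.0
    phases = []
    for name in names:
        d = float(np.round(config.phase_durations[name] * rng.normal(1.0, 0.05)))
        d = max(30.0, d)
        phases.append(Phase(name, t, t + d))
        t += d
    return PhaseLog(tuple(phases))


def _draw_events(
    config: SessionConfig, rng: np.random.Generator, phases: PhaseLog
) -> EventLog:
    """Poisson events in Gameplay/Mission-2, thinned to a minimum spacing."""
    times: list[float] = []
    kinds: list[str] = []
    rate = config.event_rate / 60.0
    for p in phases.phases:
        if p.name not in ("Gameplay", "Mission-2"):
            continue
        n = rng.poisson(rate * (p.end - p.start))
        cand = np.sort(rng.uniform(p.start, p.end, size=n))
        for t in cand:
            if times and t - times[-1] < config.event_min_spacing:
                continue
            times.append(float(t))
            kinds.append(EVENT_KINDS[int(rng.integers(len(EVENT_KINDS)))])
    return EventLog(np.array(times), np.array(kinds, dtype=object))


def _latent_engagement(
    config: SessionConfig,
    rng: np.random.Generator,
    phases: PhaseLog,
    events: EventLog,
) -> np.ndarray:
    """Per-second latent engagement: phase mean + level-scaled AR(1) + bumps."""
    total = int(phases.phases[-1].end)
    sec = np.arange(total, dtype=float)
    means = np.zeros(total)
    for p in phases.phases:
        m = (sec >= p.start) & (sec < p.end)
        means[m] = config.engagement_levels[p.name]
    jitter = np.zeros(total)
    x = 0.0
    rho = config.ar_rho
    innov = rng.normal(size=total)
    for t in range(total):
        sd = config.noise.engagement_jitter * (0.4 + 1.2 * means[t])
        x = rho * x + np.sqrt(1 - rho**2) * sd * innov[t]
        jitter[t] = x
    bump = np.zeros(total)
    for te in events.times:
        after = sec >= te
        bump[after] += config.event_bump * np.exp(-(sec[after] - te) / config.bump_tau)
    return np.clip(means + jitter + bump, 0.0, 1.0)


def _posture_walk(
    config: SessionConfig, rng: np.random.Generator, e: np.ndarray
) -> np.ndarray:
    """Per-second posture labels following the engagement-coupled walk."""
    c = config.coupling
    total = len(e)
    labels = np.empty(total, dtype=object)

    def draw_posture(et: float) -> str:
        p_back = float(np.clip(0.5 - c.posture * (et - 0.5), 0.05, 0.95))
        if rng.random() < p_back:
            return str(rng.choice(BACKREST_POSTURES, p=_BACK_WEIGHTS))
        return str(rng.choice(FRONT_POSTURES, p=_FRONT_WEIGHTS))

    current = draw_posture(e[0])
    for t in range(total):
        p_switch = float(
            np.clip(config.base_switch * (1 + c.mobility * 2 * (e[t] - 0.5)), 1e-3, 0.5)
        )
        if t > 0 and rng.random() < p_switch:
            nxt = draw_posture(e[t])
            if nxt == current:  # a switch must change the label
                others = [q for q in BACKREST_POSTURES + FRONT_POSTURES if q != current]
                nxt = str(rng.choice(others))
            current = nxt
        labels[t] = current
    return labels


def _pressure_from_postures(
    config: SessionConfig, rng: np.random.Generator, labels: np.ndarray
) -> PressureStream:
    rate = config.pressure_rate
    total = len(labels)
    n = int(total * rate)
    times = np.arange(n) / rate
    sec_idx = np.minimum(np.floor(times).astype(int), total - 1)
    values = rng.normal(config.inactive_mv[0], config.inactive_mv[1], size=(n, 12))
    active_draw = rng.normal(config.active_mv[0], config.active_mv[1], size=(n, 12))
    active_mask = np.zeros((n, 12), dtype=bool)
    for posture, active_set in CANONICAL_ACTIVATIONS.items():
        rows = labels[sec_idx] == posture
        for k, lab in enumerate(SENSOR_LABELS):
            if lab in active_set:
                active_mask[rows, k] = True
    values[active_mask] = active_draw[active_mask]
    return PressureStream(times, np.clip(values, 0.0, None))


def _heart_streams(
    config: SessionConfig, rng: np.random.Generator, e: np.ndarray
) -> tuple[IbiSeries, BpmSeries]:
    """Beat-by-beat IBIs with level- and amplitude-coupled heart rate.

    The instantaneous rate carries a slow respiratory-style oscillation
    with a baseline amplitude plus an engagement-scaled component, so
    higher engagement widens the within-frame BPM swing while the
    baseline swing saturates within one oscillation period regardless of
    frame length.  A small fraction of reported intervals are corrupted
    (halved or stretched) to emulate ectopic/missed beats for the
    cleaning stage.
    """
    c = config.coupling.heart
    total = len(e)
    t = 0.0
    times: list[float] = []
    ibis: list[float] = []
    while t < total - 1:
        et = e[min(int(t), total - 1)]
        amp = config.bpm_amp_base + c * config.bpm_amp_max * et
        bpm_inst = (
            config.bpm_base
            + c * config.bpm_level_gain * (et - 0.5) * 2
            + amp * np.sin(2 * np.pi * t / config.bpm_osc_period)
        )
        ibi_s = 60.0 / max(bpm_inst, 30.0)
        t += ibi_s
        ibi_ms = ibi_s * 1000.0 + rng.normal(0.0, config.noise.ibi_ms)
        u = rng.random()
        if u < config.noise.artifact_prob / 2:
            ibi_ms *= 0.5  # ectopic (premature) beat
        elif u < config.noise.artifact_prob:
            ibi_ms *= 1.8  # missed beat
        times.append(t)
        ibis.append(max(ibi_ms, 1.0))
    ibi = IbiSeries(np.array(times), np.array(ibis))
    return ibi, BpmSeries(ibi.times, 60000.0 / ibi.intervals)


def _mouse_stream(
    config: SessionConfig, rng: np.random.Generator, e: np.ndarray
) -> MouseStream:
    c = config.coupling.mouse
    total = len(e)
    rows = []
    x, y = SCREEN_W / 2, SCREEN_H / 2
    for t in range(total):
        gain = max(0.0, 1 + c * 2 * (e[t] - 0.5))
        n_clicks = rng.poisson(config.click_rate * gain)
        for dt in np.sort(rng.uniform(0, 1, size=n_clicks)):
            press = t + float(dt)
            rows.append((press, "press", x, y))
            rows.append((press + float(rng.exponential(0.1)), "release", x, y))
        step = abs(rng.normal(0.0, config.move_speed * gain))
        ang = rng.uniform(0, 2 * np.pi)
        x = float(np.clip(x + step * np.cos(ang), 0, SCREEN_W))
        y = float(np.clip(y + step * np.sin(ang), 0, SCREEN_H))
        rows.append((float(t), "move", x, y))
    df = pd.DataFrame(rows, columns=["time_s", "event_type", "x_px", "y_px"])
    df = df.sort_values("time_s", kind="stable").reset_index(drop=True)
    return MouseStream(df)


def _annotation(
    config: SessionConfig, rng: np.random.Generator, e: np.ndarray
) -> AnnotationTrace:
    """Noisy, wheel-quantized annotation of the latent engagement."""
    total = len(e)
    raw = e + rng.normal(0.0, config.noise.annotation, size=total)
    ticks = np.round(raw * 50.0)  # mouse-wheel granularity
    return AnnotationTrace(np.arange(total, dtype=float), ticks)


def generate_play_session(config: SessionConfig, participant_index: int) -> SessionBundle:
    """Generate one participant's full synthetic playthrough."""
    ss = np.random.SeedSequence([config.seed, participant_index])
    rng = np.random.default_rng(ss)
    plays_m2 = rng.random() < config.mission2_fraction
    phases = _phase_log(config, rng, plays_m2)
    events = _draw_events(config, rng, phases)
    e = _latent_engagement(config, rng, phases, events)
    labels = _posture_walk(config, rng, e)
    pressure = _pressure_from_postures(config, rng, labels)
    ibi, bpm = _heart_streams(config, rng, e)
    mouse = _mouse_stream(config, rng, e)
    annotation = _annotation(config, rng, e)
    truth = AnnotationTrace(np.arange(len(e), dtype=float), e)
    return SessionBundle(
        participant=participant_index,
        pressure=pressure,
        ibi=ibi,
        bpm=bpm,
        mouse=mouse,
        phases=phases,
        events=events,
        annotation=annotation,
        truth=truth,
    )


def generate_cohort(config: SessionConfig) -> list[SessionBundle]:
    """All participants' sessions for one study run."""
    return [
        generate_play_session(config, i) for i in range(config.n_participants)
    ]


def null_config(config: SessionConfig) -> SessionConfig:
    """Copy of a config with every engagement coupling set to zero."""
    return replace(config, coupling=config.coupling.all_zero())
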