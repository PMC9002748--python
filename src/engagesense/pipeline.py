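"""End-to-end study runs: harmonize → classify → frame → featurize → fuse.

``run_study`` executes the whole analysis for a cohort of sessions —
synthetic or read from per-participant CSV bundles — and returns a
:class:`StudyReport` whose tables mirror the study's result layout:
posture distributions and transition contingency tables per frame type,
annotation-feature summaries, Wilcoxon phase contrasts, and the c^z
agreement table with the majority-vote multimodal feature V.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats as sps

from . import __version__
from .biosignals import bpm_from_ibi, clean_ibi, heart_features
from .chair import (
    ALL_POSTURE_STATES,
    CalibrationResult,
    PatternTable,
    PostureSeries,
    calibrate_threshold,
    classify_stream,
    posture_features,
    transition_contingency,
)
from .config import StudyConfig
from .errors import ConfigurationError, UndefinedFeatureError
from .framing import CONTINUOUS, EventLog, ObservationFrame, build_frames, harmonize_streams
from .io import list_participants, read_bundle, write_bundle
from .stats import (
    HIGHLY_SIGNIFICANT,
    NOT_SIGNIFICANT,
    SIGNIFICANT,
    agreement_table,
    majority_vote,
    sign_series,
    wilcoxon_signed_rank,
)
from .synthetic import (
    BACKREST_POSTURES,
    SessionBundle,
    generate_calibration_cohort,
    generate_cohort,
)
from .traces import annotation_features, mouse_features, normalize_trace

log = logging.getLogger(__name__)

ANNOTATION_FEATURES = ["muA", "intA", "ampA", "dA"]
PRIMARY_FEATURES = ["muMc", "muMm", "muT", "dT", "ampH", "sdH"]
PHASE_ORDER = ["Tutorial", "Gameplay", "Review", "Mission-2", "Mission-3"]


@dataclass
class StudyReport:
    """All result tables of one study run."""

    threshold_used: float
    calibration: CalibrationResult | None
    features: pd.DataFrame  # one row per (participant, frame)
    posture_distribution: pd.DataFrame
    contingency: pd.DataFrame  # long: group, from, to, count, pct
    annotation_summary: pd.DataFrame
    wilcoxon: pd.DataFrame
    signs: pd.DataFrame  # pooled frame pairs with per-feature signs
    agreement: pd.DataFrame  # long c^z table
    agreement_wide: pd.DataFrame  # Table-3 shaped, numeric c
    agreement_labeled: pd.DataFrame  # Table-3 shaped, "c (significance)" cells
    pair_counts: pd.DataFrame  # Table-2 shaped
    excluded_from_reactive: list[int]
    manifest: dict

    def write(self, outdir: Path | str) -> Path:
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        self.features.to_csv(out / "frame_features.csv", index=False)
        self.posture_distribution.to_csv(out / "posture_distribution.csv", index=False)
        self.contingency.to_csv(out / "contingency_tables.csv", index=False)
        self.annotation_summary.to_csv(out / "annotation_summary.csv", index=False)
        self.wilcoxon.to_csv(out / "wilcoxon_tests.csv", index=False)
        self.signs.to_csv(out / "frame_pair_signs.csv", index=False)
        self.agreement.to_csv(out / "agreement_long.csv", index=False)
        self.agreement_wide.to_csv(out / "agreement_table.csv")
        self.agreement_labeled.to_csv(out / "agreement_table_labeled.csv")
        self.pair_counts.to_csv(out / "pair_counts.csv", index=False)
        if self.calibration is not None:
            self.calibration.to_frame().to_csv(out / "calibration_accuracy.csv", index=False)
            self.calibration.anova.to_csv(out / "calibration_anova.csv", index=False)
        with open(out / "run_manifest.json", "w") as fh:
            json.dump(self.manifest, fh, indent=2, default=_jsonable)
        return out


def _jsonable(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, (tuple, set)):
        return list(obj)
    return str(obj)


def _events_valid(bundle: SessionBundle) -> bool:
    """A malformed event log excludes the participant from reactive analyses."""
    t = bundle.events.times
    if len(t) == 0:
        return True
    if np.any(np.diff(t) < 0):
        return False
    return all(bundle.phases.containing(float(x)) is not None for x in t)


def _frame_type(frame: ObservationFrame) -> str:
    if frame.kind == CONTINUOUS:
        return "continuous"
    return f"reactive-{int(frame.nominal_duration)}"


def extract_frame_features(
    bundle: SessionBundle,
    series: PostureSeries,
    p1hz,
    ann_norm,
    ibi_clean,
    bpm_clean,
    frames: list[ObservationFrame],
) -> pd.DataFrame:
    """Feature row per observation frame; undefined features become NaN."""
    rows = []
    for fr in frames:
        row: dict = {
            "participant": bundle.participant,
            "frame_kind": fr.kind,
            "frame_type": _frame_type(fr),
            "label": fr.label,
            "start_s": fr.start,
            "end_s": fr.end,
        }
        try:
            af = annotation_features(ann_norm, fr)
            row.update(muA=af.mean, intA=af.area, ampA=af.amplitude, dA=af.gradient)
        except UndefinedFeatureError:
            row.update(muA=np.nan, intA=np.nan, ampA=np.nan, dA=np.nan)
        mf = mouse_features(bundle.mouse, fr)
        row.update(muMc=mf.clicks_per_second, muMm=mf.movement)
        try:
            pf = posture_features(series, p1hz, fr)
            row.update(muT=pf.transitions_per_second, dT=pf.mean_gradient)
        except UndefinedFeatureError:
            row.update(muT=np.nan, dT=np.nan)
        try:
            hf = heart_features(ibi_clean, bpm_clean, fr)
            row.update(ampH=hf.bpm_amplitude, sdH=hf.ibi_sd)
        except UndefinedFeatureError:
            row.update(ampH=np.nan, sdH=np.nan)
        sub = series.slice(fr.start, fr.end)
        identified = [x for x in sub.labels if x != "none"]
        row["backrest_frac"] = (
            float(np.mean([x in BACKREST_POSTURES for x in identified]))
            if identified
            else np.nan
        )
        rows.append(row)
    return pd.DataFrame(rows)


def build_frame_pairs(features: pd.DataFrame, frame_type: str) -> pd.DataFrame:
    """Adjacent-frame pairs of one frame type, pooled across participants.

    Continuous frames pair consecutively in time per participant
    (truncated at the last phase the participant played); reactive frames
    pair pre → post per event and duration.  Output columns are
    ``<feature>_1`` and ``<feature>_2`` per feature.
    """
    feats = ANNOTATION_FEATURES + PRIMARY_FEATURES
    sub = features[features["frame_type"] == frame_type]
    rows = []
    if frame_type == "continuous":
        for pid, grp in sub.groupby("participant"):
            grp = grp.sort_values("start_s")
            for (_, a), (_, b) in zip(grp.iterrows(), grp.iloc[1:].iterrows()):
                row = {"participant": pid, "pair": f"{a['label']}->{b['label']}"}
                for f in feats:
                    row[f"{f}_1"], row[f"{f}_2"] = a[f], b[f]
                rows.append(row)
    else:
        for (pid, label), grp in sub.groupby(["participant", "label"]):
            pre = grp[grp["frame_kind"] == "reactive-pre"]
            post = grp[grp["frame_kind"] == "reactive-post"]
            if len(pre) != 1 or len(post) != 1:
                continue
            a, b = pre.iloc[0], post.iloc[0]
            row = {"participant": pid, "pair": label}
            for f in feats:
                row[f"{f}_1"], row[f"{f}_2"] = a[f], b[f]
            rows.append(row)
    return pd.DataFrame(rows)


def pair_signs(pairs: pd.DataFrame, clarity: float) -> pd.DataFrame:
    """Per-pair relative-change signs for every feature, plus the vote V."""
    out = pairs[["participant", "pair"]].copy()
    for f in ANNOTATION_FEATURES + PRIMARY_FEATURES:
        out[f] = sign_series(
            pairs[f"{f}_1"].to_numpy(), pairs[f"{f}_2"].to_numpy(), clarity
        )
    vote_matrix = out[PRIMARY_FEATURES].to_numpy()
    out["V"] = majority_vote(vote_matrix) if len(out) else np.array([], dtype=np.int8)
    return out


def _posture_distribution(
    series_by_participant: dict[int, PostureSeries],
    frames_by_participant: dict[int, list[ObservationFrame]],
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Identified-posture distribution and contingency tables per group.

    Continuous frames group by phase name; reactive frames by
    (duration, pre/post).
    """
    counts: dict[str, dict[str, int]] = {}
    tables: dict[str, pd.DataFrame] = {}
    for pid, frames in frames_by_participant.items():
        series = series_by_participant[pid]
        for fr in frames:
            if fr.kind == CONTINUOUS:
                group = fr.label
            else:
                group = f"{_frame_type(fr)}-{'pre' if fr.kind.endswith('pre') else 'post'}"
            sub = series.slice(fr.start, fr.end)
            c = counts.setdefault(group, {p: 0 for p in ALL_POSTURE_STATES})
            for lab in sub.labels:
                c[lab] += 1
            tab = transition_contingency(series, fr)
            tables[group] = tables.get(group, 0) + tab
    dist_rows = []
    for group, c in counts.items():
        total = sum(c.values())
        for p, n in c.items():
            dist_rows.append(
                {
                    "group": group,
                    "posture": p,
                    "count": n,
                    "fraction": n / total if total else np.nan,
                }
            )
    cont_rows = []
    for group, tab in tables.items():
        total = int(tab.to_numpy().sum())
        for a in tab.index:
            for b in tab.columns:
                n = int(tab.loc[a, b])
                cont_rows.append(
                    {
                        "group": group,
                        "from": a,
                        "to": b,
                        "count": n,
                        "pct": 100.0 * n / total if total else np.nan,
                    }
                )
    return pd.DataFrame(dist_rows), pd.DataFrame(cont_rows)


_PHASE_CONTRASTS = [
    # (feature, phase_a, phase_b, alternative); alternative tests a > b
    ("backrest_frac", "Tutorial", "Gameplay", "greater"),
    ("muA", "Tutorial", "Gameplay", "two-sided"),
    ("intA", "Tutorial", "Gameplay", "two-sided"),
    ("ampA", "Tutorial", "Gameplay", "two-sided"),
    ("dA", "Tutorial", "Gameplay", "two-sided"),
    ("muA", "Gameplay", "Review", "two-sided"),
    ("intA", "Gameplay", "Review", "two-sided"),
    ("dA", "Gameplay", "Review", "two-sided"),
    ("muA", "Review", "Mission-2", "two-sided"),
    ("intA", "Review", "Mission-2", "two-sided"),
]

_REACTIVE_CONTRAST_FEATURES = ["muA", "intA", "ampA", "backrest_frac", "muT"]


def phase_contrasts(features: pd.DataFrame) -> pd.DataFrame:
    """Wilcoxon signed-rank contrasts between game phases and around events."""
    rows = []
    cont = features[features["frame_type"] == "continuous"]
    for feat, pa, pb, alt in _PHASE_CONTRASTS:
        wide = cont.pivot_table(index="participant", columns="label", values=feat)
        if pa not in wide.columns or pb not in wide.columns:
            continue
        paired = wide[[pa, pb]].dropna()
        if len(paired) < 2:
            continue
        p = wilcoxon_signed_rank(
            paired[pa].to_numpy(), paired[pb].to_numpy(), alternative=alt
        )
        ma, mb = paired[pa].mean(), paired[pb].mean()
        rows.append(
            {
                "frame_type": "continuous",
                "feature": feat,
                "contrast": f"{pa} vs {pb}",
                "alternative": alt,
                "n_pairs": len(paired),
                "mean_a": ma,
                "mean_b": mb,
                "pct_change": 100.0 * (mb - ma) / abs(ma) if ma != 0 else np.nan,
                "p_value": p,
            }
        )
    for ft in sorted(set(features["frame_type"]) - {"continuous"}):
        sub = features[features["frame_type"] == ft]
        for feat in _REACTIVE_CONTRAST_FEATURES:
            wide = sub.pivot_table(
                index=["participant", "label"], columns="frame_kind", values=feat
            )
            if "reactive-pre" not in wide.columns or "reactive-post" not in wide.columns:
                continue
            paired = wide[["reactive-pre", "reactive-post"]].dropna()
            if len(paired) < 2:
                continue
            p = wilcoxon_signed_rank(
                paired["reactive-pre"].to_numpy(),
                paired["reactive-post"].to_numpy(),
                alternative="two-sided",
            )
            ma = paired["reactive-pre"].mean()
            mb = paired["reactive-post"].mean()
            rows.append(
                {
                    "frame_type": ft,
                    "feature": feat,
                    "contrast": "pre vs post",
                    "alternative": "two-sided",
                    "n_pairs": len(paired),
                    "mean_a": ma,
                    "mean_b": mb,
                    "pct_change": 100.0 * (mb - ma) / abs(ma) if ma != 0 else np.nan,
                    "p_value": p,
                }
            )
    return pd.DataFrame(rows)


def run_study(
    config: StudyConfig,
    write_bundles_to: Path | None = None,
    write_harmonized_to: Path | None = None,
) -> StudyReport:
    """Execute the full pipeline and assemble the report.

    The report is a pure function of (input data, config): rerunning with
    the same seed reproduces every table bitwise.
    """
    patterns = PatternTable()
    calibration: CalibrationResult | None = None

    if config.mode == "synthetic":
        session_cfg = dataclasses.replace(config.session, seed=config.seed)
        bundles = generate_cohort(session_cfg)
        if write_bundles_to is not None:
            for b in bundles:
                write_bundle(b, write_bundles_to)
    else:
        indices = list_participants(Path(config.input_dir))
        if not indices:
            raise ConfigurationError(f"no participant bundles under {config.input_dir}")
        bundles = [read_bundle(Path(config.input_dir), i) for i in indices]

    if config.threshold == "calibrate":
        calib_cfg = dataclasses.replace(config.calibration, seed=config.seed)
        calibration = calibrate_threshold(
            generate_calibration_cohort(calib_cfg), patterns=patterns
        )
        threshold = float(calibration.selected_threshold)
    else:
        threshold = float(config.threshold)

    n_m3 = sum(
        any(p.name == "Mission-3" for p in b.phases.phases) for b in bundles
    )
    omit = ("Mission-3",) if n_m3 < config.min_mission3 else ()

    all_features = []
    series_by_pid: dict[int, PostureSeries] = {}
    frames_by_pid: dict[int, list[ObservationFrame]] = {}
    excluded: list[int] = []
    for b in bundles:
        ann = normalize_trace(b.annotation)
        ibi_c = clean_ibi(b.ibi)
        bpm_c = bpm_from_ibi(ibi_c)
        p1hz, table = harmonize_streams(
            b.pressure, ann, ibi=ibi_c, bpm=bpm_c, mouse=b.mouse, truth=b.truth
        )
        if write_harmonized_to is not None:
            d = Path(write_harmonized_to)
            d.mkdir(parents=True, exist_ok=True)
            table.to_csv(d / f"p{b.participant:02d}_harmonized.csv", index=False)
        series = classify_stream(p1hz, threshold, patterns)
        ok = _events_valid(b)
        events = b.events if ok else EventLog(np.array([]), np.array([], dtype=object))
        if not ok:
            excluded.append(b.participant)
            log.warning(
                "participant %d: malformed event log, excluded from reactive analyses",
                b.participant,
            )
        frames = build_frames(b.phases, events, config.reactive_durations, omit)
        all_features.append(
            extract_frame_features(b, series, p1hz, ann, ibi_c, bpm_c, frames)
        )
        series_by_pid[b.participant] = series
        frames_by_pid[b.participant] = frames
    features = pd.concat(all_features, ignore_index=True)

    dist, contingency = _posture_distribution(series_by_pid, frames_by_pid)

    q = features.groupby("frame_type")[ANNOTATION_FEATURES].describe()
    annotation_summary = q.stack(level=0, future_stack=True).reset_index().rename(
        columns={"level_1": "feature"}
    )

    wilcoxon = phase_contrasts(features)

    display_primary = [
        f
        for f in PRIMARY_FEATURES
        if config.include_transition_rate or f != "muT"
    ]
    signs_frames = []
    agreements = []
    for ft in ["continuous"] + [
        f"reactive-{int(d)}" for d in config.reactive_durations
    ]:
        pairs = build_frame_pairs(features, ft)
        if len(pairs) == 0:
            continue
        signs = pair_signs(pairs, config.clarity)
        signs.insert(0, "frame_type", ft)
        signs_frames.append(signs)
        agg = agreement_table(signs, ANNOTATION_FEATURES, display_primary)
        agg.insert(0, "frame_type", ft)
        agreements.append(agg)
    signs_all = pd.concat(signs_frames, ignore_index=True) if signs_frames else pd.DataFrame()
    agreement = pd.concat(agreements, ignore_index=True) if agreements else pd.DataFrame()

    if config.multiple_testing and len(agreement):
        if config.multiple_testing != "fdr_bh":
            raise ConfigurationError("only fdr_bh correction is supported")
        agreement["p_adjusted"] = sps.false_discovery_control(
            agreement["p_value"].to_numpy(), method="bh"
        )

    if len(agreement):
        agreement_wide = agreement.pivot_table(
            index="annotation_feature",
            columns=["frame_type", "feature"],
            values="c",
        ).reindex(ANNOTATION_FEATURES)
        lab = agreement.copy()
        mark = {HIGHLY_SIGNIFICANT: "**", SIGNIFICANT: "*", NOT_SIGNIFICANT: ""}
        lab["cell"] = [
            f"{c:+.2f}{mark[s]}" for c, s in zip(lab["c"], lab["significance"])
        ]
        agreement_labeled = lab.pivot_table(
            index="annotation_feature",
            columns=["frame_type", "feature"],
            values="cell",
            aggfunc="first",
        ).reindex(ANNOTATION_FEATURES)
    else:
        agreement_wide = pd.DataFrame()
        agreement_labeled = pd.DataFrame()

    pc_rows = []
    for ft, grp in agreement.groupby("frame_type"):
        prim = grp[grp["feature"] != "V"]["N"]
        vote = grp[grp["feature"] == "V"]["N"]
        pc_rows.append(
            {
                "frame_type": ft,
                "primary_mean_N": prim.mean(),
                "primary_sd_N": prim.std(ddof=1),
                "vote_mean_N": vote.mean(),
                "vote_sd_N": vote.std(ddof=1) if len(vote) > 1 else 0.0,
            }
        )
    pair_counts = pd.DataFrame(pc_rows)

    import hashlib

    import scipy

    config_dict = config.to_dict()
    config_hash = hashlib.sha256(
        json.dumps(config_dict, sort_keys=True, default=_jsonable).encode()
    ).hexdigest()[:16]
    manifest = {
        "package_version": __version__,
        "versions": {"numpy": np.__version__, "scipy": scipy.__version__,
                     "pandas": pd.__version__},
        "seed": config.seed,
        "config_hash": config_hash,
        "config": config_dict,
        "threshold_used": threshold,
        "n_participants": len(bundles),
        "n_frames": int(len(features)),
        "n_pairs_total": int(len(signs_all)),
        "excluded_from_reactive": excluded,
        "mission3_omitted": bool(omit),
    }
    return StudyReport(
        threshold_used=threshold,
        calibration=calibration,
        features=features,
        posture_distribution=dist,
        contingency=contingency,
        annotation_summary=annotation_summary,
        wilcoxon=wilcoxon,
        signs=signs_all,
        agreement=agreement,
        agreement_wide=agreement_wide,
        agreement_labeled=agreement_labeled,
        pair_counts=pair_counts,
        excluded_from_reactive=excluded,
        manifest=manifest,
    )
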