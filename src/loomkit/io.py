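"""CSV schemas, configuration handling and the pipeline driver.

All event data travel as plain CSV (times in ms, written with 3-decimal
precision).  Readers validate headers, numeric fields and time ordering and
report the first offending row/column by name; writers round-trip exactly at
the stored precision.  ``run_pipeline`` ties the stages together and writes
a run manifest capturing every parameter and seed.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .geometry import FrameSchedule, LoomingStimulus, WingSpec
from .glides import GlideEvent, WingbeatTrain, detect_glides, glide_proportions
from .kinematics import TrackSegment, hierarchical_mean
from .spikes import SpikeTrain, group_summary, individual_mean_peak

__all__ = [
    "read_stimuli",
    "write_stimuli",
    "read_spike_trains",
    "write_spike_trains",
    "read_wingbeat_trains",
    "write_wingbeat_trains",
    "read_tracks",
    "write_tracks",
    "write_frame_schedule",
    "write_glide_table",
    "RunConfig",
    "run_pipeline",
]

logger = logging.getLogger(__name__)

STIMULUS_COLUMNS = [
    "stim_id",
    "half_size_m",
    "speed_m_s",
    "start_m",
    "end_m",
    "wing_span_m",
    "wing_height_m",
    "wing_offset_m",
]
SPIKE_COLUMNS = ["individual_id", "stim_id", "presentation", "t_ms"]
WINGBEAT_COLUMNS = ["individual_id", "stim_id", "presentation", "t_ms", "valid_flight"]
TRACK_COLUMNS = ["kite_id", "attack_id", "segment_id", "frame", "x_px", "y_px"]

_TIME_FMT = "%.3f"


class SchemaError(ValueError):
    """A CSV file violates its expected schema."""


def _read_csv(path, columns: Sequence[str]) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing column(s) {missing}")
    return df


def _numeric(df: pd.DataFrame, col: str, path, optional: bool = False) -> pd.Series:
    raw = df[col].str.strip()
    if optional:
        raw = raw.replace("", "nan")
    out = pd.to_numeric(raw, errors="coerce")
    bad = out.isna() & (raw.str.lower() != "nan")
    if bad.any():
        row = int(np.argmax(bad.values)) + 2  # 1-based, plus header line
        raise SchemaError(
            f"{path}: non-numeric value {df[col][bad.idxmax()]!r} "
            f"in column {col!r} at line {row}"
        )
    return out


def read_stimuli(path) -> List[LoomingStimulus]:
    """Read stimulus definitions; empty wing columns mean no wing bar."""
    df = _read_csv(path, STIMULUS_COLUMNS)
    stims: List[LoomingStimulus] = []
    half = _numeric(df, "half_size_m", path)
    speed = _numeric(df, "speed_m_s", path)
    start = _numeric(df, "start_m", path)
    end = _numeric(df, "end_m", path)
    span = _numeric(df, "wing_span_m", path, optional=True)
    height = _numeric(df, "wing_height_m", path, optional=True)
    offset = _numeric(df, "wing_offset_m", path, optional=True)
    for i in range(len(df)):
        wing = None
        if not np.isnan(span[i]):
            wing = WingSpec(
                span=float(span[i]),
                bar_height=float(height[i]),
                vertical_offset=float(offset[i]),
            )
        stims.append(
            LoomingStimulus(
                half_size_l=float(half[i]),
                speed_v=float(speed[i]),
                start_distance=float(start[i]),
                end_distance=float(end[i]),
                wing=wing,
                stim_id=str(df["stim_id"][i]),
            )
        )
    return stims


def write_stimuli(stimuli: Iterable[LoomingStimulus], path) -> None:
    rows = []
    for i, s in enumerate(stimuli):
        rows.append(
            {
                "stim_id": s.stim_id or f"stim{i:02d}",
                "half_size_m": s.half_size_l,
                "speed_m_s": s.speed_v,
                "start_m": s.start_distance,
                "end_m": s.end_distance,
                "wing_span_m": s.wing.span if s.wing else "",
                "wing_height_m": s.wing.bar_height if s.wing else "",
                "wing_offset_m": s.wing.vertical_offset if s.wing else "",
            }
        )
    pd.DataFrame(rows, columns=STIMULUS_COLUMNS).to_csv(path, index=False)


def _event_trains(
    df: pd.DataFrame, path, with_flag: bool
) -> List[Tuple[Tuple[str, str, int], np.ndarray, bool]]:
    t = _numeric(df, "t_ms", path)
    pres = _numeric(df, "presentation", path)
    flags = None
    if with_flag:
        raw = df["valid_flight"].str.strip().str.lower()
        ok = raw.isin(["0", "1", "true", "false"])
        if not ok.all():
            row = int(np.argmax(~ok.values)) + 2
            raise SchemaError(
                f"{path}: non-boolean value in column 'valid_flight' at line {row}"
            )
        flags = raw.isin(["1", "true"])
    keys = list(zip(df["individual_id"], df["stim_id"], pres.astype(int)))
    groups: Dict[Tuple[str, str, int], List[int]] = {}
    for i, k in enumerate(keys):
        groups.setdefault(k, []).append(i)
    out = []
    for key, idx in groups.items():
        times = t.values[idx]
        if len(times) > 1 and np.any(np.diff(times) <= 0):
            bad = idx[int(np.argmax(np.diff(times) <= 0)) + 1] + 2
            raise SchemaError(
                f"{path}: column 't_ms' not strictly increasing within "
                f"presentation {key} at line {bad}"
            )
        flag = bool(flags.values[idx[0]]) if flags is not None else True
        out.append((key, times, flag))
    return out


def read_spike_trains(path) -> List[SpikeTrain]:
    df = _read_csv(path, SPIKE_COLUMNS)
    return [
        SpikeTrain(ind, stim, pres, times)
        for (ind, stim, pres), times, _ in _event_trains(df, path, with_flag=False)
    ]


def write_spike_trains(trains: Iterable[SpikeTrain], path) -> None:
    rows = [
        (tr.individual_id, tr.stim_id, tr.presentation, _TIME_FMT % t)
        for tr in trains
        for t in tr.spike_times
    ]
    pd.DataFrame(rows, columns=SPIKE_COLUMNS).to_csv(path, index=False)


def read_wingbeat_trains(path) -> List[WingbeatTrain]:
    df = _read_csv(path, WINGBEAT_COLUMNS)
    return [
        WingbeatTrain(ind, stim, pres, times, valid_flight=flag)
        for (ind, stim, pres), times, flag in _event_trains(df, path, with_flag=True)
    ]


def write_wingbeat_trains(trains: Iterable[WingbeatTrain], path) -> None:
    rows = [
        (
            tr.individual_id,
            tr.stim_id,
            tr.presentation,
            _TIME_FMT % t,
            int(tr.valid_flight),
        )
        for tr in trains
        for t in tr.event_times
    ]
    pd.DataFrame(rows, columns=WINGBEAT_COLUMNS).to_csv(path, index=False)


def read_tracks(
    path, fps: float = 25.0, calibration: Tuple[float, float] = (1.0, 1.0)
) -> List[TrackSegment]:
    df = _read_csv(path, TRACK_COLUMNS)
    frame = _numeric(df, "frame", path)
    x = _numeric(df, "x_px", path)
    y = _numeric(df, "y_px", path)
    groups: Dict[Tuple[str, str, str], List[int]] = {}
    for i, key in enumerate(
        zip(df["kite_id"], df["attack_id"], df["segment_id"])
    ):
        groups.setdefault(key, []).append(i)
    segments = []
    for (kite, attack, seg), idx in groups.items():
        segments.append(
            TrackSegment(
                kite_id=kite,
                attack_id=attack,
                segment_id=seg,
                frames=frame.values[idx].astype(int),
                x_px=x.values[idx],
                y_px=y.values[idx],
                fps=fps,
                calibration=calibration,
            )
        )
    return segments


def write_tracks(segments: Iterable[TrackSegment], path) -> None:
    rows = [
        (s.kite_id, s.attack_id, s.segment_id, int(f), "%.3f" % x, "%.3f" % y)
        for s in segments
        for f, x, y in zip(s.frames, s.x_px, s.y_px)
    ]
    pd.DataFrame(rows, columns=TRACK_COLUMNS).to_csv(path, index=False)


def write_frame_schedule(schedule: FrameSchedule, path) -> None:
    df = pd.DataFrame(
        {
            "frame": schedule.frame,
            "t_to_collision_s": np.round(schedule.t_to_collision, 6),
            "theta_deg": np.round(schedule.theta_deg, 4),
            "radius_px": np.round(schedule.radius_px, 3),
            "wing_w_px": (
                np.round(schedule.wing_w_px, 3)
                if schedule.wing_w_px is not None
                else ""
            ),
            "wing_h_px": (
                np.round(schedule.wing_h_px, 3)
                if schedule.wing_h_px is not None
                else ""
            ),
            "clipped": schedule.clipped.astype(int),
        }
    )
    df.to_csv(path, index=False)


def write_glide_table(
    rows: Iterable[Tuple[str, str, int, GlideEvent]], path
) -> None:
    records = [
        {
            "individual_id": ind,
            "stim_id": stim,
            "presentation": pres,
            "onset_ms": _TIME_FMT % g.onset_time,
            "gap_ms": _TIME_FMT % g.gap_duration,
            "before_collision": int(g.before_collision),
        }
        for ind, stim, pres, g in rows
    ]
    pd.DataFrame(
        records,
        columns=[
            "individual_id",
            "stim_id",
            "presentation",
            "onset_ms",
            "gap_ms",
            "before_collision",
        ],
    ).to_csv(path, index=False)


_RUNCONFIG_KEYS = {
    "spikes_path",
    "wingbeats_path",
    "tracks_path",
    "stimuli_path",
    "out_dir",
    "window_ms",
    "threshold_hz",
    "k",
    "n_history",
    "trim_s",
    "fps",
    "cal_len_px",
    "cal_len_m",
    "pixel_pitch",
    "seed",
    "log_level",
}


@dataclass
class RunConfig:
    """Validated pipeline configuration; unknown keys are rejected."""

    spikes_path: Optional[str] = None
    wingbeats_path: Optional[str] = None
    tracks_path: Optional[str] = None
    stimuli_path: Optional[str] = None
    out_dir: str = "."
    window_ms: float = 25.0
    threshold_hz: float = 150.0
    k: float = 1.25
    n_history: int = 10
    trim_s: Optional[float] = None
    fps: float = 25.0
    cal_len_px: float = 1.0
    cal_len_m: float = 1.0
    pixel_pitch: float = 0.0004
    seed: int = 0
    log_level: str = "INFO"

    @classmethod
    def from_mapping(cls, mapping: Dict) -> "RunConfig":
        unknown = set(mapping) - _RUNCONFIG_KEYS
        if unknown:
            raise ValueError(f"unknown configuration key(s): {sorted(unknown)}")
        return cls(**mapping)

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise ValueError(f"{path}: configuration must be a flat mapping")
        return cls.from_mapping(data)

    def to_manifest(self) -> Dict:
        return {"loomkit_version": __version__, **dataclasses.asdict(self)}


def _spike_stage(config: RunConfig, out_dir: Path) -> List[str]:
    trains = read_spike_trains(config.spikes_path)
    by_stim: Dict[str, Dict[str, List[SpikeTrain]]] = {}
    for tr in trains:
        by_stim.setdefault(tr.stim_id, {}).setdefault(tr.individual_id, []).append(tr)
    rows = []
    for stim_id, by_ind in sorted(by_stim.items()):
        peaks = [
            individual_mean_peak(ind_trains, config.window_ms)
            for ind_trains in by_ind.values()
        ]
        mean, sem, n = group_summary(peaks)
        rows.append(
            {
                "stim_id": stim_id,
                "mean_peak_rate_hz": round(mean, 3),
                "sem_hz": round(sem, 3),
                "n_individuals": n,
            }
        )
    path = out_dir / "peak_rates.csv"
    pd.DataFrame(rows).to_csv(path, index=False)
    return [str(path)]


def _glide_stage(config: RunConfig, out_dir: Path) -> List[str]:
    trains = read_wingbeat_trains(config.wingbeats_path)
    by_stim: Dict[str, List[WingbeatTrain]] = {}
    for tr in trains:
        by_stim.setdefault(tr.stim_id, []).append(tr)
    summary_rows = []
    glide_rows = []
    for stim_id, stim_trains in sorted(by_stim.items()):
        for tr in stim_trains:
            if not tr.valid_flight:
                continue
            for g in detect_glides(tr, k=config.k, n_history=config.n_history):
                glide_rows.append((tr.individual_id, stim_id, tr.presentation, g))
        summ = glide_proportions(stim_trains, k=config.k, n_history=config.n_history)
        summary_rows.append(
            {
                "stim_id": stim_id,
                "occurrence_mean": round(summ.occurrence_group[0], 4),
                "occurrence_sem": round(summ.occurrence_group[1], 4),
                "onset_mean_ms": round(summ.onset_group[0], 3),
                "onset_sem_ms": round(summ.onset_group[1], 3),
                "before_given_glide_mean": round(summ.before_given_glide_group[0], 4),
                "before_given_glide_sem": round(summ.before_given_glide_group[1], 4),
                "preglide_per_presentation_mean": round(summ.preglide_group[0], 4),
                "preglide_per_presentation_sem": round(summ.preglide_group[1], 4),
                "n_individuals": summ.occurrence_group[2],
                "n_gliders": summ.onset_group[2],
                "n_excluded_presentations": summ.n_excluded,
            }
        )
    glides_path = out_dir / "glides.csv"
    write_glide_table(glide_rows, glides_path)
    summary_path = out_dir / "glide_summary.csv"
    pd.DataFrame(summary_rows).to_csv(summary_path, index=False)
    return [str(glides_path), str(summary_path)]


def _kinematics_stage(config: RunConfig, out_dir: Path) -> List[str]:
    segments = read_tracks(
        config.tracks_path,
        fps=config.fps,
        calibration=(config.cal_len_px, config.cal_len_m),
    )
    summary = hierarchical_mean(segments, trim_s=config.trim_s)
    rows = [
        {"level": "kite", "id": k, "mean_speed_m_s": round(v, 4)}
        for k, v in sorted(summary.per_kite_means.items())
    ]
    rows.append(
        {
            "level": "grand",
            "id": f"n={summary.n_kites}",
            "mean_speed_m_s": round(summary.grand_mean, 4),
        }
    )
    rows.append(
        {"level": "grand_sd", "id": "", "mean_speed_m_s": round(summary.grand_sd, 4)}
    )
    path = out_dir / "speeds.csv"
    pd.DataFrame(rows).to_csv(path, index=False)
    return [str(path)]


def run_pipeline(config: RunConfig) -> Dict[str, List[str]]:
    """Run every configured stage; returns stage -> list of output paths.

    Emits a ``manifest.json`` alongside the outputs echoing all parameters,
    the seed and the package version, sufficient to reproduce the run.
    """
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    outputs: Dict[str, List[str]] = {}
    stages = [
        ("kinematics", config.tracks_path, _kinematics_stage),
        ("spikes", config.spikes_path, _spike_stage),
        ("glides", config.wingbeats_path, _glide_stage),
    ]
    for name, enabled, stage_fn in stages:
        if not enabled:
            continue
        try:
            outputs[name] = stage_fn(config, out_dir)
        except Exception as exc:
            raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc
    if not outputs:
        raise ValueError("no input paths configured; nothing to run")
    manifest = config.to_manifest()
    manifest["outputs"] = outputs
    manifest_path = out_dir / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    outputs["manifest"] = [str(manifest_path)]
    return outputs
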