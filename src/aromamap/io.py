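"""CSV readers/writers, run configuration, and the results manifest.

Interchange format is plain CSV: per participant one file per channel
(columns ``time_s,value``) plus a timeline file (columns
``condition,stim_type,onset_s,duration_s``), tied together by a cohort
manifest (``participant_id,gender,generation,eeg_path,ppg_path,
timeline_path``). All times are seconds from session start.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .core import RawSignal
from .synthetic import GENDER_BANDS, EffectSpec, SessionTimeline, StimulusEvent

log = logging.getLogger(__name__)

SIGNAL_COLUMNS = ["time_s", "value"]
TIMELINE_COLUMNS = ["condition", "stim_type", "onset_s", "duration_s"]
MANIFEST_COLUMNS = [
    "participant_id", "gender", "generation", "eeg_path", "ppg_path", "timeline_path",
]


@dataclass
class PipelineConfig:
    """Everything needed to reproduce one full run."""

    eeg_fs_hz: float = 512.0
    ppg_fs_hz: float = 500.0
    ma_window_s: int = 15
    pnn_threshold_ms: float = 50.0
    rest_s: float = 60.0
    group_sizes: dict[str, int] = field(
        default_factory=lambda: {
            "male,20s-30s": 15,
            "male,40s-50s": 15,
            "female,20s-30s": 17,
            "female,40s-50s": 15,
        }
    )
    effects: str = "illustrative"  # "null" | "illustrative"
    seed: int = 0
    out_dir: str = "results"

    def __post_init__(self) -> None:
        if self.eeg_fs_hz <= 0 or self.ppg_fs_hz <= 0:
            raise ValueError("sampling rates must be positive")
        if self.ma_window_s < 1:
            raise ValueError("moving-average window must be at least 1 s")
        if self.effects not in ("null", "illustrative"):
            raise ValueError(f"unknown effects preset {self.effects!r}")

    def group_sizes_tuples(self) -> dict[tuple[str, str], int]:
        out = {}
        for key, n in self.group_sizes.items():
            gender, band = key.split(",")
            out[(gender, band)] = int(n)
        missing = set(GENDER_BANDS) - set(out)
        if missing:
            raise ValueError(f"group_sizes missing {sorted(missing)}")
        return out

    def effect_spec(self) -> EffectSpec:
        return EffectSpec.null() if self.effects == "null" else EffectSpec.illustrative()

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        unknown = set(raw) - {f.name for f in dataclasses.fields(cls)}
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)


def write_signal_csv(signal: RawSignal, path: str | Path) -> None:
    df = pd.DataFrame({"time_s": signal.times_s, "value": signal.values})
    df.to_csv(path, index=False, float_format="%.17g")  # bit-exact round trip


def read_signal_csv(path: str | Path, channel: str) -> RawSignal:
    df = pd.read_csv(path, float_precision="round_trip")
    if list(df.columns) != SIGNAL_COLUMNS:
        raise ValueError(f"{path}: line 1 must be header '{','.join(SIGNAL_COLUMNS)}'")
    t = df["time_s"].to_numpy(dtype=float)
    if t.size < 2:
        raise ValueError(f"{path}: need at least 2 samples")
    dt = np.diff(t)
    if np.any(dt <= 0):
        bad = int(np.argmax(dt <= 0)) + 2  # +2: 1-based, after header
        raise ValueError(f"{path}: non-monotone time at line {bad + 1}")
    mean_dt = float(dt.mean())
    if np.any(np.abs(dt - mean_dt) > 0.01 * mean_dt):
        bad = int(np.argmax(np.abs(dt - mean_dt) > 0.01 * mean_dt)) + 2
        raise ValueError(f"{path}: non-uniform sampling near line {bad + 1}")
    return RawSignal(df["value"].to_numpy(dtype=float), 1.0 / mean_dt, channel=channel)


def write_timeline_csv(timeline: SessionTimeline, path: str | Path) -> None:
    rows = []
    for start, end, stim in timeline.windows():
        if stim is None:
            rows.append(("rest", "rest", start, end - start))
        else:
            ev = next(e for e in timeline.events if e.name == stim)
            rows.append((ev.name, ev.stim_type, ev.onset_s, ev.duration_s))
    pd.DataFrame(rows, columns=TIMELINE_COLUMNS).to_csv(path, index=False)


def read_timeline_csv(
    path: str | Path, participant_id: str, gender: str, generation: str
) -> SessionTimeline:
    df = pd.read_csv(path)
    if list(df.columns) != TIMELINE_COLUMNS:
        raise ValueError(f"{path}: line 1 must be header '{','.join(TIMELINE_COLUMNS)}'")
    events = []
    pre_rest = None
    rest_s = None
    for i, row in df.iterrows():
        stype = row["stim_type"]
        if stype == "rest":
            if pre_rest is None:
                pre_rest = float(row["duration_s"])
            rest_s = float(row["duration_s"])
            continue
        if stype not in ("aroma", "unpleasant"):
            raise ValueError(f"{path}: unknown stim_type {stype!r} at line {i + 2}")
        events.append(
            StimulusEvent(row["condition"], stype, float(row["onset_s"]), float(row["duration_s"]))
        )
    if pre_rest is None:
        raise ValueError(f"{path}: timeline has no rest blocks")
    return SessionTimeline(
        events=tuple(events),
        participant_id=participant_id,
        gender=gender,
        generation=generation,
        pre_rest_s=pre_rest,
        rest_s=rest_s if rest_s is not None else pre_rest,
    )


def write_session_csv(
    out_dir: str | Path,
    participant_id: str,
    eeg: RawSignal,
    ppg: RawSignal,
    timeline: SessionTimeline,
) -> dict[str, str]:
    """Write one session's three CSV files; returns relative paths."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {
        "eeg_path": f"{participant_id}_eeg.csv",
        "ppg_path": f"{participant_id}_ppg.csv",
        "timeline_path": f"{participant_id}_timeline.csv",
    }
    write_signal_csv(eeg, out_dir / paths["eeg_path"])
    write_signal_csv(ppg, out_dir / paths["ppg_path"])
    write_timeline_csv(timeline, out_dir / paths["timeline_path"])
    return paths


def read_session_csv(
    eeg_path: str | Path,
    ppg_path: str | Path,
    timeline_path: str | Path,
    participant_id: str = "p000",
    gender: str = "male",
    generation: str = "20s",
) -> tuple[RawSignal, RawSignal, SessionTimeline]:
    eeg = read_signal_csv(eeg_path, channel="eeg")
    ppg = read_signal_csv(ppg_path, channel="ppg")
    timeline = read_timeline_csv(timeline_path, participant_id, gender, generation)
    return eeg, ppg, timeline


def write_manifest_csv(rows: list[dict], path: str | Path) -> None:
    pd.DataFrame(rows, columns=MANIFEST_COLUMNS).to_csv(path, index=False)


def read_manifest_csv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    if list(df.columns) != MANIFEST_COLUMNS:
        raise ValueError(f"{path}: line 1 must be header '{','.join(MANIFEST_COLUMNS)}'")
    return df


def write_results(tables: dict[str, pd.DataFrame], out_dir: str | Path, config: PipelineConfig) -> dict[str, Path]:
    """Write tidy result CSVs plus a JSON run manifest.

    ``tables`` maps short names (``summaries``, ``anova``, ``pairwise``,
    ``map_points``) to tidy frames; every table gets ``<name>.csv``.
    """
    if not tables:
        raise ValueError("no tables to write")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}
    for name, df in tables.items():
        p = out_dir / f"{name}.csv"
        df.to_csv(p, index=False)
        written[name] = p
    from . import __version__

    manifest = {
        "config": dataclasses.asdict(config),
        "seed": config.seed,
        "version": __version__,
        "tables": {k: str(v.name) for k, v in written.items()},
    }
    mpath = out_dir / "run_manifest.json"
    with open(mpath, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    written["manifest"] = mpath
    return written
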