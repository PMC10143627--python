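"""Arousal-valence "emotion map" construction and rendering.

Following the circumplex model of affect, each stimulus is placed on a 2-D
map: valence on the X-axis (group-mean raw pNN50, range [0, 1], origin at
the group's resting-state mean) and arousal on the Y-axis (one of
Attention-Meditation in [-100, 100] with origin 0, the smoothed
high-beta/high-alpha ratio in [0, 2], or the raw delta band power with a
data-driven range and no origin line). Each stimulus contributes three
points, one per exposure window (all / first half / latter half), drawn as
circle / triangle / square in a stimulus-specific color.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .core import (
    INDEX_ATT_MED,
    INDEX_DELTA,
    INDEX_MA_HB_HA,
    INDEX_PNN50,
    STIMULI,
    WINDOWS,
)

log = logging.getLogger(__name__)

AROUSAL_INDEXES = (INDEX_ATT_MED, INDEX_MA_HB_HA, INDEX_DELTA)

WINDOW_MARKERS = {"all": "o", "first_half": "^", "latter_half": "s"}
STIMULUS_COLORS = dict(zip(STIMULI, plt.get_cmap("tab10").colors))

QUADRANTS = ("HAHV", "HALV", "LAHV", "LALV", "on_axis")


@dataclass(frozen=True)
class AxisConfig:
    index_name: str
    min: float
    max: float
    origin: float  # NaN = no origin line (delta axis)
    origin_rule: str  # fixed | resting_mean | data_max_scaled | data_driven

    def __post_init__(self) -> None:
        if not self.min < self.max:
            raise ValueError("axis min must be below max")
        if np.isfinite(self.origin) and not (self.min <= self.origin <= self.max):
            raise ValueError("axis origin must lie within [min, max]")


@dataclass(frozen=True)
class EmotionMapPoint:
    stimulus: str
    window: str
    valence: float  # group-mean raw pNN50
    arousal: float  # group-mean raw arousal index
    group: str


def build_axis(
    index_name: str,
    data: np.ndarray | None = None,
    resting_values: np.ndarray | None = None,
    range_override: tuple[float, float] | None = None,
) -> AxisConfig:
    """Axis range and origin for one plottable index.

    ``range_override`` supports alternative presets (e.g. an arousal axis
    expanded toward the low-arousal region) without changing any
    computation.
    """
    if index_name == INDEX_ATT_MED:
        lo, hi = range_override or (-100.0, 100.0)
        return AxisConfig(index_name, lo, hi, 0.0, "fixed")
    if index_name == INDEX_MA_HB_HA:
        # Ratio axis: minimum 0; ceiling 2 covers the data with balanced
        # scaling, stretched only if the data actually exceed it.
        hi = 2.0
        if data is not None and np.asarray(data).size:
            hi = max(hi, float(np.nanmax(data)))
        lo, hi = range_override or (0.0, hi)
        return AxisConfig(index_name, lo, hi, 1.0, "data_max_scaled")
    if index_name == INDEX_PNN50:
        if resting_values is None or np.asarray(resting_values).size == 0:
            raise ValueError("pnn50 axis needs resting-state values for its origin")
        origin = float(np.nanmean(resting_values))
        lo, hi = range_override or (0.0, 1.0)
        return AxisConfig(index_name, lo, hi, origin, "resting_mean")
    if index_name == INDEX_DELTA:
        if data is None or np.asarray(data).size == 0:
            raise ValueError("delta axis is data-driven and needs data")
        arr = np.asarray(data, dtype=float)
        lo, hi = float(np.nanmin(arr)), float(np.nanmax(arr))
        pad = 0.1 * (hi - lo) if hi > lo else max(abs(hi), 1.0) * 0.1
        lo, hi = range_override or (lo - pad, hi + pad)
        return AxisConfig(index_name, lo, hi, float("nan"), "data_driven")
    raise ValueError(f"unsupported emotion-map index {index_name!r}")


def build_map_points(
    summaries: pd.DataFrame,
    group: str,
    arousal_index: str = INDEX_ATT_MED,
) -> list[EmotionMapPoint]:
    """One point per stimulus x window: group means of raw window means.

    ``summaries`` is the tidy per-participant table (columns: participant,
    stimulus, window, index, raw_mean, ...) restricted here to one group.
    Stimuli with no defined data in some window are omitted with a log
    entry.
    """
    if arousal_index not in AROUSAL_INDEXES:
        raise ValueError(f"unsupported arousal index {arousal_index!r}")
    if summaries.empty:
        raise ValueError(f"no summaries for group {group!r}")
    points: list[EmotionMapPoint] = []
    for stim in STIMULI:
        for window in WINDOWS:
            cell = summaries[(summaries["stimulus"] == stim) & (summaries["window"] == window)]
            val = cell.loc[cell["index"] == INDEX_PNN50, "raw_mean"].dropna()
            aro = cell.loc[cell["index"] == arousal_index, "raw_mean"].dropna()
            if val.empty or aro.empty:
                log.info("omitting %s/%s for group %s: no defined data", stim, window, group)
                continue
            points.append(
                EmotionMapPoint(stim, window, float(val.mean()), float(aro.mean()), group)
            )
    return points


def classify_quadrant(p: EmotionMapPoint, x_axis: AxisConfig, y_axis: AxisConfig) -> str:
    """Quadrant of a point relative to the axis origins.

    High/low valence (HV/LV) right/left of the valence origin; high/low
    arousal (HA/LA) above/below the arousal origin; exact equality on
    either axis classifies as ``on_axis``.
    """
    if not (np.isfinite(x_axis.origin) and np.isfinite(y_axis.origin)):
        raise ValueError("quadrant classification needs finite axis origins")
    if not (np.isfinite(p.valence) and np.isfinite(p.arousal)):
        raise ValueError("quadrant classification needs finite coordinates")
    if p.valence == x_axis.origin or p.arousal == y_axis.origin:
        return "on_axis"
    hv = p.valence > x_axis.origin
    ha = p.arousal > y_axis.origin
    return ("HA" if ha else "LA") + ("HV" if hv else "LV")


def points_frame(points: list[EmotionMapPoint]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "group": p.group,
                "stimulus": p.stimulus,
                "window": p.window,
                "valence": p.valence,
                "arousal": p.arousal,
            }
            for p in points
        ]
    )


def render_map(
    points: list[EmotionMapPoint],
    x_axis: AxisConfig,
    y_axis: AxisConfig,
    out_path: str | Path,
    zoom: bool = False,
    title: str | None = None,
) -> tuple[Path, Path]:
    """Render the map to ``out_path`` and write a companion CSV.

    The full-scale view uses the configured axis ranges; the zoom view uses
    the data extent padded by 10%. Returns (figure path, csv path).
    """
    if not points:
        raise ValueError("need at least one point to render")
    out_path = Path(out_path)
    df = points_frame(points)

    fig, ax = plt.subplots(figsize=(6, 5))
    for stim in STIMULI:
        for window in WINDOWS:
            sub = df[(df["stimulus"] == stim) & (df["window"] == window)]
            if sub.empty:
                continue
            ax.scatter(
                sub["valence"],
                sub["arousal"],
                color=STIMULUS_COLORS[stim],
                marker=WINDOW_MARKERS[window],
                label=f"{stim} ({window})",
                s=45,
                edgecolors="k",
                linewidths=0.3,
            )
    if zoom:
        for coord, axis_set in ((df["valence"], ax.set_xlim), (df["arousal"], ax.set_ylim)):
            lo, hi = float(coord.min()), float(coord.max())
            pad = 0.1 * (hi - lo) if hi > lo else max(abs(hi), 1e-3) * 0.1
            axis_set(lo - pad, hi + pad)
    else:
        ax.set_xlim(x_axis.min, x_axis.max)
        ax.set_ylim(y_axis.min, y_axis.max)
    if np.isfinite(x_axis.origin):
        ax.axvline(x_axis.origin, color="gray", lw=0.8)
    if np.isfinite(y_axis.origin):
        ax.axhline(y_axis.origin, color="gray", lw=0.8)
    ax.set_xlabel(f"valence: {x_axis.index_name}")
    ax.set_ylabel(f"arousal: {y_axis.index_name}")
    if title:
        ax.set_title(title)
    ax.legend(fontsize=6, ncol=2, loc="best")
    fig.tight_layout()
    fig.savefig(out_path, dpi=120)
    plt.close(fig)

    csv_path = out_path.with_suffix(".csv")
    df.to_csv(csv_path, index=False, float_format="%.17g")  # bit-exact round trip
    return out_path, csv_path
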