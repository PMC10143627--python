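"""End-to-end orchestration: signals -> indexes -> changes -> statistics -> maps."""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import emotion_map as emap
from . import io as amio
from .core import (
    ALL_INDEXES,
    INDEX_ATT_MED,
    INDEX_DELTA,
    INDEX_MA_HB_HA,
    INDEX_PNN50,
    INDEX_RMSSD,
    INDEX_THETA,
    STIMULI,
    IndexSeries,
    RawSignal,
)
from .eeg_indexes import attention_minus_meditation, band_index, band_powers, ma_hbeta_halpha
from .ppg_hrv import detect_beats, hrv_indexes, ibi_from_beats
from .segmentation import (
    baseline_average,
    exposure_windows,
    group_key,
    normalize,
    segment_session,
    summarize_exposure,
)
from .stats import WithinSubjectMatrix, posthoc_pairwise, rm_anova
from .synthetic import SessionTimeline, generate_cohort

log = logging.getLogger(__name__)

SUMMARY_COLUMNS = [
    "participant", "gender", "generation", "group",
    "stimulus", "window", "index", "ex_mean", "raw_mean", "n_defined",
]

#: Windows entering the statistical analysis (the halves, as in the
#: stimulus-comparison figures); the emotion map additionally uses "all".
STATS_WINDOWS = ("first_half", "latter_half")


def extract_session(
    eeg: RawSignal,
    ppg: RawSignal,
    timeline: SessionTimeline,
    ma_window_s: int = 15,
) -> tuple[list[dict], dict[str, float]]:
    """All per-window index summaries for one session.

    Returns tidy summary rows (one per stimulus x window x index) and the
    participant's resting-state raw index values (used for map origins).
    """
    pid = timeline.participant_id
    meta = {
        "participant": pid,
        "gender": timeline.gender,
        "generation": timeline.generation,
        "group": "_".join(group_key(timeline.gender, timeline.generation)),
    }
    rows: list[dict] = []
    resting: dict[str, float] = {}

    # EEG indexes: 1 Hz series over the whole session, then slice.
    bp = band_powers(eeg)
    series = [
        attention_minus_meditation(bp),
        ma_hbeta_halpha(bp, window_s=ma_window_s),
        band_index(bp, INDEX_DELTA),
        band_index(bp, INDEX_THETA),
    ]
    for s in series:
        baseline, slices = segment_session(timeline, s)
        b = baseline_average(baseline)
        resting[s.name] = b.b_avg
        for stim, wins in slices.items():
            for window, sl in wins.items():
                rows.append(
                    {
                        **meta,
                        **summarize_exposure(normalize(sl, b), sl, pid, stim, window).__dict__,
                    }
                )

    # HRV indexes: computed per analysis window directly from the IBI series.
    beats = detect_beats(ppg)
    ibi = ibi_from_beats(beats)
    base_hrv = hrv_indexes(ibi, (0.0, timeline.pre_rest_s))
    if not np.isfinite(base_hrv.pnn50):
        raise ValueError(f"participant {pid}: undefined HRV baseline; excluded")
    resting[INDEX_PNN50] = base_hrv.pnn50
    resting[INDEX_RMSSD] = base_hrv.rmssd
    for stim, wins in exposure_windows(timeline).items():
        for window, bounds in wins.items():
            h = hrv_indexes(ibi, bounds)
            for index, value, base in (
                (INDEX_PNN50, h.pnn50, base_hrv.pnn50),
                (INDEX_RMSSD, h.rmssd, base_hrv.rmssd),
            ):
                rows.append(
                    {
                        **meta,
                        "participant_id": pid,
                        "stimulus": stim,
                        "window": window,
                        "index_name": index,
                        "ex_mean": value - base if np.isfinite(value) else float("nan"),
                        "raw_mean": value,
                        "n_defined": h.n_intervals,
                    }
                )
    return rows, resting


def _tidy(rows: list[dict]) -> pd.DataFrame:
    df = pd.DataFrame(rows)
    df["index"] = df["index_name"]
    return df[SUMMARY_COLUMNS]


def extract_cohort(sessions) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Run extraction over (member, (eeg, ppg, timeline)) pairs.

    Returns the tidy summary table and a per-participant resting-value
    table. Participants whose extraction fails (e.g. undefined baseline)
    are dropped with a log entry.
    """
    all_rows: list[dict] = []
    resting_rows: list[dict] = []
    for member, (eeg, ppg, timeline) in sessions:
        try:
            rows, resting = extract_session(eeg, ppg, timeline)
        except ValueError as err:
            log.warning("excluding participant %s: %s", member.participant_id, err)
            continue
        all_rows.extend(rows)
        resting_rows.append(
            {
                "participant": member.participant_id,
                "gender": member.gender,
                "generation": member.generation,
                "group": "_".join(group_key(member.gender, member.generation)),
                **resting,
            }
        )
    if not all_rows:
        raise ValueError("no participants survived extraction")
    return _tidy(all_rows), pd.DataFrame(resting_rows)


def analyze(summaries: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Repeated-measures ANOVA + post hoc pairs per group x index x window."""
    anova_rows, pair_rows = [], []
    for (group, index, window), cell in summaries[
        summaries["window"].isin(STATS_WINDOWS)
    ].groupby(["group", "index", "window"]):
        rows = {
            pid: dict(zip(sub["stimulus"], sub["ex_mean"]))
            for pid, sub in cell.groupby("participant")
        }
        m = WithinSubjectMatrix.from_rows(
            rows, STIMULI, index_name=index, group=group, window=window
        )
        if m.data.shape[0] < 3:
            log.warning("skipping %s/%s/%s: <3 complete cases", group, index, window)
            continue
        res = rm_anova(m)
        anova_rows.append(
            {
                "group": group, "index": index, "window": window,
                "n": m.data.shape[0], "F": res.F,
                "df_num": res.df_num, "df_den": res.df_den,
                "p": res.p, "p_gg": res.p_gg, "eps_gg": res.eps_gg,
            }
        )
        for c in posthoc_pairwise(m):
            pair_rows.append(
                {
                    "group": group, "index": index, "window": window,
                    "stim_a": c.stim_a, "stim_b": c.stim_b,
                    "t": c.t, "df": c.df, "p": c.p,
                    "mean_diff": c.mean_diff, "significance": c.significance,
                }
            )
    return pd.DataFrame(anova_rows), pd.DataFrame(pair_rows)


def build_maps(
    summaries: pd.DataFrame,
    resting: pd.DataFrame,
    out_dir: str | Path | None = None,
) -> pd.DataFrame:
    """Emotion maps per group and arousal index; returns the point table.

    When ``out_dir`` is given, full-scale and zoom figures plus companion
    CSVs are written there.
    """
    point_rows = []
    for group, gsum in summaries.groupby("group"):
        pids = gsum.loc[
            (gsum["index"] == INDEX_PNN50) & np.isfinite(gsum["raw_mean"]), "participant"
        ].unique()
        rest_vals = resting.loc[resting["participant"].isin(pids), INDEX_PNN50].to_numpy()
        for arousal_index in emap.AROUSAL_INDEXES:
            points = emap.build_map_points(gsum, group, arousal_index)
            if not points:
                continue
            aro = np.array([p.arousal for p in points])
            x_axis = emap.build_axis(INDEX_PNN50, resting_values=rest_vals)
            y_axis = emap.build_axis(arousal_index, data=aro)
            for p in points:
                quad = (
                    emap.classify_quadrant(p, x_axis, y_axis)
                    if np.isfinite(y_axis.origin)
                    else ""
                )
                point_rows.append(
                    {
                        "group": group, "arousal_index": arousal_index,
                        "stimulus": p.stimulus, "window": p.window,
                        "valence": p.valence, "arousal": p.arousal,
                        "valence_origin": x_axis.origin, "arousal_origin": y_axis.origin,
                        "quadrant": quad,
                    }
                )
            if out_dir is not None:
                stem = f"map_{group}_{arousal_index}"
                emap.render_map(
                    points, x_axis, y_axis, Path(out_dir) / f"{stem}.png",
                    zoom=False, title=f"{group} / {arousal_index}",
                )
                emap.render_map(
                    points, x_axis, y_axis, Path(out_dir) / f"{stem}_zoom.png",
                    zoom=True, title=f"{group} / {arousal_index} (zoom)",
                )
    return pd.DataFrame(point_rows)


def run_pipeline(config: amio.PipelineConfig) -> dict[str, Path]:
    """simulate -> extract -> analyze -> map, writing all result tables."""
    stage = "simulate"
    try:
        cohort = generate_cohort(
            config.group_sizes_tuples(),
            config.effect_spec(),
            seed=config.seed,
            rest_s=config.rest_s,
        )
        if len(cohort) == 0:
            raise ValueError("cohort is empty; nothing to analyze")
        log.info("simulate: %d participants", len(cohort))

        stage = "extract"
        summaries, resting = extract_cohort(cohort.iter_sessions())
        log.info("extract: %d summary rows, %d participants kept",
                 len(summaries), resting.shape[0])

        stage = "analyze"
        anova, pairwise = analyze(summaries)
        log.info("analyze: %d ANOVA cells, %d pairwise rows", len(anova), len(pairwise))

        stage = "map"
        out_dir = Path(config.out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        map_points = build_maps(summaries, resting, out_dir)

        stage = "write"
        return amio.write_results(
            {
                "summaries": summaries,
                "resting": resting,
                "anova": anova,
                "pairwise": pairwise,
                "map_points": map_points,
            },
            out_dir,
            config,
        )
    except Exception as err:
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {err}") from err
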