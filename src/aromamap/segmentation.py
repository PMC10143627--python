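"""Condition segmentation, baseline-change normalization, and grouping.

Normalization removes between-participant offsets: for each index X the
baseline average B_avg = (1/N) * sum_i B_i is taken over the first
pre-resting minute (the only window guaranteed free of stimulus
after-effects), and every exposure sample is replaced by its change
EX = Ex_i - B_avg. Only these changes enter the statistical analysis.

Exposure windows follow the protocol: the full exposure (60 s aromas, 30 s
unpleasant odor) and its first and latter halves, split half-open at the
midpoint. Participants are grouped into four gender x generation-band
groups (male/female x 20s-30s/40s-50s).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .core import WINDOWS, IndexSeries
from .synthetic import SessionTimeline

log = logging.getLogger(__name__)

#: A window summary is reported undefined when more than this fraction of
#: its samples is undefined.
MAX_UNDEFINED_FRACTION = 0.5

GENERATION_BANDS = {
    "20s": "20s-30s",
    "30s": "20s-30s",
    "40s": "40s-50s",
    "50s": "40s-50s",
}


@dataclass(frozen=True)
class BaselineStats:
    """Mean of an index over the pre-resting baseline window."""

    index_name: str
    b_avg: float
    n: int


@dataclass(frozen=True)
class NormalizedSummary:
    """Mean baseline change of one index over one exposure window.

    ``raw_mean`` keeps the un-normalized window mean alongside the change
    ``ex_mean``; the emotion map plots raw means while the statistics use
    the changes.
    """

    participant_id: str
    stimulus: str
    window: str  # all | first_half | latter_half
    index_name: str
    ex_mean: float
    raw_mean: float
    n_defined: int


def exposure_windows(timeline: SessionTimeline) -> dict[str, dict[str, tuple[float, float]]]:
    """Per-stimulus analysis windows: all / first_half / latter_half.

    Halves split the exposure at duration/2 with half-open bounds
    [onset, mid) and [mid, end): 30 s halves for aromas, 15 s for the
    unpleasant odor.
    """
    out: dict[str, dict[str, tuple[float, float]]] = {}
    for ev in timeline.events:
        mid = ev.onset_s + ev.duration_s / 2.0
        out[ev.name] = {
            "all": (ev.onset_s, ev.end_s),
            "first_half": (ev.onset_s, mid),
            "latter_half": (mid, ev.end_s),
        }
    return out


def segment_session(
    timeline: SessionTimeline, series: IndexSeries
) -> tuple[IndexSeries, dict[str, dict[str, IndexSeries]]]:
    """Baseline slice plus per-stimulus all/first/latter slices of a series."""
    end = series.times_s[-1] + 1.0 if series.times_s.size else 0.0
    for ev in timeline.events:
        if ev.end_s > end:
            raise ValueError(
                f"stimulus {ev.name!r} window ends at {ev.end_s:.0f} s "
                f"but the recording covers only {end:.0f} s"
            )
    baseline = series.slice(0.0, timeline.pre_rest_s)
    slices = {
        stim: {w: series.slice(*bounds) for w, bounds in wins.items()}
        for stim, wins in exposure_windows(timeline).items()
    }
    return baseline, slices


def baseline_average(baseline: IndexSeries) -> BaselineStats:
    """Arithmetic mean of the defined baseline samples (Eq. B_avg)."""
    defined = baseline.values[np.isfinite(baseline.values)]
    if defined.size == 0:
        raise ValueError(
            f"baseline for {baseline.name!r} has no defined samples; participant excluded"
        )
    return BaselineStats(baseline.name, float(defined.mean()), int(defined.size))


def normalize(series: IndexSeries, b: BaselineStats) -> IndexSeries:
    """Elementwise change from baseline, EX = Ex_i - B_avg."""
    if series.name != b.index_name:
        raise ValueError(f"index mismatch: series {series.name!r} vs baseline {b.index_name!r}")
    return IndexSeries(series.name, series.times_s, series.values - b.b_avg)


def summarize_exposure(
    ex: IndexSeries,
    raw: IndexSeries,
    participant_id: str,
    stimulus: str,
    window: str,
) -> NormalizedSummary:
    """Window mean of the EX changes (and of the raw values).

    Undefined samples are excluded; if more than half the window is
    undefined the summary itself is undefined (NaN) and logged.
    """
    if window not in WINDOWS:
        raise ValueError(f"unknown window {window!r}")
    finite = np.isfinite(ex.values)
    n_def = int(finite.sum())
    undefined_frac = 1.0 - n_def / ex.values.size if ex.values.size else 1.0
    if n_def == 0 or undefined_frac > MAX_UNDEFINED_FRACTION:
        log.info(
            "summary undefined: %s/%s/%s/%s (%d of %d defined)",
            participant_id, stimulus, window, ex.name, n_def, ex.values.size,
        )
        return NormalizedSummary(
            participant_id, stimulus, window, ex.name, float("nan"), float("nan"), n_def
        )
    raw_finite = raw.values[np.isfinite(raw.values)]
    return NormalizedSummary(
        participant_id,
        stimulus,
        window,
        ex.name,
        float(ex.values[finite].mean()),
        float(raw_finite.mean()) if raw_finite.size else float("nan"),
        n_def,
    )


def group_key(gender: str, generation: str) -> tuple[str, str]:
    """(gender, generation-band) group of one participant."""
    if gender not in ("male", "female"):
        raise ValueError(f"unknown gender {gender!r}")
    if generation not in GENERATION_BANDS:
        raise ValueError(f"unknown generation {generation!r}")
    return gender, GENERATION_BANDS[generation]


def group_participants(
    manifest: list[tuple[str, str, str]]
) -> dict[tuple[str, str], list[str]]:
    """Partition participants into the four gender x generation-band groups.

    ``manifest`` rows are (participant_id, gender, generation). The result
    always contains all four keys; the partition is exhaustive and disjoint.
    """
    groups: dict[tuple[str, str], list[str]] = {
        (g, b): [] for g in ("male", "female") for b in ("20s-30s", "40s-50s")
    }
    for pid, gender, generation in manifest:
        groups[group_key(gender, generation)].append(pid)
    return groups
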