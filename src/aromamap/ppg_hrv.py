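"""Beat detection and ultra-short-term HRV valence indexes (pNN50, RMSSD).

Both indexes operate on successive differences of normal-to-normal (NN)
inter-beat intervals and are therefore suitable for the 30-60 s exposure
windows of the protocol: pNN50 is the proportion of successive differences
exceeding 50 ms (a parasympathetic / valence proxy, reported in [0, 1]);
RMSSD is the root mean square of the successive differences in ms (a
stress-relax index).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.signal import find_peaks

from .core import IBI_MAX_MS, IBI_MIN_MS, IBISeries, RawSignal

log = logging.getLogger(__name__)

#: Strict threshold (ms) on |delta NN| for the NN50 count.
PNN_THRESHOLD_MS = 50.0

#: Minimum spacing between detected beats (s); a 300 ms refractory period
#: corresponds to the 200 bpm physiologic ceiling implied by the IBI clamp.
REFRACTORY_S = 0.3


@dataclass(frozen=True)
class HRVIndexes:
    """pNN50 and RMSSD over one analysis window."""

    pnn50: float
    rmssd: float
    n_intervals: int
    window: tuple[float, float]


def detect_beats(
    signal: RawSignal,
    fs_hz: float | None = None,
    k_mad: float = 3.0,
    threshold_window_s: float = 2.0,
) -> np.ndarray:
    """Beat times (s) as thresholded local maxima of the PPG.

    A sample qualifies as a beat when it is a local maximum, exceeds an
    adaptive threshold (rolling median + ``k_mad`` * rolling MAD over
    ``threshold_window_s``), and is at least 300 ms after the previous beat.
    A flat signal yields an empty result with a warning, not an exception.
    """
    fs = fs_hz if fs_hz is not None else signal.fs_hz
    x = signal.values
    if x.size < 2 * fs:
        raise ValueError("PPG must be at least 2 s long")

    # Rolling median/MAD evaluated on a coarse stride then interpolated:
    # the threshold varies on the 2 s scale, so a ~0.1 s stride loses nothing.
    win = max(int(threshold_window_s * fs), 3)
    stride = max(int(0.1 * fs), 1)
    anchors = np.arange(0, x.size, stride)
    s = pd.Series(x)
    med = s.rolling(win, min_periods=1, center=True, step=stride).median().to_numpy()
    dev = (s - pd.Series(np.interp(np.arange(x.size), anchors, med))).abs()
    mad = dev.rolling(win, min_periods=1, center=True, step=stride).median().to_numpy()
    threshold = np.interp(np.arange(x.size), anchors, med + k_mad * mad)

    peaks, _ = find_peaks(x, distance=max(int(REFRACTORY_S * fs), 1))
    peaks = peaks[x[peaks] > threshold[peaks]]
    if peaks.size == 0:
        warnings.warn("no beats detected (flat or sub-threshold signal)", stacklevel=2)
        return np.empty(0)
    return peaks / fs


def ibi_from_beats(beat_times_s: np.ndarray) -> IBISeries:
    """NN-interval series from beat times, with a physiologic plausibility clamp.

    Intervals outside [300, 2000] ms are flagged invalid (kept in place so
    adjacency is preserved); downstream successive-difference pairs touching
    a flagged interval are excluded. Removal counts are logged.
    """
    beat_times_s = np.asarray(beat_times_s, dtype=float)
    if beat_times_s.size < 2:
        raise ValueError("need at least 2 beats to form an interval")
    intervals = np.diff(beat_times_s) * 1000.0
    valid = (intervals >= IBI_MIN_MS) & (intervals <= IBI_MAX_MS)
    n_bad = int((~valid).sum())
    if n_bad:
        log.info("ibi_from_beats: flagged %d implausible interval(s)", n_bad)
    return IBISeries(beat_times_s=beat_times_s, intervals_ms=intervals, valid=valid)


def _window_diff_pairs(
    ibi: IBISeries, window: tuple[float, float] | None
) -> np.ndarray:
    """Successive differences over consecutive valid intervals in a window.

    An interval belongs to the window iff its second beat falls inside it
    (half-open [start, end)); a difference is counted only when the two
    intervals are adjacent in the original series and both valid.
    """
    intervals = ibi.intervals_ms
    mask = ibi.valid.copy()
    if window is not None:
        start, end = window
        second_beats = ibi.beat_times_s[1:]
        mask &= (second_beats >= start) & (second_beats < end)
    if intervals.size < 2:
        return np.empty(0)
    pair_ok = mask[:-1] & mask[1:]
    return np.diff(intervals)[pair_ok]


def pnn50(
    ibi: IBISeries,
    window: tuple[float, float] | None = None,
    threshold_ms: float = PNN_THRESHOLD_MS,
) -> float:
    """Proportion of successive NN differences strictly exceeding 50 ms.

    Returns NaN (undefined) when fewer than two intervals fall in the window.
    """
    d = _window_diff_pairs(ibi, window)
    if d.size == 0:
        return float("nan")
    return float(np.count_nonzero(np.abs(d) > threshold_ms) / d.size)


def rmssd(ibi: IBISeries, window: tuple[float, float] | None = None) -> float:
    """Root mean square of successive NN differences (ms); NaN if undefined."""
    d = _window_diff_pairs(ibi, window)
    if d.size == 0:
        return float("nan")
    return float(np.sqrt(np.mean(d**2)))


def hrv_indexes(ibi: IBISeries, window: tuple[float, float]) -> HRVIndexes:
    """Both HRV indexes plus bookkeeping for one analysis window."""
    d = _window_diff_pairs(ibi, window)
    if d.size == 0:
        return HRVIndexes(float("nan"), float("nan"), 0, window)
    return HRVIndexes(
        pnn50=float(np.count_nonzero(np.abs(d) > PNN_THRESHOLD_MS) / d.size),
        rmssd=float(np.sqrt(np.mean(d**2))),
        n_intervals=int(d.size + 1),
        window=window,
    )
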