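"""Per-second EEG band powers and the arousal indexes built from them.

The analysis mirrors the ~1 Hz output cadence of a single-channel consumer
EEG headset: the raw signal is cut into non-overlapping 1 s epochs, each
epoch gets a Hann-windowed periodogram, and the power spectral density is
integrated over each band's closed frequency range (delta 1-3 Hz through
gamma 31-50 Hz).

Arousal indexes:

* ``surrogate_attention_meditation`` - transparent stand-ins for the
  proprietary Attention/Meditation scores. Attention is known to emphasize
  beta activity and Meditation alpha activity, so the surrogates are the
  relative beta and alpha power shares scaled to 0-100. Their difference
  (Attention - Meditation) spans [-100, 100] with neutral point 0.
* ``hbeta_halpha_ratio`` - high-beta / high-alpha power ratio; high values
  indicate high arousal. Note the ratio is high-beta over high-alpha
  (numerator high-beta): the alert band on top, so alertness raises the
  index.
* delta and theta band powers are used directly as raw, unitless series.

Smoothing: a trailing 15 s moving average (``moving_average``) is applied to
the per-second ratio series before analysis, giving the "MA high-beta /
high-alpha" index.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.signal import periodogram

from .core import (
    BAND_NAMES,
    BANDS,
    INDEX_ATT_MED,
    INDEX_MA_HB_HA,
    BandPowerSeries,
    IndexSeries,
    RawSignal,
)

#: Analysis-wide spectral ceiling (Hz): the top of the gamma band.
_F_MAX = 50.0


def band_powers(signal: RawSignal, fs_hz: float | None = None) -> BandPowerSeries:
    """Band power per non-overlapping 1 s epoch (trailing partial epoch dropped)."""
    fs = float(fs_hz if fs_hz is not None else signal.fs_hz)
    if fs < 2.0 * _F_MAX:
        raise ValueError(f"sampling rate {fs} Hz cannot resolve {_F_MAX} Hz")
    n_per = int(round(fs))
    n_epochs = signal.values.size // n_per
    if n_epochs < 1:
        raise ValueError("signal must be at least 1 s long")
    epochs = signal.values[: n_epochs * n_per].reshape(n_epochs, n_per)
    freqs, psd = periodogram(epochs, fs=fs, window="hann", axis=1)
    powers = {}
    for band in BAND_NAMES:
        lo, hi = BANDS[band]
        sel = (freqs >= lo) & (freqs <= hi)
        powers[band] = psd[:, sel].sum(axis=1)
    return BandPowerSeries(epoch_times_s=np.arange(n_epochs, dtype=float), powers=powers)


def total_power_1_50(bp: BandPowerSeries) -> np.ndarray:
    """Per-epoch power summed over the full 1-50 Hz analysis range."""
    return bp.total()


def surrogate_attention_meditation(bp: BandPowerSeries) -> tuple[IndexSeries, IndexSeries]:
    """Surrogate Attention and Meditation scores on the 0-100 scale.

    Attention = 100 * (low-beta + high-beta) / T and
    Meditation = 100 * (low-alpha + high-alpha) / T, where T is the summed
    power of all seven bands. Epochs with T = 0 are undefined (NaN), not 0.
    """
    total = bp.total()
    beta = bp.powers["low_beta"] + bp.powers["high_beta"]
    alpha = bp.powers["low_alpha"] + bp.powers["high_alpha"]
    with np.errstate(invalid="ignore", divide="ignore"):
        att = np.where(total > 0, 100.0 * beta / total, np.nan)
        med = np.where(total > 0, 100.0 * alpha / total, np.nan)
    return (
        IndexSeries("attention_surrogate", bp.epoch_times_s, att),
        IndexSeries("meditation_surrogate", bp.epoch_times_s, med),
    )


def attention_minus_meditation(bp: BandPowerSeries) -> IndexSeries:
    """Arousal index: surrogate Attention minus Meditation, in [-100, 100]."""
    att, med = surrogate_attention_meditation(bp)
    return IndexSeries(INDEX_ATT_MED, bp.epoch_times_s, att.values - med.values)


def hbeta_halpha_ratio(bp: BandPowerSeries, epsilon: float = 1e-12) -> IndexSeries:
    """High-beta / high-alpha power ratio per epoch; epsilon guards division."""
    ratio = bp.powers["high_beta"] / (bp.powers["high_alpha"] + epsilon)
    return IndexSeries("hb_ha", bp.epoch_times_s, ratio)


def moving_average(series: IndexSeries, window_s: int = 15, name: str | None = None) -> IndexSeries:
    """Trailing mean over the last ``window_s`` samples of a 1 Hz series.

    The first ``window_s - 1`` samples use the expanding prefix mean (no
    future samples are ever used). Undefined (NaN) inputs are excluded from
    each window's mean; a window with no defined samples stays undefined.
    """
    if window_s < 1:
        raise ValueError("window must be at least 1 sample")
    if series.values.size == 0:
        return IndexSeries(name or series.name, series.times_s, series.values)
    smoothed = (
        pd.Series(series.values).rolling(window_s, min_periods=1).mean().to_numpy()
    )
    return IndexSeries(name or series.name, series.times_s, smoothed)


def ma_hbeta_halpha(bp: BandPowerSeries, window_s: int = 15) -> IndexSeries:
    """The smoothed arousal ratio: 15 s moving average of high-beta/high-alpha."""
    return moving_average(hbeta_halpha_ratio(bp), window_s=window_s, name=INDEX_MA_HB_HA)


def band_index(bp: BandPowerSeries, band: str) -> IndexSeries:
    """A raw band-power series (e.g. delta or theta) as an index."""
    if band not in BAND_NAMES:
        raise ValueError(f"unknown band {band!r}")
    return IndexSeries(band, bp.epoch_times_s, bp.powers[band])
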