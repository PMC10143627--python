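"""Shared data containers and domain constants.

All times are seconds from session start; inter-beat intervals are
milliseconds; EEG band powers are unitless magnitudes (power, not amplitude).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: EEG frequency bands (closed ranges, Hz) as reported by single-channel
#: consumer EEG headsets: delta through gamma.
BANDS: dict[str, tuple[float, float]] = {
    "delta": (1.0, 3.0),
    "theta": (4.0, 7.0),
    "low_alpha": (8.0, 9.0),
    "high_alpha": (10.0, 12.0),
    "low_beta": (13.0, 17.0),
    "high_beta": (18.0, 30.0),
    "gamma": (31.0, 50.0),
}

BAND_NAMES: tuple[str, ...] = tuple(BANDS)

#: The six aroma stimuli plus the unpleasant odor (isovaleric acid),
#: which is always presented last.
AROMAS: tuple[str, ...] = ("citrus", "lavender", "soap", "woody", "fruity", "floral")
UNPLEASANT: str = "unpleasant"
STIMULI: tuple[str, ...] = AROMAS + (UNPLEASANT,)

AROMA_DURATION_S: float = 60.0
UNPLEASANT_DURATION_S: float = 30.0
REST_DURATION_S: float = 60.0

#: Physiologically plausible inter-beat-interval range (ms); intervals
#: outside this range are treated as detection artifacts.
IBI_MIN_MS: float = 300.0
IBI_MAX_MS: float = 2000.0

#: Index names used throughout the pipeline.
INDEX_ATT_MED = "att_minus_med"
INDEX_MA_HB_HA = "ma_hb_ha"
INDEX_DELTA = "delta"
INDEX_THETA = "theta"
INDEX_PNN50 = "pnn50"
INDEX_RMSSD = "rmssd"

EEG_INDEXES: tuple[str, ...] = (INDEX_ATT_MED, INDEX_MA_HB_HA, INDEX_DELTA, INDEX_THETA)
HRV_INDEXES: tuple[str, ...] = (INDEX_PNN50, INDEX_RMSSD)
ALL_INDEXES: tuple[str, ...] = EEG_INDEXES + HRV_INDEXES

WINDOWS: tuple[str, ...] = ("all", "first_half", "latter_half")


@dataclass(frozen=True)
class RawSignal:
    """A uniformly sampled one-dimensional signal (EEG or PPG)."""

    values: np.ndarray
    fs_hz: float
    channel: str = "eeg"

    def __post_init__(self) -> None:
        object.__setattr__(self, "values", np.asarray(self.values, dtype=float))
        if self.values.ndim != 1:
            raise ValueError("signal must be one-dimensional")
        if self.fs_hz <= 0:
            raise ValueError("sampling rate must be positive")

    @property
    def duration_s(self) -> float:
        return self.values.size / self.fs_hz

    @property
    def times_s(self) -> np.ndarray:
        return np.arange(self.values.size) / self.fs_hz


@dataclass
class IBISeries:
    """Beat times (s) with successive inter-beat intervals (ms).

    ``intervals_ms[k]`` spans ``beat_times_s[k]`` to ``beat_times_s[k+1]``.
    ``valid[k]`` is False for intervals outside the physiologic range; they
    are kept in place so that adjacency of the surviving intervals is known.
    """

    beat_times_s: np.ndarray
    intervals_ms: np.ndarray = field(default=None)  # type: ignore[assignment]
    valid: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.beat_times_s = np.asarray(self.beat_times_s, dtype=float)
        if self.beat_times_s.size and np.any(np.diff(self.beat_times_s) <= 0):
            raise ValueError("beat times must be strictly increasing")
        if self.intervals_ms is None:
            self.intervals_ms = np.diff(self.beat_times_s) * 1000.0
        else:
            self.intervals_ms = np.asarray(self.intervals_ms, dtype=float)
        if self.valid is None:
            self.valid = np.ones(self.intervals_ms.size, dtype=bool)
        else:
            self.valid = np.asarray(self.valid, dtype=bool)
        if self.intervals_ms.size != max(self.beat_times_s.size - 1, 0):
            raise ValueError("need exactly len(beats) - 1 intervals")
        if self.valid.size != self.intervals_ms.size:
            raise ValueError("valid mask must match intervals")

    @property
    def n_intervals(self) -> int:
        return int(self.intervals_ms.size)

    @property
    def n_removed(self) -> int:
        return int((~self.valid).sum())


@dataclass
class BandPowerSeries:
    """Per-1-s-epoch power in each EEG band; one row per full epoch."""

    epoch_times_s: np.ndarray
    powers: dict[str, np.ndarray]

    def __post_init__(self) -> None:
        self.epoch_times_s = np.asarray(self.epoch_times_s, dtype=float)
        missing = set(BAND_NAMES) - set(self.powers)
        if missing:
            raise ValueError(f"missing bands: {sorted(missing)}")
        for name, arr in self.powers.items():
            arr = np.asarray(arr, dtype=float)
            if arr.size != self.epoch_times_s.size:
                raise ValueError(f"band {name!r} length mismatch")
            self.powers[name] = arr

    @property
    def n_epochs(self) -> int:
        return int(self.epoch_times_s.size)

    def total(self) -> np.ndarray:
        """Summed power over all seven bands, per epoch."""
        return np.sum([self.powers[b] for b in BAND_NAMES], axis=0)


@dataclass
class IndexSeries:
    """A 1 Hz series of one named biological index.

    NaN marks epochs where the index is undefined (e.g. zero total EEG
    power); undefined values propagate and are excluded from averages.
    """

    name: str
    times_s: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        self.times_s = np.asarray(self.times_s, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.times_s.size != self.values.size:
            raise ValueError("times and values must have equal length")
        if self.times_s.size > 1:
            steps = np.diff(self.times_s)
            if not np.allclose(steps, 1.0, atol=1e-9):
                raise ValueError("index series must be on a uniform 1 Hz grid")

    def slice(self, start_s: float, end_s: float) -> "IndexSeries":
        """Half-open time slice [start_s, end_s)."""
        mask = (self.times_s >= start_s) & (self.times_s < end_s)
        return IndexSeries(self.name, self.times_s[mask], self.values[mask])
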