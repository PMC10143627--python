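"""Synthetic EEG/PPG session generator.

Emulates the olfactory-stimulation protocol: a 60 s pre-rest baseline, then
seven stimulus exposures (six aromas for 60 s each in randomized order, the
unpleasant odor last for 30 s), each followed by a 60 s rest. Two signals are
produced per session: single-channel EEG at 512 Hz with controllable
per-band power, and a fingertip PPG at 500 Hz driven by an inter-beat
interval (IBI) process with controllable successive-difference variability,
so that target pNN50/RMSSD levels are recoverable by the analysis pipeline.

The IBI process is a stationary AR(1) on the intervals,

    x[k+1] = mu + phi * (x[k] - mu) + e[k],   e[k] ~ N(0, s_e^2),

with phi = 0.5 and s_e chosen so that the successive differences
d[k] = x[k+1] - x[k] are exactly Gaussian with standard deviation sigma_d.
This gives closed-form targets: E[RMSSD] -> sigma_d and
E[pNN50] = 2 * Phi(-50 / sigma_d). Mean reversion keeps intervals near mu;
a physiologic clamp at [300, 2000] ms guards the tails.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .core import (
    AROMA_DURATION_S,
    AROMAS,
    BAND_NAMES,
    BANDS,
    IBI_MAX_MS,
    IBI_MIN_MS,
    REST_DURATION_S,
    STIMULI,
    UNPLEASANT,
    UNPLEASANT_DURATION_S,
    IBISeries,
    RawSignal,
)

#: AR(1) pole of the interval process. With phi = 0.5 the stationary
#: marginal SD of the intervals equals sigma_d, and the innovation SD is
#: sigma_d * sqrt((1 + phi) / 2).
_PHI = 0.5

#: Guard band (Hz) kept clear at each band edge when synthesizing
#: band-limited noise; see docs for why this matters at 1 Hz resolution.
_EDGE_GUARD_HZ = 0.25

#: Number of random-phase sinusoids per band in noise mode.
_N_COMPONENTS = 12

GENERATIONS = ("20s", "30s", "40s", "50s")
GENDER_BANDS = (
    ("male", "20s-30s"),
    ("male", "40s-50s"),
    ("female", "20s-30s"),
    ("female", "40s-50s"),
)


@dataclass(frozen=True)
class StimulusEvent:
    """One stimulus exposure window."""

    name: str
    stim_type: str  # "aroma" | "unpleasant"
    onset_s: float
    duration_s: float

    def __post_init__(self) -> None:
        if self.stim_type not in ("aroma", "unpleasant"):
            raise ValueError(f"unknown stim_type {self.stim_type!r}")
        expected = AROMA_DURATION_S if self.stim_type == "aroma" else UNPLEASANT_DURATION_S
        if self.duration_s != expected:
            raise ValueError(
                f"{self.stim_type} exposure must last {expected:.0f} s, got {self.duration_s}"
            )
        if self.onset_s < 0:
            raise ValueError("onset must be non-negative")

    @property
    def end_s(self) -> float:
        return self.onset_s + self.duration_s


@dataclass(frozen=True)
class SessionTimeline:
    """Condition schedule of one session plus participant metadata."""

    events: tuple[StimulusEvent, ...]
    participant_id: str
    gender: str
    generation: str
    pre_rest_s: float = REST_DURATION_S
    rest_s: float = REST_DURATION_S

    def __post_init__(self) -> None:
        if self.gender not in ("male", "female"):
            raise ValueError(f"unknown gender {self.gender!r}")
        if self.generation not in GENERATIONS:
            raise ValueError(f"unknown generation {self.generation!r}")
        if len(self.events) != 7:
            raise ValueError("a session has exactly 7 stimulus events")
        if self.events[-1].name != UNPLEASANT:
            raise ValueError("the unpleasant odor must be the last stimulus")
        if sorted(e.name for e in self.events[:-1]) != sorted(AROMAS):
            raise ValueError("the first six events must be a permutation of the aromas")
        prev_end = self.pre_rest_s
        for ev in self.events:
            if ev.onset_s < prev_end:
                raise ValueError(f"event {ev.name!r} overlaps the preceding window")
            prev_end = ev.end_s

    @classmethod
    def standard(
        cls,
        aroma_order: tuple[str, ...] | list[str],
        participant_id: str = "p000",
        gender: str = "male",
        generation: str = "20s",
        rest_s: float = REST_DURATION_S,
    ) -> "SessionTimeline":
        """Timeline with a rest block after every exposure."""
        events = []
        t = rest_s  # pre-rest occupies [0, rest_s)
        for name in list(aroma_order) + [UNPLEASANT]:
            stype = "unpleasant" if name == UNPLEASANT else "aroma"
            dur = UNPLEASANT_DURATION_S if stype == "unpleasant" else AROMA_DURATION_S
            events.append(StimulusEvent(name, stype, t, dur))
            t += dur + rest_s
        return cls(
            events=tuple(events),
            participant_id=participant_id,
            gender=gender,
            generation=generation,
            pre_rest_s=rest_s,
            rest_s=rest_s,
        )

    @property
    def duration_s(self) -> float:
        return self.events[-1].end_s + self.rest_s

    def condition_at(self, t: float) -> str | None:
        """Stimulus name active at time t, or None during rest."""
        for ev in self.events:
            if ev.onset_s <= t < ev.end_s:
                return ev.name
        return None

    def windows(self) -> list[tuple[float, float, str | None]]:
        """Contiguous (start, end, stimulus-or-None) partition of the session."""
        out: list[tuple[float, float, str | None]] = [(0.0, self.pre_rest_s, None)]
        t = self.pre_rest_s
        for ev in self.events:
            if ev.onset_s > t:
                out.append((t, ev.onset_s, None))
            out.append((ev.onset_s, ev.end_s, ev.name))
            t = ev.end_s
        out.append((t, t + self.rest_s, None))
        return out


def _default_baseline_amps() -> dict[str, float]:
    # Resting frontal EEG: alpha-dominant, modest beta, some slow-wave power.
    return {
        "delta": 1.2,
        "theta": 1.0,
        "low_alpha": 1.4,
        "high_alpha": 1.6,
        "low_beta": 0.9,
        "high_beta": 0.7,
        "gamma": 0.3,
    }


@dataclass(frozen=True)
class EffectSpec:
    """Per-stimulus generator parameters.

    ``band_multipliers[stim][band]`` scales the baseline EEG amplitude of one
    band during that stimulus; ``sigma_d_ms[stim]`` sets the IBI
    successive-difference SD during that stimulus. Rest windows use the
    baseline parameters.
    """

    baseline_mean_ibi_ms: float = 800.0
    baseline_sigma_d_ms: float = 25.0
    baseline_band_amps: dict[str, float] = field(default_factory=_default_baseline_amps)
    band_multipliers: dict[str, dict[str, float]] = field(default_factory=dict)
    sigma_d_ms: dict[str, float] = field(default_factory=dict)
    eeg_noise_sd: float = 0.1
    ppg_noise_sd: float = 0.0

    def __post_init__(self) -> None:
        if not IBI_MIN_MS <= self.baseline_mean_ibi_ms <= IBI_MAX_MS:
            raise ValueError("mean IBI must lie in [300, 2000] ms")
        if self.baseline_sigma_d_ms < 0:
            raise ValueError("sigma_d must be non-negative")
        for stim, mults in self.band_multipliers.items():
            if stim not in STIMULI:
                raise ValueError(f"unknown stimulus {stim!r}")
            for band, m in mults.items():
                if band not in BAND_NAMES:
                    raise ValueError(f"unknown band {band!r}")
                if m <= 0:
                    raise ValueError("band multipliers must be positive")
        for stim, s in self.sigma_d_ms.items():
            if stim not in STIMULI:
                raise ValueError(f"unknown stimulus {stim!r}")
            if s < 0:
                raise ValueError("sigma_d must be non-negative")

    @classmethod
    def null(cls) -> "EffectSpec":
        """No stimulus effects: every window uses baseline parameters."""
        return cls()

    @classmethod
    def illustrative(cls) -> "EffectSpec":
        """Plausible effect pattern used by the demo pipeline.

        Lavender raises vagally mediated IBI variability (higher pNN50),
        citrus lowers it, and the unpleasant odor shifts EEG power toward
        high-beta (higher arousal) while suppressing alpha. Magnitudes are
        illustrative; the study reports no effect sizes in physical units.
        """
        return cls(
            sigma_d_ms={"lavender": 40.0, "citrus": 15.0, UNPLEASANT: 18.0},
            band_multipliers={
                "lavender": {"high_alpha": 1.3, "high_beta": 0.8},
                UNPLEASANT: {"high_beta": 1.6, "high_alpha": 0.7, "delta": 1.3},
            },
        )

    def amps_for(self, stimulus: str | None) -> dict[str, float]:
        amps = dict(self.baseline_band_amps)
        if stimulus is not None:
            for band, m in self.band_multipliers.get(stimulus, {}).items():
                amps[band] *= m
        return amps

    def sigma_for(self, stimulus: str | None) -> float:
        if stimulus is None:
            return self.baseline_sigma_d_ms
        return self.sigma_d_ms.get(stimulus, self.baseline_sigma_d_ms)


def _as_rng(seed: int | np.random.Generator | np.random.SeedSequence) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def generate_ibi_series(
    duration_s: float,
    mean_ibi_ms: float = 800.0,
    sigma_d_ms: float = 25.0,
    seed: int | np.random.Generator = 0,
) -> IBISeries:
    """Beat times covering [0, duration_s] from the AR(1) interval model."""
    if duration_s <= 0:
        raise ValueError("duration must be positive")
    if not IBI_MIN_MS <= mean_ibi_ms <= IBI_MAX_MS:
        raise ValueError("mean IBI must lie in [300, 2000] ms")
    if sigma_d_ms < 0:
        raise ValueError("sigma_d must be non-negative")
    rng = _as_rng(seed)
    sig_eps = sigma_d_ms * math.sqrt((1.0 + _PHI) / 2.0)
    x = mean_ibi_ms + rng.normal(0.0, sigma_d_ms) if sigma_d_ms > 0 else mean_ibi_ms
    intervals: list[float] = []
    total = 0.0
    target = duration_s * 1000.0
    while total < target:
        x = float(np.clip(x, IBI_MIN_MS, IBI_MAX_MS))
        intervals.append(x)
        total += x
        x = mean_ibi_ms + _PHI * (x - mean_ibi_ms) + (rng.normal(0.0, sig_eps) if sig_eps > 0 else 0.0)
    beats = np.concatenate([[0.0], np.cumsum(intervals) / 1000.0])
    return IBISeries(beat_times_s=beats, intervals_ms=np.asarray(intervals))


def generate_ppg(
    ibi: IBISeries,
    fs_hz: float = 500.0,
    pulse_width_s: float = 0.12,
    noise_sd: float = 0.0,
    seed: int | np.random.Generator = 0,
    duration_s: float | None = None,
) -> RawSignal:
    """PPG as one Gaussian pulse centered at each beat time plus white noise."""
    if ibi.beat_times_s.size == 0:
        raise ValueError("IBI series has no beats")
    if fs_hz <= 2.0 / pulse_width_s:
        raise ValueError("sampling rate too low to resolve the pulse shape")
    rng = _as_rng(seed)
    if duration_s is None:
        duration_s = float(ibi.beat_times_s[-1]) + 2.0 * pulse_width_s
    n = int(round(duration_s * fs_hz))
    signal = np.zeros(n)
    sigma = pulse_width_s / 4.0  # pulse_width spans ~ +/- 2 sigma
    half = int(math.ceil(4.0 * sigma * fs_hz))
    offsets = np.arange(-half, half + 1)
    for tb in ibi.beat_times_s:
        center = int(round(tb * fs_hz))
        idx = center + offsets
        keep = (idx >= 0) & (idx < n)
        t_rel = idx[keep] / fs_hz - tb
        signal[idx[keep]] += np.exp(-0.5 * (t_rel / sigma) ** 2)
    if noise_sd > 0:
        signal += rng.normal(0.0, noise_sd, size=n)
    return RawSignal(signal, fs_hz, channel="ppg")


def generate_eeg(
    duration_s: float,
    fs_hz: float = 512.0,
    band_amplitudes: dict[str, float] | None = None,
    noise_sd: float = 0.0,
    seed: int | np.random.Generator = 0,
    mode: str = "noise",
) -> RawSignal:
    """Sum of band-limited processes, one per EEG band, plus white noise.

    In ``noise`` mode each band is a sum of random-phase sinusoids with
    frequencies drawn uniformly from the band interior; in ``sinusoid`` mode
    it is a single sinusoid at the band center. Either way the band's RMS
    amplitude equals ``band_amplitudes[band]``, so its power contribution is
    the amplitude squared.
    """
    if duration_s <= 0:
        raise ValueError("duration must be positive")
    if mode not in ("noise", "sinusoid"):
        raise ValueError(f"unknown mode {mode!r}")
    band_amplitudes = band_amplitudes or {}
    unknown = set(band_amplitudes) - set(BAND_NAMES)
    if unknown:
        raise ValueError(f"unknown band(s): {sorted(unknown)}")
    if any(a < 0 for a in band_amplitudes.values()):
        raise ValueError("band amplitudes must be non-negative")
    rng = _as_rng(seed)
    n = int(round(duration_s * fs_hz))
    t = np.arange(n) / fs_hz
    signal = np.zeros(n)
    for band in BAND_NAMES:
        amp = band_amplitudes.get(band, 0.0)
        if amp == 0.0:
            continue
        lo, hi = BANDS[band]
        if mode == "sinusoid":
            phase = rng.uniform(0.0, 2.0 * np.pi)
            signal += amp * math.sqrt(2.0) * np.sin(2.0 * np.pi * 0.5 * (lo + hi) * t + phase)
        else:
            freqs = rng.uniform(lo + _EDGE_GUARD_HZ, hi - _EDGE_GUARD_HZ, size=_N_COMPONENTS)
            phases = rng.uniform(0.0, 2.0 * np.pi, size=_N_COMPONENTS)
            comp_amp = amp * math.sqrt(2.0 / _N_COMPONENTS)
            signal += comp_amp * np.sin(
                2.0 * np.pi * t[:, None] * freqs[None, :] + phases[None, :]
            ).sum(axis=1)
    if noise_sd > 0:
        signal += rng.normal(0.0, noise_sd, size=n)
    return RawSignal(signal, fs_hz, channel="eeg")


def generate_session(
    timeline: SessionTimeline,
    effects: EffectSpec | None = None,
    seed: int | np.random.SeedSequence = 0,
    eeg_fs_hz: float = 512.0,
    ppg_fs_hz: float = 500.0,
) -> tuple[RawSignal, RawSignal, SessionTimeline]:
    """One full session: contiguous EEG and PPG honoring the timeline.

    Within each stimulus window the generators use that stimulus's
    parameters from ``effects``; rest windows use the baseline parameters.
    """
    effects = effects or EffectSpec.null()
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    eeg_ss, ibi_ss, ppg_ss = ss.spawn(3)
    duration = timeline.duration_s

    # EEG: generate each condition window with its own parameters, concatenate.
    eeg_rng = np.random.default_rng(eeg_ss)
    segments = []
    for start, end, stim in timeline.windows():
        seg = generate_eeg(
            end - start,
            fs_hz=eeg_fs_hz,
            band_amplitudes=effects.amps_for(stim),
            noise_sd=effects.eeg_noise_sd,
            seed=eeg_rng,
        )
        segments.append(seg.values)
    eeg = RawSignal(np.concatenate(segments), eeg_fs_hz, channel="eeg")

    # IBI: one AR(1) track whose sigma_d switches with the active condition.
    ibi_rng = np.random.default_rng(ibi_ss)
    mu = effects.baseline_mean_ibi_ms
    sigma0 = effects.sigma_for(timeline.condition_at(0.0))
    x = mu + (ibi_rng.normal(0.0, sigma0) if sigma0 > 0 else 0.0)
    intervals: list[float] = []
    total = 0.0
    while total < duration * 1000.0:
        x = float(np.clip(x, IBI_MIN_MS, IBI_MAX_MS))
        intervals.append(x)
        total += x
        sig = effects.sigma_for(timeline.condition_at(total / 1000.0))
        sig_eps = sig * math.sqrt((1.0 + _PHI) / 2.0)
        x = mu + _PHI * (x - mu) + (ibi_rng.normal(0.0, sig_eps) if sig_eps > 0 else 0.0)
    beats = np.concatenate([[0.0], np.cumsum(intervals) / 1000.0])
    ibi = IBISeries(beat_times_s=beats)
    ppg = generate_ppg(
        ibi,
        fs_hz=ppg_fs_hz,
        noise_sd=effects.ppg_noise_sd,
        seed=np.random.default_rng(ppg_ss),
        duration_s=duration,
    )
    return eeg, ppg, timeline


@dataclass(frozen=True)
class CohortMember:
    """Metadata plus the seed needed to regenerate one participant's session."""

    participant_id: str
    gender: str
    generation: str
    timeline: SessionTimeline
    effects: EffectSpec
    seed: np.random.SeedSequence

    def session(self) -> tuple[RawSignal, RawSignal, SessionTimeline]:
        return generate_session(self.timeline, self.effects, seed=self.seed)


@dataclass(frozen=True)
class Cohort:
    members: tuple[CohortMember, ...]

    def __len__(self) -> int:
        return len(self.members)

    def iter_sessions(self):
        for m in self.members:
            yield m, m.session()


def generate_cohort(
    group_sizes: dict[tuple[str, str], int],
    group_effects: dict[tuple[str, str], EffectSpec] | EffectSpec | None = None,
    seed: int | np.random.SeedSequence = 0,
    jitter_rel_sd: float = 0.05,
    rest_s: float = REST_DURATION_S,
) -> Cohort:
    """Cohort of sessions with per-group effects and participant-level jitter.

    ``group_sizes`` maps each of the four (gender, generation-band) groups to
    a participant count. Each participant gets a random aroma order
    (unpleasant always last), a generation drawn within the group's band,
    and baseline parameters jittered log-normally around the group's
    ``EffectSpec`` (stimulus effect parameters are left exact so that a null
    ``EffectSpec`` stays null for every participant).
    """
    missing = set(GENDER_BANDS) - set(group_sizes)
    if missing:
        raise ValueError(f"group_sizes must cover all 4 groups; missing {sorted(missing)}")
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    order_rng = np.random.default_rng(ss.spawn(1)[0])
    members: list[CohortMember] = []
    pid = 0
    for gender, band in GENDER_BANDS:
        n = group_sizes[(gender, band)]
        if group_effects is None:
            eff = EffectSpec.null()
        elif isinstance(group_effects, EffectSpec):
            eff = group_effects
        else:
            eff = group_effects[(gender, band)]
        gens = ("20s", "30s") if band == "20s-30s" else ("40s", "50s")
        for _ in range(n):
            member_seed = ss.spawn(1)[0]
            order = tuple(order_rng.permutation(AROMAS))
            generation = gens[int(order_rng.integers(2))]
            jitter = float(order_rng.lognormal(0.0, jitter_rel_sd)) if jitter_rel_sd > 0 else 1.0
            amp_jitter = float(order_rng.lognormal(0.0, jitter_rel_sd)) if jitter_rel_sd > 0 else 1.0
            eff_p = replace(
                eff,
                baseline_mean_ibi_ms=float(
                    np.clip(eff.baseline_mean_ibi_ms * jitter, IBI_MIN_MS, IBI_MAX_MS)
                ),
                baseline_band_amps={
                    b: a * amp_jitter for b, a in eff.baseline_band_amps.items()
                },
            )
            timeline = SessionTimeline.standard(
                order,
                participant_id=f"p{pid:03d}",
                gender=gender,
                generation=generation,
                rest_s=rest_s,
            )
            members.append(
                CohortMember(f"p{pid:03d}", gender, generation, timeline, eff_p, member_seed)
            )
            pid += 1
    return Cohort(tuple(members))
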