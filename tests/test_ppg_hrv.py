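"""Beat detection and the pNN50/RMSSD index math."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import aromamap as am
from aromamap.ppg_hrv import _window_diff_pairs


def loop_pnn50(intervals):
    """Independent loop-based reference (proportion of |diff| > 50 ms)."""
    diffs = [intervals[i + 1] - intervals[i] for i in range(len(intervals) - 1)]
    if not diffs:
        return float("nan")
    return sum(1 for d in diffs if abs(d) > 50.0) / len(diffs)


def loop_rmssd(intervals):
    diffs = [intervals[i + 1] - intervals[i] for i in range(len(intervals) - 1)]
    if not diffs:
        return float("nan")
    return (sum(d * d for d in diffs) / len(diffs)) ** 0.5


def ibi_from_intervals(intervals_ms):
    beats = np.concatenate([[0.0], np.cumsum(intervals_ms) / 1000.0])
    return am.IBISeries(beat_times_s=beats, intervals_ms=np.asarray(intervals_ms, float))


class TestDetectBeats:
    def test_all_zero_signal_gives_empty_with_warning(self):
        sig = am.RawSignal(np.zeros(5000), 500.0, channel="ppg")
        with pytest.warns(UserWarning, match="no beats"):
            beats = am.detect_beats(sig)
        assert beats.size == 0

    def test_refractory_suppresses_close_pulse(self):
        # two pulses 0.2 s apart: only one survives the 300 ms refractory rule
        fs = 500.0
        t = np.arange(int(3 * fs)) / fs
        sig = np.exp(-0.5 * ((t - 1.0) / 0.03) ** 2) + 0.9 * np.exp(
            -0.5 * ((t - 1.2) / 0.03) ** 2
        )
        beats = am.detect_beats(am.RawSignal(sig, fs, channel="ppg"))
        assert beats.size == 1
        assert beats[0] == pytest.approx(1.0, abs=0.02)

    def test_recovers_ten_noise_free_beats(self):
        ibi = am.generate_ibi_series(8.0, 800, 20, seed=2)
        ppg = am.generate_ppg(ibi, noise_sd=0.0)
        beats = am.detect_beats(ppg)
        interior = ibi.beat_times_s[1:-1]
        assert beats.size >= interior.size
        err = np.abs(beats[:, None] - interior[None, :]).min(axis=0)
        assert err.max() < 0.020

    def test_short_signal_rejected(self):
        with pytest.raises(ValueError, match="2 s"):
            am.detect_beats(am.RawSignal(np.zeros(100), 500.0))


class TestIbiFromBeats:
    def test_basic_intervals(self):
        ibi = am.ibi_from_beats(np.array([0.0, 0.8, 1.6]))
        assert np.allclose(ibi.intervals_ms, [800.0, 800.0])
        assert ibi.valid.all()

    def test_implausible_interval_flagged(self):
        ibi = am.ibi_from_beats(np.array([0.0, 0.8, 0.9, 1.7]))
        assert ibi.n_intervals == 3
        assert list(ibi.valid) == [True, False, True]
        assert ibi.n_removed == 1

    def test_interval_count_invariant(self, rng):
        beats = np.cumsum(rng.uniform(0.4, 1.2, size=20))
        ibi = am.ibi_from_beats(beats)
        assert ibi.n_intervals == beats.size - 1

    def test_too_few_beats_rejected(self):
        with pytest.raises(ValueError, match="at least 2"):
            am.ibi_from_beats(np.array([1.0]))


class TestIndexMath:
    @pytest.mark.parametrize(
        "intervals,expected",
        [
            ([800, 800, 800, 800], 0.0),
            ([800, 860, 820, 880, 870], 0.5),  # diffs 60,-40,60,-10
            ([700, 800, 900], 1.0),  # diffs 100,100
            ([800, 850, 900], 0.0),  # diffs exactly 50: strict threshold
        ],
    )
    def test_pnn50_hand_cases(self, intervals, expected):
        assert am.pnn50(ibi_from_intervals(intervals)) == expected

    @pytest.mark.parametrize(
        "intervals,expected",
        [
            ([800, 800, 800], 0.0),
            ([800, 860, 820, 880, 870], np.sqrt(2225.0)),  # ~47.17 ms
            ([800, 730], 70.0),  # single difference: |c|
        ],
    )
    def test_rmssd_hand_cases(self, intervals, expected):
        assert am.rmssd(ibi_from_intervals(intervals)) == pytest.approx(expected, abs=1e-12)

    @given(
        st.lists(st.floats(min_value=300, max_value=2000), min_size=2, max_size=50)
    )
    @settings(max_examples=200, derandomize=True)
    def test_matches_loop_reference_and_bounds(self, intervals):
        ibi = ibi_from_intervals(intervals)
        p, r = am.pnn50(ibi), am.rmssd(ibi)
        assert p == loop_pnn50(intervals)
        assert r == pytest.approx(loop_rmssd(intervals), rel=1e-12)
        assert 0.0 <= p <= 1.0
        assert r >= 0.0

    @given(
        st.lists(st.floats(min_value=400, max_value=1500), min_size=3, max_size=30),
        st.floats(min_value=-80, max_value=80),
    )
    @settings(max_examples=100, derandomize=True)
    def test_shift_invariance(self, intervals, c):
        """Both indexes depend only on successive differences."""
        base = ibi_from_intervals(intervals)
        shifted = ibi_from_intervals([x + c for x in intervals])
        assert am.pnn50(shifted) == am.pnn50(base)
        assert am.rmssd(shifted) == pytest.approx(am.rmssd(base), rel=1e-9)

    def test_rmssd_zero_iff_constant(self, rng):
        const = ibi_from_intervals([750.0] * 10)
        assert am.rmssd(const) == 0.0
        wiggly = ibi_from_intervals(750.0 + rng.normal(0, 5, 10))
        assert am.rmssd(wiggly) > 0.0

    def test_undefined_below_two_intervals(self):
        one = ibi_from_intervals([800.0])
        assert np.isnan(am.pnn50(one))
        assert np.isnan(am.rmssd(one))


class TestWindowing:
    def test_window_equals_manual_slice(self, rng):
        intervals = rng.uniform(600, 1000, size=40)
        ibi = ibi_from_intervals(intervals)
        start, end = 10.0, 20.0
        second = ibi.beat_times_s[1:]
        inside = (second >= start) & (second < end)
        manual = ibi_from_intervals(intervals[inside])
        assert am.pnn50(ibi, (start, end)) == am.pnn50(manual)
        assert am.rmssd(ibi, (start, end)) == pytest.approx(am.rmssd(manual), rel=1e-12)

    def test_flagged_intervals_break_diff_pairs(self):
        # diffs adjacent to the flagged 100 ms interval are excluded
        ibi = am.ibi_from_beats(np.array([0.0, 0.8, 0.9, 1.7, 2.5, 3.3]))
        d = _window_diff_pairs(ibi, None)
        assert d.size == 2  # only the (800,800) pairs at the end
        assert np.allclose(d, [0.0, 0.0])

    def test_hrv_indexes_bundle(self):
        ibi = ibi_from_intervals([800, 860, 820, 880, 870])
        h = am.hrv_indexes(ibi, (0.0, 10.0))
        assert h.pnn50 == 0.5
        assert h.rmssd == pytest.approx(np.sqrt(2225.0))
        assert h.window == (0.0, 10.0)
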