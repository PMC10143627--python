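"""Generator behavior: protocol timelines, controllable HRV/EEG structure,
round trips and determinism."""

import numpy as np
import pytest

import aromamap as am
from aromamap.core import BAND_NAMES
from aromamap.eeg_indexes import band_powers
from aromamap.synthetic import GENDER_BANDS, StimulusEvent


class TestTimeline:
    def test_standard_layout(self, standard_timeline):
        tl = standard_timeline
        assert len(tl.events) == 7
        assert tl.events[-1].name == am.UNPLEASANT
        assert tl.events[-1].duration_s == 30.0
        assert all(e.duration_s == 60.0 for e in tl.events[:-1])
        assert sorted(e.name for e in tl.events[:-1]) == sorted(am.AROMAS)
        # contiguous coverage: windows partition [0, duration]
        wins = tl.windows()
        assert wins[0][0] == 0.0
        for (s0, e0, _), (s1, e1, _) in zip(wins, wins[1:]):
            assert e0 == s1
        assert wins[-1][1] == tl.duration_s

    def test_wrong_duration_rejected(self):
        with pytest.raises(ValueError, match="must last"):
            StimulusEvent("citrus", "aroma", 60.0, 30.0)

    def test_unpleasant_must_be_last(self, standard_timeline):
        events = list(standard_timeline.events)
        events[-1], events[-2] = events[-2], events[-1]
        with pytest.raises(ValueError, match="last"):
            am.SessionTimeline(
                events=tuple(events), participant_id="p0", gender="male", generation="20s"
            )

    def test_overlap_rejected(self, standard_timeline):
        events = list(standard_timeline.events)
        shifted = StimulusEvent(events[1].name, "aroma", events[0].onset_s + 10.0, 60.0)
        events[1] = shifted
        with pytest.raises(ValueError, match="overlap"):
            am.SessionTimeline(
                events=tuple(sorted(events, key=lambda e: e.onset_s)),
                participant_id="p0",
                gender="male",
                generation="20s",
            )


class TestIBIGenerator:
    def test_zero_variance_is_exactly_periodic(self):
        ibi = am.generate_ibi_series(60, 800, 0, seed=1)
        assert np.all(ibi.intervals_ms == 800.0)
        assert am.pnn50(ibi) == 0.0
        assert am.rmssd(ibi) == 0.0

    def test_covers_duration(self):
        ibi = am.generate_ibi_series(300, 800, 30, seed=7)
        assert ibi.beat_times_s[0] == 0.0
        assert ibi.beat_times_s[-1] >= 300.0

    def test_single_run_recovery(self):
        # sharp bounds live in the acceptance suite; one replicate is looser
        ibi = am.generate_ibi_series(300, 800, 30, seed=7)
        assert am.rmssd(ibi) == pytest.approx(30.0, rel=0.25)
        assert am.pnn50(ibi) == pytest.approx(0.0956, abs=0.06)

    def test_rejects_bad_args(self):
        with pytest.raises(ValueError, match="duration"):
            am.generate_ibi_series(0, 800, 10)
        with pytest.raises(ValueError, match="mean IBI"):
            am.generate_ibi_series(60, 100, 10)

    def test_deterministic(self):
        a = am.generate_ibi_series(120, 800, 25, seed=3)
        b = am.generate_ibi_series(120, 800, 25, seed=3)
        assert np.array_equal(a.beat_times_s, b.beat_times_s)


class TestPPGGenerator:
    def test_pulses_centered_at_beats(self):
        ibi = am.IBISeries(beat_times_s=np.array([0.8, 1.6, 2.4]))
        ppg = am.generate_ppg(ibi, noise_sd=0.0)
        for tb in ibi.beat_times_s:
            lo, hi = int((tb - 0.1) * 500), int((tb + 0.1) * 500)
            peak = lo + int(np.argmax(ppg.values[lo:hi]))
            assert abs(peak - tb * 500) <= 1  # within one sample

    def test_round_trip_recovers_beats(self):
        ibi = am.generate_ibi_series(60, 800, 40, seed=9)
        ppg = am.generate_ppg(ibi, noise_sd=0.0, seed=1)
        det = am.detect_beats(ppg)
        # every interior generating beat matched within 20 ms
        interior = ibi.beat_times_s[1:-1]
        err = np.abs(det[:, None] - interior[None, :]).min(axis=0)
        assert err.max() < 0.020

    def test_empty_rejected(self):
        with pytest.raises(ValueError, match="no beats"):
            am.generate_ppg(am.IBISeries(beat_times_s=np.empty(0)))

    def test_deterministic(self):
        ibi = am.generate_ibi_series(30, 800, 20, seed=5)
        a = am.generate_ppg(ibi, noise_sd=0.05, seed=11)
        b = am.generate_ppg(ibi, noise_sd=0.05, seed=11)
        assert np.array_equal(a.values, b.values)


class TestEEGGenerator:
    def test_zero_amplitudes_give_zero_signal(self):
        sig = am.generate_eeg(5, band_amplitudes={}, noise_sd=0.0, seed=1)
        assert np.all(sig.values == 0.0)
        bp = band_powers(sig)
        assert all(np.all(bp.powers[b] == 0.0) for b in BAND_NAMES)

    @pytest.mark.parametrize("band", BAND_NAMES)
    def test_single_band_power_concentrates(self, band):
        sig = am.generate_eeg(30, band_amplitudes={band: 1.0}, noise_sd=0.0, seed=2)
        bp = band_powers(sig)
        frac = bp.powers[band].sum() / bp.total().sum()
        assert frac >= 0.90

    def test_amplitude_doubling_quadruples_power(self):
        s1 = am.generate_eeg(60, band_amplitudes={"theta": 1.0, "delta": 1.0}, seed=5)
        s2 = am.generate_eeg(60, band_amplitudes={"theta": 2.0, "delta": 1.0}, seed=5)
        # cross-band spectral leakage keeps this from being exact
        p1, p2 = band_powers(s1), band_powers(s2)
        assert p2.powers["theta"].mean() == pytest.approx(4 * p1.powers["theta"].mean(), rel=0.02)
        assert p2.powers["delta"].mean() == pytest.approx(p1.powers["delta"].mean(), rel=0.05)

    def test_unknown_band_rejected(self):
        with pytest.raises(ValueError, match="unknown band"):
            am.generate_eeg(5, band_amplitudes={"mu": 1.0})

    def test_deterministic(self):
        a = am.generate_eeg(10, band_amplitudes={"delta": 1.0}, noise_sd=0.1, seed=4)
        b = am.generate_eeg(10, band_amplitudes={"delta": 1.0}, noise_sd=0.1, seed=4)
        assert np.array_equal(a.values, b.values)


class TestSession:
    def test_signals_cover_session(self, null_session):
        eeg, ppg, tl = null_session
        assert eeg.duration_s == pytest.approx(tl.duration_s, abs=0.01)
        assert ppg.duration_s == pytest.approx(tl.duration_s, abs=0.01)

    def test_deterministic(self, standard_timeline):
        e1, p1, _ = am.generate_session(standard_timeline, am.EffectSpec.null(), seed=42)
        e2, p2, _ = am.generate_session(standard_timeline, am.EffectSpec.null(), seed=42)
        assert np.array_equal(e1.values, e2.values)
        assert np.array_equal(p1.values, p2.values)

    def test_lavender_sigma_raises_pnn50_change(self):
        """A raised successive-difference SD during lavender must surface as
        a positive pNN50 change through the full pipeline."""
        eff = am.EffectSpec(baseline_sigma_d_ms=25.0, sigma_d_ms={"lavender": 45.0})
        changes = []
        for seed in range(4):
            tl = am.SessionTimeline.standard(am.AROMAS, f"p{seed}", "male", "20s")
            eeg, ppg, _ = am.generate_session(tl, eff, seed=seed)
            rows, _ = am.extract_session(eeg, ppg, tl)
            changes.extend(
                r["ex_mean"]
                for r in rows
                if r["index_name"] == "pnn50"
                and r["stimulus"] == "lavender"
                and r["window"] == "all"
            )
        assert np.mean(changes) > 0


class TestCohort:
    def test_study_sizes_give_62_sessions(self):
        sizes = {
            ("male", "20s-30s"): 15,
            ("male", "40s-50s"): 15,
            ("female", "20s-30s"): 17,
            ("female", "40s-50s"): 15,
        }
        cohort = am.generate_cohort(sizes, seed=0)
        assert len(cohort) == 62
        # unpleasant last and aroma order randomized per participant
        orders = {tuple(e.name for e in m.timeline.events) for m in cohort.members}
        assert all(o[-1] == am.UNPLEASANT for o in orders)
        assert len(orders) > 1

    def test_single_member_cohort(self):
        sizes = dict.fromkeys(GENDER_BANDS, 0)
        sizes[("male", "20s-30s")] = 1
        cohort = am.generate_cohort(sizes, seed=1)
        assert len(cohort) == 1
        assert cohort.members[0].generation in ("20s", "30s")

    def test_identical_seed_identical_cohort(self):
        sizes = dict.fromkeys(GENDER_BANDS, 1)
        c1 = am.generate_cohort(sizes, seed=9)
        c2 = am.generate_cohort(sizes, seed=9)
        for m1, m2 in zip(c1.members, c2.members):
            assert m1.timeline == m2.timeline
            (e1, p1, _), (e2, p2, _) = m1.session(), m2.session()
            assert np.array_equal(e1.values, e2.values)
            assert np.array_equal(p1.values, p2.values)

    def test_missing_group_rejected(self):
        with pytest.raises(ValueError, match="missing"):
            am.generate_cohort({("male", "20s-30s"): 1}, seed=0)
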