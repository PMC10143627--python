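# aromamap

Quantifying psychological responses to olfactory stimuli (aromas and an
unpleasant odor) from two wearable biosignals: single-channel frontal EEG
and a fingertip pulse (PPG) sensor. The package turns raw recordings into
arousal and valence indexes, normalizes them against a resting baseline,
compares stimuli with within-subject statistics, and places each stimulus
on a circumplex-style arousal–valence *emotion map*. A fully seeded
synthetic-data module emulates the experimental protocol so every stage is
testable without access to participant recordings.

Intended users: researchers in affective physiology / affective computing
who want a transparent, reproducible reference pipeline for ultra-short-term
HRV and consumer-EEG band-power analyses of short stimulus exposures.

## The measurement model

**Protocol.** A session is a 60 s pre-rest baseline followed by seven
stimulus exposures (six aromas, 60 s each, randomized order; the unpleasant
odor isovaleric acid always last, 30 s), each followed by a 60 s rest.
EEG is sampled at 512 Hz, PPG at 500 Hz.

**Valence (HRV) indexes.** Beats are detected on the PPG (adaptive
rolling-median + 3·MAD threshold, 300 ms refractory), giving NN intervals.
For successive differences ΔNNₖ over an analysis window:

- `pNN50 = #{|ΔNNₖ| > 50 ms} / #{ΔNNₖ}` (proportion in [0, 1]; a
  parasympathetic, pleasantness-related index),
- `RMSSD = sqrt(mean(ΔNNₖ²))` in ms (vagal-tone / stress-relax index;
  used in statistics only, never plotted).

Both are valid on the ultra-short (15–60 s) windows the protocol imposes.

**Arousal (EEG) indexes.** Per non-overlapping 1 s epoch, a Hann-windowed
periodogram is integrated over the consumer-EEG bands δ(1–3), θ(4–7),
low-α(8–9), high-α(10–12), low-β(13–17), high-β(18–30), γ(31–50 Hz); γ is
computed but excluded from analyses. From these:

- *Attention−Meditation (surrogate)*: `100·(β share) − 100·(α share)` of
  total band power, in [−100, 100] — a transparent stand-in for the
  proprietary headset scores (which emphasize β and α respectively),
- *MA Highβ/Highα*: the high-β/high-α power ratio smoothed by a trailing
  15 s moving average,
- raw δ and θ band-power series.

**Normalization.** For each index X, `B_avg = (1/N) Σ Bᵢ` over the
pre-rest baseline and `EX = Exᵢ − B_avg` during exposure; only these
baseline changes enter the statistics. Exposure windows are the full
exposure and its first/latter halves.

**Statistics.** Per gender×generation-band group, index, and window: a
one-factor (7 stimuli) repeated-measures ANOVA
(`F = MS_conditions/MS_error`, sphericity-uncorrected p with a
Greenhouse–Geisser p alongside) and all 21 unadjusted post hoc paired
t tests.

**Emotion map.** Valence (raw group-mean pNN50, range [0, 1], origin at the
group's resting mean) on X against one arousal index on Y
(Attention−Meditation in [−100, 100] origin 0; MA Hβ/Hα in [0, 2]; δ with a
data-driven range). Each stimulus contributes three points: circle = whole
exposure, triangle = first half, square = latter half.

## Worked example

```python
import numpy as np
import aromamap as am

# ultra-short-term HRV indexes from a hand-checkable interval list
intervals = np.array([800., 860., 820., 880., 870.])
beats = np.concatenate([[0.0], np.cumsum(intervals) / 1000.0])
ibi = am.IBISeries(beat_times_s=beats, intervals_ms=intervals)
print(f"pNN50 = {am.pnn50(ibi):.2f}, RMSSD = {am.rmssd(ibi):.2f} ms")

# one synthetic session with a lavender effect, run through the pipeline
timeline = am.SessionTimeline.standard(am.AROMAS, "p000", "male", "20s")
eeg, ppg, _ = am.generate_session(timeline, am.EffectSpec.illustrative(), seed=0)
rows, resting = am.extract_session(eeg, ppg, timeline)
print(f"resting pNN50 = {resting['pnn50']:.3f}")
for r in rows:
    if r["index_name"] == "pnn50" and r["window"] == "all":
        print(f"{r['stimulus']:<10} pNN50 change {r['ex_mean']:+.3f}")
```

prints

```
pNN50 = 0.50, RMSSD = 47.17 ms
resting pNN50 = 0.055
citrus     pNN50 change -0.055
lavender   pNN50 change +0.195
soap       pNN50 change -0.027
woody      pNN50 change -0.014
fruity     pNN50 change -0.015
floral     pNN50 change -0.028
unpleasant pNN50 change -0.055
```

The interval list has successive differences (60, −40, 60, −10) ms, so two
of four exceed 50 ms (pNN50 = 0.5) and RMSSD = √2225 ≈ 47.17 ms. In the
synthetic session the generator raises the IBI successive-difference SD
during lavender (and lowers it during citrus), and the pipeline recovers
exactly that pattern as positive (negative) pNN50 changes from baseline.

The same stages are available from the shell:

```sh
aromamap simulate --config cfg.yaml --out data/   # session + manifest CSVs
aromamap extract  --data data/ --out out/         # index summaries
aromamap analyze  --summaries out/summaries.csv --out out/
aromamap map      --summaries out/summaries.csv --resting out/resting.csv --out out/
aromamap run-all  --seed 0 --out results/         # everything, in memory
```

`run-all` with the default configuration simulates the full 62-participant
cohort (15/15/17/15 across the four gender × generation-band groups),
writes tidy CSVs (per-participant index summaries, ANOVA table, 21-row
pairwise tables, emotion-map coordinates) plus full-scale and zoom map
figures and a JSON run manifest. Identical config + seed reproduces every
output byte.

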