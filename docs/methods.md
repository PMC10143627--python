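# Methods notes

This note records the modeling assumptions, parameter choices, and known
limitations behind the pipeline, in the order data flows through it.

## Synthetic sessions

The generator emulates the statistical structure the analysis relies on,
not physiological realism.

**Inter-beat intervals.** Intervals xₖ (ms) follow a stationary AR(1),
`x[k+1] = μ + φ(x[k] − μ) + ε`, with pole φ = 0.5 and innovation SD
`σε = σd·√((1+φ)/2)`. This makes the successive differences ΔNNₖ exactly
Gaussian with SD σd, giving closed-form recovery targets for the HRV
indexes: E[RMSSD] → σd and E[pNN50] = 2Φ(−50/σd). The stationary marginal
SD of the intervals equals σd, so the physiologic clamp at [300, 2000] ms
is essentially never active at the defaults (μ = 800 ms, σd ≤ 60 ms).
Consecutive ΔNN are negatively correlated (corr = (φ−1)/2 = −0.25), which
slightly tightens Monte-Carlo error but leaves the marginal targets exact.
Baseline defaults: mean IBI 800 ms, σd 25 ms — a plausible resting adult
heart rate with moderate vagal variability.

**PPG.** One Gaussian bump per beat (width 0.12 s, i.e. σ = 30 ms),
sampled at 500 Hz. The default noise floor is zero: the beat detector's
median + k·MAD threshold is scale-free, so a white-noise floor of *any*
amplitude produces occasional supra-threshold noise maxima in the
inter-pulse gaps at the default k = 3. Detection on deliberately noisy
synthetic PPG therefore calls for a larger `k_mad` (≈ 6). Real PPG
morphology (dicrotic notch, baseline wander, motion artifacts) is out of
scope.

**EEG.** Each band is a sum of 12 random-phase sinusoids with frequencies
drawn uniformly from the band interior, leaving a 0.25 Hz guard band at
each edge, scaled so the band's RMS amplitude equals the configured value
(power = amplitude²). The guard band matters: spectral resolution of the
1 s analysis epochs is 1 Hz, and Hann leakage from components at a band
edge would push the in-band power fraction of the 2-Hz-wide low-α band
below 0.9. A pure center-frequency sinusoid mode is available for exact
tests. Band synthesis is windowed per condition, so band amplitudes switch
instantaneously at condition boundaries (a small discontinuity a real EEG
would not show). Baseline amplitudes are α-dominant with moderate β, the
typical resting frontal pattern; a white-noise floor (SD 0.1) is added.

**Sessions and cohorts.** The timeline is fixed by the protocol: 60 s
pre-rest; 60 s per aroma and 30 s for the unpleasant odor, each followed by
60 s rest; aroma order randomized per participant, unpleasant odor always
last. The IBI track is one continuous AR(1) whose σd switches with the
active condition, so beats are contiguous across the session. Cohorts
draw a generation label within each gender × generation-band group, jitter
each participant's *baseline* parameters log-normally (5% relative SD) and
leave stimulus effect parameters exact — so a null effect specification
stays exactly null at the participant level. Seeding is hierarchical
(numpy `SeedSequence.spawn`), making cohorts reproducible byte-for-byte.
The study reports no stimulus effect sizes in physical units, so the
"illustrative" effect preset (lavender σd 40 ms vs baseline 25 ms, citrus
15 ms, high-β-shifted EEG for the unpleasant odor) is a plausible
invention, not a calibration.

## Index extraction

**Beat detection.** Local maxima above a rolling median + 3·MAD threshold
(2 s window), with a 300 ms refractory period keeping the larger peak. The
rolling statistics are evaluated on a 0.1 s stride and interpolated — the
threshold varies on the 2 s scale, so nothing is lost. Intervals outside
[300, 2000] ms are flagged invalid in place (not deleted), and any
successive-difference pair touching a flagged interval is excluded; this
is the only artifact handling applied.

**HRV windowing.** An interval belongs to a window iff its *second* beat
falls inside the half-open window — a causal rule that matters for 15 s
half-windows. pNN50 uses the strict inequality |ΔNN| > 50 ms (the
conventional NN50 definition) and is reported as a proportion in [0, 1].
Indexes are computed once per analysis window rather than emulating the
sensor's ~1 Hz streaming output; the statistics only ever consume
per-window values.

**Band powers.** Non-overlapping 1 s epochs (matching the headset's output
cadence), Hann-windowed periodogram, power summed over each band's closed
range; the trailing partial epoch is dropped. Whether consumer headsets
report amplitudes or powers is undocumented; power (magnitude²) is used
throughout.

**Surrogate Attention/Meditation.** The proprietary headset scores cannot
be reproduced; the published characterization is only that Attention
emphasizes β and Meditation α. The surrogates are the β and α shares of
total 7-band power scaled to 0–100, so Attention−Meditation lies in
[−100, 100] with 0 as the neutral point — the same scale contract as the
original. Outputs are labeled "surrogate"; epochs with zero total power
are undefined (NaN), never 0.

**Highβ/Highα ratio.** The named ratio high-β/(high-α + ε), ε = 1e−12, so
high values mean high arousal. (The source description of this index
contradicts itself about which band is the denominator; the named ratio
with β on top is implemented, matching the stated interpretation that
alertness raises the index.) The 15 s moving average is trailing/causal
with an expanding prefix, so no future samples enter a window; undefined
epochs are excluded per-window.

## Normalization and grouping

The baseline is the *first pre-resting minute only* — the only window
guaranteed free of stimulus after-effects — not the rest before each
stimulus. Half-windows are half-open on the 1 Hz grid, [onset, mid) and
[mid, end), so the midpoint sample belongs to the latter half and halves
average exactly to the full window. A window summary is undefined when
more than 50% of its samples are undefined (threshold configurable); an
all-undefined baseline excludes the participant, with a log entry.

## Statistics

Classical within-subject partition SS_total = SS_subjects + SS_conditions
+ SS_error; p from F(k−1, (n−1)(k−1)) uncorrected for sphericity, which is
the design being mirrored; a Greenhouse–Geisser corrected p (covariance-
based ε, clipped to [1/(k−1), 1]) is emitted alongside for transparency.
Missing or undefined cells are handled by listwise deletion with logged
counts; at least 3 complete rows are required. Degenerate inputs are
reported, not hidden: zero error variance yields p = 0 with a warning, and
an all-equal matrix yields F = 0, p = 1. Post hoc comparisons are all 21
two-sided paired t tests with unadjusted p-values and 0.05/0.01/0.001
significance flags; identical columns give a flagged NaN statistic. The
statistical analysis runs on the first-half and latter-half windows (the
windows in which stimulus differences are reported to concentrate); the
emotion map additionally uses the full window.

## Emotion map

Valence is on the X-axis and arousal on the Y-axis. Points are *raw*
per-window group means (pNN50 against one arousal index), matching the
origin-at-resting-mean construction — the normalized changes feed the
statistics instead, and both values appear in the tidy summary table.
Axis presets: Attention−Meditation [−100, 100], fixed origin 0; MA Hβ/Hα
[0, 2] (ceiling 2 covers the data with balanced scaling, stretched only if
data exceed it) with origin 1.0 — β–α parity as the natural neutral point
of a ratio, configurable, since no published origin exists; pNN50 [0, 1]
with origin at the mean resting value of the participants actually plotted
(complete cases); δ auto-scales with no origin line. RMSSD is never
plotted. An alternative axis-range preset hook exists for an arousal axis
expanded toward the low-arousal region; it changes no computation.
Quadrant labels (HAHV/HALV/LAHV/LALV) use strict inequalities; exact
equality with an origin is classified `on_axis`.

## Problem sizes and what the tests show

The test-suite and acceptance-script simulations are sized for a
single-CPU run: HRV recovery uses 100 replicates of 300 s IBI tracks per
σd ∈ {10, 30, 60} ms; the normalization null uses 100 single-participant
cohorts on the full 870 s protocol; ANOVA calibration uses 500 null
replicates at n = 15, k = 7; the default pipeline pass uses the full
62-participant cohort. Passing tests demonstrate that the *method* is
implemented correctly and recovers known synthetic structure; they say
nothing about effect sizes or significance patterns in real participants,
whose recordings are not public. The synthetic generator omits EEG
artifacts (blinks, EMG), realistic PPG morphology, respiration coupling,
and any questionnaire modeling.
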