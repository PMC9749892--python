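# crylight

Analysis pipeline for four assays used to characterise how insect
Cryptochrome (CRY) photoreceptors shape circadian and acute light-driven
behaviour and physiology — for chronobiology and neurophysiology labs
working with *Drosophila* activity monitors, whole-cell current-clamp
rigs, two-environment light-choice tubes and confocal ROI exports:

1. **Circadian locomotor rhythmicity** from per-minute beam-crossing
   counts (TriKinetics DAM-style monitor files): chi-square
   (Sokolove–Bushell) periodogram, rhythmicity scoring, free-running
   period τ, morning/evening anticipation indices, eduction profiles and
   actogram matrices.
2. **Light-evoked electrophysiology** from multi-sweep current-clamp
   recordings under a 50 s dark / 5 s light / 95 s dark × 5 protocol:
   spike detection, firing-frequency (FF) ratios, tonic/burst
   classification, resting membrane potential, and the averaged,
   baseline-adjusted, low-pass-filtered evoked potential.
3. **Light attraction/avoidance preference** from lit-vs-dark activity
   counts: per-bin percent activity and 30-minute window means.
4. **ROI fluorescence quantification** (e.g. TIM and GFP-CRY):
   background-ratio normalisation and pooled per-ZT profiles.

Because raw recordings of this kind are rarely deposited, the package
ships a first-class synthetic-data module (`crylight.synth`) that
emulates each assay with known latent parameters, so every analysis
stage is verifiable end-to-end by parameter recovery.

## The statistics at the core

**Chi-square periodogram.** For a candidate period of `P` one-minute
bins, the count series is folded into `K = ⌊N/P⌋` complete cycles
(incomplete final cycle trimmed). With column means `M_h`, grand mean
`M` and variance `σ² = (1/N′) Σ (x_i − M)²` over the `N′ = K·P` retained
bins,

```
Q_P = K · Σ_h (M_h − M)² / σ²
```

is referred to the χ² quantile with `P − 1` degrees of freedom. A fly is
**rhythmic** when the peak exceeds the α = 0.05 line, its *power*
(`Q_P` minus the line) is ≥ 20 and the contiguous supra-threshold span
around the peak (*width*) is ≥ 2 h.

**Anticipation index.** `AI = mean(activity in the 3 h before a light
transition) / mean(activity in the 6 h before it)`, per day, averaged
over the last 5 entrained days. `AI = 1` means no ramping; `AI = 2`
means all activity fell in the final 3 h.

**FF ratio.** Stimulus-window firing rate over the mean of the five
10-s-binned baseline rates (spikes pooled across the recording's
sweeps), plus four post-stimulus 10-s bin ratios up to 40 s.

**Group statistics.** Anderson–Darling normality dispatches each
two-group contrast to a pooled/Welch one-tailed t-test (F-test on
variances) or a Mann–Whitney U-test; families of p-values are
Benjamini–Hochberg adjusted at q = 0.1, with black significance tiers
from the raw p (≤ .05/.005/.001) and red tiers from the adjusted p
(≤ .1/.05/.01).

## Worked example

```python
import numpy as np
from crylight import synth, locomotor

preset = synth.standard_presets()["AgCRY1"]       # tau 25.4 h line
sim = synth.simulate_locomotor(preset, n_flies=16, days_ld=7,
                               days_dd=7, seed=42)
results = [locomotor.chi_square_periodogram(s) for s in sim.series]
summary = locomotor.cohort_summary(results)
print(f"n = {summary.n}, rhythmic = {summary.n_rhythmic} "
      f"({summary.percent_rhythmic:.1f}%)")
print(f"tau   = {summary.tau_mean:.2f} +/- {summary.tau_sem:.2f} h")
ai = locomotor.anticipation_index(sim.series[0], "evening")
print(f"evening anticipation index (fly 0) = {ai.ai:.3f}")
```

prints

```
n = 16, rhythmic = 14 (87.5%)
tau   = 25.40 +/- 0.00 h
evening anticipation index (fly 0) = 1.581
```

The cohort carries a 90% rhythmic fraction, so 14/16 flies pass the
20/2/0.05 criteria; the recovered free-running period matches the
generator's 25.4 h on the 0.1-h grid; and the evening anticipation index
above 1 reflects the exponential activity ramp built into the preset.

The same analyses run from the shell on fixture files:

```sh
crylight simulate --seed 1 --outdir run
crylight locomotor --outdir run
crylight ephys --outdir run
crylight choice --outdir run
crylight icc --outdir run
```

Each stage writes tidy TSVs plus a JSON manifest (config hash, seed,
version, outputs); identical config + seed gives byte-identical files.

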