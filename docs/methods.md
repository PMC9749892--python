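# Methods

This note records the models, parameter choices and numerical decisions
behind each crylight module, in the order data flows through the
pipeline.

## Synthetic assay generators (`crylight.synth`)

The generators exist so that every analysis stage can be tested by
parameter recovery against known latent values. They reproduce the
*statistical structure* the analyses assume — not insect biophysics.
All randomness flows from one explicit seed per call
(`numpy.random.Generator`); identical arguments and seed give
bit-identical output.

**Locomotor.** Beam crossings are inhomogeneous Poisson counts with
rate `base_rate · (1 + amplitude · s(φ(t)))` per minute, clipped at
zero. The daily shape `s` is two raised-cosine lobes centred on
lights-on and lights-off plus exponential anticipation ramps rising over
`anticipation_ramp_h` (default 3 h) before each transition. The lobe
half-width is 4 h: real flies express hours-long morning and evening
activity bouts, and substantially narrower pulses would concentrate the
periodogram peak into an unrealistically narrow band of candidate
periods. During entrainment the phase tracks the 24-h light cycle; in
constant darkness it advances with the preset's free-running period
`tau_h` with no masking, the simplest free run that exercises the
periodogram. A `1 − rhythmic_fraction` subset of flies (drawn from the
seed) is generated with amplitude 0. Defaults: `base_rate` 1.5
counts/min and `amplitude` 3, giving clearly resolvable but not
noise-free rhythms at 7 entrained + 7 free-running days; demo presets
carry free-running periods of 24.7/24.6/25.4/23.6 h, spanning the range
such cohorts typically report.

**Voltage traces.** `V(t) = RMP + D(t) + spikes + Gaussian noise`,
where the light-evoked depolarisation rises as
`A(1 − e^{−t/τ_on})` during the 5-s stimulus and decays as
`e^{−t/τ_off}` afterwards. Spikes are an inhomogeneous Poisson process
(thinning) with rate `basal + gain·D(t)`, rendered as a fixed biphasic
2-ms template whose +60 mV peak makes threshold detection unambiguous
at the default 1.2 mV noise SD; burst presets emit triplets with 50-ms
intra-burst intervals at Poisson onsets. The generator returns the
template-peak spike times and `D(t)` as ground truth. Default RMP is
−37 mV, the mean such recordings report for the wild-type-like control.

**Choice.** Per minute, `total ~ Poisson(total_rate)` and
`lit ~ Binomial(total, p_lit(t))`; conservation `lit + dark = total`
holds per bin by construction. `p_lit` may be a constant or a function
of the minute index.

**ROI fluorescence.** Neuron intensities are lognormal around the
preset's per-ZT mean (CV = `noise_cv`, default 0.25, typical of
confocal ROI repeats), with a per-brain lognormal background around
`background_mean` at half that CV. The TIM-like presets peak at ZT23
and trough at ZT5/ZT11.

**What the generators do not emulate** — and hence what passing tests do
not show about real data: activity masking by light, ultradian bouts and
inter-fly waveform diversity; spike-shape variability, electrode drift
and seal instability; positional persistence (autocorrelation) in the
choice tubes; optical-section-level background structure in imaging.
Recovery results on synthetic data bound algorithmic, not biological,
error.

## Data formats (`crylight.dataio`)

Bins are half-open `[t, t + 60 s)`; ZT0 is lights-on; ZT is decimal
hours. The DAM dialect is tab-separated with ≥ 42 columns (index, date,
time, status, 6 metadata columns, 32 channel counts), one row per
minute; status 1 is valid data, other codes skip the row with a logged
warning. Missing minutes are a hard error unless `zero_fill_gaps=True`
(a documented relaxation of strictness). Voltage traces, ROI tables and
choice tables are TSV with a header and units row; voltage files carry
their protocol as `#`-prefixed metadata and must match it in length
within one sample. All readers fail with line (and where possible
column) context; round-trips are identities.

## Locomotor analysis (`crylight.locomotor`)

The statistic `Q_P = K Σ_h (M_h − M)² / σ²` is computed per candidate
period after trimming the incomplete final cycle, with the variance
taken over the retained `K·P` bins, and compared to the χ² quantile
with `P − 1` degrees of freedom. Numerical choices:

* **Grid** 16–32 h in 0.1-h steps, each period folded at the nearest
  whole number of 1-min bins (no published defaults exist for the
  legacy toolchains this emulates).
* **Power** is `Q_P(peak) − threshold(peak)` and **width** the
  contiguous supra-threshold span around the peak (span plus one grid
  step, so a single supra-threshold point has width one step). Both are
  interpretations of quantities whose exact legacy definitions are
  unpublished.
* The rhythmicity rule — significant at α = 0.05 AND power ≥ 20 AND
  width ≥ 2 h, boundaries inclusive — reads the conventional
  "chi-square significance ≥ 0.05" criterion as "peak above the χ² line
  at α = 0.05"; the literal reading (p ≥ 0.05) would score noise as
  rhythmic.
* An all-constant series has `σ² = 0` and is classified arrhythmic with
  a `degenerate_variance` flag rather than raising.
* Free-running analyses use only post-DD-onset data; entrained days
  enter only eduction and anticipation.
* Under an iid null the folded-χ² approximation is *conservative*
  (observed per-period exceedance ≈ 0.02 at α = 0.05 for 3-day
  records), because few complete cycles fit the record at long
  candidate periods; the property tests assert false-positive control
  rather than exact calibration.

The anticipation index is computed per day (both windows end at, and
exclude, the transition bin), days with zero 6-h-window activity are
excluded, and the per-day values are averaged over the **last** 5
entrained days (per-day-then-average, with the last-5 convention chosen
where pooling order and day selection were ambiguous). For nonnegative
counts AI ∈ [0, 2].

## Electrophysiology (`crylight.ephys`)

Spike detection thresholds the high-pass residual (trace minus its
20-ms Gaussian smooth) at `median + 6·MAD`, floored at an absolute
10 mV prominence so flat noiseless traces yield nothing; one event per
2-ms refractory window, timed at the peak sample.

FF ratios pool spikes across the five sweeps before any ratio is formed
(pooled-then-ratio); the stimulus count is converted to Hz so the ratio
is dimensionless and equals 1 under no effect. Cells with zero baseline
spikes are flagged `defined=False` and excluded rather than
pseudocounted — imputation would fabricate a ratio for silent cells.

The evoked potential averages sweeps aligned on stimulus onset,
subtracts the mean of the final 10 s before the stimulus ("pre-pulse"
left otherwise unspecified by convention), applies a 50-ms Gaussian
smooth then a zero-phase 3rd-order 2-Hz low-pass Butterworth
(`sosfiltfilt`), and re-subtracts the pre-pulse mean after filtering:
the filter transient otherwise leaves a small nonzero baseline, and the
reported trace should be exactly baseline-referenced. The filter
settings suppress the ~300-Hz spike content while preserving the
tens-of-seconds depolarisation envelope; all are configurable.

RMP is the mode of the 1-mV-binned histogram of spike-blanked (±5 ms)
pre-stimulus samples — robust to residual spikes, unlike the mean.
Burst classification: ≥ 50% of baseline spikes in runs of ≥ 3 with
ISI ≤ 100 ms, runs separated by ≥ 300 ms gaps; fewer than 10 baseline
spikes is unclassified.

## Choice preference (`crylight.choice`)

`percent_lit = 100·lit/(lit+dark)` where the bin total is positive and
undefined (NaN) otherwise: a zero-activity bin carries no positional
information, and imputing 50/50 would bias inactive flies toward
no-preference. `percent_dark` is stored as the exact complement, so
complementarity holds bit-exactly; label-swap symmetry holds to
floating-point roundoff. The 30-min window mean is per fly over defined
bins, anchored at ZT0; flies with no window activity are excluded with
a flag; the per-fly mean is the unit entering group statistics.

## ROI quantification (`crylight.icc`)

Normalisation is the ratio of neuron intensity to its own brain's
background — dimensionless, hence comparable across imaging sessions,
where subtraction would not be (the convention is an interpretation;
background is treated as one value per brain). Per-ZT summaries pool
all neurons from all brains; a per-brain-means mode exists behind a
flag for sensitivity checks. Pooled means equal neuron-count-weighted
means of per-brain means (tested as an algebraic identity).

## Statistics (`crylight.stats`)

Anderson–Darling (critical values for the estimated-mean-and-variance
case) at α = 0.05 on both samples dispatches to the t-branch; there a
two-sided F-test at 0.05 selects pooled vs. Welch. Non-normal data use
Mann–Whitney U, exact when both n ≤ 8 and tie-free, tie-corrected
normal approximation otherwise. The one-tailed direction must be
declared per contrast — inferring it from the data doubles the type-I
error, so that default is refused. BH adjustment
(`statsmodels multipletests fdr_bh`) operates within a configurable
family — one figure-panel analysis per family — at q = 0.1. Tier
thresholds (black ≤ .05/.005/.001 on raw p; red ≤ .1/.05/.01 on
adjusted p) are inclusive. Constant-constant sample pairs are rejected
as degenerate. A nominal test-level α of 0.05 is used throughout; a
literal 0.5 would make every contrast significant and is treated as a
transcription error in the conventions this follows.

## Pipeline (`crylight.cli`)

Subcommand-per-assay CLI over the library; YAML config merged onto the
packaged demo defaults and schema-checked (field-naming errors, no
partial outputs) before any computation. Per-stage seeds are derived
from the run seed by hashing, keeping streams independent across stages
and genotypes. Manifests record a config hash (excluding the output
directory), seed, version and outdir-relative output paths, so repeat
runs are byte-comparable. Logged counts make the pipeline's exclusions
auditable: skipped monitor rows, zero-baseline cells, undefined choice
bins, excluded anticipation days.

## Problem sizes

Defaults were sized for interactive use on a laptop: demo cohorts of
8 flies × 14 days per genotype, 2 cells per genotype at 2 kHz, 12
choice flies × 30 min, 3 brains × 5 neurons × 4 ZT points; verification
cohorts of 30 flies and 1000-replicate null simulations where sampling
error needs to be small. All sizes are arguments.

## Known limitations

* Periodogram power/width magnitudes depend on the unpublished
  conventions of legacy toolchains; comparisons across software should
  use the rhythmic/arrhythmic call, which is far less sensitive.
* The spike detector assumes positive-going spikes well above noise
  (as in the generator and healthy l-LNv recordings); it is not a
  general-purpose sorter.
* The Mann–Whitney asymptotic branch is slightly conservative at very
  small n with heavy ties.
* No ANOVA/mixed models: the workflow implements two-group contrasts
  with FDR only.
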