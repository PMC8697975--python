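# Methods

## Model and procedure

The pipeline is: cue-locked epoching → trial-wise wavelet power →
per-frequency baseline normalization → mass-univariate one-way ANOVA.

**Epoching.** Trials are half-open windows `[tmin, tmax)` around each cue
sample; the default −2..4 s at 250 Hz gives exactly 1500 samples (6 s ×
250 Hz).  Sample indexing is 0-based; events are specified in samples, not
seconds, to avoid rounding ambiguity.  Input EEG is assumed
acquisition-filtered (amplifier band-pass/notch); the library never
re-filters analysis data.

**Wavelet power.** Each trial and channel is convolved (same-length,
zero-padded) with unit-energy complex Morlet kernels — a Gaussian-windowed
complex exponential with σ_t = n_cycles / (2π f), truncated at ±5 σ_t with
odd length.  Default `n_cycles = 7`, fixed across frequencies: a common
neuroscience default giving ~2 Hz spectral bandwidth at 10 Hz; it is a
config parameter, not a constant.  Power is |W|² by default; |W| is
available (`WaveletParams(power="magnitude")`) because both conventions
circulate.  No zero-mean correction term is applied to the kernel; at
n_cycles = 7 the DC leakage of the analytic Morlet is below 10⁻²⁰ and
irrelevant at these frequencies.  The default frequency grid is 1–100 Hz
in 1 Hz steps.

**Edges.** Kernels may be longer than the epoch (a 1 Hz, 7-cycle kernel
spans ~11 s against a 6 s trial).  Rather than refusing such frequencies,
the transform stores a per-frequency cone-of-influence half-width (5 σ_t)
on the `TFRSet` so users can blank unreliable pixels; low-frequency rows of
a short epoch are smoothed estimates, not errors.

**Baseline.** Per trial, channel and frequency, power is expressed relative
to its mean μ over the baseline interval (default −2..0 s): `ratio` x/μ
(default — "normalized by baseline power" read as division), `percent`
100·(x−μ)/μ, or `dB` 10·log₁₀(x/μ).  A zero baseline mean raises an error
instead of producing silent infinities.

**FTF statistic.** At every (channel, frequency, time) pixel the per-trial
values Y_ij form a one-way ANOVA across condition groups:
F = [Σ nᵢ(Ȳᵢ−Ȳ)²/(K−1)] / [Σᵢⱼ(Yᵢⱼ−Ȳᵢ)²/(N−K)], df = (K−1, N−K).
The map implementation is vectorised but algebraically identical to the
per-pixel formula (tested to 1e−9 against an independent ANOVA).  Group
accumulation uses a canonical sorted group order so results do not depend
on dict ordering.  Degenerate pixels: within = 0 with between > 0 → +∞
(maximally significant); all trials identical → F = 0.  F is computed on
baseline-normalized per-trial power by default; passing an unnormalized
`TFRSet` to `ftf_map` computes it on raw power instead — the choice is the
caller's, since either reading is defensible.

**Inference.** Critical values are upper-tail F quantiles
(`scipy.stats.f.isf`).  The default display convention compares every pixel
against the single α = 0.01 critical value (3.851286 at df (3, 284)), which
is how FTF maps are conventionally thresholded; because 100 × 1500 pixels
per channel inflate family-wise error, `bonferroni` and `bh-fdr`
corrections are offered.  Averages of F maps (across subjects or channels)
are summary images: the mean of F values is not F distributed, so figures
annotate rather than threshold averaged maps.  Band topographies average F
over an inclusive frequency band on the grid (17–27 Hz on a 1 Hz grid is
11 rows) and half-open time windows.

## Synthetic data

The generator emulates a cue-based 4-condition imagery session: `n_runs`
runs × `trials_per_condition_per_run` trials per condition, condition order
randomized within run, cues uniformly spaced (default 8 s period, ≥7.25 s
required: 2 s fixation lead-in plus 6 s imagery), default 6 × 12 × 4 = 288
trials (72 per condition) at 250 Hz — the canonical session structure for
this paradigm.

Background per channel: 1/f^β Gaussian noise (β = 1, 10 µV RMS) + band
rhythms (alpha 10 ± 1 Hz at 5 µV, beta 20 ± 2 Hz at 3 µV) + 2 µV white
floor, values picked to give realistic resting spectra with visible
alpha/beta peaks.  Effects are multiplicative: inside a declared
(condition, channels, band, window) region the band-limited *amplitude* is
scaled by `amplitude_factor` (raised-cosine ramps of 0.1 s), so band power
scales by factor² — ERD magnitudes are quoted both as amplitude and power
changes in the literature, and the convention here is documented rather
than guessed at.  The default demo effects are contralateral alpha ERD for
hand imagery (factor 0.4 at C4/C3), beta ERD (0.5) and alpha ERS (1.8) at
Cz for foot/tongue, with Pz as an effect-free control channel.  One integer
seed drives everything; paradigm and noise use independent derived streams.

What the generator does *not* model: volume conduction (effects do not leak
across channels, unlike real EEG), eye/muscle artifacts, non-stationary
background, inter-subject variability, or realistic source geometry.
Passing tests therefore demonstrate the statistical machinery — calibration
under the null and sensitivity to genuine condition-dependent band power —
not robustness to the artifacts of real recordings.

Null calibration uses i.i.d. squared-Gaussian (χ²₁) pixels with labels
assigned independently of the data: strongly skewed, like single-trial
power, so the observed false-positive rate also probes the F-test's
robustness to non-normality at n = 72 per group (it runs marginally
conservative, ~0.008 at nominal 0.01).

## Problem sizes and numerics

The test suite and acceptance script run the full study geometry where it
is what is being checked (100 × 1500-pixel maps; four 72-trial groups) and
a 40-frequency, 4-channel session for effect recovery, which keeps the
trial-power tensor at ~0.5 GB and the whole suite in well under a minute of
ANOVA time.  All statistics accumulate in float64.  Ties and edge cases:
half-open windows everywhere (time windows, epochs, baseline); band edges
inclusive on the frequency grid; tiny negative within/between sums from
rounding are clamped to 0.

## Known limitations

- No cluster-based permutation inference or post-hoc pairwise contrasts;
  the omnibus F is the method's scope.
- EDF is read (via MNE) but not written; the package's portable recording
  container is HDF5.
- The one-way ANOVA assumes independent trials and equal group variances;
  wavelet power is heavy-tailed, and with 72 trials per group the statistic
  is robust but slightly conservative (see calibration above).
- Phase information is discarded by construction (|W|²); phase-locked
  effects invisible in power are invisible to FTF.
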