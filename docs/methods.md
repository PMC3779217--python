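# Methods

## Overview

The pipeline tests, separately for every subject of an auditory active
oddball cohort, whether the EEG distinguishes the three stimulus classes
(standard, target, distractor), and then asks how consistent those
individual effects are across subjects. It operates on epoched,
re-referenced multichannel data (re-referencing and ocular-channel
derivation are upstream of this pipeline's contract) and consists of:
synthetic cohort generation, zero-phase filtering with rule-based
artifact rejection, ERP and STFT time-frequency analysis, per-subject
max-statistic permutation tests, and cross-subject consistency summaries
with exact binomial group tests.

## Paradigm and synthetic cohorts

A session presents 300 standards and 50 + 50 deviants in two parts of
equal stimulus count; within each part every deviant is preceded by 2–7
standards, and the gaps absorb all of the part's standards (so each part
ends on a deviant). Trials last 1500 ms plus a uniform 34–480 ms jitter
that only affects continuous-time bookkeeping: epochs (−600…+1600 ms,
250 Hz, 15 scalp channels of the 10–20 system) are synthesized directly
rather than cut from a simulated continuous recording.

**Gap sampling.** The inter-deviant gap vector is drawn *exactly
uniformly* over all compositions of the part's standards into gaps within
[2, 7], via an integer dynamic-programming count table and sequential
conditional draws. (Naive rejection sampling of independent uniform gaps
until the sum matches is astronomically inefficient here: the required
mean gap is 3 while the uniform mean is 4.5, putting the target sum ~9
standard deviations below the sampling mean.) Target/distractor identity
order is a uniform random interleaving. Whether the gap constraint spans
the part boundary is not specified by the paradigm description; it is
enforced within each part.

**Signal model.** Each trial is the sum of

- *background*: Gaussian white noise shaped to a 1/f amplitude spectrum
  (flat below 1 Hz, unit-RMS, scaled to the subject's noise level,
  default 8 µV RMS), spatially correlated through a fixed smooth
  channel-mixing kernel over approximate 10–20 electrode positions, plus
  an ongoing 10 Hz oscillator with random phase and lognormal amplitude
  per trial, weighted toward posterior channels;
- *transient components*: Gaussian kernels in time with per-channel
  topography weights, condition gains, trial-level latency jitter and
  subject-level amplitude (lognormal) and latency (normal) scaling.
  Defaults: N1 (100 ms, −4 µV, all tones, deviants ×1.3), P3a (300 ms,
  +8 µV, fronto-central, deviants only, distractor > target), P3b
  (360 ms, +9 µV, parietal, target > distractor), late negative component
  (600 ms, −4 µV, distractor > target);
- *oscillatory modulations*: condition-gated band-power changes under a
  raised-cosine envelope. A positive relative power change Δ adds
  independent band-limited noise with RMS = base_RMS·√Δ (additive power);
  a negative Δ attenuates the background's own band content by
  √(1+Δ) − 1 inside the window (a decrease cannot be realised
  additively, and at zero background both definitions agree on "no
  signal"). Defaults: delta–theta (1–5 Hz) increase at 200–600 ms for
  deviants; alpha (7–12 Hz) decrease at 300–1000 ms for deviants,
  parieto-occipital, with an inverted (sign-flipped) response in a
  configurable fraction of subjects (default 2/18).

**Heterogeneity.** Each subject's profile — component scalings, noise
level, alpha-response sign, and whether the subject expresses the
target-vs-distractor asymmetry at all — is drawn from an RNG keyed on
(master seed, subject index), so any subject is reproducible in
isolation. The target-vs-distractor effect has Bernoulli prevalence π
(default 8/18); non-expressing subjects receive the *mean* of the target
and distractor gains for the P3a/P3b/LNC components, preserving their
deviant-vs-standard response. All remaining randomness (trial noise,
jitter) flows from a per-profile seed.

## Preprocessing

Filtering is an order-4 Butterworth band-pass applied forward and
backward (`sosfiltfilt`), the zero-phase equivalent of a 48 dB/oct
roll-off; the recording filter is 1–48 Hz, the ERP filter 1–20 Hz. The
quoted recorder time constant (0.1592 s) merely restates the 1 Hz corner
(1/2π·1 Hz) and is metadata only.

Automatic artifact rules run per epoch and channel with windows advancing
one sample at a time (window length = round(ms·fs/1000)): reject when any
single-sample step exceeds 50 µV, when any 200 ms window spans more than
200 µV, or when any 100 ms window spans less than 0.5 µV (flatline). The
original rules carry exclusion margins (±100 ms, ±500 ms) that mark
surrounding samples; since the unit of data here is the epoch and a trial
containing any marked sample is rejected, the margins are outcome-neutral
and whole-trial rejection is adopted (an interpretation — the source
procedure ran on continuous recorder output and may have removed segments
instead). At the default noise level the three rules keep ≥ 95 % of clean
synthetic trials; very low noise levels would trip the flatline rule on
legitimately smooth 1/f background, which is why the rejection fixtures
use the study-default noise.

## ERP analysis

Kept trials are 1–20 Hz filtered per segment (filtering before averaging
follows the stated order; for a linear filter the result is identical),
truncated to 0–1000 ms (251 samples inclusive) and averaged per
condition; differences are pointwise. The global field potential of a
difference map is the Lehmann–Skrandies spatial RMS about the spatial
mean — the term's field-standard meaning, adopted because no formula is
given in the source description. Scalp-map tables average each electrode
over 20 ms windows tiling the requested range (half-open windows, last
window closed).

## Time-frequency analysis

128 ms (32-sample) Hamming-windowed subdivisions every 64 ms, first
window left-aligned to the epoch start, a bin's timestamp its window
center. The 2 Hz frequency grid at odd centers (1, 3, …, 45 Hz; 23 bins)
cannot come from a 32- or 125-point FFT (those give even-frequency bins),
so the windowed DFT is evaluated directly at the configured centers —
equivalent to zero-padding each subdivision to one second and reading the
odd bins. Output is *amplitude* (µV; 2|X|/Σw, so a unit in-bin sinusoid
reads ≈ 1), not power, consistent with the small symmetric display
scales of the original spectrogram figures; baseline subtraction
(mean of bins centered in −200…0 ms, per trial × frequency × channel,
then truncation to 0…1000 ms) is likewise done on magnitude. Note the
physical frequency resolution of a 128 ms window is ~7.8 Hz (Hamming
main lobe ±15 Hz), so energy from a narrowband source legitimately leaks
across several 2 Hz grid bins; time localisation, by contrast, is exact
to ± one window. Display copies of the three condition-difference
matrices are affinely mapped to a single global min–max range; analysis
copies remain unnormalised.

## Permutation statistics

The t statistic is the pooled-variance two-sample Student t (the
conventional default of the max-statistic framework; the unequal group
sizes, 300 vs 50, are handled by the formula). Points with zero pooled
variance are excluded from extremes and mask, with a logged count.

Permutations are simple re-shuffles of the pooled trials into the
original group sizes, sampled with replacement across partitions; when
the number of distinct partitions is at most the requested count (1000
by default) the test switches to exhaustive enumeration with a logged
notice. Monte-Carlo p-values use the add-one convention
p = (b+1)/(m+1), avoiding p = 0; exact enumeration reports p = b/m (the
observed partition is itself enumerated, so p ≥ 1/m). Extreme
comparisons carry a relative tolerance of 1e−9 so the observed
partition's own extreme counts as "as extreme" despite floating-point
differences between the vectorised null path and the direct observed-t
path.

**Tail handling.** Two conventions are implemented. `per-tail` (default,
mirroring the historical procedure): each observed t is compared to its
own-sign extreme histogram at the full corrected alpha; this controls
each tail at α_corr, so the overall family-wise rate can reach
~2·α_corr (measured ≈ 0.03 at α_corr = 0.0167 on null data). `split`:
α_corr is halved across tails, bounding the overall family-wise rate at
α_corr; the null-calibration experiments and the FWER acceptance check
use this mode, since it is the one that carries the family-wise
guarantee. Three contrasts share the Bonferroni-corrected level
α/3 = 0.05/3.

## Consistency and group tests

Subject-count maps sum boolean masks at identical points. Effect windows
are inclusive at both ends on time and frequency; electrode groups follow
standard 10–20 nomenclature (frontal = F3 F4 F7 F8 Fz, central = C3 C4
Cz, parietal = P3 P4 P7 P8 Pz, occipital = O1 O2; fpc and po are the
indicated unions). The default effect table has the thirteen windows of
the study's summary table; the two single-instant minor windows (0.7 s
and 0.9 s) are widened by one STFT hop (±32 ms). The best-electrode
summary maximises the cross-subject sum of significant bins, ties broken
toward channel-list order with a logged notice.

The binomial group test is the exact upper tail P(X ≥ s | n, p0) with
p0 = 0.05 — kept at the nominal single-test rate for fidelity to the
original procedure even though the per-subject masks are thresholded at
α/3; a parameter allows p0 = α/3. P-values are computed unrounded and
displayed at two decimals.

## Calibration and recovery experiments

`experiments.py` holds the study-level checks shared by the tests, the
acceptance script and the analysis drivers:

- *FWER calibration* on exchangeable Gaussian datasets over a reduced
  grid (5 electrodes × 250 time points, 20 + 20 trials, 200 permutations,
  200 datasets) and on fully synthetic zero-effect cohorts (reduced
  session of 30/10/10 trials on 5 channels) — the reduced problem sizes
  keep the null ensembles cheap while preserving the multiplicity
  structure the max-statistic must handle;
- *prevalence recovery*: high-SNR cohorts (component amplitudes ×2,
  noise 3 µV) with target-vs-distractor prevalence 0, 8/18 and 1. The
  expressing subset is stratified — exactly round(n·π) subjects express,
  chosen by a seeded permutation — so the recovered success count
  measures analysis error rather than the binomial noise of the cohort
  draw (±2 tolerance at n = 18); the Bernoulli assignment path is
  validated separately by a Monte-Carlo property on the profile
  generator (mean expressing count within 3 SE of n·π over 200 cohorts).

## What the synthetic data does and does not show

The generator reproduces the paradigm's trial structure, plausible ERP
morphology and topography, 1/f background with ongoing alpha, spatial
correlation, and the between-subject heterogeneity that motivates
single-subject inference (prevalence, inverted alpha responders,
amplitude/latency variability). It does not model real volume-conduction
physics, non-stationary or non-Gaussian noise, ocular/muscle artifact
morphology beyond the three rule-triggering archetypes, semantic or
emotional stimulus differences, or drifts in vigilance across a session.
Passing tests therefore certify the *statistical machinery* — error
control, recovery of known ground truth, agreement with exact oracles —
not the physiological realism of any particular effect size; headline
subject counts from real cohorts depend on unavailable raw data and are
deliberately reproduced only as parameter-recovery properties.

## Degenerate inputs and numerical conventions

Empty trial sets yield empty masks; conditions with fewer than two kept
trials raise explicit errors naming the condition; infeasible paradigm
configurations name the violated bound; window-range and geometry
mismatches raise configuration errors rather than broadcasting. All
randomness descends from one master seed via RNG keys
(master, purpose + index), so every stage is reproducible in isolation;
re-running the pipeline with an identical configuration reproduces
byte-identical numeric outputs (verified in the test suite).
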