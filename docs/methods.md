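# Methods

This note documents the models, estimators and design choices behind
`oscishift`, in the spirit of a package methods appendix: what each stage
assumes, which knobs matter, and what the synthetic benchmarks do and do
not establish about real recordings.

## Data model

The unit of exchange is an `EpochSet`: a `(trials × channels × samples)`
float32 tensor with a uniform time axis (step 1/fs, relative tolerance
1e-9), two-level per-trial condition labels, correctness flags, and
subject/window metadata. Windows are half-open `[t0, t1)`, so cropping
arithmetic is exact: a 2 s crop at 250 Hz is exactly 500 samples, and
adjacent crops partition samples without loss or duplication. Time is in
seconds relative to window onset; channel and trial indices are 0-based
internally. Amplitude units are carried as an opaque string and never
converted — every statistic in the package is either unit-invariant
(t statistics, AUC, FOM) or a within-unit contrast.

Channel adjacency is a user-supplied undirected graph (JSON
`{"channels": [...], "edges": [[a, b], ...]}`); no template montages ship
with the package. The default synthetic layout has four prefrontal sources
(left/right dlPFC and vmPFC) with same-hemisphere adjacency, so each
source has exactly one neighbor.

On disk, one HDF5 file per subject per window holds `/data` (float32),
`/time`, `/trial_condition`, `/trial_correct` and the scalar attributes;
datasets are written with `track_times=False` so identical content yields
byte-identical files.

## Synthetic cohorts

The generator emulates the statistical structure of decision-delay
recordings:

- **Background**: Gaussian noise spectrally shaped to PSD ∝ f^(−χ)
  (multiply the FFT of white noise by f^(−χ/2), zero the DC bin, invert).
  The shaping gain is normalized to unit expected variance, so
  `fractal_amplitude` is the expected RMS. Default χ = 1.
- **Oscillation**: either a sustained sinusoid over the whole window with
  per-trial frequency ~ Normal(center, `freq_jitter_sd`) and random phase,
  or Poisson-rate transient events with Hann envelopes
  (`burst_len_cycles`/f long, onsets uniform over the window, overlaps
  summing linearly, edge-clipped events flagged as truncated in the
  ground-truth event log).
- **Planted effect**: condition A oscillates at `f_center_A`, condition B
  at `f_center_A + sign·Δ`, on the configured effect channels only
  (defaults: Δ = 0.3 Hz on the two left-hemisphere sources). Non-effect
  channels oscillate at the unshifted center in both conditions. The
  baseline window has no condition difference and its oscillatory
  amplitude is `osc_amplitude / decision_power_scale` (default scale 0.75,
  i.e. oscillatory power suppressed during the decision window).
- **Cohort structure**: exactly `round(fraction · n)` subjects receive a
  positive shift sign (default 17/24), with the assignment order shuffled
  by the master seed. Exact-count assignment (rather than Bernoulli) keeps
  fixture tests deterministic in the count. All per-subject and per-stage
  seeds spawn from one master seed via `numpy.random.SeedSequence`; equal
  config + seed reproduce a cohort bit-exactly.

**Calibration.** The default sustained-mode amplitude (2.0 × background
RMS) and trial-to-trial center jitter (0.5 Hz) were fixed once from an
attenuation sweep: band-limited 1/f noise pulls the instantaneous
frequency of a mixed signal toward the band's spectral centroid, and at
these defaults a planted 0.3 Hz shift is recovered at ≈ 0.28 Hz group
mean with ~100 trials/condition, giving the group pipeline high power at
cohort sizes of 24. These values are a calibration choice of this
package's benchmark conditions, not measurements of any particular
dataset.

**What the generator does not model**: forward head models and correlated
sensor noise, artifacts (ocular, muscular, cardiac), nonstationary 1/f
exponents, and autocorrelated across-trial structure. Passing recovery
tests on these cohorts therefore demonstrates correctness of the
estimators and inference under the stated generative model, not robustness
to every property of real recordings.

## Multitaper spectra

Per-trial PSDs use DPSS tapers with half-bandwidth `smoothing` (default
±2 Hz): the taper count is `floor(2·smoothing·T) − 1` with T the true
(unpadded) window length, and the signal is zero-padded to `pad_to`
(default 4 s) so the grid step is `1/pad_to` = 0.25 Hz. One-sided density
scaling is used, so for white noise the integral of the PSD over frequency
matches the signal variance (checked to 10%). Each trial/channel is
demeaned before tapering — with zero-padding, an un-removed DC offset
would otherwise leak broadband sidelobe power into the analysis band. No
other time-domain baseline correction is applied. Default analysis range
8–38 Hz for the decision-vs-baseline contrast; 13–35 Hz elsewhere.

## IRASA decomposition

For each resampling factor h in 1.1, 1.15, …, 1.9, the signal is resampled
by h and by 1/h (polyphase rational resampling). Resampling scales an
oscillatory peak's frequency by h while leaving a power law's shape
invariant, so the geometric mean of the two resampled PSDs — median'd
across the h set — retains the fractal component and erases narrowband
peaks. The oscillatory component is the original Hann-periodogram PSD
minus the fractal, making fractal + oscillatory reproduce the original
exactly (asserted to 1e-10 relative).

One numerical point matters for short epochs: a single-epoch periodogram
power estimate is χ²₂-distributed, and the geometric mean of two such
estimates is biased low by ≈ π/4. Feeding per-trial periodograms through
the geometric mean would therefore leave a spurious positive oscillatory
residual (~30% of the fractal level) on purely fractal input. The
implementation consequently averages periodograms across trials within
subject *before* the geometric-mean/median step; the returned spectra have
one "subject-average" unit per channel. On χ = 1 input the oscillatory
residual is then a few percent of the fractal component (sampling noise,
shrinking as 1/√n_trials), and the fitted fractal log-log slope is −1
within ±0.1.

## Instantaneous frequency

The estimator follows the standard frequency-sliding chain:

1. zero-phase (forward–backward) FIR bandpass, Hamming design, transition
   width 0.6·f_lo, length ⌈3.3·fs/Δf⌉ rounded odd — a 5 Hz tone is
   attenuated below 1% while a mid-band tone passes within 2%;
2. Hilbert transform → analytic phase, unwrapped at tolerance π;
3. temporal derivative by central differences (one-sided at the edges,
   which are masked anyway), scaled by fs/2π;
4. ten median filters with kernels spaced evenly over 10–400 ms
   (rounded to odd sample counts — 3 to 101 samples at 250 Hz), combined
   by the pointwise median across the ten filtered series.

The median cascade removes the spike artifacts that phase slips produce in
the raw derivative without smearing genuine frequency steps; its output is
always bounded by the raw series' extremes. Kernel count, range and the
median combination rule are configurable; the defaults span sub-cycle to
multi-cycle smoothing at beta frequencies. The validity mask excludes the
bandpass half-length plus the largest kernel half-width at each edge, and
samples where the analytic amplitude falls below 1e-12 of the trial RMS
(phase undefined). The moving median is a numba sorted-insertion kernel,
verified element-for-element against `scipy.ndimage.median_filter`
(`mode="nearest"`); it exists because the cascade is the pipeline's
computational bottleneck at cohort scale.

Accuracy on closed-form signals: a pure 20 Hz tone is recovered with MAE
≈ 0.001 Hz over valid samples; a 16→24 Hz linear chirp reads 20.0 Hz at
the window midpoint within 0.2 Hz; a Hann-enveloped tone stays at its
carrier within 0.2 Hz over the envelope's top half (amplitude modulation
does not masquerade as frequency modulation).

Subject-level condition summaries average IF over trials per condition
(correct trials only by default, with a flag to include all), then report
the per-channel signed and absolute window-mean differences.

## Burst detection

Time-frequency power comes from 7-cycle complex Morlet convolution on a
13–35 Hz, 1 Hz-step grid. Power is normalized per (channel, frequency) by
the median across all trials and times of the subject — "factors of
median" (FOM) — which cancels global amplitude scale exactly. Connected
suprathreshold regions (8-connectivity) in the (frequency, time) plane
each yield one event at the region's global power maximum, with ties
broken toward earliest time then lowest frequency; events keep FWHM
duration and frequency span measured by linear interpolation at half the
peak. The default threshold is the literature's canonical 6 FOM.

Two behaviors are worth knowing. First, χ²-distributed background power
alone crosses 6 FOM roughly once per 1.5 s window, so detected event rates
include a background-event component — this is inherent to the method, not
an artifact; recovery benchmarks that need clean recall use a higher
threshold (12 FOM) at which background crossings are rare. Second, in
dense regimes overlapping bursts merge into one region and are counted
once, so detected rates undercount the generative Poisson rate; Poisson
recovery within 3 standard errors holds in sparse regimes (≲ 1 event per
window).

Summaries per subject and condition report the event rate per decision
window (with a per-second rate alongside, since "per window" depends on
window length) and the mean peak frequency (undefined and flagged when a
condition has no events). Group contrasts: rates vs zero by one-tailed
one-sample t per condition; peak-frequency difference between conditions
by two-tailed paired t, excluding subjects with undefined means pairwise.

## Cluster permutation inference

All group contrasts share one engine. The paired t map over
(channel, bin) uses the n−1 variance denominator; zero-variance samples
yield t = 0 (finite maps; such samples arise only in degenerate synthetic
input and are counted). Suprathreshold samples — |t| above the two-tailed
critical value at `cluster_alpha` = 0.05 for n−1 df — are grouped into
connected components under bin adjacency within channel plus channel
neighborhood at the same bin, with same-sign membership; each cluster is
scored by its mass (sum of member t values).

The null exchanges condition labels within subject, i.e. randomly flips
the sign of each subject's difference, and records the maximum |cluster
mass| per permutation (both signs for two-tailed tests — weak FWER
control). When 2^n ≤ `n_permutations` the full sign-flip set is enumerated:
the test is exact and deterministic, p-values are multiples of 2^(−n), and
the identity pattern guarantees p ≥ 2^(−n). Otherwise Monte-Carlo draws
use the +1/+1 correction, p = (1 + #{null ≥ |mass|})/(1 + N), so p is
never zero and the smallest attainable value with N = 1000 draws is
≈ 0.001. Permutation t maps are computed vectorized using the flip
invariance of Σd². Observed-vs-null mass comparisons use a 1e-9 relative
tolerance because the two routes are algebraically equal but not
bit-identical.

Empirical calibration: across 200 null cohorts (no planted shift, n = 10
subjects) the family-wise rate of any significant cluster at α = 0.05
falls inside the binomial 95% interval around 0.05 (recomputed by the test
suite and, at smaller scale, the acceptance script).

## Decoding

At each time bin independently, channels are features for an LDA with
least-squares fitting and analytic (Ledoit–Wolf) shrinkage toward the
scaled identity — chosen because channels can approach or exceed per-fold
trial counts. Folds are stratified 8-fold, repeated twice with reshuffled
folds; performance is the AUC of held-out decision values, averaged over
folds and repeats. Fold assignment derives from a single seeded
permutation with round-robin assignment within class, which makes the
partition invariant to renaming the two classes; since an LDA retrained
under a label swap negates its decision values exactly, per-fold AUC is
invariant under class renaming (the familiar 1 − AUC complement applies
when fixed scores are re-scored against swapped labels). Group inference
contrasts per-subject AUC time courses against 0.5 with the cluster
permutation test over time bins, one-tailed positive.

On planted-shift cohorts the group peak AUC is deliberately modest
(≈ 0.55 at the default SNR) — single-trial IF features are noisy — yet the
above-chance cluster is detected reliably; with label-independent features
the time-mean AUC stays within 0.5 ± 0.05.

## Pipeline and reproducibility

`oscishift run` executes simulate → IF → group IF contrast (plus a
decision-vs-baseline window-mean IF contrast) → multitaper and IRASA power
contrasts → bursts → decoding from one YAML `RunConfig` with a versioned
schema; unknown keys are hard errors. Every stage logs (stage, subject,
seed) to stderr and a run log; intermediates (per-subject HDF5, event
tables) and report tables are persisted. The report carries provenance
(hash of the scientific configuration — output paths and log level
excluded — seed, package and library versions) and no wall-clock
information, so identical config + seed reproduce `report.json` and
`report.txt` byte-for-byte. When no cluster forms in the IF contrast, the
subject-level effect summary falls back to the whole-window, all-channel
average difference and says so in the report.

The packaged golden fixture stores key report numbers rounded to 1e-6 and
the test compares at that tolerance; bit-exactness is asserted by running
the pipeline twice within one environment rather than against a frozen
binary artifact, which would be brittle to BLAS threading differences
across machines.

## Problem sizes used by the benchmark suite

The cohort-scale checks run at: shift recovery — 20 cohorts × 24 subjects
× 100 trials/condition (sustained, Δ = 0.3 Hz, 1000 permutations);
type-I calibration — 200 cohorts × 10 subjects × 50 trials/condition on
two channels (500 permutations); decoding — 20 cohorts × 10 subjects × 50
trials/condition on eight channels with every 16th valid sample as a time
bin. These sizes were chosen once as the package's benchmark conditions:
large enough that recovery bands and error rates are meaningful, small
enough to run routinely on a single CPU.

## Known limitations

- IF estimates of noise-dominated segments are pulled toward the band
  centroid; recovered shifts are attenuated at low SNR (the calibration
  note above quantifies the default operating point).
- IRASA here returns subject-average components; a per-trial decomposition
  would need an explicit small-sample bias correction.
- Burst rates depend on the FOM threshold and include background
  crossings at the canonical 6 FOM; cross-threshold comparability is by
  design limited.
- The permutation engine covers paired (within-subject) designs only;
  between-subject designs, TFCE and cluster-size statistics are out of
  scope.
- The generator's independence assumptions (trials, channels) make the
  benchmarks necessary but not sufficient evidence for performance on
  recordings with correlated noise fields.
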