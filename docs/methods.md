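# Methods

`lexosc` implements a complete oscillatory analysis of a 2 (task: picture
naming vs. size judgment) x 2 (cognate status) within-subject EEG experiment,
together with a synthetic EEG + behavior generator that realizes the
statistical structure the analysis assumes.  This note documents the models,
the numerical choices, and what the synthetic data do and do not emulate.

## Analysis chain

### Preprocessing

Continuous signals are band-pass filtered 0.1–100 Hz and band-stop filtered
48–52 / 98–102 Hz with zero-phase (forward–backward) Butterworth filters
(order 4 per pass, second-order sections).  Epochs span −1 to +1 s around
stimulus onset and are zero-padded (literal zeros) out to ±5 s so that the
5-cycle wavelet at 1 Hz fits everywhere inside the analysis windows.  Trials
whose peak-to-peak amplitude exceeds a threshold (default 150 µV) on any
channel are rejected — an automated stand-in for operator-driven artifact
screening; the threshold is a config parameter, not a claim about the
original procedure.  Bad channels are interpolated as the
inverse-planar-distance weighted mean of their good Delaunay neighbors, and
data are re-referenced to the common average.  The stage order
filter → epoch → reject → interpolate → re-reference is enforced by
`run_preprocess`.

### Time–frequency decomposition

Morlet wavelets with 5 cycles (σ_t = 5/(2πf)), 1–40 Hz in 1 Hz steps, power
sampled on a 20 ms grid.  The transform is evaluated by direct windowed
products at the requested output times only, which makes per-trial
decompositions of full cohorts tractable; it is validated against MNE's
`tfr_array_morlet` in the test suite.  Analyses that only need the baseline
(−700 to −200 ms) and the post-stimulus windows request exactly those output
times.

### Aperiodic (1/f) subtraction

For each electrode–sample pair the log power spectrum is regressed on log
frequency and the fitted line subtracted, leaving oscillatory power as a
log-ratio against the aperiodic background.  Frequencies whose residual
exceeds 2 residual SDs are excluded (oscillatory peaks are positive
excursions) and the line refit until the exclusion set stabilizes (max 10
iterations).  Three stabilizations matter on strongly oscillatory data:

- **Robust start.** The initial line is refit once on the lower-residual
  half of the bins, so broad oscillatory plateaus (a beta peak seen through
  the wavelet's ±6 Hz bandwidth spans ~15 of 40 bins) cannot anchor it.
- **Trial pooling** (`share_trials`).  The fit per electrode–sample pair
  uses the trial-mean log spectrum — equivalently, pooled least squares —
  which shrinks residual noise by √n_trials and makes peak exclusion
  reliable; the same line is applied to every trial.
- **Per-channel exclusion set and line** (`share_exclusion`,
  `share_times`, used by the pipeline).  Oscillatory peaks are slowly
  varying properties of a channel's spectrum; estimating the excluded set
  and the aperiodic line once per channel from the time-averaged spectrum
  prevents marginal per-sample exclusion flips from jittering the
  extrapolated background under the peaks, and — because baseline
  normalization is a ratio — a time-constant line cannot leak event-related
  band-power changes into the normalized values through the fit.  Per-sample
  fits remain available through the module API.

### Baseline normalization and band power

The corrected log-ratio is exponentiated back to linear power and expressed
as a relative change against the −700 to −200 ms baseline mean,
(P(t) − P̄_base)/P̄_base, per channel and frequency.  Band power is the mean
over a channel set (naming ROI: T3, C3, CP3, CP4, P3, P4, Pz, POz, PO2, Oz,
O2; size ROI: T5, Cz, C3, C4, CP3, CP4, P3, P4), a frequency band (theta
3–7 Hz, beta 25–35 Hz), and the task's analysis window (naming 160–260 ms,
size judgment 260–380 ms).

### Cluster-based permutation statistics

Paired t maps are thresholded two-sided at α = 0.05 of t(n−1); a channel
survives only with ≥ 3 supra-threshold same-sign neighbors (Delaunay
adjacency on the azimuthal-equidistant projection); same-sign connected
components are scored by size (default, as in the source procedure) or by
mass (|Σt|).  The null is built from 2000 within-subject sign flips of the
condition differences, recording the maximum cluster statistic over both
signs (a single familywise two-sided null), and p = (1 + exceedances)/2001.
On a 38-channel array the size statistic is heavily tied and the neighbor
rule prunes null clusters, which makes the default test conservative
(familywise rate ≈ 0.01); the continuous mass statistic without pruning
calibrates at ≈ 0.03–0.05 and is the variant used for type-I calibration
checks.  The same machinery with temporal-contiguity adjacency (and no
neighbor rule) tests ROI band-power timecourses.

### Searchlight mini-cluster analysis

For every electrode outside the ROI, a mini-cluster of the ROI's size is
formed from the center and its k−1 nearest electrodes in the projection
plane (ties broken by channel name).  The cognate effect (paired t of the
mini-cluster-mean band power, NC vs. C) over all mini-clusters forms the
scalp distribution.  The test statistic is the ROI's excess over the scalp,
D = |t_ROI| − max|t_minicluster|, and its p-value comes from 2000 sign-flip
permutations recomputing D.  This statistic is what makes the test answer
"is the ROI special?", not "is there any effect?": a spatially uniform
effect leaves D ≤ 0 and non-significant, while an ROI-confined effect
drives it positive.  The ROI t's percentile within the observed mini-cluster
distribution is reported descriptively.

### Theta–beta phase–amplitude coupling

Per subject and task: the most prominent theta (3–7 Hz) and beta (13–30 Hz)
peaks of the ROI/window-mean corrected spectrum; balanced trial counts by
repeatedly (100 iterations) drawing floor(0.8 × smallest correct-trial
count) trials per condition; per trial and ROI electrode, frequency-domain
Gaussian filters at the peaks (spectral SD 0.5 Hz theta, 5 Hz beta) whose
one-sided spectrum yields the analytic signal — theta phase and beta
amplitude; beta amplitude binned into twelve 30° theta-phase bins; the
modulation index MI = (log 12 − H(p))/log 12, with p the normalized bin
profile and 0·log 0 = 0.  Because the analysis windows are shorter than a
theta cycle, the extraction segment is extended symmetrically to two theta
cycles (~400 ms at 5 Hz); the full-epoch mode is available as an option.
MI per trial–electrode is averaged over electrodes, resampling iterations,
and trials to one value per subject and condition.

### Behavioral statistics

Accuracy is the correct-trial proportion; RT means use correct trials
within the subject-condition mean ± 2 SD (single pass).  Inference: 2×2
within-subject ANOVA with subject-by-effect error terms (F = MS_effect /
MS_effect×subject, partial η²), planned paired t tests with Cohen's
d = t/√n, JZS Bayes factors (Cauchy prior scale 0.707 on the standardized
effect, numerical integration; cross-checked against pingouin), Holm
adjustment within planned-comparison families, and Bonferroni α = 0.0125
for the four one-sample band-power tests.

## Synthetic data generator

Each channel carries four components: a 1/f aperiodic background
(FFT-shaped Gaussian noise, PSD = A²/f^χ with χ = 1, flat below 1 Hz),
white sensor noise, an ongoing theta rhythm, and an ongoing beta rhythm.
The theta component is narrowband noise centered at 5 Hz (spectral SD
0.5 Hz) whose envelope is fixed at its RMS level — the phase dynamics of a
narrowband process without Rayleigh amplitude statistics; trial-to-trial
power variability is instead carried by an explicit unit-mean log-normal
power jitter (SD 0.25) that is constant within a trial and therefore
cancels in baseline-relative measures.  The beta component is a tone
(~29.5–29.9 Hz, per-subject jitter) whose instantaneous amplitude follows
(1 + m cos φ_theta)/√(1 + m²/2) — coupled to the narrowband theta core's
phase, normalized to preserve mean power so that coupling strength and band
power stay orthogonal.  Single-trial band-power SNR for the condition
effects is ≈ 0.3, so averaging across trials is required for detection.

Oscillation amplitudes are set so that the oscillation-to-background power
ratio at the carrier's wavelet bin is 50 (theta) and 40 (beta) — large
enough that residual aperiodic power under the peaks dilutes relative
changes by only a few percent, at the cost of peaks far more prominent than
typical resting EEG.

**Condition effects.**  Effects are multiplicative amplitude steps applied
to the ROI channels (weight 1, immediate neighbors 0.5, elsewhere 0) inside
the task's window, padded by 2σ_t of the band's wavelet and clipped to
stimulus onset.  The generator's contract is that the configured relative
power change is the *pipeline's estimand*: the injected step compensates,
in order, (1) the analytically known band-average dilution by residual
background (including the coupling sidebands for beta), (2) the wavelet's
temporal smoothing of the step (coherent amplitude smoothing for the beta
tone; squared-envelope power smoothing for the narrowband theta), both
solved in closed form, and (3) a final empirical fixed-point correction
(`calibrate_band_effects`): the recovered (theta, beta) changes are
measured through the actual analysis chain on probe condition blocks with
common random numbers, a zero-effect twin acting as control variate, and
the injected steps rescaled until the recovered values match the configured
means.  The measurement-chain offset under zero effects (chiefly a small
baseline attenuation where the 5 Hz wavelet overlaps the padding edge) is
estimated per task and included in the target, since the pipeline measures
it too.  Coupling is calibrated the same way (`calibrate_coupling`):
bisection on m against Monte-Carlo MI estimates computed with the cohort's
own estimator (multi-channel, average-referenced) until the per-condition
MI targets are met within 2%.

**Between-subject structure.**  Per-subject condition effects are drawn
around the configured means with SDs equal to half the reported
across-subject SDs — the reported SDs conflate trait variability with
single-subject estimation noise, which the generator already produces at
trial level; the realized across-subject SD of *measured* effects matches
the reported magnitudes.  Condition effects within a band share a subject
"reactivity" component (correlation 0.7), keeping within-subject condition
differences tighter than the marginal SDs, as the published within-subject
statistics imply.  RTs: subject intercept SD 110 ms, condition-specific
SD 20 ms, trial SD 150 ms, truncated at 150 ms.  Accuracy: subject effect
SD 0.05 plus Bernoulli trial noise, giving observed across-subject accuracy
SDs ≈ 0.09.

**What the generator does not emulate.**  No ocular or muscle artifacts, no
volume conduction (channels are independent up to the average reference and
ROI weighting), no phase-locked (ERP) components, no alpha dynamics, and
oscillation prominence well above typical resting EEG.  Passing recovery
tests therefore demonstrates the correctness and calibration of the
analysis chain under its own assumptions, not its robustness to real-world
artifacts.

## Problem sizes in the test suite

The default suite runs one fully calibrated 18-subject cohort (32
trials/condition) for the recovery checks; the replicate-cohort detection
test uses 5 cohorts sharing one calibration (≥ 4 of 5 must detect both
cognate beta effects with the naming onset earlier, plus the theta
Task × Cognate interaction); permutation counts are reduced to 500–1000 in
calibration loops (2000 remains the analysis default).  The behavioral
accuracy panel uses 30 fixed seeds.  These sizes were chosen so the whole
suite completes in minutes while keeping every estimate's Monte-Carlo error
well inside the asserted tolerances.

## Known limitations

- The 38-channel layout is a stand-in: it contains every ROI electrode
  (including the 10-05 name PO2 and legacy T3/T5) but the remaining
  channels are conventional fill, not the original cap.
- The default cluster statistic (maximum size with the 3-neighbor rule) is
  conservative on 38 channels; use `statistic="mass"` where exact
  calibration matters.
- The searchlight permutation answers "does the ROI exceed the scalp
  distribution"; the descriptive percentile is reported alongside because
  the source procedure's exact permutation scheme is underdetermined.
- MI values near the targets sit close to the estimator's ceiling under the
  prescribed 5 Hz-SD amplitude filter (sidebands of a 5 Hz modulation are
  attenuated ×0.6), so calibrated coupling strengths are high (m ≈ 0.9).
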