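# Methods

This note documents the generative model, the analysis procedures, the
defaults and the numerical choices in `nirsrel`, and what the test suite
does and does not establish about real recordings.

## Signal model and simulator

Each channel's haemoglobin signal is a two-component mixture

    dHbO(t) = F(t) + S(t)
    dHbR(t) = k_f * F(t) + k_s * S(t),      k_f < 0 < k_s

with a *functional* component F (neurovascular: HbO and HbR move in
opposite directions, fixed coupling k_f = −0.6) and a *systemic*
component S (superficial/physiological: HbO and HbR move together,
coupling k_s = 2.0 in the simulator; estimated from data in the
analysis). Units are arbitrary concentration units: without a
partial-volume correction absolute haemoglobin changes are not
interpretable, so only relative magnitudes carry meaning anywhere in the
package.

**Paradigm.** Three conditions (A-ONLY, V-ONLY, AV) × five 24-s blocks,
interleaved in random order, separated by rests drawn uniformly from
20–40 s; two control trials occur 2 s after randomly chosen blocks and
extend the following rest by 5 s; a lead-in rest of 20 s (the rest-range
minimum) precedes the first block, and the run ends after the final
rest. Expected run length ≈ 14 min at 10 Hz.

**Functional component.** F = Σ_c amp_c × (boxcar_c ⊛ HRF). The HRF is
the canonical double-gamma (peak 6 s, undershoot 16 s, ratio 6, no
derivative terms), and the convolution kernel is normalised to unit DC
gain so that a sustained block response plateaus at amp_c. This makes
the GLM beta directly interpretable as the peak concentration change and
puts the functional and systemic components on a common scale; with a
peak-normalised kernel instead, the convolution would inflate the
functional component by the kernel sum (~48 at 10 Hz) and betas would sit
on an arbitrary scale.

**Amplitude model.** Session amplitude = condition mean + subject effect
+ session effect, drawn from independent normals. Defaults: means 0.07
(A-ONLY), 0.035 (V-ONLY, weak speechreading response), 0.075 (AV);
between-subject SD 0.04; between-session SD 0.025. The implied true
test-retest ICC is σ²_b/(σ²_b+σ²_s) ≈ 0.72. Only ROI channels (left
{9,10,12}, right {20,21,23} of 24) respond; all others are true nulls.
The means mirror the scale of typical ROI beta weights in this kind of
experiment; the variance split is a plausible choice (no empirical
calibration exists) fixed once and used by all tests.

**Systemic component.** Cardiac sinusoid (1.1 Hz, amp 0.015), Mayer wave
(0.095 Hz, amp 0.03), slow drift (0.004 Hz, amp 0.05), white
physiological noise (SD 0.01), and a stimulus-locked superficial trend:
a piecewise-linear excursion from 0 at block onset to −1 (scaled by amp
0.03) at 8 s after block offset, recovering linearly over 15 s. The
trend makes S time-locked to stimulation — deliberately, since
stimulus-locked systemic activity is exactly what makes HbO unreliable
in practice. Random phases per channel; amplitudes are plausible rather
than calibrated.

**Optics.** Forward modified Beer–Lambert law with extinction
coefficients from the Gratzer/Kollias compilation (OMLC tabulation)
interpolated to 695/830 nm — (0.2830, 1.9231) and (0.9740, 0.6930)
cm⁻¹·mM⁻¹ for (HbO, HbR) — pathlength = 30 mm separation × DPF 6.
Motion artifacts: Poisson-rate events (default 0.3/min), half Gaussian
spikes (8× channel OD SD, 0.4 s), half step baseline shifts (3× SD),
identical at both wavelengths of the affected channel.

**Determinism.** A cohort is fully determined by its config and seed;
per-recording design/signal/motion seeds derive from one master
generator, so identical configs are bit-identical.

## Preprocessing

Fixed order: intensity → ΔOD → wavelet motion correction → band-pass →
Beer–Lambert inversion.

* ΔOD = −ln(I/I₀) with I₀ the whole-series mean (any other convention
  only shifts the baseline).
* Wavelet correction: Daubechies-5 discrete wavelet transform, reflect
  padding, maximum decomposition depth; within each detail level,
  coefficients outside Q1 − 1.5·IQR … Q3 + 1.5·IQR are set to zero
  (excluded, not shrunk); approximation coefficients untouched.
  *Numerical choice:* thresholding is applied only to detail levels with
  at least 64 coefficients (`min_level_size`). At coarser levels the
  quartiles are estimated from a handful of values, and the sparse
  coefficients carrying the evoked block response are themselves extreme
  within their level — thresholding there measurably attenuates the
  response while contributing nothing to artifact removal, since spikes
  are broadband and fully represented in the well-populated fine levels.
* Band-pass: Butterworth order 3, applied forward-backward
  (zero-phase, effective order 6), 0.01–0.5 Hz, reflect padding. This
  removes drift and attenuates the cardiac line by far more than 20 dB
  while leaving the block-response fundamental (~0.02 Hz) essentially
  untouched.
* Inversion: per-sample 2×2 linear solve of the Beer–Lambert system; no
  partial-volume correction.

The wavelet correction targets spikes; brief step shifts largely fall
below the pass band and are mostly neutralised by the band-pass instead.

## Component separation (HMS)

For fixed k_f and candidate k_s the mixture inverts exactly:

    F = (k_s·dHbO − dHbR) / (k_s − k_f)
    S = (dHbR − k_f·dHbO) / (k_s − k_f)

k_s is picked by exhaustive search over a log-spaced grid (60 points on
[0.05, 20]) minimising the mutual information between F and S, on the
assumption that the neurovascular and systemic processes are
statistically independent. MI estimator: plug-in on a 2-D equal-width
histogram with ⌈√(N/5)⌉ bins per axis (≈ 41 at N ≈ 8 400); deterministic
and directly checkable against the bivariate-Gaussian closed form
−½ln(1−ρ²). Ties resolve to the smallest k_s. k_s is estimated per
channel per recording (the coupling is task- and tissue-dependent; this
is the least-assuming scope). Both components are retained; the GLM
consumes F on the HbO scale, and S stays available for inspection.

Caveat: when the systemic component is itself stimulus-locked, F and S
are not independent and the MI minimiser acquires a small bias in k_s
(the recovered F is still essentially exact — its correlation with the
true functional series stays >0.999 under the default trend amplitude).
The coupling-recovery guarantees are therefore stated for independent
components.

## GLM

Design matrix: one HRF-convolved boxcar per condition, one
HRF-convolved delta regressor at the control-trial onsets
(regressor-of-no-interest), and an intercept; no temporal derivatives,
no drift regressors (the band-pass already removed drift). All-zero
columns (e.g. a simulation without control trials) are dropped with a
warning and reported as NaN.

Estimation: stage-1 OLS; ρ̂ = lag-1 autocorrelation of its residuals
(Σe_t·e_{t−1}/Σe_t²; defined as 0 when the residuals are numerically
zero); quasi-differencing y*_t = y_t − ρ̂y_{t−1}, X*_t = X_t − ρ̂X_{t−1}
with the first sample dropped (classical Cochrane–Orcutt, single
iteration; an iterated variant sits behind a flag); stage-2 OLS gives
the reported β, SE, t with dof = (N−1) − rank(X*). Under simulated
AR(1) noise with ρ = 0.7 this calibrates the one-sided test to ≈ 5%
type-I error where naive OLS exceeds 25%.

Inference: one-sided t-tests per channel (activation = positive t for
the functional component and HbO, negative t for HbR), α = 0.05;
multiplicity handled by Benjamini–Yekutieli step-up at q = 0.05 with the
family = 24 channels within one condition × measure × session (valid
under arbitrary between-channel dependence). Group level: one-sample
one-sided t-test on subject betas per channel (summary-statistics
random effects, no within-subject weighting), then BY-FDR across
channels.

## Reliability metrics

* Pattern correlation: Pearson r between the two sessions' per-channel
  t maps (undefined if a map has zero variance).
* R_QUANTITY = 1 − |A₁−A₂|/(A₁+A₂); R_OVERLAP = 2·A_overlap/(A₁+A₂);
  both undefined (reported missing) when A₁+A₂ = 0. Per-subject
  versions use the single-subject FDR-corrected maps.
* ICCs: one-way random-effects ANOVA on the subjects × sessions
  amplitude matrix. ICC(1) = (BMS−WMS)/(BMS+(k−1)·WMS) for a single
  session; ICC(k) = (BMS−WMS)/BMS for the k-session average; the two are
  linked by the Spearman–Brown identity ICC(k) = k·ICC(1)/(1+(k−1)·ICC(1)),
  which holds exactly pre-clamping. Negative estimates (sampling noise)
  are clamped to 0 in reported values; raw values are retained
  internally. Computed per single ROI channel (range and mean reported)
  and at cluster level (unweighted mean of the three member channels).
* Block averages: epochs −5…+40 s around condition onsets, baseline
  −5…0 s subtracted per epoch, averaged over the five repetitions;
  out-of-bounds epochs are excluded with a warning. The window covers
  pre-stimulus context, the 24-s block, and the return to baseline.
  Time-course reliability is the Pearson r between the two sessions'
  grand-average ROI epochs over the full window.
* Paired t-tests across subjects on cluster amplitudes (two-sided), with
  Cohen's d for paired observations = mean(diff)/SD(diff), uncorrected,
  differences taken session 2 − session 1.
* Qualitative bands for reliability coefficients: poor < 0.40 ≤ fair
  < 0.60 ≤ good < 0.75 ≤ excellent ≤ 1.00 (negatives are poor); effect
  sizes: negligible < 0.20 ≤ small < 0.50 ≤ medium < 0.80 ≤ large.

## Problem sizes used in validation

The package's own validation runs at these sizes, chosen to give stable
Monte-Carlo estimates: ICC recovery at 17 subjects × 2 sessions × 1000
replicates for true ICC ∈ {0.2, 0.5, 0.8} (mean bias < 0.05); GLM
type-I calibration at 2000 AR(1) replicates of a single-condition run;
coupling recovery over 100 independent-component recordings (k_s within
one grid step of 2.0, corr(F̂,F) > 0.95); FDR oracle identity on 500
random 24-channel p-vectors; end-to-end determinism on the full default
17 × 2 cohort run twice. The full pipeline on the default cohort takes
on the order of a minute on one CPU, dominated by the per-channel k_s
grid search.

## What the tests do and do not show

Passing tests establish that every stage implements its stated
mathematics correctly (against closed forms, brute-force oracles, and
independent library implementations: statsmodels for the transformed-
model OLS and the BY procedure, pingouin for the one-way ICCs), that the
estimators recover the generating parameters under the simulator's
assumptions, and that the whole pipeline is deterministic.

They do not certify performance on real recordings. The simulator omits,
among other things: spatial correlation of systemic physiology across
channels beyond the shared stimulus-locked trend; optode-coupling
differences and channel-specific gains; heteroscedastic and non-AR(1)
noise; HRF shape variability across subjects and regions (the simulator
and GLM share one HRF by default, which makes amplitude recovery exact
in the noise-free limit — an option to mismatch exists for robustness
checks); slow baseline-shift artifacts are injected but only partially
corrected (the wavelet step targets spikes). Reported reliability on a
single simulated cohort also inherits genuine sampling variability: with
17 subjects the realised amplitude ICC of a draw can sit far from the
population value, and the estimator will faithfully report the draw.

## Known limitations

* k_s is searched on a fixed log grid; resolution near the optimum is
  ~10% per step by construction.
* The MI estimator's plug-in bias (~(B−1)²/2N nats) is common to all
  grid points but not exactly constant; extremely short recordings make
  the k_s profile noisy.
* The SNIRF export is a minimal writer/reader built directly on h5py
  (time series, measurement list, probe wavelengths, metadata sidecar),
  sufficient for round-tripping this package's recordings rather than a
  complete implementation of the container specification.
* Channel-to-scalp geometry is not modelled; "channels" are indices with
  an ROI membership table (1–12 left, 13–24 right by convention).
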