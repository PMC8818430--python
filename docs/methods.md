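# Methods

This note documents the models, numerical choices and open design
decisions behind `vi_emdar`: a pipeline that discriminates two
visual-imagery tasks (imagining a static picture vs a picture moving
right) from frontal EEG, using empirical mode decomposition (EMD),
Hilbert–Huang features, autoregressive (AR) features and their hybrid,
with an SVM classifier.  Because the original subject recordings are not
publicly deposited, the pipeline runs end-to-end on a synthetic EEG
generator whose role and limits are described below.

## The synthetic EEG generator

`synth.SynthConfig` / `generate_dataset` produce two-class trial sets
(default: 100 trials per class, 8 channels labelled FP2, F8, C3, Cz, C4,
O1, Oz, O2, 4 s epochs at 1 kHz).  Every channel receives

* 1/f-shaped Gaussian noise, `noise_sd` = 3 µV, exponent 1.0, band-limited
  by a 100 Hz roll-off emulating the acquisition amplifier;
* a 50 Hz line sinusoid (1 µV, common phase across channels);
* a linear drift (slope bounded by 2 µV per epoch, per channel).

FP2 and F8 additionally carry a coherent alpha rhythm: a carrier at a
per-trial frequency in 9–11 Hz with **phase diffusion** giving a 2 Hz
Lorentzian linewidth (real cortical alpha is a narrowband stochastic
process, not a sinusoid — a deterministic carrier would make the signal
trivially predictable and grossly favour AR modelling), and a per-trial
log-normal base amplitude (median 2.5 µV, σ = 0.3 in log units; alpha
power varies strongly trial to trial in real EEG).

The class difference is confined to this frontal rhythm's envelope: the
*static* class has a constant envelope A, the *moving* class has
A·(1 + contrast·s(t)) where s(t) is a **periodic 0.5 Hz ramp-and-hold**
(linear ramp 0→1 over the first half of each 2 s period, hold at 1 for
the second half).  The periodic form was chosen over a one-shot ramp
because a modulation with an actual 0.5 Hz rate produces recurring
envelope transients and sidebands — a nonstationarity that per-IMF AR
residual variances can respond to — whereas a single ramp is essentially
a DC change in envelope.  At `alpha_contrast = 0` the two classes are
drawn from identical distributions (the null used for calibration).

Amplitude and SNR figures are not reported for the original recordings;
the defaults above were fixed once so that the end-to-end pipeline lands
in a mid-range accuracy regime (roughly 75–90% at contrast 1) where
method differences are measurable in both directions.

**What the generator does not emulate:** volume-conducted cross-channel
correlations, realistic artifact morphology (a crude frontal blink
injector exists only to exercise the ICA stage), non-Gaussian background
statistics, between-subject heterogeneity beyond the seed, and any class
information outside the frontal alpha envelope.  Consequently, the class
difference is effectively one-dimensional (the frontal alpha envelope),
and all three feature families ultimately read the same cue: passing the
ordering checks here shows the pipeline is correct and calibrated, not
that the hybrid's large advantage on real recordings is reproduced — on
this generator the three methods tie within one accuracy point.

Reproducibility: each trial's random stream derives from
(seed, class, trial index), so trial k is unchanged when the dataset
grows; the pipeline fans one global seed out to per-subject and per-split
substreams.

## Preprocessing

Fixed stage order: least-squares linear detrend → filtering → optional
ICA artifact rejection → epoching.  Two filter paths exist:

* **Narrowband**: an elliptic 8–13 Hz band-pass (0.5 dB passband ripple,
  50 dB stopband, minimum order for 1 Hz transition bands — order 5 at
  1 kHz), applied forward–backward so later stages see no phase
  distortion (attenuations double in dB; the 50 Hz line falls ≥ 100 dB).
* **Broadband**: a 50 Hz IIR notch (Q = 30) only.

Feature extraction runs on the **broadband** path.  Two observations force
this choice: an 8–13 Hz input would concentrate ~99% of IMF variance in
IMF1, which contradicts the study's own screening profile (eight IMFs
with IMF1 carrying 57%), and the long impulse response of the narrow
band-pass smears exactly the envelope transients the hybrid's residual
variances respond to.  Band statistics also run broadband, else every
non-alpha band would be annihilated before testing.  The narrowband path
remains available (`RunConfig.band = (8, 13)`).

ICA rejection uses FastICA with automatic screening: components whose
sample-kurtosis z-score (across components) exceeds 5 are zeroed.  The
algorithm and criteria are a deterministic-given-seed stand-in for manual
component inspection; on clean synthetic data the stage is a no-op and it
is disabled by default in the pipeline.

## EMD

Sifting uses natural cubic-spline envelopes with mirror extension of the
two extrema nearest each end.  Flat plateaus (equal samples within
`extrema_tol`) count once, at the plateau midpoint.  A sift stops at the
first of: IMF admissibility (|#extrema − #zero crossings| ≤ 1 **and**
mean |envelope midline| over the central 80% < 0.05·RMS), the Cauchy
criterion SD < 0.2, or 100 sifts.  The mean-absolute form of the midline
test matters: a signed mean would accept any zero-mean wiggly midline and
mis-classify two-tone signals as IMFs.

Decomposition stops when the residual is monotone or has fewer than two
interior extrema, with two guards: a candidate whose energy is below
10⁻¹² of the input's is machine-noise residue and is folded back, and a
candidate with fewer than two zero crossings is trend-like, not an
oscillatory mode, and stays in the residual.  `max_imfs` = 12 caps
over-decomposition (hitting it logs a warning).  Reconstruction
Σcⱼ + r = x is exact up to floating point and asserted at 10⁻⁹ relative
tolerance.

The test suite cross-checks against an independently written minimal
sifting implementation (`tests/reference_emd.py`, a constructed stand-in
reference that uses different extrema, envelope and stopping routes).
Agreement is evaluated where the algorithm is actually determined:
per-IMF correlations on the central 80% of samples (boundary policy is
the one genuinely open choice, and it only affects the edges) and counts
of resolvable modes (≥ 2 cycles per epoch; slower terminal components of
a 4 s epoch are split or merged arbitrarily by any variant).

## Hilbert features

The analytic signal is the standard frequency-domain construction
(negative frequencies zeroed).  All instantaneous statistics trim to the
central 80% of samples to discard end effects, since the continuous
Hilbert integral gives no boundary guidance.  "Average instantaneous
energy" is implemented as mean(a²) (energy semantics); mean(a) is exposed
as a switch.  Four IMFs per channel are used, mirroring the screening
result that the first four slots carry the bulk of the variance; missing
IMFs contribute zero-filled feature slots.

## AR features

The AR convention is y(i) = Σ φⱼ y(i−j) + n(i) (positive φ on past
values).  Burg estimation comes from statsmodels; stationarity (all
characteristic roots inside the unit circle) is asserted on every fit.
The pipeline order is fixed at p = 6 — AIC selection is computed and
logged per dataset as a diagnostic but not varied per trial, so feature
vectors stay comparable.  The feature vector contains only the 12
coefficients; residual variance is deliberately excluded (it enters only
the hybrid's eigenvectors).

## EMD+AR hybrid

Per channel: decompose → keep/zero-pad to 4 IMFs → energy-normalize →
least-squares fit of cᵢ(t) + Σₖ h_{ik} cᵢ(t−k) = eᵢ(t), order m = 4 per
IMF (per-IMF FPE selection available as `m="fpe"`).  Normalization
divides by the L2 norm √(Σc²·dt) — the literal division by the energy
itself is dimensionally not a normalization and is kept only behind a
flag.  The least-squares regression runs on the normalized IMF, so eᵢ²
is also scale-free; the whole 40-dim vector is invariant to positive
rescaling of the input (asserted to 10⁻⁶).  Zero-padded IMF slots yield
h = 0, e² = 0 blocks by convention so the feature matrix is rectangular.
Class-template eigenvectors (per-class means of h and e²) are computed on
training folds only and exposed for diagnostics; the classifier of record
is the SVM.

IMF screening reports each IMF's variance contribution rate
var(cᵢ)/Σvar(cₖ)·100 (residual excluded) and Pearson correlation with the
input; the selected set is the smallest prefix reaching 95% cumulative
contribution, never fewer than four.

## Classification protocol

Class-stratified random halves (100 train / 100 test at the defaults),
features z-scored by training statistics only, SVC with RBF kernel,
C = 1, and inverse bandwidth 1/(2·median²) of the training pairwise
distances.  The kernel and C are unrecorded in the source study; RBF with
the median heuristic was chosen once for all three methods (a linear
kernel, also available, collapses the hybrid's accuracy and was not
adopted).  Accuracies average over 10 independent splits per subject;
single-split mode is available.  Cohorts of 18 independent generator
seeds emulate the 18-subject structure.  Time-resolved curves re-extract
features in 1 s windows sliding by 0.1 s (defaults; the analysis driver
uses 0.5 s steps for speed) under a fixed split.

## Band statistics

Band power is a Hann-tapered periodogram integrated over band bins
(delta 0.5–4, theta 4–8, alpha 8–13, beta 13–30, gamma 30–80 Hz; edges
configurable).  Class comparisons use Welch's two-sided t-test; per
channel a balanced two-way fixed-effects ANOVA (task × band) computed by
direct sum-of-squares decomposition reports the task effect with
df = 1 (two tasks).  The source study prints df = 3 per channel for a
three-factor description that cannot be reconciled with per-channel
reporting; the two-way design implemented here is documented rather than
reverse-engineered.  No multiple-comparison correction is applied by
default (mirroring the original analysis); Benjamini–Hochberg is
available behind a flag.

## Problem sizes and determinism

The default experiment (18 subjects × 200 trials × 2 channels, EMD
shared between the HHT and hybrid extractors) completes in about three
minutes; statistical calibrations use reduced geometries (1 s epochs at
250 Hz, 15 trials per class, 200 replicate datasets) chosen so that the
quantities being checked — type-I error rates, binomial null intervals —
are unaffected by the reduction.  All results are bit-reproducible from
the global seed.

## Known limitations

* The generator's one-dimensional class cue makes the three feature
  methods near-equivalent; it cannot, and is not meant to, reproduce the
  large between-method gaps reported on real recordings.
* EMD boundary handling and terminal slow modes are variant-dependent;
  only central-window, resolvable-mode quantities should be interpreted.
* The ICA stage rejects only heavy-tailed (kurtotic) components; slow
  ocular drifts with near-Gaussian statistics pass through (the linear
  detrend and filters absorb most of them).
* EDF input requires `mne`; EDF export is not implemented (the delimited
  writer plus JSON sidecar is the interchange format).
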