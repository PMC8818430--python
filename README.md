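# vi-emdar

Classification of **visual imagery (VI)** from frontal EEG: can we tell,
from 4 s of eight-channel EEG, whether a person is imagining a *static*
picture or a picture *moving to the right*?  This package implements the
full analysis for that question — a from-scratch empirical mode
decomposition (EMD), Hilbert–Huang spectral features, autoregressive (AR)
model features, the hybrid EMD+AR feature extractor, and SVM
classification — together with a synthetic EEG generator that emulates
the study conditions (2 classes × 100 trials, 8 channels at 1 kHz, class
differences confined to the alpha rhythm of FP2/F8), so the entire
pipeline is testable without access to subject recordings.

It is written for neural-signal-processing researchers and BCI students
who want a compact, fully tested reference implementation of the
EMD → per-IMF AR modelling route to EEG feature extraction.

## The methods in brief

**EMD.** A signal x(t) is sifted into intrinsic mode functions: at each
step the midline m(t) of the cubic-spline envelopes through the local
maxima and minima is subtracted, h = x − m, until h has equal (±1) counts
of extrema and zero crossings and a locally symmetric envelope midline,
or until the Cauchy criterion SD = Σ(h_prev − h)² / Σ h_prev² < 0.2.
Successive IMFs c₁…c_n are peeled off the residual until it is monotone,
giving the exact reconstruction x(t) = Σⱼ cⱼ(t) + r_n(t).

**HHT features.** Each IMF's analytic signal z = c + i·H[c] = a·e^{iθ}
yields the instantaneous amplitude a(t); the feature is the average
instantaneous energy mean(a²) of the first four IMFs of FP2 and F8
(8 features).

**AR features.** y(i) = Σⱼ φⱼ y(i−j) + n(i) with order p = 6 selected by
AIC; the Burg-estimated coefficients of FP2 and F8 form a 12-dimensional
vector {FP2_AR1…FP2_AR6, F8_AR1…F8_AR6}.

**EMD+AR (the headline hybrid).** Per channel: decompose, zero-pad to a
common IMF count, energy-normalize each IMF (c̄ = c/‖c‖₂), and fit
c̄ᵢ(t) + Σₖ h_{ik} c̄ᵢ(t−k) = eᵢ(t) by least squares (order m = 4, FPE
available).  The per-IMF eigenvector Aᵢ = {h_{i1}…h_{im}, eᵢ²} includes
the residual variance — the coordinate that responds to nonstationarity
and that the plain-AR feature set lacks.  Four IMFs × two channels give
40 features; class-template eigenvectors Āⱼ,ᵢ are the class means.

**Classification.** Stratified 100/100 train–test splits, z-scoring by
training statistics, RBF-kernel SVM (C = 1, median-heuristic bandwidth);
accuracies are averaged over 10 splits and summarized over 18 synthetic
"subjects" (independent generator seeds) as mean ± SE / max / min.

## Worked example

```python
import numpy as np
from vi_emdar import SynthConfig, generate_dataset, decompose
from vi_emdar.preprocess import preprocess_trials
from vi_emdar.emdar import emdar_feature_matrix
from vi_emdar.classify import train_eval

ts = preprocess_trials(generate_dataset(SynthConfig(seed=0)),
                       band=None, notch=True)   # broadband path, 50 Hz notch
dec = decompose(ts.trials[0, ts.channel_index("FP2")])
print("IMFs:", dec.n)                            # IMFs: 7
fm = emdar_feature_matrix(ts, k_imfs=4, m=4)
print(fm.X.shape)                                # (200, 40)
res = train_eval(fm, n_train_per_class=50, n_test_per_class=50, seed=0)
print(f"{res.accuracy:.1f}%")                    # 76.0%
```

A broadband 4 s epoch decomposes into about seven or eight IMFs; the
40-dim hybrid feature matrix classifies the two imagery classes in the
75–85% range at the default class contrast (chance = 50%; a single split
is a few points noisier than the 10-split averages the cohort experiment
reports).

The numbered drivers under `analysis/` run the complete study:

| script | what it does |
| --- | --- |
| `01_simulate.py` | generate a subject, summarize frontal alpha power by class |
| `02_band_statistics.py` | Welch t-tests per (channel, band) + task ANOVA |
| `03_imf_screening.py` | variance contribution and correlation per IMF slot |
| `04_classification.py` | multi-subject accuracy tables for HHT / AR / EMD+AR |
| `05_time_resolved.py` | sliding-window accuracy curves over the 4 s epoch |

Each writes its tables under `results/`.  A thin CLI mirrors the stages:
`vi-emdar synth|preprocess|features|run`.

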