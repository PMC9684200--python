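# Methods

## Problem and scope

`semgdeco` decodes *compound motions* from 8-channel surface EMG (sEMG):
every combination of 4 hand gestures (fist, pinch, poke, palm), 5 wrist
angles (flexion, extension, ulnar, radial, neutrality) and 3 strength
levels (0 g, 480 g, 960 g load), i.e. 60 classes. The interest of the
problem is multi-target structure: the class is a triple, so it can be
decoded by one integrated 60-class model or by three parallel factor
classifiers whose decisions are composed through the label algebra

    compound_id = 20·s + 5·g + w + 1,   g ∈ 0..3, w ∈ 0..4, s ∈ 0..2.

The package covers classical-pipeline decoding only: time-domain feature
engineering plus shallow classifiers. Deep-network decoding, prosthesis
control logic and cross-subject transfer are out of scope.

## Signal model of the synthetic generator

No public recordings exist for this protocol, so the package ships a
generator whose defaults define the study conditions all tests run under.
A trial is a 60 s isometric hold sampled at 1000 Hz on 8 channels. Each
channel c of a trial with label (g, w, s) is

    x_c(t) = A_c · n_c(t) + m·sin(2π·50·t + φ_c) + d_c(t) + ε_c(t)

- **Class-conditional amplitude** `A_c = subject_gain_c · strength_gain_s ·
  (baseline_c + G[g,c] + W[w,c])`. The gesture matrix G (4×8) and wrist
  matrix W (5×8) give each factor level a dominant channel subset,
  mimicking electrodes targeted at eight forearm muscles; an exhaustive
  60×60 check at construction guarantees pairwise-distinct expected
  profiles. Strength gains default to (1.0, 1.4, 1.8) — a plausible
  amplitude growth across the 0/480/960 g loads, large enough for
  separability.
- **Carrier** `n_c(t)`: unit-variance Gaussian noise band-limited to
  20–450 Hz (zero-phase 4th-order Butterworth on white noise,
  renormalised). The *lower* band edge rises with strength level by
  (0, 20, 40) Hz: stronger contractions recruit faster motor units and
  raise the EMG median frequency, so waveform-shape features (ZC, SSC,
  AR) carry strength information as they do in real recordings. The
  shift sits inside the 20–250 Hz analysis band on purpose — a shift
  outside it would be erased by preprocessing.
- **Nuisance terms** exercised by the preprocessing chain: 50 Hz mains
  interference with random per-channel phase (relative amplitude 0.5,
  clearly visible above the carrier spectrum), sub-1 Hz baseline drift
  (slow sinusoid plus linear ramp, amplitude 0.5) and a white noise floor
  (0.05).
- **Subject variability**: per-channel log-normal gains with log-scale σ
  = 0.15, derived deterministically from the subject-ID string, so a
  "subject" keeps one electrode/physiology signature across datasets.
  Trial noise streams split from the master seed by (seed, subject,
  compound ID); the whole dataset is a pure function of (config, model,
  subject, seed).

What the generator does **not** emulate: motor-unit action potentials,
fatigue, electrode shift, amplitude non-stationarity within a hold, or
any calibration to real per-class statistics (none are published).
Passing end-to-end tests therefore demonstrates pipeline correctness and
the qualitative structure of the problem, not expected accuracy on human
data. In particular the synthetic classes are amplitude-dominant, so
single-feature (MAV) decoding is already near ceiling and the benefit of
the full 7-feature set is marginal here, whereas on real data it is
substantial.

## Preprocessing

Per trial, in order: least-squares linear detrend per channel; 2nd-order
IIR notch at 50 Hz (−3 dB bandwidth 2 Hz, Q = 25 — narrow enough to spare
the EMG band; the printed sources leave Q unstated); Butterworth bandpass
with edges 20/250 Hz, designed with 4 pole pairs per edge (an 8th-order
transfer function — the design the stated stopband behaviour, ≥30 dB at
5 Hz and ≥12 dB at 400 Hz, requires). Filtering is causal single-pass by
default because the decoding budget is a sub-200 ms real-time pipeline;
zero-phase forward-backward filtering is a config option for offline
parity. All designs are stability-checked (poles strictly inside the unit
circle) at construction. The chain runs on the whole trial before
windowing, and a metadata flag forbids accidental double conditioning.

## Windowing and splitting

Trials are cut into disjoint 150 ms windows (150 samples at 1000 Hz, zero
overlap, trailing remainder dropped): 400 windows per 60 s trial. The
train/test split is chronological per (subject, class): the first
round(fraction·n) windows train, the rest test, so every test window is
later in trial time than every training window (no temporal leakage);
each side is then shuffled reproducibly. Default fraction 0.9 → 360/40
per mode at full scale.

## Features

Per channel of a 150-sample window, in canonical order MAV, RMS, VAR,
ARC, WL, ZC, SSC; channel-major concatenation gives ≤ 8×7 = 56 dims.

- VAR uses denominator N−1; RMS² = ((N−1)/N)·VAR + mean² is asserted as
  an identity in tests.
- ZC counts strict sign changes (adjacent product < 0); zeros do not
  count.
- SSC counts interior turning points whose slope product meets the
  threshold ω = 0.05 × per-window sample std. The threshold is linear in
  amplitude while the product is quadratic, so SSC is intentionally not
  scale-invariant; the definition is applied as stated. A flat signal
  yields 0 (the degenerate 0 ≥ 0 case is excluded: a constant has no
  turning points).
- ARC is the 4th coefficient of an order-4 autoregressive fit under the
  convention x_i = −Σ a_k x_{i−k} + e_i, estimated by Yule–Walker with
  biased autocovariances on the mean-removed window (deterministic and
  robust at N = 150). One coefficient per channel keeps the full vector
  at 56 dims. A constant window returns 0 with a warning. The in-package
  solver is a batched 4×4 Toeplitz solve; tests pin it to
  `statsmodels.yule_walker(method="mle")` as an independent oracle.

A per-window scalar path and a vectorised batch path coexist; tests
assert their agreement, and a brute-force Python loop re-derives every
feature on 1000 random windows.

## Decoders

Features are z-scored with training-set statistics (zero-variance
dimensions pass through with a warning); the Gaussian-kernel scale
presets (γ ∈ {0.56, 2.2, 8.9}, as K = exp(−‖u−v‖²/γ)) presuppose
standardized inputs. Classifier presets mirror a point-and-click
learner's grid: capped-leaf Gini trees (100/20/4), linear/quadratic
discriminants (QDA unregularised by default so singular class
covariances fail loudly; regularisation is a config override), Gaussian
naive Bayes, SVMs (linear, (1+x'y)², (1+x'y)³, Gaussian; one-vs-one, box
constraint 1), k-NN (k ∈ {1, 10, 100}; euclidean, cosine, Minkowski-3,
squared-inverse-distance-weighted voting), bagged/boosted trees and
random-subspace ensembles (30 learners). Kernel naive Bayes and RUSBoost
have no scikit-learn backend and are rejected with a clear message.

The *integrated* decoder fits one 60-class model. The *chain* fits three
independent classifiers on the factor labels obtained by decomposing the
compound ID and composes their argmax decisions back into a compound ID;
its theoretical compound accuracy is the product of the three factor
accuracies (implemented with an explicit fraction-vs-percent scale
check). Since a compound prediction is correct only when all three
factors are, empirical chain accuracy never exceeds the minimum factor
accuracy — asserted as an invariant.

## Evaluation

Overall accuracy, per-mode accuracy (undefined — not zero — for modes
with no test windows), the 60×60 confusion matrix (rows = truth),
factor and joint-factor accuracies by projection through the label
algebra, and two robustness sweeps: training fraction 0.9 → 0.5, and
cumulative feature subsets MAV → all seven. Cross-subject aggregation
reports mean ± *population* standard deviation (denominator N); this is
the convention that reproduces the published aggregate rows from their
per-subject values (sample std would not). Display rounding is 2 d.p.
for prose-style numbers and 3 d.p. for table-style numbers; storage is
unrounded.

## Problem sizes used by tests and the acceptance script

Unit and property tests run on 3 s trials (20 windows per mode, one
subject). The end-to-end acceptance run uses 2 synthetic subjects with
30 s trials — 200 windows per mode, 12 000 windows per subject — with
the default 0.9 chronological split and the quadratic-kernel SVM; these
sizes are the package's reference desk-scale configuration. Determinism
is demonstrated by byte-identical feature tables and identical reports
across re-runs at fixed seed.

## Known limitations

- Synthetic classes are amplitude-dominant by construction; feature-set
  and classifier rankings measured on them need not transfer to humans.
- The causal default introduces filter group delay within each trial;
  the zero-phase option exists for offline comparisons but is not the
  default because of the real-time framing.
- The chain and integrated decoders share one feature table; no
  per-factor feature selection is attempted.
- Only 0-overlap windowing is implemented; overlapping windows and
  majority-vote post-processing are out of scope.
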