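# Methods

## Problem setting

A head-mounted 6-axis IMU (3-axis accelerometer in g, 3-axis gyroscope in
deg/s) streams raw motion data while a wearer performs everyday activities.
A closed-set classifier trained on a fixed activity set Y_train fails
silently when the wearer does something outside that set.  Open-set
recognition (OSR) adds a scalar score S(x) to each classified window x, with
the convention that higher S(x) means the window more likely belongs to an
unknown class.  This package implements the complete pipeline — synthetic
cohort generation, windowing, a lightweight 1D CNN, six post hoc logit-space
scores, and a nested leave-one-activity-out / leave-one-subject-out
evaluation — entirely on top of numpy/scipy/scikit-learn.

## Synthetic cohort model

Real head-mounted IMU cohorts of this kind are not freely redistributable,
so the package ships a parametric generator that reproduces the statistical
structure the method relies on rather than biomechanical detail:

* **Baseline (low-motion) classes** — sensor noise plus a constant +1 g
  gravity offset on one accelerometer axis.  Nothing else: these windows are
  "neutral motion" anchors.
* **Gesture classes** (nodding, shaking) — a harmonic series
  sum_{k=1..H} (A/k) sin(2 pi k f t + phi) on the three gyroscope channels,
  gated by a 50%-duty on/off envelope with period 4 s, emulating repeated
  head-gesture bursts separated by rests.
* **Locomotion classes** (walking, stairs, running) — the same harmonic
  series on the three accelerometer channels, continuous (no envelope),
  emulating gait harmonics.

Phases are drawn per recording and channel.  Per-subject variability is a
pair of log-normal multipliers (amplitude, frequency) with log-sd
`subject_variability` (default 0.12), drawn once per subject; this is what
creates the subject-generalization gap that the subject-wise protocols probe.
Class imbalance is produced the way it arises in real protocols — unequal
recording durations per activity — never by dropping windows.  Signals are
never filtered or normalized.

Default cohort (the package's study conditions): 8 subjects x 6 activities
at 26 Hz — breathing (baseline, 180 s), nodding (1.2 Hz, 40 deg/s, 45 s),
shaking (2.4 Hz, 70 deg/s, 45 s), walking (1.8 Hz, 0.35 g, 150 s), stairs
(1.1 Hz, 0.5 g, 60 s), running (2.8 Hz, 0.9 g, 100 s); noise sd 0.03 g on
accelerometer and 1.5 deg/s on gyroscope channels.  These amplitudes and
frequencies are engineering choices in plausible physiological ranges
(gait cadence 1–3 Hz, sub-g head accelerations, tens of deg/s head
rotation); no signal-level statistics of any specific cohort were available
to calibrate against.  The 26 Hz default keeps 3-second windows at 78
samples, which keeps the whole nested protocol cheap on a single CPU; the
generator and model are agnostic to the rate (the CNN ends in a global
average pool), and 100 Hz works identically.

A *null* cohort (`null_cohort_config`) makes every class an identical
locomotion signal under different names.  Labels then carry no information,
so any correct scoring method must separate an excluded class at chance
(AUROC ≈ 0.5); this is the package's strongest end-to-end self-test.

**What passing on synthetic data does and does not show.** The generator
makes class separations spectral and stationary; real IMU data add
transients, orientation changes, drift, inter-axis coupling and activity
overlap.  Green tests demonstrate the pipeline's correctness and the
qualitative behaviours (density scores discriminate a distinct unknown;
removing the only low-motion class degrades OSR), not field performance.

## Windowing

Sliding windows of `window_s` = 3 s with 50% overlap.  Window length
W = round(window_s · fs) samples; the step is defined in seconds and then
converted to samples (1.5 s → 39 samples at 26 Hz, 150 at 100 Hz).  The
number of windows from an N-sample recording is floor((N − W)/step) + 1;
trailing samples are discarded and windows never span recordings.  Start/end
transients of each activity bout are not trimmed.

## Backbone

Conv1D(6→16, k=7, same padding)–ReLU–MaxPool(2), Conv1D(16→32)–ReLU–
MaxPool(2), global average pooling over time, layer normalization (the
32-d feature), FC(32→64)–ReLU–dropout(0.3), linear(64→C).  Training uses
class-weighted cross-entropy (weights n/(C·n_c), mean-normalized), Adam
(lr 1e-3, weight decay 1e-5), batch 64, max 50 epochs, a stratified
80/20 window-level train/validation split, reduce-on-plateau (factor 0.5,
patience 3) and early stopping (patience 10) both driven by validation
macro-F1; the returned weights are the best-validation-epoch snapshot.
Kernel size, pool size, FC width, dropout and patiences are conventional
lightweight-1D-CNN choices surfaced in `BackboneConfig`, not tuned values.

The network is small enough (≈20k parameters) that forward and backward
passes are written directly on numpy arrays (im2col convolutions, exact
layer-norm backprop — verified against finite differences in the test
suite).  This keeps the dependency set to the scientific Python stack and
makes every run bit-reproducible from one integer seed (init, splits,
shuffling and dropout all derive from it).  Argmax ties break to the lowest
class index.

## Open-set scores

All six scores consume the raw logit vector z(x) ∈ R^C; higher = more
likely unknown.

| method | score | calibration state |
| --- | --- | --- |
| mls | −max_c z_c | none |
| energy | −T·log Σ_c exp(z_c/T), T = 1 | temperature |
| nndr | min dist to predicted-class training logits / min dist to other-class logits | stored logits per class |
| gmm | −log Σ_c π_c N(z; μ_c, Σ_c) | per-class mean, full covariance (+1e-6·I), empirical priors |
| kde | −log Σ_c π_c p̂_c(z) | per-class Gaussian KDE, Scott's-rule bandwidth (floor 1e-3), empirical priors |
| openmax | softmax probability of the explicit unknown slot after Weibull recalibration | per-class MAV + Weibull tail (size 20), α = min(3, C) |

Numerical choices:

* Energy's sign follows the defining formula (the score *is* the energy),
  which makes confident known windows score low, consistent with the global
  orientation; T = 1 recovers the standard energy score, and T → 0 recovers
  −max logit (asserted to 1e-6 at T = 1e-4).
* nndr: a zero other-class distance with nonzero same-class distance maps to
  a finite cap (1e6) so AUROC stays defined; both distances zero gives 1.
* gmm/kde/nndr calibrate on *all* training logits partitioned by true class
  (empirical priors); OpenMax restricts to correctly classified samples when
  computing MAVs and distance tails, and errors if a class has none.
* OpenMax distance is the unweighted sum of Euclidean and cosine distance to
  the MAV; Weibull tails (the `tail_size` largest distances, truncated to
  the class count with a warning) are fitted by maximum likelihood with the
  location fixed at 0.  For the α top-ranked activations the outlier weight
  is ω_c = ((α − rank + 1)/α)·WeibullCDF(δ_c); revised activations
  z_c(1 − ω_c) plus an unknown activation Σ z_c ω_c enter a (C+1)-softmax.
* kde log-densities can underflow far from all training data; scores are
  clamped to ±1e6, which is monotone-safe for AUROC.

## Evaluation protocols

**Closed-set**: subject-wise k-fold CV (default k = 5; k = 4 on the 8-subject
default cohort).  Subjects are shuffled by seed and partitioned; each fold
trains on the rest and reports accuracy and per-class precision/recall/F1,
aggregated as mean ± sd over folds.

**Open-set**: nested LOAO (outer) × LOSO (inner).  For excluded activity a
and each held-out subject s, a backbone is retrained from scratch on the
known-class windows of all subjects ≠ s (per-fold seed = base seed + fold
index), every scorer is calibrated on that fold's training-set logits, and
subject s's known-class windows (ground-truth known) and excluded-class
windows (ground-truth unknown) are scored.  Unknown test windows come only
from the held-out subject, preserving strict subject independence on the
unknown side as well.  AUROC uses the Mann–Whitney rank formulation with
ties at 1/2.  The headline per-excluded-class number pools scores over the
union of inner folds (stable at small per-fold counts); per-fold AUROCs are
reported alongside.  Folds without unknown test windows are flagged
degenerate, logged and skipped in pooling rather than erroring the run.

## Known limitations

* The generator's spectral separability is idealized; absolute AUROC values
  on synthetic data do not transfer to any real cohort.
* Scorer calibration inherits whatever logit geometry the backbone learned;
  with very few subjects the per-fold logit distributions are noisy and the
  density scores (gmm in particular, needing ≥ C+1 samples per class) can
  be unstable.
* No decision-threshold selection is provided: the package evaluates score
  orientation and ranking quality (AUROC), deferring operating points to
  deployment.
* No resampling between rates, gap repair, or transition relabelling.
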