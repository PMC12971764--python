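# Methods

`neuroskill` implements a subject-independent pipeline for classifying
surgical expertise during robot-assisted vesico-urethral anastomosis (VUA)
subtasks from two synchronized physiological streams: high-density EEG
(512 Hz, 116 usable channels) and a Tobii-style eye-tracking export (50 Hz,
20 signals). Because no public recording of such a study setup exists, the
package ships a first-class synthetic-data generator that emulates the
recording conditions; every downstream stage is exercised and tested
against it.

## Ground truth: RACE ratings and skill classes

Three raters score each segmented subtask on five Likert (1–5) domains of
the Robotic Anastomosis Competency Evaluation (RACE): needle positioning
and needle entry label Subtask 1; needle driving & tissue trauma, suture
placement and tissue approximation label Subtask 2 (knot tying is out of
scope). Per rater, the relevant domain scores are averaged; the ordinal
mean is cut into three classes — 1 (inexperienced), 2 (competent),
3 (experienced) — and rater disagreements are resolved by majority vote.

Decisions where the design was open:

* **Class thresholds.** No standard RACE→class cuts exist; they are
  required configuration, defaulting to tertile cuts of the 1–5 scale
  (2.33, 3.67), and are carried into reports.
* **Three-way vote ties** (raters say 1, 2, 3) resolve to the ordinal
  median, 2 — deterministic and scale-preserving.
* **Granularity.** Labels are per-segment by default;
  `ratings.labels_by_participant` provides the coarser per-participant
  aggregation.

Agreement is quantified two ways, both authored here and cross-checked in
tests against independent implementations (statsmodels, pingouin):

* **Fleiss' kappa** on the categorical labels,
  κ = (P̄ − P̄ₑ)/(1 − P̄ₑ), with a seeded item-level percentile bootstrap CI
  (2000 resamples). An all-one-category table makes κ 0/0; a degenerate
  flag is returned rather than a number.
* **ICC(2,1)** — single-measure, two-way random effects, absolute
  agreement — from the ANOVA mean squares,
  ICC = (MSR − MSE)/(MSR + (k−1)MSE + k(MSC − MSE)/n), with the standard
  F-based confidence bounds. The average-measure form ICC(2,k) is
  available behind a flag.

## Preprocessing

EEG, applied identically to every subject, in order: exclusion of 8
poor-quality electrodes (F8, POz, AF4, AF8, F6, FC3 and mastoids M1/M2;
124 → 116 channels) → 60 Hz notch (zero-phase 2nd-order IIR, Q = 30) →
0.2–250 Hz band-pass (zero-phase 4th-order Butterworth, i.e. 24 dB/octave)
→ common average reference → PCA-based artifact removal → surface (Hjorth)
Laplacian, each channel minus the mean of its 4 nearest neighbours on a
schematic 2-D layout. Filters are forward–backward, so the chain is linear
and phase-free; linearity is property-tested.

The artifact stage stands in for interactive review software: principal
components whose scalp projection correlates with a synthetic frontal
(ocular) template, or that individually exceed a variance fraction, are
removed and the signal reconstructed. It is transparent, deterministic,
and has an exact no-op mode; it makes no claim of fidelity to
expert-guided source decomposition.

Eye tracking: missing samples (sentinel NaN, eye-movement-type 3) are
mean-imputed per signal, then a centred 3-point moving average smooths the
19 continuous signals (shrinking window at the edges). The categorical
eye-movement-type channel is never averaged: missing → type 3, smoothing
by majority-of-3.

**Fusion.** Within each subtask segment (delimited by event timestamps),
continuous gaze signals are resampled from 50 Hz onto the 512 Hz EEG
timeline with an interpolating cubic spline applied after the smoothing
step — so spline values at the original 50 Hz timestamps reproduce the
smoothed series exactly — and the categorical channel by previous-value
hold. Rows are stacked EEG-then-gaze: 116 + 20 = 136 features. The
32-channel EEG configuration is a named channel subset taken from the
preprocessed high-density montage.

## Model input preparation

Segments are cut into label-preserving sliding windows of L ∈ {3, 5, 10} s
with 50 % overlap; windows inherit the segment's majority-vote label.
Segments shorter than L (common for experienced participants) yield one
window zero-padded at the end. Each window is subdivided into T = 10
temporal steps of L × 51.2 samples (256 for L = 5; for L = 3 the product
153.6 is not an integer, so boundaries sit at round(i·L·512/10), giving
153/154-sample steps padded to 154 for rectangularity). A step is masked
False iff it contains only padding; partially padded steps stay True.

Channel-wise z-scoring uses statistics from the **training** windows' real
samples only — test and validation batches are transformed with training
statistics, and padded samples remain exactly zero (normalize-then-pad).
Class imbalance is handled by seeded random downsampling of majority
classes to the minority count at the window level; synthetic oversampling
is deliberately avoided because it can introduce non-physiological
temporal and spectral structure. Residual imbalance is absorbed by
"balanced" class weights in the loss, w_c = n/(3·n_c).

## Classifier

Per window of shape (T = 10, S, F): a 1-D convolution applied to each
temporal step independently (ReLU, L2 on the kernel) → per-step max
pooling and flattening → a single LSTM over the 10 step vectors (L2 on
both kernels) → additive attention over the step outputs,
score_t = v·tanh(W h_t + b), with fully padded steps excluded from the
softmax (score −∞, weight exactly 0) → dropout → dense ReLU → dropout →
softmax over the 3 classes. Because padding is always a suffix and its
attention weight is exactly zero, logits are invariant to the content of
masked steps — asserted to < 1e-5 in tests.

The network runs on a small in-repo reverse-mode autodiff engine
(`neuroskill.nn`) over NumPy float32 arrays; gradients are verified
against central finite differences. Training minimizes class-weighted
categorical cross-entropy (weights normalized to sum 1, so uniform
weights reduce exactly to the unweighted mean) with Adam, stopping early
when the monitored loss fails to improve for `patience` consecutive
epochs and restoring the best weights. All randomness — initialization,
shuffling, dropout — derives from `ModelConfig.seed`; identical seeds give
bit-identical trained models.

Open choices fixed here: additive attention (mask-compatible, standard);
Adam at 1e-3 default; pool size 2; one LSTM layer; dropout after both the
attention context and the dense layer; attention width defaults to the
LSTM width.

## Evaluation protocol

Participants are the unit of splitting throughout. Each repeat holds out
`n_test` participants; grid search scores configurations by mean weighted
F1 over group-based K-fold cross-validation of the training participants
(GroupKFold semantics — no participant's windows cross a fold boundary);
the winning configuration is retrained on all training participants (early
stopping then monitors training loss, as no held-out participants remain)
and evaluated once on the held-out set; the partition repeats with fresh
randomness. A leakage audit scans every (train, eval) pair in the plan
for participant overlap. Reports include both pooled metrics
(test predictions concatenated across repeats) and per-run mean ± sd.

`make_split_plan` optionally stratifies the partitions by class: at the
reduced cohort sizes used for demonstration (12–15 participants), plain
random partitions routinely leave a class unrepresented in a fold, which
makes 3-class training impossible. At the full 23-participant design the
option is unnecessary and off by default.

Metrics follow the standard confusion-matrix definitions: per-class
precision TP/(TP+FP) (0 if no predicted positives, with a warning),
recall TP/(TP+FN), F1 as their harmonic mean, weighted F1 as the
support-weighted average, accuracy as trace/total. Modality comparisons
use two-tailed paired t-tests across matched runs with Holm–Bonferroni
correction over the comparison family (all modality pairs); an optional
Wilcoxon signed-rank companion is provided as a distribution-free
extension. All-zero paired differences give t = 0, p = 1.

## Synthetic cohorts

The generator emulates the study conditions: 23 participants by default
with class proportions skewed toward inexperienced (11/23, 7/23, 5/23,
matching a pool of 9 pre-medical students and 2 scientists, 3 residents
and 4 fellows, 5 surgeons), two anastomosis trials per participant, each
containing both subtask segments with event markers, EEG at 512 Hz
(124 raw channels on a schematic montage, including the 8 to be excluded)
and gaze at 50 Hz on a shared millisecond clock.

Class structure is placed in both modalities, independently switchable
(`eeg_effect`, `gaze_effect`):

* **EEG:** 1/f background (5 µV RMS) plus band-limited oscillations whose
  amplitude scales as 1 + 0.35·effect_size·(class − 2), floored at 0.1:
  frontal theta (4–8 Hz, base 4 µV) rises with expertise and occipital
  alpha (8–13 Hz, base 6 µV) falls — the direction associated with
  efficient cognitive control and visuospatial processing. A common-phase
  60 Hz sinusoid (5 µV default) models line noise; sporadic frontal
  blink transients exercise the artifact stage.
* **Gaze:** an alternating fixation/saccade regime; mean fixation duration
  0.25 s × (1 + 0.4·effect_size·(class − 2)) (longer fixations, fewer
  saccades with expertise). Fixations hold a target with 3 px jitter;
  saccades ramp to a new target. All 20 export signals are derived from
  this geometry; dropout marks samples missing with type 3.
* **Ratings:** each rater's domain score is the class-mapped ideal
  (1.5 / 3.0 / 4.5) plus Gaussian noise (sd 0.5 default), rounded and
  clipped to [1, 5].

`effect_size = 0` makes the signal distributions class-exchangeable.
Segment durations are free parameters (no published distribution):
defaults 20–45 s (class 1), 10–25 s (class 2), 4–14 s (class 3), so
experienced segments can be shorter than the 5 s window and force the
zero-padding path. Everything is driven by one `numpy.random.Generator`
seed; identical configurations produce bit-identical cohorts.

What the generator does **not** emulate: biophysical forward-modeled EEG,
per-subject idiosyncratic spectra, realistic saccade kinematics, drift in
synchronization, or rater bias structure. Passing tests therefore
demonstrate that the pipeline recovers the *kind* of structure the
analysis assumes — band-power and gaze-dynamics differences that are
stable across subjects — not that it would reach any particular accuracy
on real operating-room recordings.

## Demonstration profiles and problem sizes

`neuroskill.presets` fixes two reduced profiles used by the tests and the
reproduction script:

* **smoke** — effect size 8 ("strong"), 15 participants (5 per class,
  explicitly assigned), 6 trials each, segment durations 12–20 / 9–16 /
  4–14 s, subtask 1, combined modality, windows L = 5 s, balanced; 2
  repeated 10/5 stratified splits with 2 inner folds; a small
  single-configuration model (8 conv filters, kernel 5, pool 8, LSTM 16,
  dense 16, dropout 0.2, L2 1e-3, ≤200 epochs, batch 16, Adam 2e-3,
  patience 40). Held-out pooled accuracy is expected well above the 0.80
  acceptance bar.
* **null** — the same pipeline at effect size 0 with class-independent
  durations (6–12 s for every class), 9 participants, shorter training;
  held-out accuracy should sit inside the binomial confidence band of
  1/3.

These sizes are the package's choice of a tractable demonstration scale;
the full study design (23 participants, 10 repeats, 4 folds, the complete
hyperparameter grid) is expressed with the same functions.

## Numerical notes and limitations

* float32 throughout the network; finite-difference gradient agreement is
  asserted at 5e-4 absolute, consistent with float32 forward noise.
* Normalizer standard deviations are floored at 1e-8 (warning) so
  constant channels cannot produce NaNs.
* The L = 3 s window cannot satisfy an integer samples-per-step count at
  512 Hz / T = 10; the rounding rule above absorbs the remainder in the
  step partition and pads steps to equal length.
* Grid-search ties (including duplicated configurations) break
  deterministically toward the lexicographically smallest configuration.
* The t-tests operate on as few as 10 paired runs; normality is not
  verified. The Wilcoxon companion is the conservative alternative.
* Training the NumPy network is CPU-bound; the presets keep end-to-end
  runs in the minutes range. Scaling to the full grid would be slow, and
  a GPU framework would be the natural substitution for production use.
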