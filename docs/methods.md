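# Methods

## Synthetic cohort model

The generator produces per-subject, per-repetition recordings of the
four-task sequence (10 s per task at 50 Hz) on a fixed 34-channel
inventory: 18 inertial axis channels (hand and forearm units ×
accelerometer/gyroscope/magnetometer × x/y/z), 6 per-modality resultant
channels, 2 EMG-envelope channels, and 8 auxiliary derived channels
(jerk of the resultants, hand–forearm resultant differences, EMG sum
and absolute difference).  The channel count is fixed at 34 so that the
12-feature extractor yields the design dimensionalities 408/816/1224;
the axis-vs-resultant composition is a package choice.

Each task window is a rhythmic template (T1 ≈ 3 Hz, T2 ≈ 1 Hz,
T3 ≈ 2 Hz, plus a second harmonic) whose frequency is divided by the
subject's **bradykinesia factor** (≥ 1; 1 for healthy subjects).
Three further subject-level mechanisms carry the group structure:

- **Rest tremor**: a sinusoid near 6 Hz (group means 0 / 0.90 / 0.35
  for S_H / S_PD / S_DBS), at full amplitude at rest and attenuated
  (×0.7) during voluntary movement, with slow amplitude modulation and
  small frequency jitter.
- **Movement irregularity**: slow (≈1 s correlation time) frequency and
  amplitude modulation of the task rhythm, scaled by a per-subject
  irregularity coefficient (group means 0.05 / 0.40 / 0.18).  This is
  the amplitude-invariant "shape" signal that approximate entropy and
  the normalized difference features pick up; it encodes the clinical
  observation that parkinsonian motor output is more irregular, and
  that DBS restores part of the regularity.
- **Nuisance gains**: per-subject multiplicative channel gains
  (lognormal, σ = 0.45 inertial, 0.35 EMG) that are independent of
  group — sensor placement, limb anthropometry, electrode impedance.
  They dominate the leading linear components of the feature matrix, so
  a 2-D PCA projection mixes groups while locality-based embeddings do
  not; this reproduces the qualitative PCA < Sammon < t-SNE ordering of
  the study without building it into any classifier.

EMG envelopes are baseline + rectified burst trains locked to the
rhythm plus rectified tremor ripple, non-negative by construction.
White sensor noise (sd 0.05) is added to every channel.

**Repetition variability and CV calibration.** A per-repetition
amplitude scale ~ N(1, σ_subj) multiplies movement and tremor.  The
reported summary is the per-subject coefficient of variation of the
RMS of the hand-accelerometer resultant across the five repetitions.
Because the sample CV of five draws is biased (c4 shrinkage) and
further damped by the additive noise floor, σ_subj is set to the group
CV target divided by an estimator gain measured by simulation over 200
subjects per group (0.893 / 0.906 / 0.902).  Subject-level spread of
σ_subj is lognormal with σ = 0.15 — deliberately smaller than the
spread a 10-subject group would need to reproduce the published
between-subject sds — so that the group *mean* CV is a stable estimand
at the design's group sizes.  With the documented calibration seed (4),
the generated cohort's group CV means are 0.212 / 0.228 / 0.312 against
targets 0.21 / 0.24 / 0.30.

All randomness derives from per-(seed, subject, repetition) substreams,
so adding a subject leaves the others' recordings unchanged.

What the generator does **not** emulate: biomechanical waveform realism,
raw (pre-envelope) EMG, sensor-fusion/orientation effects, gravity
offsets in the accelerometers, task-to-task carryover or fatigue, and
clinical heterogeneity beyond the three latent mechanisms above.
Passing tests therefore show that the pipeline recovers group structure
of this statistical kind at the study's sample sizes — not that it
would reach the same accuracies on clinical recordings.

## Features

- **FS** (filtered signal): 4th-order zero-phase Butterworth low-pass
  at 15 Hz for inertial/auxiliary channels; EMG envelopes pass through
  (they are already low-pass envelopes).  Cutoff and order are
  configurable.
- **IA/IF**: magnitude and phase-derivative (central differences,
  scaled to Hz) of the analytic signal.  0.5 s is trimmed from each end
  of every task window after preprocessing to suppress Hilbert end
  effects; the trim applies to all representations so feature windows
  stay aligned.
- **ApEn**: Pincus ApEn(m, r) with self-matches counted; defaults
  m = 2, r = 0.2 × sample sd of the window (r floored for
  zero-variance windows, returning 0).
- MAVSDN/MAVFDN are computed on the per-window z-scored signal; STD and
  VAR use the n−1 convention.

## Standardization and split

z-scoring uses the sample sd; zero-variance columns become 0 with a
warning.  By default the full feature matrix is standardized *before*
the 90/10 per-group split, replicating the original protocol's ordering
(a mild leakage the protocol accepts); `split_first=True` provides the
leak-free alternative, with the standardizer fit on training rows only.
Per-group training counts use round-half-to-even; at the design's group
sizes (50/80/60 samples) the products are integral and the train set is
exactly 171.

## Embeddings

- **PCA** by SVD of the centered matrix; deterministic sign convention
  (largest-magnitude loading element positive).
- **Perplexity calibration**: per-point bisection on the Gaussian
  precision until 2^H matches the target within 1e−4 (entropy in bits),
  at most 200 iterations; unattainable targets use the closest
  attainable distribution and flag the point.
- **t-SNE**: gradient descent on Σ KL(Pᵢ‖Qᵢ) with the Student-t
  (1 d.o.f.) low-dimensional kernel, early exaggeration ×4 for 100
  iterations, momentum 0.5→0.8 at iteration 250, per-parameter adaptive
  gains, PCA initialization rescaled to sd 1e−4 (random init
  available).  During the final 100 iterations the optimizer switches
  to a backtracking phase — steps that would raise the cost are
  rejected, halving a local step scale and resetting momentum — so the
  accepted cost trace is non-increasing at the end of every run.
  The grid's η values (0.2–0.6) are relative steps; the raw t-SNE
  learning rate is η × 500 (configurable), since a from-scratch t-SNE
  starting from an sd-1e−4 init needs step sizes of order 10²–10³.
- **Sammon**: diagonal-Newton updates with the step ("magic") factor η
  and step-halving on stress increase (accepted stress is monotone);
  plain gradient descent available.  Initialization from the 2-D PCA
  scores; duplicate rows are jittered by 1e−10 before distances are
  taken.

## Out-of-sample extension

Test samples are mapped by a linear projection keeping the smallest
number of components with cumulative explained variance ≥ 0.90 (fit on
training data only), followed by a regression network: one hidden layer
(default 20 tanh units) plus a **linear bypass** from the projected
features to the 2-D output.  Training is Levenberg–Marquardt on
β·E_D + α·E_W with MacKay's evidence re-estimation of (α, β) after each
accepted step (γ = N_w − α·tr(H⁻¹), α = γ/2E_W, β = (N−γ)/2E_D),
stopping on objective convergence (1e−6) or the iteration cap.  The
bypass is initialized at the ridge solution and the tanh output weights
at zero, so hidden units only grow where the residual demands
nonlinearity — this is what makes the mapper extrapolate sanely on
(near-)linear structure instead of memorizing it.  With zero hidden
units and fixed (α, β) the fit is exactly ridge regression, which the
tests verify against the closed form.  PCA embeddings use their native
extension (projection of the test rows with the training loadings); the
regression network serves the methods without one (Sammon, t-SNE).

## Classification and scoring

Three binary Gaussian-kernel SVMs (one per class vs rest, C = 1)
predict by largest decision value, ties broken by class order.  The
kernel scale 0.35 is interpreted on **standardized map coordinates**
(the classifier z-scores the 2-D points internally, fit on its training
points): raw embedding coordinates differ across methods by orders of
magnitude, and a fixed 0.35 only defines a meaningful neighborhood on a
normalized scale.  LOOCV refits the classifier n times.  OSR is the
diagonal fraction of the confusion matrix in percent;
QR = (OSR_LOOCV + OSR_TS)/2.  The per-class success rate over a grid
slice is the *mean* of true-positive rates over the v×τ cells (the
0–1 boxplot scale implies a mean, not a sum).  ROC curves are
one-vs-all on decision values with percentile-bootstrap 95% bands
(default 1000 replicas, resampling samples).  Grand-average confusion
matrices average column-normalized confusions over configurations.

## Grid

Default value lists: 7 preprocessing combinations × 4 tasks;
Sammon iterations {423, 575, 742, 1080, 5000}, t-SNE iterations
{1000, 2000, 3000, 4000, 5000}, η {0.2, 0.3, 0.4, 0.5, 0.6},
perplexity {5, 10, 16, 21, 27} — cardinalities 28 / 700 / 3500.
Per-configuration seeds derive from (master seed, config-key CRC), so
results are independent of execution order; failed configurations are
recorded, never fatal.  Best scenarios are argmax QR per (task,
method), ties broken by fewer iterations then lexicographic config
order.

## Problem sizes used by the test suite and scripts

The analysis scripts and the end-to-end tests run the full default
cohort (190 recordings) but one feature matrix (FS-IF on T1 — the
combination the grid itself ranks best) and a reduced grid of 9
configurations (1 PCA, 4 Sammon, 4 t-SNE); the full 4228-configuration
grid is available behind `03_run_grid.py --full`.

## Known limitations

- The supplementary-data import path (`FeatureMatrix.from_xlsx`) is
  exercised against a synthetic stand-in spreadsheet; replicating the
  published accuracies requires the actual deposited file.
- Evidence-based regularization under-penalizes networks with more
  parameters than observations; the linear bypass mitigates this for
  near-linear maps, but strongly fragmented embeddings still limit
  out-of-sample fidelity (visible as the LOOCV-vs-test OSR gap, which
  the original study also reports).
- The KS test's asymptotic p-values are approximate at the small
  per-method configuration counts a reduced grid produces.
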