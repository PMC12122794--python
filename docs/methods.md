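# Methods

This note documents the models and procedures implemented in `impact`, the
assumptions behind them, and the numerical choices a user should know about.

## Problem setting

The package classifies subjects (patient vs. control) from preprocessed
resting-state fMRI, on the hypothesis that disease-relevant information lives
in *transient* coordination between brain regions rather than in stationary
averages. Three per-subject feature streams feed a single classifier:

1. **ROI stream** `X_ROI ∈ R^{T×R}` — mean BOLD signal per atlas region
   (Harvard-Oxford-style label image, R = 48 by default), z-scored per region.
2. **ICA stream** `X_ICA ∈ R^{T×C}` — C = 5 independent-component time
   series per subject, unit variance, deterministic seed and sign.
3. **dFC stream** `X_Conn ∈ R^{N_w×R(R−1)/2}` — sliding-window Pearson
   correlation (W = 50 time points, stride 25, full windows only), Fisher
   z-transformed, strict upper triangle flattened row-major (i < j).

## Feature-extraction conventions

* **Volume handling.** The first 5 frames are discarded (scanner
  stabilization). Parcellation is the exact arithmetic voxel mean per
  labelled region; regions with no voxels are an error, not a NaN.
* **Temporal filtering.** The optional high-pass is a zero-phase
  second-order Butterworth at 1/cutoff Hz (default cutoff 100 s), followed by
  de-meaning; filtering precedes z-scoring.
* **Motion QC.** Framewise displacement uses the Power convention:
  FD_t = Σ|Δtranslation| + 50 mm·Σ|Δrotation|, rotations in radians on a
  50 mm sphere; subjects with mean FD above 0.5 mm are flagged for exclusion.
* **Z-scoring** divides by the population standard deviation (n); Pearson
  correlation uses the sample deviation (n−1). The two conventions are fixed
  so tests can be exact; they cancel inside the correlation itself.
  Constant columns z-score to zeros and correlate to 0 off-diagonal.
* **Fisher z** is `atanh` after clamping |r| ≤ 1 − 1e−7, so self- or
  duplicate-column correlations stay finite and dFC vectors are always
  finite.
* **ICA** is a per-subject temporal FastICA of the ROI matrix (scikit-learn),
  seeded, components rescaled to unit variance with the sign fixed so each
  mixing column's largest-magnitude loading is positive. A group-level
  spatial ICA with per-subject projection would be the natural alternative;
  the per-subject decomposition was chosen because it is well-defined for a
  single subject, leaks nothing across subjects, and preserves the T×C
  contract.

## The classifier

Each stream passes through its own temporal transformer encoder (no
parameter sharing): a linear embedding to hidden width h with fixed
sinusoidal positional encodings, then `n_layers` blocks of

    h1 = LayerNorm(X + MultiHead(X))
    h2 = LayerNorm(h1 + FFN(h1)),   FFN(x) = GELU(x W1 + b1) W2 + b2

Multi-head attention is the standard scaled-dot form
`softmax(QKᵀ/√d_k + B) V` with learned per-head relative-position biases B
over offsets clipped to ±32, shared across a given encoder's layers. Both
positional mechanisms (absolute sinusoidal and learned relative) are
implemented and independently switchable; the defaults enable both.

**Fusion** happens in two stages. Stage 1: cross-modal attention with ROI
states as queries and ICA states as keys/values. Stage 2: each stream is
temporal-mean-pooled; scalar gate logits `w_m·h_m + b_m` are softmaxed into
a probability triple (α_ROI, α_ICA, α_Conn), and the fused vector is the
convex combination of the pooled vectors, with the ROI slot carrying the
pooled *cross-attention* states. Feeding the cross states through the ROI
slot is a deliberate design choice: gating over the three raw pooled
streams would leave the cross-attention stage disconnected from the output.
When a modality subset is configured (ablations), the gate softmax runs
over the remaining streams, and cross attention only engages when both ROI
and ICA are present.

**Classifier head:** two residual blocks
`LayerNorm(x + Linear_{w→h}(GELU(Linear_{h→w}(x))))` and a final linear map
to 2 logits; probabilities use a max-subtracted softmax.

**Initialization.** All weights are Kaiming normal (std √(2/fan_in));
the attention projections W_Q/W_K/W_V *and* the FFN weights are additionally
scaled by 1/√n_heads; biases start at exactly zero. Every parameter tensor
is created from a single seeded generator, so a config seed fixes the model
bit-for-bit.

**Defaults.** Hidden width 256, 8 heads, 2 layers, dropout 0.2. The FFN
expansion factor (9) and classifier width (89) are calibrated so that the
default three-stream model (input dims 48/5/1128) totals 9.34M trainable
parameters; the reference architecture fixes the total and the headline
dimensions but not these two, so they are set once here and shipped as
defaults.

A fusion working-set estimate `M = T(d_ROI + d_ICA) + N_w·d_conn + 2T·d_h`
is provided as a helper; it is linear in sequence length.

## Numerical engine

No deep-learning framework is used; the package ships a compact reverse-mode
automatic-differentiation engine over NumPy arrays (`impact.nn`): ~25 tensor
operations with exact vector-Jacobian products, verified against central
finite differences to ~1e−10 through the full model graph. LayerNorm and the
relative-bias gather have fused analytic backwards for speed. The engine
preserves float32 end-to-end; training utilities cast to float32 (unit tests
and oracles run in float64).

## Training and evaluation

* **Loss:** weighted cross-entropy (class weights ∝ 1/n_c, normalized to
  mean 1, as a weighted mean over samples) plus an L1 penalty on the fusion
  gate weights only (coefficient 1e−5). Restricting L1 to the gates is the
  smallest-scope reading of "cross-entropy + L1" consistent with reporting
  gate/attention sparsity.
* **Class weights are computed at cohort level, not per fold.** Under
  leave-one-out CV the training set is always one subject short in the
  held-out subject's class; weights recomputed per fold therefore covary
  with the held-out label, and the upweighted minority class shifts
  predictions systematically toward the held-out class — enough to push
  null-cohort LOOCV AUC far from ½ (we measured 0.86 for the deep model and,
  with the sign flipped by overfitting, 0.05 for a logistic probe). Fixing
  the weight vector to the cohort's class composition removes this bias
  while preserving the inverse-frequency weighting contract.
* **Model-input scaling:** all three streams are z-scored per subject at
  model input; ROI and ICA streams already are by construction, and the
  Fisher-z connectivity vectors (natural scale ≈ 0.15) are standardized so
  the conn embedding is not drowned by the O(1) positional encodings.
* **Optimizer:** AdamW (decoupled weight decay 1e−4), gradient-norm clipping
  at 1.0, one-cycle LR schedule (peak 1e−3, div factor 25, final div factor
  1000, peak at 30% of steps). These are the consolidated defaults; a more
  conservative companion recipe (1e−4 / 5e−4 / 150 epochs / clip 0.1) ships
  as `ALTERNATE_RECIPE`.
* **Early stopping** requires a validation signal that leave-one-out CV does
  not define; each fold therefore carves a stratified inner split (20% of
  training subjects, seeded per fold), stops after 25 epochs without
  inner-loss improvement, and restores the best-loss parameters before
  scoring the held-out subject. For very small cohorts this is optional
  (`TrainConfig.early_stopping=False`): with only ~5 inner-validation
  subjects the stopping signal is mostly noise, and training the full
  one-cycle budget on all training subjects (the schedule anneals the
  learning rate to ~1e−6, which regularizes on its own) gives visibly more
  stable fold predictions. Per-fold seed ensembling
  (`TrainConfig.n_ensemble`) further averages out initialization noise.
* **Augmentation for small cohorts.** Mixup (`TrainConfig.mixup_alpha`,
  Beta(α, α) convex combinations of stream batches and their labels) is the
  single most effective regularizer we measured at n ≈ 20 subjects, moving
  held-out AUC on coupled synthetic cohorts by ≈ +0.1; Gaussian input noise
  (`input_noise`) is a weaker alternative. Both are off by default and
  enabled in the verification protocol.
* **LOOCV** keeps all of a subject's streams on one side of every fold.
  Because z-scoring, ICA and dFC are computed strictly per subject, no
  statistic is pooled across the train/test boundary.
* **Metrics:** AUC by the Mann-Whitney rank formulation (ties credited ½),
  accuracy at threshold 0.5, F1, balanced accuracy, MCC; 95% CIs by
  subject-level percentile bootstrap (10,000 resamples by default;
  single-class resamples are redrawn).
* **Model comparison:** each model's per-subject predictions are
  bootstrapped into an AUC distribution; the reference is compared to each
  baseline by Mann-Whitney U (exact enumeration when n_a·n_b ≤ 400 and no
  ties, otherwise normal approximation with tie correction) and Cliff's
  delta (sorted counting, equal to the all-pairs count), with
  Benjamini-Hochberg adjustment across comparisons. Comparing bootstrap
  AUC distributions is a deliberate choice: it reuses the same
  10,000-resample machinery as the confidence intervals and works for any
  pair of models scored on the same subjects.
* **Baselines:** seven small architectures (CNN2D, CNN1D, bidirectional
  LSTM/GRU, TCN, MLP, autoencoder) consuming the same preprocessed streams
  (ROI by default, optional ROI+ICA concatenation) under the same harness.
  Their depths/widths are conventional and deliberately below the main
  model's capacity. The autoencoder trains a reconstruction pretext first,
  then classifies from its mean-pooled bottleneck.

## Interpretability

* **GradCAM for temporal transformers.** Gradients are taken of the
  class-contrast score z_target − z_other (the class-discriminative
  direction of a two-logit head). Two activation maps are combined, weighted
  by the model's own fusion gates and max-normalized per subject:
  1. *ROI component* — classic GradCAM at the last ROI-encoder layer
     (states T×h): channel weights are the temporal mean of the gradient,
     and the map ReLU(Σ_c w_c A[t,c] ρ[r,c]) is routed to regions through ρ,
     each channel's column of |W_e| normalized over regions.
  2. *Connectivity component* — transient coupling changes the correlation
     structure of the signals, not their amplitude, so it is invisible to
     an amplitude map on the ROI encoder (we measured chance-level event
     localization through that layer alone). The gradient of the score with
     respect to the dFC input identifies *which region pairs* drive the
     decision (positive parts, normalized and raised to the 4th power —
     small-sample gradients are diffuse and need sharpening); the rectified,
     lightly smoothed edge time series x_i(t)·x_j(t) of those pairs says
     *when* they co-fluctuate. Their product is the time-resolved map for
     the connectivity stream, assigned to both member regions of each pair.
  A vanished gradient yields an all-zero map with a warning flag, never
  NaN. Group-level tables average the *normalized* per-subject maps so
  single high-gradient subjects cannot dominate.
* **Attention statistics:** mean and std over all attention entries
  (layers × heads × subjects) plus a sparsity factor defined here as the
  fraction of entries below a tenth of the uniform weight 1/T. Sparsity
  factors reported elsewhere rarely state their formula, so this definition
  is made explicit and should not be compared across tools.
* **Edge importance:** mean |∂logit/∂dFC entry| per region pair, averaged
  over windows and subjects, with a patient-minus-control difference column.
* **Lobe summaries** use a packaged region→lobe table for the 48
  Harvard-Oxford cortical regions (frontal / parietal / temporal /
  occipital / insular-limbic); scores are member means normalized to sum 1.

## Synthetic cohorts

The generator emulates the shape of small two-class resting-state cohorts:
balanced classes of 12 subjects by default, T = 132 time points, R = 48
regions, TR 2 s. Each region is an AR(1) process (lag-1 coefficient 0.4,
unit marginal variance) — the cheapest process with BOLD-like smoothness.
Patients carry brief coupling events: within each configured window (two
30-point windows by default, onsets jittered ±10 time points per subject), a
single white latent is mixed into a fixed "striatum-like" region subset
(indices 5–8) with weight δ and renormalized to unit variance, making the
expected within-window pairwise correlation exactly δ²/(1+δ²). δ = 0 makes
the classes exchangeable in distribution. Per-subject RNG streams derive
from (seed, subject index), so cohorts are bit-reproducible and
order-independent.

What the generator does *not* model: hemodynamic response, physiological
noise, head motion, scanner/site effects, spatial structure within regions.
Passing recovery tests on these cohorts therefore demonstrates that the
pipeline can detect transient coupling of known strength and location under
idealized noise — not clinical validity on real data.

The event timing statistics (duration, amplitude) of real transient
dysconnectivity are not characterized in the source material; the defaults
here are fixture choices made once for testability, not claims about
disease.

## Verification problem sizes

End-to-end recovery checks run at reduced scale so the full suite completes
on a laptop-class CPU: cohorts of 12 subjects per class, R = 20 regions,
T = 132, a hidden-32 single-layer model, and a fixed one-cycle budget
(50 epochs, peak learning rate 1e−2 — small models need a larger peak than
the full-size default — no early stopping, mixup α = 0.4; shape constants
unchanged). The protocol lives in `impact.verification`. The architecture defaults (hidden
256 etc.) are exercised by construction, counting and forward-pass tests
rather than by training.

## Known limitations

* Per-subject temporal ICA components are not aligned across subjects; the
  encoder must treat them as an unordered basis, which limits how much the
  ICA stream can contribute on its own.
* The relative-bias bucket scheme (clip at ±32) saturates for sequences much
  longer than ~64 time points apart; distant-offset pairs share one bias.
* Bootstrap CIs are percentile (not BCa); with n ≈ 20 subjects they are
  conservative near AUC 1.
* The Mann-Whitney comparison of bootstrap AUC distributions inherits the
  resample count in its effective sample size; p-values should be read as
  descriptive, which is why effect sizes (Cliff's delta) are reported
  alongside.
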