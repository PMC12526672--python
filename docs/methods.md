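# Methods

`asft` implements an EEG-based binary fatigue-recognition pipeline: band
decomposition and windowing of multichannel EEG, time/frequency feature
extraction, statistical feature screening, SVM/AUC channel ranking, an
FT-Transformer tabular classifier, and two cross-validation protocols, plus
a seeded synthetic-study generator that stands in for (undeposited) pilot
recordings. This note records the model, the defaults, the numerical
choices, and what the synthetic experiments do and do not demonstrate.

## Signal model and preprocessing

Input is a multichannel scalp EEG trace (16 channels in the 10–20 layout
FP1…O2 by default, 500 Hz, microvolts). Per channel:

1. **Bandpass 0.5–30 Hz.** Zero-phase 4th-order Butterworth applied
   forward-backward (`sosfiltfilt`), so time-domain features see no group
   delay. The effective attenuation is the squared magnitude response.
2. **FFT band decomposition.** One forward real FFT of the *whole* trace;
   for each band — δ [0.5, 4), θ [4, 8), α [8, 13), β [13, 30] Hz — all bins
   outside the band are zeroed and the spectrum inverted. Intervals are
   half-open with the shared edge assigned to the higher band, and β closed
   at 30 Hz, so the four masks tile the passband exactly: the band series
   sum to the full-band-masked signal at machine precision (this is a unit
   test). Versus the Butterworth output itself the residual is the filter
   skirt outside 0.5–30 Hz, measured at 3–10 % of signal energy on white
   noise.
3. **Windowing.** Each band series is cut into windows of
   `round(win_seconds·fs)` samples (2 s → 1000) advanced by
   `round(n_win·(1−overlap))` (50 % → 500); a trailing remainder shorter
   than one window is dropped. A 10-minute trace (300,000 samples) yields
   `(300000−1000)/500 + 1 = 599` windows per channel-band, hence
   16 × 4 × 599 = 38,336 windows per recording and 599 rows per recording
   in the feature table.

## Features

Each window contributes eight features per (band, channel):

* time domain — mean `MEA = (1/N)Σxᵢ`, energy `ENE = Σxᵢ²`, population
  variance `VAR = (1/N)Σ(xᵢ−MEA)²`, root mean square
  `RMS = √(ENE/N)`;
* frequency domain, from the window's own rectangular-window DFT restricted
  to the band's bins with power weights `w_k = |S(k)|²` — band power
  density `PSD = (1/|band bins|) Σ w_k`, centroid frequency
  `CF = Σ f_k w_k / Σ w_k`, frequency variance
  `FV = Σ (f_k−CF)² w_k / Σ w_k`, and mean square frequency
  `MSF = Σ f_k² w_k / Σ w_k`.

These definitions satisfy `MSF = FV + CF²` identically, `VAR = RMS² − MEA²`,
and clean scaling laws (MEA/RMS linear, ENE/VAR/PSD quadratic, CF/FV/MSF
scale-invariant); all are property-tested. PSD divides by the *bin count* of
the band, making it comparable across bands of different widths. Windows
with zero band power return NaN spectral moments (logged) and PSD 0. A
full-layout table has 4 × 8 × 16 = 512 columns, ordered bands-outer,
features-inner, channels-innermost; every column is keyed
`band__feature__channel`.

## Feature screening (ANOVA)

Per column, a one-way ANOVA between the alert and fatigue groups (for two
groups, F ≡ t² of the pooled two-sample t, which is asserted in tests). A
(feature, band, channel) combination is significant at p < 0.01; a feature
is retained when significant in at least `min_combos` of the 64 band ×
channel combinations. The full-scale default is 40/64. Zero-variance columns
get p = 1 with a warning rather than an error.

`min_combos` is a power-dependent rule: with a few hundred samples the
off-pivotal channels (which carry 15 % of the effect) are underpowered, so
the desk-scale experiment presets use 16/64 (default 8-channel effect) and
6/64 (4-channel planted-recovery studies). Both thresholds sit in the wide
gap between the amplitude-sensitive features' counts (≈24–48) and the
amplitude-invariant features' counts (≈0–5), so retention is insensitive to
the exact value.

## Channel selection (SVM + rank AUC)

For each (channel, band), a soft-margin linear SVM (C = 1, features z-scored
per training split) is trained on that channel's retained features under
stratified k-fold CV (10 folds at full scale, 5 in the desk presets).
Validation decision values `f(x) = w·x + b` are scored with the rank-based
AUC: ranks ascending with midranks for ties,

    AUC = (Σ_{i∈positive} rank_i − T(T+1)/2) / (T·F),

with the alert state as positive class (T positives, F negatives). This
equals the exhaustive pairwise `P(s⁺>s⁻) + ½P(tie)` — property-tested
against brute force and against an independent library implementation — and
is invariant under monotone transforms of the scores. Channels are ranked by
the unweighted mean of their four band AUCs and the top k (default 8) are
retained; ties break lexically and are logged. A cross-band variant (one SVM
on all four bands' features of a channel) is available via `band=None`.
Applying 6 retained features × 8 channels to a 512-column table leaves
4 × 6 × 8 = 192 columns.

## Classifier (FT-Transformer)

Numerical feature `x_j` becomes a token `T_j = b_j + x_j·W_j ∈ R^d`; a
learned [CLS] token is prepended; L PreNorm transformer encoder layers
(multi-head self-attention, then a ReGLU feed-forward block, each sublayer
with a residual connection and a leading LayerNorm — omitted for the
attention sublayer of layer 1) process the (k+1) × d token matrix; the head
is `Linear(ReLU(LayerNorm(·)))` on the final [CLS] row, giving two logits
(class 0 alert, class 1 fatigue). Defaults: d = 64, L = 3, 8 heads,
feed-forward hidden width 128, dropout 0.2 everywhere a dropout appears
(attention probabilities, feed-forward, residuals), ReGLU activation with a
ReLU switch. Training: AdamW (no weight decay, no schedule or warmup),
lr 1e-3, batch 64, 100 epochs, cross-entropy; inputs are z-scored with
training-split statistics stored on the model; per-epoch mean loss is
logged and a non-finite loss aborts with a diagnostic.

The network and its training loop are implemented on a small reverse-mode
autodiff core over NumPy arrays (`asft.autodiff`), written for this package
and verified end-to-end by finite-difference gradient checks. Compute dtype
is float32 by default (float64 available via config); training is exactly
reproducible for a fixed seed on one machine, and evaluation mode is
bit-deterministic. Known limitation: single-device CPU execution; large
token counts (512 features → 513 tokens) train at minutes-per-fold scale,
which shapes the experiment sizes below.

## Evaluation protocols

Metrics from the confusion counts with fatigue as positive class: accuracy,
precision, recall, F1; zero denominators yield 0 with a warning. Two
protocols:

* **cross-clip** — stratified 4-fold CV over individual 2 s windows; a
  subject's windows can appear on both sides of a split.
* **cross-subject** — subjects are partitioned into 4 near-equal
  subject-disjoint folds; the partition is repeated (default 5×) with fresh
  randomisation, giving 20 fold evaluations aggregated as mean ± std over
  fold-level metrics. Disjointness and coverage are asserted on every run.

Selection is refit inside each training fold by default, so screening and
channel ranking never see validation data. A `paper_mode` flag instead fits
selection once on the full table before splitting — the global-selection
protocol common in the EEG literature — for comparability; the default is
the leakage-free variant. The ablation runner evaluates three conditions:
FT (no selection), AFT (screening only), ASFT (screening + channel
selection).

## Synthetic studies

Each channel is a sum over bands of unit-RMS FFT-masked Gaussian noise
scaled by `band_base_amp × subject_effect × state_factor`, plus broadband
noise (2 µV RMS). Defaults: base amplitudes δ 20, θ 10, α 12, β 6 µV RMS;
fatigue multiplies θ by 1.4 and α, β by 0.7 (δ unchanged) on the pivotal
channels O1/O2 (weight 1.0), C3/C4/T3/T4 (0.85), FP1/FP2 (0.7), and at 15 %
of the effect elsewhere; subject amplitude effects are lognormal (σ = 0.2)
per band, shared between a subject's two sessions. Everything is a pure
function of (seed, subject index, state). The shared subject effects are
what make cross-subject evaluation genuinely harder than cross-clip: clip
folds can exploit subject-specific amplitude levels, subject folds cannot.

What the generator does *not* emulate: 1/f spectral shape, waveform
morphology, artifacts (blinks, line noise), non-stationarity, or any
spectral-*shape* change under fatigue. Consequently only amplitude-coupled
features (ENE, VAR, RMS, PSD) respond to the planted effect — screening on
synthetic data retains those four, not the six a spectral-shift-bearing
dataset would support — and passing tests demonstrate pipeline correctness
and protocol behaviour, not biological validity or real-data accuracy.

## Experiment presets and problem sizes

`asft.studies` defines the presets used by the test suite,
`scripts/acceptance.py` and the examples:

* emulated full study: 32 subjects × 2 × 10 min (counts and width checks);
* protocol comparison: 8 subjects × 2 × 24 s (368 windows), reduced encoder
  (d = 32, 1 layer, 1 head, feed-forward 64, no dropout, 6 epochs, batch
  32) — the smallest configuration that exercises the whole architecture
  while keeping repeated 512-column CV runs at minutes scale on one CPU;
  five seeded studies per comparison;
* planted-channel recovery: 4 subjects × 2 × 30 s, effect on
  {O1, O2, C3, C4}, k = 4, 20 seeded runs;
* classifier sanity: default configuration on separable 2-D Gaussian blobs
  (±3 means, unit SD, n = 2000) and on label-shuffled blobs with a held-out
  split.

## Numerical and degenerate-case choices

* Window/hop lengths are rounded to integer samples; `overlap ∈ [0, 1)`.
* Band-edge bins belong to the higher band; β keeps its 30 Hz bin.
* AUC ties use midranks; channel-ranking ties break lexically (logged).
* z-scoring guards zero-variance columns by substituting unit scale.
* ANOVA on zero-variance columns reports p = 1 (logged).
* `n_layers = 0` is accepted as a degenerate encoder: the head then sees
  only the (input-independent) [CLS] embedding — useful for plumbing tests,
  useless as a classifier, and documented as such.
* Checkpoints are NumPy `.npz` archives holding weights, normalisation
  statistics, config and loss history.
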