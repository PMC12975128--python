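# Methods

## Overview

`stimrecon` reconstructs grayscale movies from the activity of a visual
neuron population by descending the gradient of a response-matching loss
through a frozen, differentiable encoding model. The package implements the
full experimental loop in silico: stimulus synthesis, a reference encoder
with known ground truth, transparency-mask learning, windowed reconstruction
with ensembling and ablation, receptive-field mapping, and evaluation. This
note documents the models, the parameters that matter, the numerical choices,
and what the synthetic setting does and does not establish.

## The reconstruction procedure

The movie `x̂` is initialized to uniform gray (127) and optimized for a fixed
number of epochs. Each epoch:

1. The encoder predicts activity for every sliding window of
   `window_length = 32` frames at stride 8 (a final flush window starting at
   `T − 32` guarantees full coverage; stride must not exceed the window
   length or coverage is impossible). Stride 2 is available for slightly
   denser window averaging.
2. The Poisson negative log-likelihood `Σ ŷ − y·log(ŷ + 1e-8)` is summed over
   all (neuron, frame) entries of each window. Whether window losses are
   summed or averaged over neurons is irrelevant downstream: the gradient is
   renormalized before use, and a test asserts this scale invariance.
3. Per-pixel gradients are averaged across the windows covering each pixel
   (frames covered by fewer windows average over fewer terms), normalized by
   the Frobenius norm of the whole T×H×W gradient tensor, clipped to
   [−1, 1], and multiplied by the binarized (α > 0.5) transparency mask.
4. The update uses Adam with only its first moment (β₁ = 0.9, bias
   correction retained, unit denominator), base learning rate 1000, and a
   linear warm-up from lr/10 to lr over the first 10 epochs. The movie is
   clipped to [0, 255] after every epoch.

**Ensembling.** With several model instances, either each instance optimizes
its own movie and the finals are averaged elementwise (`average_videos`), or
all instances contribute masked, normalized gradients to a single movie each
epoch (`average_gradients`). Individual reconstructions carry
instance-specific high-frequency noise; averaging suppresses it.

**Ablation.** A uniformly random fraction of neurons has its activity set to
0 (rows zeroed, not removed). Note zeroed neurons are not "missing": a zero
target actively pulls their receptive fields toward anti-preferred
stimulation, so quality degrades faster than pure information loss would
predict. This mirrors the ablation protocol the package emulates.

**Post-processing.** Reconstructions are denoised with a 3-D Gaussian filter
(σ = 0.5 over t, h, w; reflective boundaries, which preserve the mean to
<1e-3), optionally rescaled affinely so whole-movie mean and SD match the
ground-truth movie (computed before masking), then multiplied by the
evaluation mask (α ≥ 1).

**Correlation is not monotone in epochs.** Pearson correlation is invariant
to intensity scale, so the very first masked gradient steps — essentially a
matched-filter projection of the target activity onto the receptive fields —
already correlate highly with the stimulus (r ≈ 0.95 at epoch 10 on the
default recovery problem). Later epochs keep lowering the likelihood but
introduce pixel-level structure the population does not constrain, settling
near r ≈ 0.86 at epoch 300. The tests therefore assert what the procedure
guarantees: the loss decreases across checkpoints and recovery stays above
threshold, not monotone correlation growth.

## The reference encoder

A linear–nonlinear population with Poisson observation noise available as an
explicit, optional sampling step (recovery experiments default to noise-free
rates, the idealized no-biological-noise regime):

    rate[n, t] = softplus( A · gain_n(b_t) · (k_n ∗ ⟨RF_n, s_t⟩) + baseline_n )

- `s_t` — the frame standardized as `(pixels − 127)/127`, so a gray screen
  produces zero drive and rate `softplus(baseline)`.
- `RF_n` — truncated-Gaussian spatial receptive field (hard zero beyond 3σ,
  so gradient locality is exact), unit L2 norm, signed by On/Off polarity
  (≈50/50 mixture). Centers tile a configurable region on a jittered grid;
  σ defaults to 1.5 px with ±20% jitter.
- `k_n` — causal K-frame temporal kernel (default K = 6), a gamma-like bump
  `(i+1)·exp(−(i+1)/τ_n)` with τ_n ∈ [1.5, 2.5], normalized to sum 1;
  history before the window is zero-padded.
- `gain_n(b) = softplus(1 + w_n·b)/softplus(1)` — a multiplicative behavior
  gain equal to 1 at neutral (zero) behavior; weights onto the four channels
  are N(0, 0.1).
- `A = 3` (shared drive amplitude) and `baseline_n ~ N(0, 0.1)` put
  gray-screen rates near 0.7 and stimulus-driven rates in roughly 0–10 per
  frame, a plausible activity scale for deconvolved calcium signals.

All derivatives of this chain are closed-form, so input gradients are
computed analytically; a finite-difference oracle verifies them to 1e-4
relative on randomized small instances. The encoder contract
(`predict` + `input_gradient`, nonnegative rates, no gradient into behavior)
is a `Protocol`: any differentiable video encoder can be plugged in.

**Model instances.** `perturb_model` produces imperfect instances of the same
population (RF centers jittered by N(0, 0.4) px, σ rescaled by ±10%,
baselines and behavior weights perturbed). This emulates independently
trained encoder instances, which all approximate the same neurons with
different errors — the precondition for ensembling to help. Using fully
independent populations per seed instead would make ensemble experiments
meaningless, since neuron identities would no longer match the target.

## Synthetic stimuli and behavior

- **Gaussian-process movies**: separable space–time squared-exponential
  covariance; a length constant of 0 degenerates to white noise along that
  axis. Sampling applies per-axis Cholesky factors (jittered by 1e-8·n for
  near-singular long-length-constant kernels) to a white-noise tensor — for
  a separable kernel this is distributionally exact. Samples are
  standardized to mean 127, SD 40 before clipping to [0, 255], so clipping
  touches <2% of pixels (±3.2 SD). The standard battery grid is
  `DEFAULT_GP_GRID = {0, 1, 2, 4, 8, 16, 32}` in both axes, a config
  default. `phase_invert` is intensity inversion about the display midpoint,
  `255 − v`, the unique involution fixing mid-gray.
- **Gratings**: full-field square waves in {0, 255}, drifting in a cardinal
  direction; cycles/degree convert to cycles/pixel through the central
  angular resolution of the flat screen (3.4°/px at the default 56.5 cm /
  64 px / 15 cm geometry), applied uniformly with no per-pixel perspective
  correction. `temporal_freq = 0` is a static grating; `spatial_freq = 0`
  with `temporal_freq > 0` is the full-field flicker case.
- **Sparse noise**: per pixel and polarity, 0.5 s gray (127), 0.5 s with the
  single pixel at 0 or 255, 0.5 s gray; `2·H·W` stimuli (4608 at 36×64).
  The set is a lazy sequence — length and indexing are O(1); movies
  materialize on access.
- **Behavior**: Gaussian-smoothed random walks (default σ = 20 frames, so
  lag-1 autocorrelation > 0.9), standardized to plausible amplitudes;
  running speed is rectified at 0. Only smoothness and reproducibility
  matter downstream; no claim of physiological realism is made.

## Transparency-mask learning

Per epoch, a random 32-frame foreground segment and an independently chosen
background clip are alpha-blended, `V_blend = V·α + BG·(1−α)`, and the loss
`MSE(y, ŷ·(1−ᾱ))` is taken between the population response to the unblended
segment (the synthetic stand-in for recorded activity) and the prediction on
the blend, with `ᾱ` the mean mask weight. The mean runs over all
(neuron, frame) entries. The α gradient includes both the blending path and
the direct `ᾱ` path (as backpropagation through the full expression would).
Per-frame gradients are normalized by their Frobenius norms ("matrix norm"
read as Frobenius, the default unqualified reading), clipped to [−1, 1],
averaged across frames, smoothed with a 2-D Gaussian (σ = 5), and subtracted
with learning rate 10. α is initialized uniform on [0, 0.05] and never
clipped: the evaluation threshold α ≥ 1 requires values above 1, and
transiently negative values are handled by binarization. Thresholds follow
the two masking conventions exactly: strict `α > 0.5` for gradient gating,
inclusive `α ≥ 1` for evaluation, so the evaluation mask is always a subset
of the training mask.

## Evaluation

- Frame correlation: Pearson r over masked pixels per frame, averaged over
  frames; frames with zero variance inside the mask are undefined and are
  excluded from the mean (count logged).
- Video correlation: one Pearson r pooling all masked pixels over all frames.
- Shannon entropy: per-frame 25-bin histogram of masked intensities on
  [0, 255], `−Σ p log₂ p` over occupied bins, averaged over frames. A
  constant frame scores 0 (single bin); an empty mask is an error.
- Motion energy: mean absolute inter-frame difference over masked pixels,
  frames 2..T.
- Retinotopic diameter: per-pixel angular areas from arctangent differences
  of pixel edges on the flat screen at the perpendicular center distance
  (eye position ignored — a visuotopic approximation); the mask's summed
  area A gives `2√(A/π)`. The per-pixel areas telescope exactly to the total
  `4·atan(W/2d)·atan(H/2d)`.
- Quality correlates: Pearson r of per-frame correlation against named
  regressors (contrast = per-frame masked SD, luminance = per-frame masked
  mean, motion energy, behavior channels); constant regressors are flagged
  NaN.

## RF mapping

Responses to the sparse-noise set are summarized as the mean predicted rate
during the stimulus half-second (`R_stim`) and the preceding gray
half-second (`R_pre`), per neuron, pixel and polarity; in-silico mapping
uses a neutral all-zero behavior trace. The response map
`(R_stim − R_pre)/R_pre` is thresholded at 0.1 *before* smoothing (the
literal order of operations), smoothed with a 2-D Gaussian (σ = 2),
normalized per neuron by its maximum; the RF center is the argmax pixel.
Neurons with no suprathreshold pixel get NaN centers. On−Off difference maps
are normalized by their positive maximum (degenerate when none exists); the
population map sums On+Off over neurons before normalizing by the maximum
absolute value, so its peak magnitude is exactly 1. On the reference
population, recovered centers land within ~0.4 px (median) of ground truth,
and the population map overlaps the trained transparency mask (Jaccard
≥ 0.4 on the shared fixture).

## Error maps

`simulate_then_reconstruct` predicts activity from the ground-truth movie
(ensemble-mean across instances) and reconstructs from that prediction with
the same configuration as the measured-activity reconstruction. The
difference `d = x̂ − x̂_ŷ` splits into a positive (over-estimation) and
negative (under-estimation) map with disjoint supports. Rendering overlays
the maps on the grayscale ground truth with simple linear warm/cyan ramps
over the magnitude ranges [25, 75] and [−25, −75]; below-floor magnitudes
show no overlay, above-ceiling ones saturate. Magnitudes inside the range
are retained (linearly mapped), not binarized.

## Problem sizes

The default validation problems use a 24×24 frame with a 400-neuron
population tiling the central 18×18 region, 2-s movies (60 frames at
30 Hz), 300 epochs for full recovery runs and 150 for comparative runs
(fall-off, ensembling, ablation), and 200 epochs / 200 neurons for mask
training. These sizes put every experiment within minutes on one CPU while
leaving all qualitative effects — recovery above 0.8, the high-frequency
fall-off, the ensembling gain under Poisson noise, ablation degradation,
mask specificity — clearly resolvable. At these sizes the λ = 16 and λ = 4
fall-off conditions both sit near the recoverable ceiling (r ≈ 0.9) and
differ only marginally; the sharp drop at λ = 1 is robust across seeds.

## What the synthetic setting shows — and does not

Passing tests demonstrate that the optimization machinery inverts a known
encoder correctly: gradients are exact, recovery approaches the
representational limit of the population, masks localize the true collective
RF, and ensembling/ablation behave as the theory predicts. The reference
population omits much of what makes real recordings hard: nonlinear
cortical dynamics, correlated (non-Poisson) noise, deconvolution artifacts,
eye-position-dependent retinotopy, adaptation, and top-down modulation.
Quantities obtained here (e.g., recovery correlations near 0.9) therefore
characterize the pipeline, not expected performance on measured data, and
headline numbers from large-scale recordings are not reproducible at this
scale. The encoder contract is the designed seam for swapping in a trained
deep encoding model.

## Known limitations

- The reference encoder's behavior gain is multiplicative on the stimulus
  drive; encoders that mix behavior nonlinearly into spatial processing are
  representable only through the pluggable contract.
- Reconstruction allocates the full T×H×W gradient tensor per model; very
  long movies should be processed in chunks.
- The degree↔pixel conversion is uniform (central resolution); wide-field
  stimuli on close screens are perspective-distorted at the edges.
- MP4 export is not provided; visual export goes through multi-page TIFF and
  HDF5.
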