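"""Gradient-based movie reconstruction through frozen encoders.

The input video is treated as the free parameter: starting from uniform gray,
the Poisson negative log-likelihood between predicted and target population
activity is minimized by descending its gradient with respect to every input
pixel. Prediction runs on sliding windows (32 frames, stride 8 by default,
plus a final flush window so every frame is covered); per-pixel gradients are
averaged across the windows covering each pixel, normalized by the Frobenius
norm of the whole gradient tensor, clipped to [-1, 1], gated by the binarized
transparency mask, and applied with first-moment-only Adam (beta1 = 0.9, no
second-order momentum) with a linear learning-rate warm-up. After each epoch
the video is clipped back to [0, 255].

Ensembling over model instances comes in two flavors: averaging the final
reconstructions ("average_videos") or averaging each epoch's masked
normalized gradients ("average_gradients").
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter

from stimrecon.encoder import EncoderModel, ResponseMatrix, _response_values
from stimrecon.stimuli import GRAY, BehaviorTrace, Video

__all__ = [
    "ReconstructionResult",
    "OptimizerState",
    "window_starts",
    "poisson_nll",
    "prepare_gradient",
    "optimizer_step",
    "reconstruct",
    "ensemble_average",
    "ablate",
    "postprocess",
]

_EPS = 1e-8


@dataclass(frozen=True)
class ReconstructionResult:
    """Reconstructed movie plus optimization diagnostics."""

    video: Video
    loss_trace: np.ndarray  # mean window loss per epoch
    window_losses: np.ndarray  # final per-window losses
    config: dict = field(default_factory=dict)
    per_model_videos: tuple[Video, ...] = ()


@dataclass
class OptimizerState:
    """First-moment-only Adam state (beta1, no second-order momentum)."""

    m: np.ndarray
    t: int = 0
    beta1: float = 0.9
    lr: float = 1000.0
    warmup: int = 10


def window_starts(T: int, size: int = 32, stride: int = 8) -> list[int]:
    """Start indices of sliding windows covering all T frames.

    Arithmetic sequence 0, stride, 2*stride, ... while a full window fits,
    plus a final flush window starting at T - size when the last strided
    window would leave trailing frames uncovered.
    """
    if T < size:
        raise ValueError(f"need T >= window size, got T={T}, size={size}")
    if not 1 <= stride <= size:
        raise ValueError(f"stride must be in [1, window size], got {stride}")
    starts = list(range(0, T - size + 1, stride))
    if starts[-1] != T - size:
        starts.append(T - size)
    return starts


def poisson_nll(
    y: "ResponseMatrix | np.ndarray", y_hat: "ResponseMatrix | np.ndarray"
) -> float:
    """Poisson negative log-likelihood: sum of y_hat - y*log(y_hat + 1e-8)."""
    yv, yh = _response_values(y), _response_values(y_hat)
    if yv.shape != yh.shape:
        raise ValueError(f"shapes differ: {yv.shape} vs {yh.shape}")
    if yh.min() < 0:
        raise ValueError("predicted rates must be >= 0")
    return float(np.sum(yh - yv * np.log(yh + _EPS)))


def prepare_gradient(g: np.ndarray, training_mask: np.ndarray | None) -> np.ndarray:
    """Normalize by the Frobenius norm of the whole tensor, clip to [-1, 1],
    then gate by the (broadcastable) binary training mask.

    A zero gradient returns zeros rather than raising.
    """
    g = np.asarray(g, dtype=float)
    norm = np.linalg.norm(g)
    out = np.zeros_like(g) if norm == 0 else np.clip(g / norm, -1.0, 1.0)
    if training_mask is not None:
        mask = np.asarray(training_mask, dtype=float)
        out = out * mask
    return out


def optimizer_step(
    state: OptimizerState, g: np.ndarray, epoch: int
) -> tuple[OptimizerState, np.ndarray]:
    """One first-moment-only Adam step; returns (state, update to subtract).

    m <- beta1*m + (1-beta1)*g, bias-corrected by 1 - beta1^t; the learning
    rate ramps linearly from lr/warmup to lr over the first ``warmup`` epochs
    (``epoch`` is 1-based) and is lr thereafter.
    """
    state.t += 1
    state.m = state.beta1 * state.m + (1.0 - state.beta1) * np.asarray(g, float)
    m_hat = state.m / (1.0 - state.beta1**state.t)
    lr_t = state.lr * min(epoch, state.warmup) / state.warmup if state.warmup else state.lr
    return state, lr_t * m_hat


def _window_mean_gradient(
    model: EncoderModel,
    frames: np.ndarray,
    behavior: BehaviorTrace,
    y: np.ndarray,
    starts: list[int],
    size: int,
    frame_rate: float,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-pixel gradient averaged over the windows covering each frame,
    plus the per-window losses."""
    T = frames.shape[0]
    grad_sum = np.zeros_like(frames)
    coverage = np.zeros(T)
    losses = np.empty(len(starts))
    for i, s in enumerate(starts):
        win = Video.unchecked(frames[s : s + size], frame_rate)
        beh = behavior.segment(s, size)
        y_win = y[:, s : s + size]
        y_hat = model.predict(win, beh)
        losses[i] = poisson_nll(y_win, y_hat)
        grad_sum[s : s + size] += model.input_gradient(win, beh, y_win, "poisson_nll")
        coverage[s : s + size] += 1.0
    return grad_sum / coverage[:, None, None], losses


def reconstruct(
    models: "EncoderModel | list[EncoderModel]",
    y: "ResponseMatrix | np.ndarray",
    behavior: BehaviorTrace,
    training_mask: np.ndarray | None = None,
    epochs: int = 1000,
    lr: float = 1000.0,
    warmup: int = 10,
    stride: int = 8,
    ensemble_mode: str = "average_videos",
    seed: int = 0,
) -> ReconstructionResult:
    """Reconstruct the movie that drove target activity ``y``.

    The video is initialized to uniform gray (127) and optimized for
    ``epochs`` epochs as described in the module docstring. With several
    models, ``ensemble_mode`` selects whether each model optimizes its own
    video (final videos averaged) or all models contribute masked normalized
    gradients to a single video each epoch. The procedure is deterministic;
    ``seed`` is recorded in the config for provenance.
    """
    if isinstance(models, (list, tuple)):
        model_list = list(models)
    else:
        model_list = [models]
    if not model_list:
        raise ValueError("at least one model is required")
    if ensemble_mode not in ("average_videos", "average_gradients"):
        raise ValueError(f"unknown ensemble_mode {ensemble_mode!r}")
    yv = _response_values(y)
    if not np.all(np.isfinite(yv)):
        raise ValueError("target activity contains non-finite entries")
    T = yv.shape[1]
    m0 = model_list[0]
    for m in model_list:
        if m.frame_shape != m0.frame_shape or m.window_length != m0.window_length:
            raise ValueError("all models must share frame shape and window length")
        if m.n_neurons != yv.shape[0]:
            raise ValueError(
                f"target has {yv.shape[0]} neurons but model expects {m.n_neurons}"
            )
    if len(behavior) != T:
        raise ValueError("behavior length must match target frames")
    size = m0.window_length
    starts = window_starts(T, size, stride)
    frame_rate = 30.0
    H, W = m0.frame_shape
    config = {
        "epochs": int(epochs),
        "lr": float(lr),
        "warmup": int(warmup),
        "stride": int(stride),
        "window_length": size,
        "ensemble_mode": ensemble_mode,
        "n_models": len(model_list),
        "seed": int(seed),
        "masked": training_mask is not None,
    }

    def init_frames() -> np.ndarray:
        return np.full((T, H, W), GRAY)

    if ensemble_mode == "average_gradients" and len(model_list) > 1:
        frames = init_frames()
        state = OptimizerState(m=np.zeros_like(frames), lr=lr, warmup=warmup)
        loss_trace = np.empty(int(epochs))
        window_losses = np.empty(len(starts))
        for epoch in range(1, int(epochs) + 1):
            g_mean = np.zeros_like(frames)
            losses = np.zeros(len(starts))
            for m in model_list:
                g, lo = _window_mean_gradient(
                    m, frames, behavior, yv, starts, size, frame_rate
                )
                g_mean += prepare_gradient(g, training_mask)
                losses += lo
            g_mean /= len(model_list)
            losses /= len(model_list)
            state, update = optimizer_step(state, g_mean, epoch)
            frames = np.clip(frames - update, 0.0, 255.0)
            loss_trace[epoch - 1] = losses.mean()
            window_losses = losses
        return ReconstructionResult(
            Video(frames, frame_rate), loss_trace, window_losses, config
        )

    # independent optimization per model, final videos averaged
    per_model_videos: list[Video] = []
    traces = []
    final_losses = []
    for m in model_list:
        frames = init_frames()
        state = OptimizerState(m=np.zeros_like(frames), lr=lr, warmup=warmup)
        trace = np.empty(int(epochs))
        losses = np.zeros(len(starts))
        for epoch in range(1, int(epochs) + 1):
            g, losses = _window_mean_gradient(
                m, frames, behavior, yv, starts, size, frame_rate
            )
            state, update = optimizer_step(state, prepare_gradient(g, training_mask), epoch)
            frames = np.clip(frames - update, 0.0, 255.0)
            trace[epoch - 1] = losses.mean()
        per_model_videos.append(Video(frames, frame_rate))
        traces.append(trace)
        final_losses.append(losses)
    video = ensemble_average(per_model_videos)
    return ReconstructionResult(
        video,
        np.mean(traces, axis=0) if int(epochs) else np.empty(0),
        np.mean(final_losses, axis=0),
        config,
        per_model_videos=tuple(per_model_videos),
    )


def ensemble_average(videos: list[Video]) -> Video:
    """Elementwise mean of equally shaped reconstructions."""
    if not videos:
        raise ValueError("need at least one video")
    shape = videos[0].shape
    for v in videos:
        if v.shape != shape:
            raise ValueError("all videos must share a shape")
    return Video(np.mean([v.frames for v in videos], axis=0), videos[0].frame_rate)


def ablate(
    y: "ResponseMatrix | np.ndarray", fraction: float, seed: int
) -> ResponseMatrix:
    """Zero the rows of floor(fraction*N) uniformly chosen neurons."""
    if not 0.0 <= fraction <= 1.0:
        raise ValueError("fraction must be in [0, 1]")
    yv = _response_values(y).copy()
    n_drop = int(np.floor(fraction * yv.shape[0]))
    rng = np.random.default_rng(seed)
    dropped = rng.choice(yv.shape[0], size=n_drop, replace=False)
    yv[dropped] = 0.0
    return ResponseMatrix(yv)


def postprocess(
    video: Video,
    eval_mask: np.ndarray,
    reference: Video | None = None,
    smooth_sigma: float = 0.5,
) -> Video:
    """Denoise, optionally luminance/contrast match, then mask.

    3-D Gaussian smoothing (sigma over t, h, w; reflective boundary), then --
    if a reference is given -- an affine intensity rescale so whole-video mean
    and SD equal the reference's (computed before masking), then multiplication
    by the evaluation mask. Matched output may leave [0, 255] slightly, so the
    result is range-unchecked.
    """
    eval_mask = np.asarray(eval_mask, dtype=float)
    if eval_mask.shape != video.frame_shape:
        raise ValueError("mask shape must match frame shape")
    frames = gaussian_filter(video.frames, smooth_sigma, mode="reflect")
    if reference is not None:
        ref_sd = reference.frames.std()
        if ref_sd == 0:
            raise ValueError("reference video has zero SD")
        sd = frames.std()
        if sd == 0:
            raise ValueError("cannot contrast-match a constant video")
        frames = (frames - frames.mean()) / sd * ref_sd + reference.frames.mean()
    return Video.unchecked(frames * eval_mask, video.frame_rate)
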