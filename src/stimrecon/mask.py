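"""Transparency-mask learning.

The transparency mask localizes the population's collective receptive field:
a per-pixel weight map alpha learned by alpha-blending a true movie segment
with a random background movie at the encoder's input and descending the
gradient of a suppression-scaled MSE loss,

    V_blend = V * alpha + BG * (1 - alpha)
    Loss    = MSE(y, y_hat * (1 - alpha_bar))

where y is the population response to the unblended segment, y_hat the
response to the blend, and alpha_bar the mean mask weight. Pixels that matter
for predicting the response accumulate alpha; thresholding at 0.5 (strict)
yields the mask that gates reconstruction gradients, and at 1 (inclusive) the
stricter mask used to score reconstructions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter

from stimrecon.encoder import EncoderModel, ResponseMatrix, _response_values
from stimrecon.stimuli import BehaviorTrace, Video

__all__ = [
    "TransparencyMask",
    "blend",
    "mask_loss",
    "train_mask",
    "binarize",
    "training_mask",
    "evaluation_mask",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class TransparencyMask:
    """Learned H x W transparency map alpha with training provenance.

    alpha is unbounded above (the evaluation threshold alpha >= 1 requires
    values reaching 1) and is not clipped below during training; binarization
    handles out-of-range values.
    """

    alpha: np.ndarray
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        a = np.asarray(self.alpha, dtype=float)
        if a.ndim != 2:
            raise ValueError(f"alpha must be H x W, got shape {a.shape}")
        if not np.all(np.isfinite(a)):
            raise ValueError("alpha contains non-finite values")
        object.__setattr__(self, "alpha", a)

    @property
    def alpha_bar(self) -> float:
        return float(self.alpha.mean())


def _alpha_of(mask: "TransparencyMask | np.ndarray") -> np.ndarray:
    return mask.alpha if isinstance(mask, TransparencyMask) else np.asarray(mask, float)


def blend(v: Video, bg: Video, mask: "TransparencyMask | np.ndarray") -> Video:
    """Alpha-blend foreground and background: V*alpha + BG*(1-alpha).

    The same 2-D alpha applies to every frame. Returned unchecked because a
    trained alpha may leave [0, 1], taking blended intensities outside the
    display range.
    """
    alpha = _alpha_of(mask)
    if v.shape != bg.shape:
        raise ValueError(f"video shapes differ: {v.shape} vs {bg.shape}")
    if alpha.shape != v.frame_shape:
        raise ValueError(f"mask shape {alpha.shape} != frame shape {v.frame_shape}")
    return Video.unchecked(v.frames * alpha + bg.frames * (1.0 - alpha), v.frame_rate)


def mask_loss(
    y: "ResponseMatrix | np.ndarray",
    y_hat: "ResponseMatrix | np.ndarray",
    alpha_bar: float,
) -> float:
    """Suppression-scaled MSE: mean over all (neuron, frame) entries of
    (y - y_hat*(1 - alpha_bar))**2."""
    yv, yh = _response_values(y), _response_values(y_hat)
    if yv.shape != yh.shape:
        raise ValueError(f"shapes differ: {yv.shape} vs {yh.shape}")
    return float(np.mean((yv - yh * (1.0 - alpha_bar)) ** 2))


def binarize(
    mask: "TransparencyMask | np.ndarray", threshold: float, inclusive: bool = False
) -> np.ndarray:
    """Threshold alpha into a {0, 1} float map.

    ``inclusive=False`` uses strict alpha > threshold (gradient mask
    convention); ``inclusive=True`` uses alpha >= threshold (evaluation mask
    convention).
    """
    if not np.isfinite(threshold):
        raise ValueError("threshold must be finite")
    alpha = _alpha_of(mask)
    hit = (alpha >= threshold) if inclusive else (alpha > threshold)
    return hit.astype(float)


def training_mask(mask: "TransparencyMask | np.ndarray") -> np.ndarray:
    """Gradient-gating mask: alpha > 0.5 (strict)."""
    return binarize(mask, 0.5, inclusive=False)


def evaluation_mask(mask: "TransparencyMask | np.ndarray") -> np.ndarray:
    """Scoring mask: alpha >= 1 (inclusive); always a subset of the
    training mask."""
    return binarize(mask, 1.0, inclusive=True)


def train_mask(
    model: EncoderModel,
    videos: list[Video],
    behaviors: list[BehaviorTrace],
    epochs: int = 1000,
    lr: float = 10.0,
    seed: int = 0,
    smooth_sigma: float = 5.0,
) -> TransparencyMask:
    """Learn the transparency mask by stochastic gradient descent.

    Per epoch: draw a random window-length segment of a random training video
    as foreground and another random clip as background; blend with the
    current alpha; predict; compute the suppression-scaled MSE against the
    (noise-free) response to the unblended segment; take per-frame pixel
    gradients of the loss wrt alpha, normalize each frame's gradient by its
    Frobenius norm, clip to [-1, 1], average across frames, smooth with a 2-D
    Gaussian (sigma 5) and subtract (scaled by ``lr``) from alpha.

    alpha is initialized as uniform noise on [0, 0.05] and never clipped;
    values must be free to exceed 1 for the evaluation threshold to fire.
    Videos intended for reconstruction must be excluded by the caller.
    """
    if len(videos) == 0:
        raise ValueError("at least one training video is required")
    if len(videos) != len(behaviors):
        raise ValueError("videos and behaviors must pair up")
    win = model.window_length
    for v, b in zip(videos, behaviors):
        if v.n_frames < win:
            raise ValueError(
                f"every training video needs >= {win} frames, got {v.n_frames}"
            )
        if len(b) != v.n_frames:
            raise ValueError("behavior length must match its video")
        if v.frame_shape != model.frame_shape:
            raise ValueError("video frame shape must match the model")

    rng = np.random.default_rng(seed)
    H, W = model.frame_shape
    alpha = rng.uniform(0.0, 0.05, size=(H, W))
    n_pix = H * W

    for _ in range(int(epochs)):
        i_fg = rng.integers(len(videos))
        i_bg = rng.integers(len(videos))
        fg_video, fg_beh = videos[i_fg], behaviors[i_fg]
        bg_video = videos[i_bg]
        s_fg = rng.integers(fg_video.n_frames - win + 1)
        s_bg = rng.integers(bg_video.n_frames - win + 1)
        V = Video(fg_video.frames[s_fg : s_fg + win], fg_video.frame_rate)
        BG = Video(bg_video.frames[s_bg : s_bg + win], bg_video.frame_rate)
        beh = fg_beh.segment(s_fg, win)

        y = model.predict(V, beh).values
        blended = blend(V, BG, alpha)
        y_hat = model.predict(blended, beh).values

        a_bar = alpha.mean()
        resid = y - y_hat * (1.0 - a_bar)  # (N, T)
        nt = resid.size
        # path through the blended pixels
        dLdy_hat = -2.0 / nt * resid * (1.0 - a_bar)
        dL_dpix = model.backprop_dLdy(blended, beh, dLdy_hat)  # (T, H, W)
        grad_frames = dL_dpix * (V.frames - BG.frames)
        # path through alpha_bar (uniform over pixels, split per frame)
        dL_dabar_t = 2.0 / nt * (resid * y_hat).sum(axis=0)  # (T,)
        grad_frames = grad_frames + dL_dabar_t[:, None, None] / n_pix

        norms = np.linalg.norm(grad_frames.reshape(win, -1), axis=1)
        scale = np.where(norms > 0, norms, 1.0)
        grad_frames = np.clip(grad_frames / scale[:, None, None], -1.0, 1.0)
        step = gaussian_filter(grad_frames.mean(axis=0), smooth_sigma, mode="reflect")
        alpha = alpha - lr * step

    return TransparencyMask(
        alpha,
        provenance={
            "epochs": int(epochs),
            "lr": float(lr),
            "seed": int(seed),
            "smooth_sigma": float(smooth_sigma),
            "n_training_videos": len(videos),
            "model_neurons": model.n_neurons,
        },
    )
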