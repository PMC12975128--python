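"""Error maps: where reconstructions from measured activity deviate from
reconstructions from model-predicted activity.

Reconstructing from the encoder's own prediction on the ground-truth movie
(x_hat_yhat) isolates the reconstruction pipeline's intrinsic loss; the
difference d = x_hat - x_hat_yhat then highlights pixels where the measured
activity implies brighter (positive error) or darker (negative error) content
than the model expects, rendered as warm/cool overlays on the ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from stimrecon.encoder import EncoderModel, ResponseMatrix
from stimrecon.reconstruct import ReconstructionResult, reconstruct
from stimrecon.stimuli import BehaviorTrace, Video

__all__ = [
    "ErrorMapResult",
    "simulate_then_reconstruct",
    "error_maps",
    "render_composite",
]


@dataclass(frozen=True)
class ErrorMapResult:
    """Signed over-/under-estimation maps with disjoint supports."""

    positive: np.ndarray  # d where d > 0, else 0
    negative: np.ndarray  # d where d < 0, else 0


def simulate_then_reconstruct(
    models: "EncoderModel | list[EncoderModel]",
    x: Video,
    behavior: BehaviorTrace,
    **config,
) -> ReconstructionResult:
    """Predict activity from the ground-truth movie, then reconstruct from it.

    The target is the (ensemble-mean) noise-free prediction; reconstruction
    uses exactly the provided config so the result is comparable to a
    reconstruction from measured activity with the same settings.
    """
    model_list = list(models) if isinstance(models, (list, tuple)) else [models]
    y_hat = np.mean([m.predict(x, behavior).values for m in model_list], axis=0)
    return reconstruct(model_list, ResponseMatrix(y_hat), behavior, **config)


def error_maps(x_hat: "Video | np.ndarray", x_hat_yhat: "Video | np.ndarray") -> ErrorMapResult:
    """Split the difference between the two reconstructions into positive
    (over-estimation) and negative (under-estimation) parts."""
    a = x_hat.frames if isinstance(x_hat, Video) else np.asarray(x_hat, float)
    b = x_hat_yhat.frames if isinstance(x_hat_yhat, Video) else np.asarray(x_hat_yhat, float)
    if a.shape != b.shape:
        raise ValueError(f"shapes differ: {a.shape} vs {b.shape}")
    d = a - b
    return ErrorMapResult(positive=np.where(d > 0, d, 0.0), negative=np.where(d < 0, d, 0.0))


def render_composite(
    x: Video,
    err: ErrorMapResult,
    pos_range: tuple[float, float] = (25.0, 75.0),
    neg_range: tuple[float, float] = (-25.0, -75.0),
) -> np.ndarray:
    """Overlay error maps on the grayscale ground truth as a T x H x W x 3
    RGB video in [0, 255].

    Positive error blends toward a warm (red-orange) ramp, negative toward a
    cool (cyan) ramp; magnitudes below the range floor show no overlay and
    magnitudes above the ceiling saturate. Simple linear ramps are used rather
    than any specific LUT table.
    """
    lo_p, hi_p = pos_range
    if not 0 <= lo_p < hi_p:
        raise ValueError("pos_range must satisfy 0 <= low < high")
    lo_n, hi_n = neg_range
    if not (lo_n <= 0 and hi_n < lo_n):
        raise ValueError("neg_range must be (low, high) with high < low <= 0")
    if err.positive.shape != x.shape:
        raise ValueError("error maps must match the video shape")

    s_pos = np.clip((err.positive - lo_p) / (hi_p - lo_p), 0.0, 1.0)
    s_neg = np.clip((-err.negative - abs(lo_n)) / (abs(hi_n) - abs(lo_n)), 0.0, 1.0)

    gray = x.frames[..., None].repeat(3, axis=-1)
    warm = np.stack(
        [255.0 * np.ones_like(s_pos), 128.0 * s_pos, np.zeros_like(s_pos)], axis=-1
    )
    cool = np.stack(
        [np.zeros_like(s_neg), 255.0 * s_neg, 255.0 * np.ones_like(s_neg)], axis=-1
    )
    out = gray
    out = out * (1.0 - s_pos[..., None]) + warm * s_pos[..., None]
    out = out * (1.0 - s_neg[..., None]) + cool * s_neg[..., None]
    return np.clip(out, 0.0, 255.0)
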