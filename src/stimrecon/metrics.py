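"""Reconstruction quality metrics.

Similarity between ground-truth and reconstructed movies is scored inside the
evaluation mask by Pearson correlation -- per frame (spatial similarity) and
pooled over all pixels and frames (spatio-temporal similarity). Content
metrics (Shannon entropy of the masked intensity histogram, motion energy)
quantify what a reconstruction captures even when pixel correlation is low.
Retinotopic geometry converts a mask's pixel area into an equivalent circular
diameter in visual degrees on the flat display.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np

from stimrecon.stimuli import ScreenGeometry, Video

__all__ = [
    "MetricReport",
    "frame_correlation",
    "video_correlation",
    "shannon_entropy",
    "motion_energy",
    "pixel_angular_areas",
    "retinotopic_diameter",
    "quality_correlates",
]

logger = logging.getLogger(__name__)

N_BINS = 25  # intensity histogram bins on [0, 255]


@dataclass(frozen=True)
class MetricReport:
    """Bundle of evaluation metrics for one (truth, reconstruction) pair."""

    video_correlation: float
    mean_frame_correlation: float
    frame_correlations: np.ndarray
    shannon_entropy: float
    motion_energy: np.ndarray
    mask_id: str = ""

    def to_dict(self) -> dict:
        return {
            "video_correlation": self.video_correlation,
            "mean_frame_correlation": self.mean_frame_correlation,
            "frame_correlations": self.frame_correlations.tolist(),
            "shannon_entropy": self.shannon_entropy,
            "motion_energy": self.motion_energy.tolist(),
            "mask_id": self.mask_id,
        }


def _frames_of(v: "Video | np.ndarray") -> np.ndarray:
    return v.frames if isinstance(v, Video) else np.asarray(v, dtype=float)


def _mask_index(mask: np.ndarray, frame_shape: tuple[int, int]) -> np.ndarray:
    mask = np.asarray(mask)
    if mask.shape != frame_shape:
        raise ValueError(f"mask shape {mask.shape} != frame shape {frame_shape}")
    idx = mask.astype(bool)
    if not idx.any():
        raise ValueError("mask selects no pixels")
    return idx


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    a = a - a.mean()
    b = b - b.mean()
    denom = math.sqrt((a @ a) * (b @ b))
    if denom == 0:
        return math.nan
    return float((a @ b) / denom)


def frame_correlation(
    x: "Video | np.ndarray", x_hat: "Video | np.ndarray", mask: np.ndarray
) -> tuple[np.ndarray, float]:
    """Per-frame Pearson r over masked pixels, and its mean over frames.

    Frames where either movie is constant inside the mask have undefined r;
    they appear as NaN in the vector and are excluded from the mean (the
    count is logged).
    """
    xf, hf = _frames_of(x), _frames_of(x_hat)
    if xf.shape != hf.shape:
        raise ValueError(f"video shapes differ: {xf.shape} vs {hf.shape}")
    idx = _mask_index(mask, xf.shape[1:])
    if idx.sum() < 2:
        raise ValueError("need >= 2 masked pixels for correlation")
    r = np.array([_pearson(xf[t][idx], hf[t][idx]) for t in range(xf.shape[0])])
    n_bad = int(np.isnan(r).sum())
    if n_bad:
        logger.info("frame_correlation: %d zero-variance frames excluded", n_bad)
    return r, float(np.nanmean(r))


def video_correlation(
    x: "Video | np.ndarray", x_hat: "Video | np.ndarray", mask: np.ndarray
) -> float:
    """Single Pearson r pooling all masked pixels over all frames."""
    xf, hf = _frames_of(x), _frames_of(x_hat)
    if xf.shape != hf.shape:
        raise ValueError(f"video shapes differ: {xf.shape} vs {hf.shape}")
    idx = _mask_index(mask, xf.shape[1:])
    a = xf[:, idx].ravel()
    b = hf[:, idx].ravel()
    r = _pearson(a, b)
    if math.isnan(r):
        raise ValueError("correlation undefined: zero variance inside the mask")
    return r


def shannon_entropy(v: "Video | np.ndarray", mask: np.ndarray) -> float:
    """Mean per-frame Shannon entropy (bits) of the masked intensity
    histogram (25 bins on [0, 255]); a constant frame scores 0."""
    vf = _frames_of(v)
    idx = _mask_index(mask, vf.shape[1:])
    ent = np.empty(vf.shape[0])
    for t in range(vf.shape[0]):
        counts, _ = np.histogram(vf[t][idx], bins=N_BINS, range=(0.0, 255.0))
        p = counts[counts > 0] / counts.sum()
        ent[t] = float(-(p * np.log2(p)).sum())
    return float(ent.mean())


def motion_energy(v: "Video | np.ndarray", mask: np.ndarray) -> np.ndarray:
    """Mean absolute inter-frame difference over masked pixels, for frames
    2..T (vector of length T-1)."""
    vf = _frames_of(v)
    if vf.shape[0] < 2:
        raise ValueError("motion energy requires >= 2 frames")
    idx = _mask_index(mask, vf.shape[1:])
    d = np.abs(np.diff(vf[:, idx], axis=0))
    return d.mean(axis=1)


def pixel_angular_areas(geometry: ScreenGeometry) -> np.ndarray:
    """Angular area (deg^2) subtended by each pixel of the flat screen.

    Computed from arctangent differences of pixel edges along both axes at the
    perpendicular center distance (planar visuotopic approximation; eye
    position is ignored). Summing all pixels telescopes exactly to
    4*atan(W/2d)*atan(H/2d) in degrees^2.
    """
    d = geometry.distance_cm

    def edge_angles(extent_cm: float, n: int) -> np.ndarray:
        edges = np.linspace(-extent_cm / 2.0, extent_cm / 2.0, n + 1)
        return np.degrees(np.arctan(edges / d))

    th_w = np.diff(edge_angles(geometry.width_cm, geometry.pixels_w))
    th_h = np.diff(edge_angles(geometry.height_cm, geometry.pixels_h))
    return th_h[:, None] * th_w[None, :]


def diameter_from_area(area_deg2: float) -> float:
    """Equivalent circular diameter (degrees) of an angular area (deg^2):
    2*sqrt(A/pi)."""
    if area_deg2 < 0:
        raise ValueError("area must be >= 0")
    return 2.0 * math.sqrt(area_deg2 / math.pi)


def retinotopic_diameter(mask: np.ndarray, geometry: ScreenGeometry) -> float:
    """Diameter (degrees) of the circle whose area equals the mask's summed
    per-pixel angular area. An empty mask gives 0."""
    mask = np.asarray(mask, dtype=float)
    areas = pixel_angular_areas(geometry)
    if mask.shape != areas.shape:
        raise ValueError(
            f"mask shape {mask.shape} != geometry pixel grid {areas.shape}"
        )
    return diameter_from_area(float((areas * (mask != 0)).sum()))


def quality_correlates(
    frame_corr: np.ndarray, regressors: dict[str, np.ndarray]
) -> dict[str, float]:
    """Pearson r of per-frame reconstruction quality against named per-frame
    regressors (contrast, luminance, motion energy, behavior...).

    Constant regressors yield NaN (flagged via log). NaN frames in
    ``frame_corr`` are dropped pairwise.
    """
    fc = np.asarray(frame_corr, dtype=float)
    out: dict[str, float] = {}
    for name, reg in regressors.items():
        reg = np.asarray(reg, dtype=float)
        if reg.shape != fc.shape:
            raise ValueError(f"regressor {name!r} length differs from frame_corr")
        ok = ~(np.isnan(fc) | np.isnan(reg))
        r = _pearson(fc[ok], reg[ok]) if ok.sum() >= 2 else math.nan
        if math.isnan(r):
            logger.info("quality_correlates: %r has undefined correlation", name)
        out[name] = r
    return out
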