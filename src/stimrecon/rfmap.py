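"""In-silico receptive-field mapping from sparse-noise responses.

Each neuron's response map is the relative rate change between the
single-pixel stimulus period and the preceding gray period,

    OnR[h, w, n] = (R_stim - R_pre) / R_pre

thresholded at 0.1, smoothed with a 2-D Gaussian (sigma 2) and normalized per
neuron by its maximum; the RF center is the argmax pixel. On-Off difference
maps and the population On+Off map summarize subfield structure and the
population's collective visual coverage, which should align with the learned
transparency mask.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter

from stimrecon.encoder import EncoderModel
from stimrecon.stimuli import BehaviorTrace, SparseNoiseSet

__all__ = [
    "RFMaps",
    "sparse_noise_responses",
    "response_maps",
    "on_off_rf",
    "population_map",
]

THRESHOLD = 0.1
SMOOTH_SIGMA = 2.0


@dataclass(frozen=True)
class RFMaps:
    """Per-neuron On/Off response maps, centers, and the population map.

    ``on_centers``/``off_centers`` hold (row, col) of the per-neuron argmax,
    NaN where a neuron's map is identically zero (no responsive pixel).
    """

    on_maps: np.ndarray  # (N, H, W), each normalized to max 1 (or all-zero)
    off_maps: np.ndarray
    on_centers: np.ndarray  # (N, 2) float, NaN if degenerate
    off_centers: np.ndarray


def sparse_noise_responses(
    model: EncoderModel,
    stimuli: SparseNoiseSet,
    behavior: BehaviorTrace | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Predicted stimulus-period and pre-period mean rates per neuron, pixel
    and polarity.

    Returns ``(R_stim, R_pre)``, each of shape (2, N, H, W) with index 0 = On
    and 1 = Off stimuli. A neutral (all-zero) behavior trace is used unless
    one is supplied.
    """
    H, W = stimuli.height, stimuli.width
    if (H, W) != model.frame_shape:
        raise ValueError(
            f"stimulus frame {H, W} != model frame {model.frame_shape}"
        )
    n_frames = 3 * stimuli.n_segment
    beh = behavior if behavior is not None else BehaviorTrace.zeros(n_frames)
    if len(beh) != n_frames:
        raise ValueError("behavior trace must span the stimulus duration")
    N = model.n_neurons
    R_stim = np.empty((2, N, H, W))
    R_pre = np.empty((2, N, H, W))
    pol_index = {"on": 0, "off": 1}
    for i in range(len(stimuli)):
        h, w, pol = stimuli.stimulus_info(i)
        rates = model.predict(stimuli[i], beh).values
        p = pol_index[pol]
        R_stim[p, :, h, w] = rates[:, stimuli.stim_frames].mean(axis=1)
        R_pre[p, :, h, w] = rates[:, stimuli.pre_frames].mean(axis=1)
    return R_stim, R_pre


def _process_polarity(raw: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Threshold, smooth, normalize and locate centers for one polarity."""
    N, H, W = raw.shape
    maps = np.where(raw >= THRESHOLD, raw, 0.0)
    centers = np.full((N, 2), np.nan)
    for n in range(N):
        m = gaussian_filter(maps[n], SMOOTH_SIGMA, mode="reflect")
        peak = m.max()
        if peak > 0:
            m = m / peak
            centers[n] = np.unravel_index(np.argmax(m), (H, W))
        maps[n] = m
    return maps, centers


def response_maps(R_stim: np.ndarray, R_pre: np.ndarray) -> RFMaps:
    """Relative response-change maps per neuron and polarity.

    ``(R_stim - R_pre)/R_pre`` thresholded at 0.1, smoothed (2-D Gaussian,
    sigma 2), normalized per neuron by its maximum; center = argmax pixel.
    """
    R_stim = np.asarray(R_stim, float)
    R_pre = np.asarray(R_pre, float)
    if R_stim.shape != R_pre.shape or R_stim.ndim != 4 or R_stim.shape[0] != 2:
        raise ValueError("expected matching (2, N, H, W) arrays")
    if np.any(R_pre <= 0):
        raise ValueError("R_pre must be > 0 everywhere (relative change)")
    raw = (R_stim - R_pre) / R_pre
    on_maps, on_centers = _process_polarity(raw[0])
    off_maps, off_centers = _process_polarity(raw[1])
    return RFMaps(on_maps, off_maps, on_centers, off_centers)


def on_off_rf(on_map: np.ndarray, off_map: np.ndarray) -> np.ndarray | None:
    """Per-neuron On-Off subfield map, (OnR - OffR)/max(OnR - OffR).

    Returns None (degenerate) when the difference has no positive maximum.
    """
    if on_map.shape != off_map.shape:
        raise ValueError("On and Off maps must share a shape")
    d = on_map - off_map
    peak = d.max()
    if peak <= 0:
        return None
    return d / peak


def population_map(on_maps: np.ndarray, off_maps: np.ndarray) -> np.ndarray:
    """Population On+Off response, summed over neurons and normalized by its
    maximum absolute value; lies in [-1, 1] with max |value| exactly 1."""
    if on_maps.shape != off_maps.shape or on_maps.ndim != 3:
        raise ValueError("expected matching (N, H, W) stacks")
    if on_maps.shape[0] == 0:
        raise ValueError("population is empty")
    s = (on_maps + off_maps).sum(axis=0)
    peak = np.abs(s).max()
    if peak == 0:
        raise ValueError("all response maps are zero")
    return s / peak
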