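"""Visual stimulus and behavior-trace generators.

All downstream stages (mask learning, reconstruction, receptive-field mapping,
evaluation) run on stimuli produced here, so no external movie corpus is
needed. The stimulus classes mirror common visual-neuroscience protocols:

* Gaussian-process noise movies with controlled spatial/temporal correlation
  scales ("length constants"), used to probe which frequencies a
  reconstruction pipeline can recover.
* Full-field high-contrast square-wave drifting gratings.
* Single-pixel sparse-noise flashes (On/Off) for receptive-field mapping.
* Smooth synthetic behavior traces (pupil position/diameter, running speed).
"""

from __future__ import annotations

import math
from collections.abc import Sequence
from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import cholesky

__all__ = [
    "Video",
    "GPStimulusSpec",
    "ScreenGeometry",
    "BehaviorTrace",
    "SparseNoiseSet",
    "generate_gp_video",
    "phase_invert",
    "generate_grating",
    "generate_sparse_noise",
    "generate_behavior",
]

GRAY = 127.0  # display midpoint used for blank/pre-stimulus screens

# default length-constant grid (pixels/frames) for a 7 x 7 Gaussian-process
# stimulus battery spanning 0-32; a config parameter, not a fixed protocol
DEFAULT_GP_GRID = (0, 1, 2, 4, 8, 16, 32)


@dataclass(frozen=True)
class Video:
    """A grayscale movie: T x H x W intensities on [0, 255].

    Parameters
    ----------
    frames
        Array of shape (T, H, W), intensity units on [0, 255].
    frame_rate
        Frames per second (default 30).
    """

    frames: np.ndarray
    frame_rate: float = 30.0

    def __post_init__(self) -> None:
        f = np.asarray(self.frames, dtype=float)
        object.__setattr__(self, "frames", f)
        if f.ndim != 3 or f.shape[0] < 1 or f.shape[1] < 1 or f.shape[2] < 1:
            raise ValueError(f"frames must be T x H x W with T,H,W >= 1, got {f.shape}")
        if not np.all(np.isfinite(f)):
            raise ValueError("frames contain non-finite values")
        if f.min() < 0 or f.max() > 255:
            raise ValueError("frame intensities must lie in [0, 255]")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.frames.shape

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def frame_shape(self) -> tuple[int, int]:
        return self.frames.shape[1:]

    @property
    def duration(self) -> float:
        return self.n_frames / self.frame_rate

    @staticmethod
    def unchecked(frames: np.ndarray, frame_rate: float = 30.0) -> "Video":
        """Build a Video without the [0, 255] range check.

        Used for derived movies (e.g. luminance/contrast-matched output) whose
        values may legitimately leave the display range.
        """
        v = object.__new__(Video)
        object.__setattr__(v, "frames", np.asarray(frames, dtype=float))
        object.__setattr__(v, "frame_rate", float(frame_rate))
        return v


@dataclass(frozen=True)
class GPStimulusSpec:
    """Parameters of a Gaussian-process noise movie.

    ``spatial_length_constant`` (pixels) and ``temporal_length_constant``
    (frames) are the squared-exponential kernel scales; 0 means white noise
    along that axis.
    """

    spatial_length_constant: float
    temporal_length_constant: float
    height: int = 36
    width: int = 64
    duration: float = 2.0
    frame_rate: float = 30.0

    def __post_init__(self) -> None:
        for name in ("spatial_length_constant", "temporal_length_constant"):
            v = getattr(self, name)
            if not np.isfinite(v) or v < 0:
                raise ValueError(f"{name} must be finite and >= 0, got {v}")
        if self.height < 1 or self.width < 1:
            raise ValueError("height and width must be >= 1")
        if self.duration <= 0 or self.frame_rate <= 0:
            raise ValueError("duration and frame_rate must be positive")

    @property
    def n_frames(self) -> int:
        return max(1, round(self.duration * self.frame_rate))


@dataclass(frozen=True)
class ScreenGeometry:
    """Flat display geometry: physical size, pixel grid, eye distance.

    The eye is assumed perpendicular to the screen center. Defaults match a
    31.8 x 56.5 cm monitor at 15 cm displaying 36 x 64 pixel movies
    (~3.4 degrees/pixel at the center).
    """

    width_cm: float = 56.5
    height_cm: float = 31.8
    distance_cm: float = 15.0
    pixels_w: int = 64
    pixels_h: int = 36

    def __post_init__(self) -> None:
        for name in ("width_cm", "height_cm", "distance_cm", "pixels_w", "pixels_h"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    @property
    def central_resolution_deg_per_px(self) -> float:
        """Angle (degrees) subtended by one central pixel along the width."""
        px_cm = self.width_cm / self.pixels_w
        return math.degrees(2.0 * math.atan(px_cm / 2.0 / self.distance_cm))


@dataclass(frozen=True)
class BehaviorTrace:
    """Per-frame behavior channels paired with a movie.

    Four channels: pupil x/y position (screen coordinates), pupil diameter
    (a.u.) and running speed (a.u., nonnegative).
    """

    pupil_x: np.ndarray
    pupil_y: np.ndarray
    pupil_diameter: np.ndarray
    running_speed: np.ndarray

    def __post_init__(self) -> None:
        arrs = {}
        n = None
        for name in ("pupil_x", "pupil_y", "pupil_diameter", "running_speed"):
            a = np.asarray(getattr(self, name), dtype=float).ravel()
            if n is None:
                n = a.size
            elif a.size != n:
                raise ValueError("behavior channels must have equal length")
            arrs[name] = a
        if n < 1:
            raise ValueError("behavior trace must have >= 1 frame")
        if arrs["running_speed"].min() < 0:
            raise ValueError("running_speed must be >= 0")
        for name, a in arrs.items():
            object.__setattr__(self, name, a)

    def __len__(self) -> int:
        return self.pupil_x.size

    def as_array(self) -> np.ndarray:
        """Stack channels into a (4, T) array in canonical order."""
        return np.stack(
            [self.pupil_x, self.pupil_y, self.pupil_diameter, self.running_speed]
        )

    def segment(self, start: int, length: int) -> "BehaviorTrace":
        sl = slice(start, start + length)
        return BehaviorTrace(
            self.pupil_x[sl], self.pupil_y[sl], self.pupil_diameter[sl],
            self.running_speed[sl],
        )

    @staticmethod
    def zeros(n_frames: int) -> "BehaviorTrace":
        """A neutral (all-zero) trace, e.g. for in-silico RF mapping."""
        z = np.zeros(n_frames)
        return BehaviorTrace(z, z, z, z)


def _se_cholesky(n: int, length_constant: float) -> np.ndarray:
    """Cholesky factor of a squared-exponential kernel on a 1-D integer grid.

    length_constant == 0 degenerates to white noise (identity factor).
    """
    if length_constant == 0 or n == 1:
        return np.eye(n)
    d = np.arange(n, dtype=float)
    K = np.exp(-((d[:, None] - d[None, :]) ** 2) / (2.0 * length_constant**2))
    # jitter keeps long-length-constant (near-singular) kernels factorizable
    K[np.diag_indices(n)] += 1e-8 * n
    return cholesky(K, lower=True)


def generate_gp_video(spec: GPStimulusSpec, seed: int) -> Video:
    """Sample a Gaussian-process noise movie.

    The field has a separable space-time squared-exponential covariance with
    the spec's length constants; the raw sample is standardized to mean 127
    and SD 40 before clipping to [0, 255] (clipping then affects <2% of
    pixels). ``seed`` fixes the draw exactly.
    """
    if not isinstance(spec, GPStimulusSpec):
        raise TypeError("spec must be a GPStimulusSpec")
    rng = np.random.default_rng(seed)
    T, H, W = spec.n_frames, spec.height, spec.width
    z = rng.standard_normal((T, H, W))
    Lt = _se_cholesky(T, spec.temporal_length_constant)
    Ls = spec.spatial_length_constant
    Lh = _se_cholesky(H, Ls)
    Lw = _se_cholesky(W, Ls)
    x = np.einsum("ta,ahw->thw", Lt, z)
    x = np.einsum("hb,tbw->thw", Lh, x)
    x = np.einsum("wc,thc->thw", Lw, x)
    sd = x.std()
    if sd == 0:  # degenerate single-sample case
        x = np.full_like(x, GRAY)
    else:
        x = (x - x.mean()) / sd * 40.0 + GRAY
    return Video(np.clip(x, 0.0, 255.0), spec.frame_rate)


def phase_invert(v: Video) -> Video:
    """Intensity inversion about the display midpoint: 255 - v."""
    return Video(255.0 - v.frames, v.frame_rate)


_DIRECTIONS = ("up", "down", "left", "right")


def generate_grating(
    spatial_freq: float,
    temporal_freq: float,
    direction: str,
    geometry: ScreenGeometry | None = None,
    duration: float = 2.0,
    frame_rate: float = 30.0,
) -> Video:
    """Full-field high-contrast square-wave grating drifting in a cardinal
    direction.

    ``spatial_freq`` is in cycles/degree, converted to cycles/pixel with the
    geometry's central angular resolution (applied uniformly, no per-pixel
    perspective correction). ``temporal_freq`` is in cycles/s. Values are
    binary {0, 255}. ``spatial_freq == 0`` with ``temporal_freq > 0`` is the
    full-field flicker stimulus; ``temporal_freq == 0`` is a static grating.
    """
    if spatial_freq < 0 or temporal_freq < 0:
        raise ValueError("frequencies must be >= 0")
    if direction not in _DIRECTIONS:
        raise ValueError(f"direction must be one of {_DIRECTIONS}, got {direction!r}")
    geometry = geometry or ScreenGeometry()
    H, W = geometry.pixels_h, geometry.pixels_w
    T = max(1, round(duration * frame_rate))
    f_px = spatial_freq * geometry.central_resolution_deg_per_px  # cycles/pixel

    t = np.arange(T)[:, None, None] / frame_rate
    h = np.arange(H)[None, :, None].astype(float)
    w = np.arange(W)[None, None, :].astype(float)
    # drift: the pattern moves toward `direction`, i.e. phase decreases with
    # the coordinate axis pointing that way
    if direction in ("left", "right"):
        coord = w if direction == "right" else -w
    else:
        # image row index grows downward
        coord = h if direction == "down" else -h
    phase = 2.0 * np.pi * (f_px * coord - temporal_freq * t)
    frames = np.where(np.sin(phase) >= 0, 255.0, 0.0)
    frames = np.broadcast_to(frames, (T, H, W)).copy()
    return Video(frames, frame_rate)


class SparseNoiseSet(Sequence):
    """Lazy sequence of single-pixel sparse-noise stimuli.

    One stimulus per (pixel, polarity): 0.5 s gray (127), 0.5 s with that one
    pixel at 0 (Off) or 255 (On), 0.5 s gray. Stimuli are materialized on
    indexing, so the full 36 x 64 set (4608 movies) costs nothing to hold.

    Ordering: index ``2*(h*W + w) + p`` with polarity p=0 -> On, p=1 -> Off.
    """

    def __init__(self, height: int, width: int, frame_rate: float = 30.0):
        if height < 1 or width < 1:
            raise ValueError("height and width must be >= 1")
        self.height = int(height)
        self.width = int(width)
        self.frame_rate = float(frame_rate)
        self.n_segment = max(1, round(0.5 * frame_rate))  # frames per 0.5 s

    def __len__(self) -> int:
        return 2 * self.height * self.width

    def stimulus_info(self, i: int) -> tuple[int, int, str]:
        """(row, col, polarity-name) of stimulus ``i``."""
        i = range(len(self))[i]  # normalize/validate index
        pix, p = divmod(i, 2)
        h, w = divmod(pix, self.width)
        return h, w, ("on" if p == 0 else "off")

    @property
    def pre_frames(self) -> slice:
        return slice(0, self.n_segment)

    @property
    def stim_frames(self) -> slice:
        return slice(self.n_segment, 2 * self.n_segment)

    def __getitem__(self, i: int) -> Video:
        h, w, pol = self.stimulus_info(i)
        n = self.n_segment
        frames = np.full((3 * n, self.height, self.width), GRAY)
        frames[self.stim_frames, h, w] = 255.0 if pol == "on" else 0.0
        return Video(frames, self.frame_rate)


def generate_sparse_noise(
    height: int, width: int, frame_rate: float = 30.0
) -> SparseNoiseSet:
    """Sparse-noise RF-mapping set: 2*height*width single-pixel stimuli."""
    return SparseNoiseSet(height, width, frame_rate)


def generate_behavior(
    T: int, seed: int, smoothing_frames: float = 20.0
) -> BehaviorTrace:
    """Synthesize smooth behavior traces for T frames.

    Each channel is a Gaussian-smoothed random walk (low-pass filtered so the
    lag-1 autocorrelation at the default smoothing exceeds 0.9), standardized
    to a plausible amplitude; running speed is rectified at 0.
    """
    if T < 1:
        raise ValueError("T must be >= 1")
    from scipy.ndimage import gaussian_filter1d

    rng = np.random.default_rng(seed)

    def smooth_walk(scale: float) -> np.ndarray:
        w = np.cumsum(rng.standard_normal(T))
        w = gaussian_filter1d(w, smoothing_frames, mode="nearest")
        sd = w.std()
        if sd > 0:
            w = (w - w.mean()) / sd
        return w * scale

    pupil_x = smooth_walk(2.0)
    pupil_y = smooth_walk(2.0)
    pupil_diameter = 1.0 + 0.25 * smooth_walk(1.0)
    running_speed = np.maximum(0.0, 0.5 + smooth_walk(1.0))
    return BehaviorTrace(pupil_x, pupil_y, pupil_diameter, running_speed)
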