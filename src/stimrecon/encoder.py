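"""Frozen differentiable encoder contract and the LNP reference population.

The reconstruction engine only needs two capabilities from an encoding model:
``predict`` (video window + behavior -> nonnegative rates for every neuron and
frame) and ``input_gradient`` (the gradient of a response-matching loss with
respect to every input pixel). Any differentiable video encoder can satisfy
this contract; the package ships a linear-nonlinear-Poisson (LNP) population
with known ground-truth receptive fields so recovery can be scored exactly.

Reference model, per neuron n and frame t::

    rate[n, t] = softplus( A * gain_n(b_t) * (k_n (*) <RF_n, s_t>) + baseline_n )

where s_t is the frame standardized as (pixels - 127)/127, <RF_n, .> is the
spatial projection onto a truncated-Gaussian receptive field (signed by On/Off
polarity), k_n (*) denotes causal temporal convolution with a K-frame kernel
(zero-padded history), gain_n(b) = softplus(1 + w_n . b)/softplus(1) is a
behavior-dependent multiplicative gain that equals 1 for neutral (zero)
behavior, and A is a shared drive amplitude. All derivatives are closed-form,
so input gradients are computed analytically (and checked against finite
differences in the test suite).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Protocol, runtime_checkable

import numpy as np
from scipy.special import expit

from stimrecon.stimuli import GRAY, BehaviorTrace, Video

__all__ = [
    "EncoderModel",
    "LNPEncoder",
    "ResponseMatrix",
    "make_reference_population",
    "perturb_model",
    "predict",
    "input_gradient",
    "sample_poisson",
]

_EPS = 1e-8  # Poisson-NLL log offset


@dataclass(frozen=True)
class ResponseMatrix:
    """N-neurons x T-frames nonnegative activity (target or predicted)."""

    values: np.ndarray
    neuron_ids: np.ndarray | None = None

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2:
            raise ValueError(f"values must be N x T, got shape {v.shape}")
        if not np.all(np.isfinite(v)):
            raise ValueError("response values contain non-finite entries")
        if v.min() < 0:
            raise ValueError("response values must be >= 0")
        object.__setattr__(self, "values", v)
        ids = self.neuron_ids
        ids = np.arange(v.shape[0]) if ids is None else np.asarray(ids)
        if ids.shape != (v.shape[0],):
            raise ValueError("neuron_ids length must match N")
        object.__setattr__(self, "neuron_ids", ids)

    @property
    def n_neurons(self) -> int:
        return self.values.shape[0]

    @property
    def n_frames(self) -> int:
        return self.values.shape[1]


def _response_values(y: "ResponseMatrix | np.ndarray") -> np.ndarray:
    return y.values if isinstance(y, ResponseMatrix) else np.asarray(y, dtype=float)


def _softplus(z: np.ndarray) -> np.ndarray:
    return np.logaddexp(0.0, z)


@runtime_checkable
class EncoderModel(Protocol):
    """What the reconstruction engine requires of an encoding model."""

    n_neurons: int
    window_length: int
    frame_shape: tuple[int, int]

    def predict(self, video: Video, behavior: BehaviorTrace) -> ResponseMatrix: ...

    def input_gradient(
        self,
        video: Video,
        behavior: BehaviorTrace,
        target: "ResponseMatrix | np.ndarray",
        loss: str = "poisson_nll",
    ) -> np.ndarray: ...


@dataclass(frozen=True)
class LNPEncoder:
    """Frozen linear-nonlinear population encoder (see module docstring).

    Attributes
    ----------
    rf_maps : (N, H, W)
        Signed spatial receptive fields (polarity baked in, unit L2 norm,
        truncated at 3 sigma so support is exactly local).
    kernels : (N, K)
        Causal temporal kernels, nonnegative, summing to 1; kernels[:, 0]
        weights the current frame.
    baseline : (N,)
        Pre-nonlinearity offset; gray screen with neutral behavior gives
        rate = softplus(baseline).
    behavior_gain : (N, 4)
        Weights onto (pupil_x, pupil_y, pupil_diameter, running_speed).
    drive_gain : float
        Shared amplitude A on the stimulus drive.
    """

    rf_maps: np.ndarray
    kernels: np.ndarray
    baseline: np.ndarray
    behavior_gain: np.ndarray
    drive_gain: float = 3.0
    window_length: int = 32
    # ground truth for recovery scoring (not used by predict)
    rf_centers: np.ndarray | None = None
    rf_sigmas: np.ndarray | None = None
    polarity: np.ndarray | None = None

    @property
    def n_neurons(self) -> int:
        return self.rf_maps.shape[0]

    @property
    def frame_shape(self) -> tuple[int, int]:
        return self.rf_maps.shape[1:]

    @property
    def kernel_length(self) -> int:
        return self.kernels.shape[1]

    # ---- forward ---------------------------------------------------------

    def _check_inputs(self, video: Video, behavior: BehaviorTrace) -> None:
        if video.frame_shape != self.frame_shape:
            raise ValueError(
                f"video frame shape {video.frame_shape} != model {self.frame_shape}"
            )
        if len(behavior) != video.n_frames:
            raise ValueError(
                f"behavior length {len(behavior)} != video frames {video.n_frames}"
            )

    def _gain(self, behavior: BehaviorTrace) -> np.ndarray:
        """(N, T) behavior-dependent multiplicative gain; 1 at zero behavior."""
        b = behavior.as_array()  # (4, T)
        z = 1.0 + self.behavior_gain @ b
        return _softplus(z) / _softplus(np.array(1.0))

    def _drive(self, video: Video) -> tuple[np.ndarray, np.ndarray]:
        """Returns (proj, drive), both (N, T)."""
        T = video.n_frames
        s = (video.frames.reshape(T, -1) - GRAY) / GRAY  # (T, P)
        proj = self.rf_maps.reshape(self.n_neurons, -1) @ s.T  # (N, T)
        drive = np.zeros_like(proj)
        for k in range(self.kernel_length):
            if k == 0:
                drive += self.kernels[:, :1] * proj
            elif k < T:
                drive[:, k:] += self.kernels[:, k : k + 1] * proj[:, :-k]
        return proj, drive

    def _preactivation(self, video: Video, behavior: BehaviorTrace) -> np.ndarray:
        _, drive = self._drive(video)
        return self.drive_gain * self._gain(behavior) * drive + self.baseline[:, None]

    def predict(self, video: Video, behavior: BehaviorTrace) -> ResponseMatrix:
        """Deterministic nonnegative rates, (N, T).

        Accepts any T >= 1 (causal history zero-padded); the reconstruction
        engine always calls it with T == window_length.
        """
        self._check_inputs(video, behavior)
        return ResponseMatrix(_softplus(self._preactivation(video, behavior)))

    # ---- backward --------------------------------------------------------

    def backprop_dLdy(
        self, video: Video, behavior: BehaviorTrace, dLdy: np.ndarray
    ) -> np.ndarray:
        """Pixel gradient of any loss given its gradient wrt predicted rates.

        Behavior channels are inputs, not free parameters: they receive no
        gradient. Returns a (T, H, W) array.
        """
        self._check_inputs(video, behavior)
        T = video.n_frames
        z = self._preactivation(video, behavior)
        dz = np.asarray(dLdy) * expit(z)  # softplus' = sigmoid
        ddrive = dz * self.drive_gain * self._gain(behavior)
        # transpose of the causal temporal convolution
        dproj = np.zeros_like(ddrive)
        for k in range(self.kernel_length):
            if k == 0:
                dproj += self.kernels[:, :1] * ddrive
            elif k < T:
                dproj[:, :-k] += self.kernels[:, k : k + 1] * ddrive[:, k:]
        dframes = dproj.T @ self.rf_maps.reshape(self.n_neurons, -1) / GRAY
        return dframes.reshape(T, *self.frame_shape)

    def input_gradient(
        self,
        video: Video,
        behavior: BehaviorTrace,
        target: "ResponseMatrix | np.ndarray",
        loss: str = "poisson_nll",
    ) -> np.ndarray:
        """Gradient of the response-matching loss wrt every input pixel.

        ``loss`` is "poisson_nll" (sum of y_hat - y*log(y_hat + 1e-8)) or
        "mse" (sum of squared errors).
        """
        y = _response_values(target)
        if not np.all(np.isfinite(y)):
            raise ValueError("target contains non-finite entries")
        rates = self.predict(video, behavior).values
        if y.shape != rates.shape:
            raise ValueError(f"target shape {y.shape} != predicted {rates.shape}")
        if loss == "poisson_nll":
            dLdy = 1.0 - y / (rates + _EPS)
        elif loss == "mse":
            dLdy = 2.0 * (rates - y)
        else:
            raise ValueError(f"unknown loss {loss!r}; use 'poisson_nll' or 'mse'")
        return self.backprop_dLdy(video, behavior, dLdy)


def _build_rf_maps(
    centers: np.ndarray,
    sigmas: np.ndarray,
    polarity: np.ndarray,
    frame_shape: tuple[int, int],
) -> np.ndarray:
    H, W = frame_shape
    hh = np.arange(H)[:, None]
    ww = np.arange(W)[None, :]
    rf_maps = np.empty((centers.shape[0], H, W))
    for n in range(centers.shape[0]):
        d2 = (hh - centers[n, 0]) ** 2 + (ww - centers[n, 1]) ** 2
        rf = np.exp(-d2 / (2.0 * sigmas[n] ** 2))
        rf[d2 > (3.0 * sigmas[n]) ** 2] = 0.0  # exact local support
        rf_maps[n] = polarity[n] * rf / np.linalg.norm(rf)
    return rf_maps


def make_reference_population(
    n_neurons: int,
    rf_region: tuple[int, int, int, int],
    seed: int,
    frame_shape: tuple[int, int] = (36, 64),
    rf_sigma: float = 1.5,
    window_length: int = 32,
    kernel_length: int = 6,
    drive_gain: float = 3.0,
    behavior_modulation: float = 0.1,
) -> LNPEncoder:
    """Build a frozen reference population with RF centers tiling a region.

    ``rf_region`` is slice-style (row_start, row_stop, col_start, col_stop) in
    pixels, and must lie inside the frame. Centers sit on a jittered grid
    covering the region; polarities are a ~50/50 On/Off mixture; temporal
    kernels are causal gamma-like bumps with per-neuron time constants;
    everything is reproducible from ``seed``.
    """
    if n_neurons < 1:
        raise ValueError("n_neurons must be >= 1")
    H, W = frame_shape
    r0, r1, c0, c1 = rf_region
    if not (0 <= r0 < r1 <= H and 0 <= c0 < c1 <= W):
        raise ValueError(f"rf_region {rf_region} outside frame {frame_shape}")
    rng = np.random.default_rng(seed)

    # jittered grid of centers covering the region
    n_rows = max(1, round(np.sqrt(n_neurons * (r1 - r0) / max(1, c1 - c0))))
    n_cols = int(np.ceil(n_neurons / n_rows))
    rows = r0 + (np.arange(n_rows) + 0.5) * (r1 - r0) / n_rows
    cols = c0 + (np.arange(n_cols) + 0.5) * (c1 - c0) / n_cols
    grid = np.array([(r, c) for r in rows for c in cols])[:n_neurons]
    jitter = rng.uniform(-0.5, 0.5, size=grid.shape)
    centers = grid + jitter
    centers[:, 0] = np.clip(centers[:, 0], r0, r1 - 1e-9)
    centers[:, 1] = np.clip(centers[:, 1], c0, c1 - 1e-9)

    polarity = rng.choice([-1.0, 1.0], size=n_neurons)
    sigmas = rf_sigma * rng.uniform(0.8, 1.2, size=n_neurons)

    rf_maps = _build_rf_maps(centers, sigmas, polarity, frame_shape)

    taus = rng.uniform(1.5, 2.5, size=n_neurons)
    lags = np.arange(1, kernel_length + 1)
    kernels = lags[None, :] * np.exp(-lags[None, :] / taus[:, None])
    kernels /= kernels.sum(axis=1, keepdims=True)

    baseline = rng.normal(0.0, 0.1, size=n_neurons)
    behavior_gain = rng.normal(0.0, behavior_modulation, size=(n_neurons, 4))

    return LNPEncoder(
        rf_maps=rf_maps,
        kernels=kernels,
        baseline=baseline,
        behavior_gain=behavior_gain,
        drive_gain=drive_gain,
        window_length=window_length,
        rf_centers=centers,
        rf_sigmas=sigmas,
        polarity=polarity,
    )


def perturb_model(
    model: LNPEncoder,
    seed: int,
    center_jitter: float = 0.4,
    sigma_jitter: float = 0.1,
    baseline_jitter: float = 0.03,
    gain_jitter: float = 0.02,
) -> LNPEncoder:
    """An imperfect instance of the same population.

    Emulates the model-to-model variability of independently trained encoder
    instances: every instance describes the same neurons, but with slightly
    displaced RF centers, rescaled RF sizes and perturbed baselines/behavior
    weights. Ensembling across such instances averages out the
    instance-specific error, which is the effect the ensembling experiments
    measure.
    """
    if model.rf_centers is None or model.rf_sigmas is None or model.polarity is None:
        raise ValueError("model lacks ground-truth RF parameters to perturb")
    rng = np.random.default_rng(seed)
    n = model.n_neurons
    centers = model.rf_centers + rng.normal(0.0, center_jitter, size=(n, 2))
    H, W = model.frame_shape
    centers[:, 0] = np.clip(centers[:, 0], 0, H - 1)
    centers[:, 1] = np.clip(centers[:, 1], 0, W - 1)
    sigmas = model.rf_sigmas * np.exp(rng.normal(0.0, sigma_jitter, size=n))
    rf_maps = _build_rf_maps(centers, sigmas, model.polarity, model.frame_shape)
    return LNPEncoder(
        rf_maps=rf_maps,
        kernels=model.kernels,
        baseline=model.baseline + rng.normal(0.0, baseline_jitter, size=n),
        behavior_gain=model.behavior_gain + rng.normal(0.0, gain_jitter, size=(n, 4)),
        drive_gain=model.drive_gain,
        window_length=model.window_length,
        rf_centers=centers,
        rf_sigmas=sigmas,
        polarity=model.polarity,
    )


def predict(model: EncoderModel, video: Video, behavior: BehaviorTrace) -> ResponseMatrix:
    return model.predict(video, behavior)


def input_gradient(
    model: EncoderModel,
    video: Video,
    behavior: BehaviorTrace,
    target: "ResponseMatrix | np.ndarray",
    loss: str = "poisson_nll",
) -> np.ndarray:
    return model.input_gradient(video, behavior, target, loss)


def sample_poisson(rates: "ResponseMatrix | np.ndarray", seed: int) -> ResponseMatrix:
    """Independent Poisson draws per (neuron, frame), reproducible by seed."""
    r = _response_values(rates)
    if r.min() < 0:
        raise ValueError("rates must be >= 0")
    rng = np.random.default_rng(seed)
    return ResponseMatrix(rng.poisson(r).astype(float))


# ---- HDF5 (de)serialization ---------------------------------------------


def save_encoder(model: LNPEncoder, path) -> None:
    import h5py

    with h5py.File(path, "w") as f:
        g = f.create_group("lnp_encoder")
        for name in ("rf_maps", "kernels", "baseline", "behavior_gain"):
            g.create_dataset(name, data=getattr(model, name))
        for name in ("rf_centers", "rf_sigmas", "polarity"):
            v = getattr(model, name)
            if v is not None:
                g.create_dataset(name, data=v)
        g.attrs["drive_gain"] = model.drive_gain
        g.attrs["window_length"] = model.window_length


def load_encoder(path) -> LNPEncoder:
    import h5py

    with h5py.File(path, "r") as f:
        if "lnp_encoder" not in f:
            raise KeyError("missing required group 'lnp_encoder'")
        g = f["lnp_encoder"]
        opt = {
            name: (g[name][()] if name in g else None)
            for name in ("rf_centers", "rf_sigmas", "polarity")
        }
        return LNPEncoder(
            rf_maps=g["rf_maps"][()],
            kernels=g["kernels"][()],
            baseline=g["baseline"][()],
            behavior_gain=g["behavior_gain"][()],
            drive_gain=float(g.attrs["drive_gain"]),
            window_length=int(g.attrs["window_length"]),
            **opt,
        )
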