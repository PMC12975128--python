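"""Session container, resampling, provenance and seeding utilities.

A Session bundles everything one experiment touches -- stimuli, behavior,
responses, masks, reconstructions and metric reports -- in a single HDF5 file
with provenance (config hash, seeds, code version) so every derived artifact
is reproducible from the file alone.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field

import h5py
import numpy as np

from stimrecon.encoder import ResponseMatrix
from stimrecon.mask import TransparencyMask
from stimrecon.stimuli import BehaviorTrace, Video

__all__ = [
    "Session",
    "SessionFormatError",
    "save_session",
    "load_session",
    "resample_to_frames",
    "config_hash",
    "spawn_seeds",
]

FORMAT_VERSION = 1
_REQUIRED_GROUPS = (
    "videos",
    "behaviors",
    "responses",
    "masks",
    "reconstructions",
    "metrics",
)


class SessionFormatError(RuntimeError):
    """Raised for unreadable or incompatible session files."""


@dataclass
class Session:
    videos: dict[str, Video] = field(default_factory=dict)
    behaviors: dict[str, BehaviorTrace] = field(default_factory=dict)
    responses: dict[str, ResponseMatrix] = field(default_factory=dict)
    masks: dict[str, TransparencyMask] = field(default_factory=dict)
    reconstructions: dict[str, Video] = field(default_factory=dict)
    metrics: dict[str, dict] = field(default_factory=dict)
    provenance: dict = field(default_factory=dict)

    def validate(self) -> None:
        """Responses sharing a trial id with a video must match its length."""
        for tid, resp in self.responses.items():
            if tid in self.videos and resp.n_frames != self.videos[tid].n_frames:
                raise ValueError(
                    f"response {tid!r} has {resp.n_frames} frames but its video "
                    f"has {self.videos[tid].n_frames}"
                )


def config_hash(config: dict) -> str:
    """Stable sha256 of a JSON-serializable configuration."""
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()


def spawn_seeds(seed: int, n: int) -> list[int]:
    """Fan one global seed out into n recorded child seeds (< 2**31)."""
    ss = np.random.SeedSequence(seed)
    return [int(s) % (2**31) for s in ss.generate_state(n)]


def save_session(session: Session, path) -> None:
    """Write the session to HDF5 (videos as uint8, responses as float32)."""
    session.validate()
    with h5py.File(path, "w") as f:
        f.attrs["format_version"] = FORMAT_VERSION
        g = f.create_group("videos")
        for tid, v in session.videos.items():
            d = g.create_dataset(tid, data=np.round(v.frames).astype(np.uint8))
            d.attrs["frame_rate"] = v.frame_rate
        g = f.create_group("behaviors")
        for tid, b in session.behaviors.items():
            g.create_dataset(tid, data=b.as_array())
        g = f.create_group("responses")
        for tid, r in session.responses.items():
            d = g.create_dataset(tid, data=r.values.astype(np.float32))
            d.attrs["neuron_ids"] = np.asarray(r.neuron_ids)
        g = f.create_group("masks")
        for tid, m in session.masks.items():
            d = g.create_dataset(tid, data=m.alpha)
            d.attrs["provenance"] = json.dumps(m.provenance, default=str)
        g = f.create_group("reconstructions")
        for tid, v in session.reconstructions.items():
            d = g.create_dataset(tid, data=v.frames)  # keep float precision
            d.attrs["frame_rate"] = v.frame_rate
        g = f.create_group("metrics")
        for tid, rep in session.metrics.items():
            g.attrs[tid] = json.dumps(rep, default=str)
        g = f.create_group("provenance")
        for k, v in session.provenance.items():
            g.attrs[k] = json.dumps(v, default=str)


def load_session(path) -> Session:
    """Read a session back; a lossless round trip of arrays and metadata."""
    with h5py.File(path, "r") as f:
        version = f.attrs.get("format_version")
        if version != FORMAT_VERSION:
            raise SessionFormatError(
                f"incompatible session format: found {version!r}, "
                f"expected {FORMAT_VERSION}"
            )
        for name in _REQUIRED_GROUPS:
            if name not in f:
                raise SessionFormatError(f"missing required group {name!r}")
        s = Session()
        for tid, d in f["videos"].items():
            s.videos[tid] = Video(d[()].astype(float), float(d.attrs["frame_rate"]))
        for tid, d in f["behaviors"].items():
            arr = d[()]
            s.behaviors[tid] = BehaviorTrace(*arr)
        for tid, d in f["responses"].items():
            s.responses[tid] = ResponseMatrix(
                d[()].astype(float), d.attrs["neuron_ids"]
            )
        for tid, d in f["masks"].items():
            s.masks[tid] = TransparencyMask(d[()], json.loads(d.attrs["provenance"]))
        for tid, d in f["reconstructions"].items():
            s.reconstructions[tid] = Video.unchecked(
                d[()], float(d.attrs["frame_rate"])
            )
        for tid in f["metrics"].attrs:
            s.metrics[tid] = json.loads(f["metrics"].attrs[tid])
        if "provenance" in f:
            for k in f["provenance"].attrs:
                s.provenance[k] = json.loads(f["provenance"].attrs[k])
        return s


def resample_to_frames(
    timestamps: np.ndarray,
    values: np.ndarray,
    n_frames: int,
    frame_rate: float = 30.0,
    t0: float | None = None,
) -> np.ndarray:
    """Linearly interpolate a time series onto the 30 Hz frame grid.

    Frame times are t0 + k/frame_rate; endpoints are held constant outside
    the source's support (np.interp convention).
    """
    t = np.asarray(timestamps, dtype=float).ravel()
    v = np.asarray(values, dtype=float).ravel()
    if t.size == 0:
        raise ValueError("empty trace")
    if t.size != v.size:
        raise ValueError("timestamps and values must have equal length")
    if np.any(np.diff(t) < 0):
        raise ValueError("timestamps must be monotone non-decreasing")
    start = t[0] if t0 is None else t0
    grid = start + np.arange(n_frames) / frame_rate
    return np.interp(grid, t, v)
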