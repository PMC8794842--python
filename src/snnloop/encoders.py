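"""Input encoders: images and event streams to spike batches.

Grayscale images are converted to a spike-latency code: each pixel drives a
virtual LIF input unit with constant current proportional to its intensity
``x``, which fires once at ``t = tau_in * ln(x / (x - theta_in))`` if
``x > theta_in`` and never otherwise — brighter pixels spike earlier.

Event datasets (e.g. the Spiking Heidelberg Digits HDF5 layout with per-sample
spike times and channel indices) are reduced to the substrate's input
dimensionality by channel subsampling, rescaled in time to model units, and
optionally augmented by stochastic channel jitter, which is applied on the
*full-resolution* channels before subsampling.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import List, Optional, Sequence, Tuple

import h5py
import numpy as np
from scipy import ndimage

__all__ = [
    "SpikeBatch",
    "LatencyCodeSpec",
    "latency_encode",
    "downscale_image",
    "subsample_channels",
    "scale_time",
    "jitter_channels",
    "rotate_images",
]


@dataclass
class SpikeBatch:
    """Batched input spikes: raw ``(times, channels)`` events per sample plus
    a dense binary time-by-channel grid view.

    ``duration`` is the simulation window in model time units and ``dt`` the
    grid step; events must satisfy ``0 <= time < duration`` and
    ``0 <= channel < n_channels``.  Events are assigned to grid bins by
    ``floor(time / dt)``.
    """

    events: List[Tuple[np.ndarray, np.ndarray]]
    n_channels: int
    duration: float
    dt: float = 1.0

    def __post_init__(self) -> None:
        clean = []
        for times, chans in self.events:
            times = np.asarray(times, dtype=float)
            chans = np.asarray(chans, dtype=np.int64)
            if times.shape != chans.shape:
                raise ValueError("times and channels must have equal length")
            if times.size and (times.min() < 0 or times.max() >= self.duration):
                raise ValueError("event times must lie in [0, duration)")
            if chans.size and (chans.min() < 0 or chans.max() >= self.n_channels):
                raise ValueError("channel index out of range")
            order = np.argsort(times, kind="stable")
            clean.append((times[order], chans[order]))
        self.events = clean

    def __len__(self) -> int:
        return len(self.events)

    @property
    def n_steps(self) -> int:
        return int(round(self.duration / self.dt))

    @property
    def dense(self) -> np.ndarray:
        """Binary grid ``[batch, n_steps, n_channels]``."""
        T = self.n_steps
        out = np.zeros((len(self.events), T, self.n_channels), dtype=np.uint8)
        for b, (times, chans) in enumerate(self.events):
            if times.size:
                bins = np.minimum((times / self.dt).astype(int), T - 1)
                out[b, bins, chans] = 1
        return out

    @classmethod
    def from_dense(cls, dense: np.ndarray, dt: float = 1.0) -> "SpikeBatch":
        dense = np.asarray(dense)
        B, T, C = dense.shape
        events = []
        for b in range(B):
            t_idx, c_idx = np.nonzero(dense[b])
            events.append((t_idx * dt, c_idx))
        return cls(events, n_channels=C, duration=T * dt, dt=dt)

    def subset(self, idx: Sequence[int]) -> "SpikeBatch":
        return replace(self, events=[self.events[i] for i in idx])

    # -- SHD-style HDF5 layout -------------------------------------------------

    def to_hdf5(self, path, labels: Optional[np.ndarray] = None) -> None:
        """Write in the event-dataset layout: ``spikes/times``,
        ``spikes/units`` (variable-length arrays) and ``labels``."""
        vlen_f = h5py.special_dtype(vlen=np.dtype("float64"))
        vlen_i = h5py.special_dtype(vlen=np.dtype("int64"))
        with h5py.File(path, "w") as f:
            g = f.create_group("spikes")
            dt_ds = g.create_dataset("times", (len(self),), dtype=vlen_f)
            du_ds = g.create_dataset("units", (len(self),), dtype=vlen_i)
            for b, (times, chans) in enumerate(self.events):
                dt_ds[b] = times
                du_ds[b] = chans
            f.create_dataset(
                "labels",
                data=np.zeros(len(self), np.int64) if labels is None else np.asarray(labels),
            )
            f.attrs["n_channels"] = self.n_channels
            f.attrs["duration"] = self.duration
            f.attrs["dt"] = self.dt

    @classmethod
    def from_hdf5(cls, path, n_channels=None, duration=None, dt=None):
        """Read an event dataset; returns ``(SpikeBatch, labels)``.

        Layout attributes are used when present; for foreign files the
        geometry must be supplied explicitly.
        """
        with h5py.File(path, "r") as f:
            times = [np.asarray(t, dtype=float) for t in f["spikes"]["times"][()]]
            units = [np.asarray(u, dtype=np.int64) for u in f["spikes"]["units"][()]]
            labels = f["labels"][()]
            n_channels = int(f.attrs.get("n_channels", n_channels or 0))
            duration = float(f.attrs.get("duration", duration or 0.0))
            dt = float(f.attrs.get("dt", dt or 1.0))
        if not n_channels:
            n_channels = int(max(u.max() for u in units if u.size) + 1)
        if not duration:
            duration = float(max(t.max() for t in times if t.size)) + dt
        batch = cls(list(zip(times, units)), n_channels, duration, dt)
        return batch, labels


# ---------------------------------------------------------------------------
# latency coding of images
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class LatencyCodeSpec:
    """Spike-latency code parameters: input time constant ``tau_in``, input
    threshold ``theta_in`` (fraction of full intensity that must be exceeded
    for a spike at all) and a cutoff ``t_max`` past which late spikes are
    dropped."""

    tau_in: float = 20.0
    theta_in: float = 0.2
    t_max: float = 60.0

    def __post_init__(self) -> None:
        if self.tau_in <= 0:
            raise ValueError("tau_in must be positive")
        if not (0 < self.theta_in < 1):
            raise ValueError("theta_in must lie in (0, 1)")


def latency_time(x: np.ndarray, spec: LatencyCodeSpec) -> np.ndarray:
    """Spike time of the latency code; infinity for ``x <= theta_in``."""
    x = np.asarray(x, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = spec.tau_in * np.log(x / (x - spec.theta_in))
    return np.where(x > spec.theta_in, t, np.inf)


def latency_encode(
    pixels: np.ndarray,
    spec: LatencyCodeSpec = LatencyCodeSpec(),
    dt: float = 1.0,
    duration: Optional[float] = None,
) -> SpikeBatch:
    """Encode intensities in [0, 1] as one spike per sufficiently bright pixel.

    ``pixels`` may be ``[B, h, w]`` or ``[B, n]``; channels follow the
    flattened pixel order.  Spike time is strictly decreasing in intensity,
    so bright pixels fire first.  Spikes at or beyond ``min(t_max, duration)``
    are dropped.
    """
    px = np.asarray(pixels, dtype=float)
    if px.ndim == 3:
        px = px.reshape(px.shape[0], -1)
    if px.ndim != 2:
        raise ValueError("pixels must be [batch, n] or [batch, h, w]")
    if px.min() < 0 or px.max() > 1:
        raise ValueError("pixel values must lie in [0, 1]")
    duration = spec.t_max if duration is None else duration
    cutoff = min(spec.t_max, duration)
    t = latency_time(px, spec)
    events = []
    for b in range(px.shape[0]):
        keep = np.isfinite(t[b]) & (t[b] < cutoff)
        events.append((t[b][keep], np.nonzero(keep)[0]))
    return SpikeBatch(events, n_channels=px.shape[1], duration=duration, dt=dt)


# ---------------------------------------------------------------------------
# image preprocessing
# ---------------------------------------------------------------------------


def load_images_npz(path) -> Tuple[np.ndarray, np.ndarray]:
    """Read a labeled image set from an NPZ archive with ``images`` and
    ``labels`` arrays (the format ``snnloop make-data`` writes)."""
    with np.load(path) as f:
        return f["images"], f["labels"]


def _area_average_operator(n_src: int, n_dst: int) -> np.ndarray:
    """1D area-averaging resampling matrix (rows sum to 1)."""
    A = np.zeros((n_dst, n_src))
    ratio = n_src / n_dst
    for i in range(n_dst):
        lo, hi = i * ratio, (i + 1) * ratio
        for j in range(int(np.floor(lo)), int(np.ceil(hi))):
            overlap = min(hi, j + 1) - max(lo, j)
            if overlap > 0:
                A[i, j] = overlap / ratio
    return A


def downscale_image(img: np.ndarray) -> np.ndarray:
    """28x28 -> 16x16: crop the two outermost pixel rows/columns on every side
    and resample the remaining 24x24 region by area averaging (intensity
    preserving; output stays in [0, 1] for inputs in [0, 1])."""
    img = np.asarray(img, dtype=float)
    single = img.ndim == 2
    if single:
        img = img[None]
    if img.shape[-2:] != (28, 28):
        raise ValueError("expected 28x28 images")
    cropped = img[:, 2:26, 2:26]
    A = _area_average_operator(24, 16)
    out = np.einsum("ij,bjk,lk->bil", A, cropped, A)
    return out[0] if single else out


def rotate_images(
    images: np.ndarray, max_deg: float, seed: int
) -> np.ndarray:
    """Augment by per-image rotation with a uniform angle in
    ``[-max_deg, +max_deg]`` (bilinear resampling, frame preserved)."""
    rng = np.random.default_rng(seed)
    images = np.asarray(images, dtype=float)
    out = np.empty_like(images)
    angles = rng.uniform(-max_deg, max_deg, size=images.shape[0])
    for b in range(images.shape[0]):
        out[b] = ndimage.rotate(
            images[b], angles[b], reshape=False, order=1, mode="constant", cval=0.0
        )
    return np.clip(out, 0.0, 1.0)


# ---------------------------------------------------------------------------
# event-stream preprocessing
# ---------------------------------------------------------------------------


def subsample_channels(batch: SpikeBatch, n_skip: int = 70, stride: int = 9) -> SpikeBatch:
    """Keep source channels ``c >= n_skip`` with ``(c - n_skip) % stride == 0``
    and remap them contiguously to ``0..n_kept-1``; all other events are
    dropped.  With the defaults and 700 source channels, exactly 70 channels
    survive."""
    kept = np.arange(n_skip, batch.n_channels, stride)
    n_kept = kept.size
    remap = -np.ones(batch.n_channels, dtype=np.int64)
    remap[kept] = np.arange(n_kept)
    events = []
    for times, chans in batch.events:
        new = remap[chans]
        sel = new >= 0
        events.append((times[sel], new[sel]))
    return SpikeBatch(events, n_channels=n_kept, duration=batch.duration, dt=batch.dt)


def scale_time(batch: SpikeBatch, factor: float) -> SpikeBatch:
    """Divide all event times (and the window) by ``factor`` — converts
    dataset seconds to substrate model time.  Order preserving."""
    if factor <= 0:
        raise ValueError("factor must be positive")
    events = [(times / factor, chans) for times, chans in batch.events]
    return SpikeBatch(
        events, batch.n_channels, duration=batch.duration / factor, dt=batch.dt
    )


def preprocess_events(
    batch: SpikeBatch,
    jitter_sigma: float = 0.0,
    seed: int = 0,
    n_skip: int = 70,
    stride: int = 9,
    time_factor: float = 1.0,
) -> SpikeBatch:
    """Standard event-dataset pipeline: channel-jitter augmentation on the
    full-resolution channels, then channel subsampling, then time scaling.
    The augmentation-before-subsampling order is load-bearing: jittered
    events can move onto (or off) the retained channel grid."""
    if jitter_sigma > 0:
        batch = jitter_channels(batch, jitter_sigma, seed)
    batch = subsample_channels(batch, n_skip=n_skip, stride=stride)
    if time_factor != 1.0:
        batch = scale_time(batch, time_factor)
    return batch


def jitter_channels(batch: SpikeBatch, sigma: float, seed: int) -> SpikeBatch:
    """Reassign each event to a neighbouring channel drawn from
    ``Normal(mu=channel, sigma)``, rounded half away from zero and clipped to
    the valid range.  Event count is preserved; deterministic given the seed.
    Applied to full-resolution data *before* channel subsampling."""
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    if sigma == 0:
        return batch
    rng = np.random.default_rng(seed)
    events = []
    for times, chans in batch.events:
        drawn = rng.normal(chans.astype(float), sigma)
        new = np.floor(drawn + 0.5).astype(np.int64)  # half away from zero (c >= 0)
        new = np.clip(new, 0, batch.n_channels - 1)
        events.append((times, new))
    return SpikeBatch(events, batch.n_channels, batch.duration, batch.dt)
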