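"""Synthetic desk-scale datasets with the statistical structure of the
benchmark tasks.

Two task families are generated, matching the two input kinds the encoders
support:

* ``latency_images`` — class-structured grayscale patterns in [0, 1]
  (smooth random blobs, one prototype per class, enforced pairwise
  separation) with per-sample pixel noise and optional rotation; encoded by
  the spike-latency code.  Stands in for downscaled handwritten-digit images.
* ``temporal_patterns`` — class-specific spatiotemporal spike motifs across
  the input channels with timing jitter, channel jitter, event deletions and
  background activity.  Classes 0 and 1 form an order-sensitive pair: the
  same channels and the same per-channel spike counts, but reversed temporal
  order, so any readout relying on rates alone cannot separate them —
  distinguishing them requires temporal integration (e.g. recurrence).
  Stands in for event-based speech data.

Generators are pure functions of ``(spec, seed)``; the defaults are sized so
that full training experiments complete in minutes on one CPU.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Tuple

import numpy as np
from scipy import ndimage

from .encoders import SpikeBatch, jitter_channels, rotate_images

__all__ = [
    "SyntheticTaskSpec",
    "make_latency_images",
    "make_temporal_patterns",
    "train_test_split",
]


@dataclass(frozen=True)
class SyntheticTaskSpec:
    """Declarative description of a synthetic dataset.

    ``n_channels`` is the number of pixels (latency task; factored into a
    near-square image shape) or input channels (temporal task).  Noise levels:
    ``pixel_noise_sd`` (latency), ``time_jitter_sd`` / ``channel_jitter_sd`` /
    ``deletion_p`` / ``background_events`` (temporal).
    """

    task: str = "latency_images"
    n_classes: int = 10
    n_channels: int = 256
    samples_per_class: int = 100
    pixel_noise_sd: float = 0.12
    rotation_max_deg: float = 0.0
    time_jitter_sd: float = 2.0
    channel_jitter_sd: float = 0.5
    deletion_p: float = 0.1
    background_events: float = 4.0
    anchors_per_class: int = 24
    duration: float = 100.0
    dt: float = 1.0
    min_prototype_distance: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.task not in ("latency_images", "temporal_patterns"):
            raise ValueError("unknown task kind")
        if self.n_classes < 2 or self.samples_per_class < 1:
            raise ValueError("need n_classes >= 2 and samples_per_class >= 1")


def _image_shape(n_pixels: int) -> Tuple[int, int]:
    """Factor a pixel count into the most square (h, w) grid."""
    h = int(np.sqrt(n_pixels))
    while h > 1 and n_pixels % h:
        h -= 1
    return h, n_pixels // h


def _blob_prototype(shape: Tuple[int, int], rng: np.random.Generator) -> np.ndarray:
    """Smooth random pattern in [0, 1] with decent bright coverage."""
    raw = rng.normal(size=shape)
    smooth = ndimage.gaussian_filter(raw, sigma=max(min(shape) / 8.0, 1.0))
    lo, hi = smooth.min(), smooth.max()
    return (smooth - lo) / (hi - lo + 1e-12)


def make_latency_images(spec: SyntheticTaskSpec) -> Tuple[np.ndarray, np.ndarray]:
    """Generate labeled images; returns ``(images [N, h, w], labels [N])``.

    Per class a smooth blob prototype is drawn (resampled until it is at
    least ``min_prototype_distance`` away in L2 from every earlier prototype);
    samples add i.i.d. Gaussian pixel noise, optional rotation, and are
    clipped back to [0, 1].
    """
    rng = np.random.default_rng(spec.seed)
    shape = _image_shape(spec.n_channels)
    protos = []
    for _ in range(spec.n_classes):
        for attempt in range(200):
            cand = _blob_prototype(shape, rng)
            if all(np.linalg.norm(cand - p) >= spec.min_prototype_distance for p in protos):
                break
        else:
            raise RuntimeError("could not draw separated prototypes; lower the margin")
        protos.append(cand)

    images, labels = [], []
    for c, proto in enumerate(protos):
        noise = rng.normal(0.0, spec.pixel_noise_sd, size=(spec.samples_per_class,) + shape)
        images.append(np.clip(proto[None] + noise, 0.0, 1.0))
        labels.append(np.full(spec.samples_per_class, c, dtype=int))
    X = np.concatenate(images)
    y = np.concatenate(labels)
    if spec.rotation_max_deg > 0:
        X = rotate_images(X, spec.rotation_max_deg, seed=spec.seed + 1)
    perm = np.random.default_rng(spec.seed + 2).permutation(len(y))
    return X[perm], y[perm]


def make_temporal_patterns(spec: SyntheticTaskSpec) -> Tuple[SpikeBatch, np.ndarray]:
    """Generate labeled spatiotemporal spike patterns.

    Each class is a fixed set of ``(channel, time)`` anchor events inside the
    central 80% of the window.  Classes come in order-sensitive pairs: class
    ``2k+1`` shares channels with class ``2k`` but has time-reversed anchors
    (identical per-channel counts).  Samples perturb
    anchors by Gaussian timing jitter and channel jitter, delete events with
    probability ``deletion_p``, and add uniformly scattered background events
    (Poisson count with mean ``background_events``).
    """
    rng = np.random.default_rng(spec.seed)
    C, D = spec.n_channels, spec.duration
    t_lo, t_hi = 0.1 * D, 0.9 * D

    # classes come in time-reversed pairs: each pair shares channels and
    # per-channel spike counts, differing only in temporal order, so the
    # task cannot be solved from rates alone
    anchors = []
    while len(anchors) < spec.n_classes:
        chans = rng.choice(C, size=spec.anchors_per_class, replace=True)
        times = rng.uniform(t_lo, t_hi, size=spec.anchors_per_class)
        anchors.append((times, chans))
        if len(anchors) < spec.n_classes:
            anchors.append((t_lo + t_hi - times, chans))

    events, labels = [], []
    for c, (a_times, a_chans) in enumerate(anchors):
        for _ in range(spec.samples_per_class):
            times = a_times + rng.normal(0.0, spec.time_jitter_sd, size=a_times.size)
            chans = a_chans.copy()
            keep = rng.random(times.size) >= spec.deletion_p
            times, chans = times[keep], chans[keep]
            n_bg = rng.poisson(spec.background_events)
            if n_bg:
                times = np.concatenate([times, rng.uniform(0, D, size=n_bg)])
                chans = np.concatenate([chans, rng.integers(0, C, size=n_bg)])
            times = np.clip(times, 0.0, np.nextafter(D, 0.0) - 1e-9)
            events.append((times, chans))
            labels.append(c)

    batch = SpikeBatch(events, n_channels=C, duration=D, dt=spec.dt)
    if spec.channel_jitter_sd > 0:
        batch = jitter_channels(batch, spec.channel_jitter_sd, seed=spec.seed + 3)
    y = np.asarray(labels, dtype=int)
    perm = np.random.default_rng(spec.seed + 4).permutation(len(y))
    return batch.subset(perm), y[perm]


def _shift_domain(X, seed: int, extra_noise: float):
    """Emulate domain shift by perturbing held-out samples with additional
    noise beyond the training regime (unseen-source structure)."""
    rng = np.random.default_rng(seed)
    if isinstance(X, SpikeBatch):
        events = []
        for times, chans in X.events:
            t = np.clip(
                times + rng.normal(0.0, extra_noise, size=times.size),
                0.0,
                np.nextafter(X.duration, 0.0),
            )
            events.append((t, chans))
        return replace(X, events=events)
    Xs = np.clip(X + rng.normal(0.0, extra_noise, size=np.shape(X)), 0.0, 1.0)
    return Xs


def train_test_split(
    X,
    y: np.ndarray,
    held_out_fraction: float,
    seed: int = 0,
    disjoint_variant: bool = False,
    shift_amount: float = None,
):
    """Random split into train and test partitions.

    ``X`` may be an array of images or a :class:`SpikeBatch`.  With
    ``disjoint_variant`` the held-out samples are additionally perturbed by
    ``shift_amount`` extra noise (pixel SD for images, timing SD for spikes;
    defaults 0.1 / 3.0), emulating evaluation on a shifted data regime such
    as speakers absent from the training set.
    """
    if not 0 <= held_out_fraction <= 1:
        raise ValueError("held_out_fraction must lie in [0, 1]")
    n = len(y)
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    n_test = int(round(held_out_fraction * n))
    test_idx, train_idx = perm[:n_test], perm[n_test:]

    def take(idx):
        return X.subset(idx) if isinstance(X, SpikeBatch) else X[idx]

    X_train, X_test = take(train_idx), take(test_idx)
    if disjoint_variant and n_test:
        if shift_amount is None:
            shift_amount = 3.0 if isinstance(X, SpikeBatch) else 0.1
        X_test = _shift_domain(X_test, seed + 1, shift_amount)
    return X_train, X_test, y[train_idx], y[test_idx]
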