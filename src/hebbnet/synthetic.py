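"""Synthetic labeled datasets for training and testing without downloads.

The toy image generator stamps a class-specific oriented pattern at
several jittered grid positions per image, so that the same local
structure recurs across space — the statistical property that lets
untied locally connected layers develop spatially similar filters.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "ToyDatasetConfig",
    "make_toy_dataset",
    "class_pattern",
    "linearly_separable_dataset",
    "split",
]


@dataclass
class ToyDatasetConfig:
    n_classes: int = 3
    image_size: int = 16
    channels: int = 1
    n_per_class: int = 500
    pattern_size: int = 5
    stamps_per_image: int = 4
    jitter: int = 1
    noise_sd: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_classes < 2:
            raise ValueError("need at least 2 classes")
        cell = self.image_size // 2
        if self.pattern_size + 2 * self.jitter > cell:
            raise ValueError(
                "pattern plus maximal jitter does not fit in a grid cell "
                f"(pattern {self.pattern_size}, jitter {self.jitter}, "
                f"cell {cell})"
            )


def class_pattern(c: int, size: int, channels: int) -> np.ndarray:
    """Deterministic oriented pattern for class c: a bar at a class angle.

    Angles are spread over [0, pi); pixel intensity falls off with
    distance from the bar's axis, giving each class a distinct local
    edge orientation.
    """
    # golden-angle spacing keeps orientations well separated for any
    # number of classes
    angle = (c * np.deg2rad(137.507764)) % np.pi
    yy, xx = np.mgrid[0:size, 0:size].astype(float)
    cy = cx = (size - 1) / 2.0
    # signed distance from the line through the center at `angle`
    d = (yy - cy) * np.cos(angle) - (xx - cx) * np.sin(angle)
    bar = np.clip(1.0 - np.abs(d), 0.0, 1.0)
    if c >= 8:  # more classes than angles: alternate polarity pattern
        bar = bar * np.sign(np.cos(np.pi * (xx + yy) / 2.0) + 0.5)
        bar = np.clip(bar, 0.0, 1.0)
    return np.broadcast_to(bar, (channels, size, size)).copy()


def make_toy_dataset(
    config: ToyDatasetConfig,
) -> tuple[np.ndarray, np.ndarray]:
    """Images ``(N, channels, S, S)`` in [0, 1] and integer labels ``(N,)``.

    Each image stamps its class pattern at up to ``stamps_per_image``
    jittered anchor positions on a 2x2 grid of cells, adds Gaussian
    noise, and clips.  Classes are exactly balanced; everything is
    deterministic under the seed.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    s = cfg.image_size
    n = cfg.n_classes * cfg.n_per_class
    images = np.zeros((n, cfg.channels, s, s))
    labels = np.repeat(np.arange(cfg.n_classes), cfg.n_per_class)
    patterns = [
        class_pattern(c, cfg.pattern_size, cfg.channels)
        for c in range(cfg.n_classes)
    ]
    cell = s // 2
    anchors = [
        (gy * cell + (cell - cfg.pattern_size) // 2,
         gx * cell + (cell - cfg.pattern_size) // 2)
        for gy in range(2)
        for gx in range(2)
    ]
    ps = cfg.pattern_size
    for i in range(n):
        pat = patterns[labels[i]]
        k = min(cfg.stamps_per_image, len(anchors))
        chosen = rng.choice(len(anchors), size=k, replace=False)
        for a in chosen:
            ay, ax = anchors[a]
            if cfg.jitter > 0:
                ay += rng.integers(-cfg.jitter, cfg.jitter + 1)
                ax += rng.integers(-cfg.jitter, cfg.jitter + 1)
            ay = int(np.clip(ay, 0, s - ps))
            ax = int(np.clip(ax, 0, s - ps))
            images[i, :, ay : ay + ps, ax : ax + ps] += pat
        if cfg.noise_sd > 0:
            images[i] += rng.normal(0.0, cfg.noise_sd, images[i].shape)
    np.clip(images, 0.0, 1.0, out=images)
    return images, labels


def linearly_separable_dataset(
    n_features: int,
    n_classes: int,
    margin: float,
    n: int,
    seed: int = 0,
    spread: float = 0.1,
) -> tuple[np.ndarray, np.ndarray]:
    """Gaussian blobs at scaled one-hot class means (for dense-layer tests).

    With ``margin`` well above ``spread`` the classes are separable and
    hinge-type training drives the error to ~0.
    """
    if margin <= 0:
        raise ValueError("margin must be positive")
    if n_classes > n_features:
        raise ValueError("need n_features >= n_classes for one-hot means")
    rng = np.random.default_rng(seed)
    labels = np.arange(n) % n_classes
    means = np.zeros((n_classes, n_features))
    means[np.arange(n_classes), np.arange(n_classes)] = margin
    x = means[labels] + rng.normal(0.0, spread, (n, n_features))
    return x, labels


def split(
    dataset: tuple[np.ndarray, np.ndarray],
    val_fraction: float,
    seed: int = 0,
) -> tuple[tuple[np.ndarray, np.ndarray], tuple[np.ndarray, np.ndarray]]:
    """Disjoint, seeded, class-stratified train/validation split."""
    if not 0.0 < val_fraction < 1.0:
        raise ValueError("val_fraction must lie strictly between 0 and 1")
    x, y = dataset
    rng = np.random.default_rng(seed)
    train_idx, val_idx = [], []
    for c in np.unique(y):
        idx = np.nonzero(y == c)[0]
        idx = rng.permutation(idx)
        n_val = int(round(val_fraction * len(idx)))
        val_idx.append(idx[:n_val])
        train_idx.append(idx[n_val:])
    tr = np.sort(np.concatenate(train_idx))
    va = np.sort(np.concatenate(val_idx))
    return (x[tr], y[tr]), (x[va], y[va])
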