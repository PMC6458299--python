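"""Saturated-linear activation, its gate, and the classification losses.

The trainer supports two top-layer error signals:

* a multi-class hinge loss whose derivative is local to each output unit
  (the unit's own activity and the target indicator suffice), and
* the usual softmax / cross-entropy comparator, whose error signal
  requires the softmax normalization across all output units.

Both error signals follow the convention ``delta = -dLoss/dx`` so that
weight updates are ``W += eta * mean(delta x^T)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ClassScores",
    "HingeParams",
    "TargetLabel",
    "satlin",
    "satlin_gate",
    "hinge_loss",
    "hinge_top_error",
    "softmax_ce_error",
    "softmax_ce_loss",
    "top_error",
    "batch_loss",
]


@dataclass(frozen=True)
class HingeParams:
    """Off-class weight ``mu`` of the one-vs-all hinge loss.

    The margin is fixed at 1; ``off_threshold`` is the activity level
    below which an off-class unit stops receiving corrections (-1 by
    default, exposed for experimentation).
    """

    mu: float = 1.0
    off_threshold: float = -1.0

    def __post_init__(self) -> None:
        if self.mu < 0:
            raise ValueError(f"mu must be nonnegative, got {self.mu}")


@dataclass(frozen=True)
class ClassScores:
    """Output-layer activities for one example (no nonlinearity applied)."""

    x_L: np.ndarray

    @property
    def n_classes(self) -> int:
        return int(np.asarray(self.x_L).shape[-1])

    @property
    def p(self) -> np.ndarray:
        """Softmax of the scores (used only by the comparator loss)."""
        return _softmax(np.asarray(self.x_L, dtype=float))


@dataclass(frozen=True)
class TargetLabel:
    """Integer class index plus its one-hot indicator."""

    c: int
    n_classes: int
    y: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        if not 0 <= self.c < self.n_classes:
            raise ValueError(
                f"class index {self.c} out of range [0, {self.n_classes})"
            )
        y = np.zeros(self.n_classes)
        y[self.c] = 1.0
        object.__setattr__(self, "y", y)


def satlin(h: np.ndarray) -> np.ndarray:
    """Saturated linearity: clip to [-1, 1] elementwise."""
    return np.clip(h, -1.0, 1.0)


def satlin_gate(h: np.ndarray) -> np.ndarray:
    """Derivative gate of :func:`satlin`: 1 where ``|h| <= 1``, else 0.

    The boundary is inclusive: a unit sitting exactly at saturation
    still passes error.
    """
    return (np.abs(np.asarray(h)) <= 1.0).astype(float)


def _as_scores(scores) -> np.ndarray:
    x = scores.x_L if isinstance(scores, ClassScores) else scores
    return np.asarray(x, dtype=float)


def _as_label(label, n_classes: int) -> int:
    c = label.c if isinstance(label, TargetLabel) else int(label)
    if not 0 <= c < n_classes:
        raise ValueError(f"class index {c} out of range [0, {n_classes})")
    return c


def hinge_loss(scores, label, params: HingeParams = HingeParams()) -> float:
    """One-vs-all hinge loss with margin 1 and off-class weight mu.

    ``max(1 - x_c, 0) + mu * sum_{i != c} max(1 + x_i, 0)``
    """
    x = _as_scores(scores)
    if x.shape[-1] < 2:
        raise ValueError("hinge loss needs at least 2 classes")
    c = _as_label(label, x.shape[-1])
    on = max(1.0 - x[c], 0.0)
    off = np.maximum(1.0 + x, 0.0)
    off_sum = off.sum() - off[c]
    return float(on + params.mu * off_sum)


def hinge_top_error(
    scores, label, params: HingeParams = HingeParams()
) -> np.ndarray:
    """Local top-layer error signal ``delta_L = -dLoss/dx_L``.

    ``+1`` at the target unit while its activity is <= 1; ``-mu`` at an
    off-class unit while its activity is >= -1; 0 otherwise.  Both
    inequalities are inclusive.  Each entry depends only on that unit's
    activity and the target indicator.
    """
    x = _as_scores(scores)
    c = _as_label(label, x.shape[-1])
    delta = np.where(x >= params.off_threshold, -params.mu, 0.0)
    delta[c] = 1.0 if x[c] <= 1.0 else 0.0
    return delta


def _softmax(x: np.ndarray) -> np.ndarray:
    z = x - x.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def softmax_ce_error(scores, label) -> np.ndarray:
    """Comparator error signal ``y - softmax(x_L)``."""
    x = _as_scores(scores)
    c = _as_label(label, x.shape[-1])
    y = np.zeros_like(x)
    y[c] = 1.0
    return y - _softmax(x)


def softmax_ce_loss(scores, label) -> float:
    """Cross-entropy of the target w.r.t. the softmax of the scores."""
    x = _as_scores(scores)
    c = _as_label(label, x.shape[-1])
    z = x - x.max()
    return float(np.log(np.exp(z).sum()) - z[c])


# Batched dispatch helpers used by the trainer ------------------------------

_LOSSES = {"hinge", "softmax"}


def top_error(
    x_L: np.ndarray, labels: np.ndarray, loss: str, params: HingeParams
) -> np.ndarray:
    """Batched top-layer error signal, rows = examples."""
    if loss not in _LOSSES:
        raise ValueError(f"unknown loss {loss!r}; expected one of {_LOSSES}")
    x = np.atleast_2d(np.asarray(x_L, dtype=float))
    labels = np.asarray(labels, dtype=int)
    n, C = x.shape
    if loss == "softmax":
        y = np.zeros_like(x)
        y[np.arange(n), labels] = 1.0
        return y - _softmax(x)
    delta = np.where(x >= params.off_threshold, -params.mu, 0.0)
    on = (x[np.arange(n), labels] <= 1.0).astype(float)
    delta[np.arange(n), labels] = on
    return delta


def batch_loss(
    x_L: np.ndarray, labels: np.ndarray, loss: str, params: HingeParams
) -> float:
    """Mean loss over a batch of score rows."""
    if loss not in _LOSSES:
        raise ValueError(f"unknown loss {loss!r}; expected one of {_LOSSES}")
    x = np.atleast_2d(np.asarray(x_L, dtype=float))
    labels = np.asarray(labels, dtype=int)
    n = x.shape[0]
    if loss == "softmax":
        z = x - x.max(axis=1, keepdims=True)
        lse = np.log(np.exp(z).sum(axis=1))
        return float(np.mean(lse - z[np.arange(n), labels]))
    on = np.maximum(1.0 - x[np.arange(n), labels], 0.0)
    off = np.maximum(1.0 + x, 0.0)
    off_sum = off.sum(axis=1) - off[np.arange(n), labels]
    return float(np.mean(on + params.mu * off_sum))
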