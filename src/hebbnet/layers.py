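"""Layer primitives: forward, feedback, and Hebbian increment computations.

Every trainable layer owns a feedforward weight array ``W`` and a
*separate* feedback array ``R`` of transposed shape, plus fixed binary
connectivity masks for each.  Feedback never reads ``W`` directly except
in back-propagation mode, where the effective feedback matrix is a
contiguous copy of ``W`` transposed.

Data layout: dense activity is ``(batch, units)``; feature maps are
``(batch, channels, height, width)``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from scipy import sparse

from .activations import satlin_gate

__all__ = [
    "WeightPair",
    "ConvGeometry",
    "dense_forward",
    "dense_feedback",
    "hebbian_increments",
    "conv_forward",
    "conv_feedback",
    "conv_update_tied",
    "conv_to_local",
    "local_forward",
    "local_feedback",
    "local_update",
    "maxpool_forward",
    "maxpool_feedback",
    "dropout_mask",
    "dropout_apply",
    "dropout_feedback",
    "residual_sum_forward",
    "residual_sum_feedback",
    "LocalWeights",
]


@dataclass
class ConvGeometry:
    """Geometry of a tied convolution or its untied counterpart.

    ``same`` zero padding, stride 1.  For odd kernels the window is
    centered; for even kernels the extra tap falls on the bottom/right.
    """

    in_channels: int
    out_channels: int
    kernel: int
    height: int
    width: int

    @property
    def pad(self) -> int:
        return (self.kernel - 1) // 2

    @property
    def in_units(self) -> int:
        return self.in_channels * self.height * self.width

    @property
    def out_units(self) -> int:
        return self.out_channels * self.height * self.width

    @property
    def taps(self) -> int:
        return self.in_channels * self.kernel * self.kernel


@dataclass
class WeightPair:
    """A dense layer's feedforward matrix W, feedback matrix R, and masks.

    ``W`` maps layer l-1 to layer l (shape ``n_l x n_{l-1}``); ``R`` maps
    layer-l errors down (shape ``n_{l-1} x n_l``).  Entries where the
    mask is 0 stay exactly 0 through any number of updates.
    """

    W: np.ndarray
    R: np.ndarray
    mask_W: Optional[np.ndarray] = None
    mask_R: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.W = np.asarray(self.W, dtype=float)
        self.R = np.asarray(self.R, dtype=float)
        if self.W.shape != self.R.shape[::-1]:
            raise ValueError(
                f"W shape {self.W.shape} and R shape {self.R.shape} "
                "are not mutually transposed"
            )
        if self.mask_W is not None:
            self.mask_W = np.asarray(self.mask_W, dtype=float)
            self.W = self.W * self.mask_W
        if self.mask_R is not None:
            self.mask_R = np.asarray(self.mask_R, dtype=float)
            self.R = self.R * self.mask_R

    @property
    def masked_W(self) -> np.ndarray:
        return self.W if self.mask_W is None else self.W * self.mask_W

    @property
    def masked_R(self) -> np.ndarray:
        return self.R if self.mask_R is None else self.R * self.mask_R


def dense_forward(pair: WeightPair, x_prev: np.ndarray) -> np.ndarray:
    """Pre-activation ``h = x_prev @ (W * mask_W)^T``; rows = examples."""
    x_prev = np.asarray(x_prev, dtype=float)
    if x_prev.shape[-1] != pair.W.shape[1]:
        raise ValueError(
            f"input width {x_prev.shape[-1]} != fan-in {pair.W.shape[1]}"
        )
    return x_prev @ pair.masked_W.T


def dense_feedback(
    pair_above: WeightPair, delta_above: np.ndarray, h_here: np.ndarray
) -> np.ndarray:
    """``delta = gate(h) * (delta_above @ (R * mask_R)^T)``.

    ``pair_above`` is the layer above's weights; its R maps errors down
    to this layer.  Saturated units (|h| > 1) pass no error.
    """
    delta_above = np.asarray(delta_above, dtype=float)
    if delta_above.shape[-1] != pair_above.R.shape[1]:
        raise ValueError(
            f"delta width {delta_above.shape[-1]} != "
            f"{pair_above.R.shape[1]}"
        )
    return satlin_gate(h_here) * (delta_above @ pair_above.masked_R.T)


def hebbian_increments(
    delta_here: np.ndarray, x_prev: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Batch-mean outer product ``(dW, dR = dW^T)``.

    ``x_prev`` must be the original feedforward activity of the layer
    below (the feedback signal replaces activity top-down, so the lower
    layer still holds its feedforward value when this fires).
    """
    delta = np.atleast_2d(np.asarray(delta_here, dtype=float))
    x = np.atleast_2d(np.asarray(x_prev, dtype=float))
    dW = delta.T @ x / delta.shape[0]
    return dW, dW.T


# Tied convolution ----------------------------------------------------------


def _im2col(x: np.ndarray, geom: ConvGeometry) -> np.ndarray:
    """Patches of shape ``(batch, taps, H*W)`` from ``(batch, C, H, W)``.

    Zero padding keeps the spatial size; even kernels pad one less on
    the top/left.
    """
    k, p = geom.kernel, geom.pad
    q = k - 1 - p
    xp = np.pad(x, ((0, 0), (0, 0), (p, q), (p, q)))
    win = sliding_window_view(xp, (k, k), axis=(2, 3))
    # win: (B, C, H, W, k, k) -> (B, C*k*k, H*W)
    b = x.shape[0]
    win = win.transpose(0, 1, 4, 5, 2, 3)
    return win.reshape(b, geom.taps, geom.height * geom.width)


def _col2im(cols: np.ndarray, geom: ConvGeometry) -> np.ndarray:
    """Adjoint of :func:`_im2col`: scatter-add patch columns back."""
    b = cols.shape[0]
    k, p, h, w = geom.kernel, geom.pad, geom.height, geom.width
    q = k - 1 - p
    cols = cols.reshape(b, geom.in_channels, k, k, h, w)
    out = np.zeros((b, geom.in_channels, h + k - 1, w + k - 1))
    for dy in range(k):
        for dx in range(k):
            out[:, :, dy : dy + h, dx : dx + w] += cols[:, :, dy, dx]
    return out[:, :, p : p + h, p : p + w]


def conv_forward(
    filterbank: np.ndarray, geom: ConvGeometry, x_prev: np.ndarray
) -> np.ndarray:
    """2-D cross-correlation, "same" zero padding, summed over channels.

    ``filterbank``: ``(out_channels, in_channels, k, k)``;
    ``x_prev``: ``(batch, in_channels, H, W)``.
    """
    f = np.asarray(filterbank, dtype=float)
    x = np.asarray(x_prev, dtype=float)
    if f.shape != (geom.out_channels, geom.in_channels, geom.kernel, geom.kernel):
        raise ValueError(f"filterbank shape {f.shape} inconsistent with geometry")
    if x.shape[1:] != (geom.in_channels, geom.height, geom.width):
        raise ValueError(f"input shape {x.shape} inconsistent with geometry")
    cols = _im2col(x, geom)
    fmat = f.reshape(geom.out_channels, geom.taps)
    h = np.einsum("ot,btp->bop", fmat, cols)
    return h.reshape(x.shape[0], geom.out_channels, geom.height, geom.width)


def conv_feedback(
    feedback_bank: np.ndarray, geom: ConvGeometry, delta: np.ndarray
) -> np.ndarray:
    """Map layer-l errors down through the feedback filter bank.

    The feedback bank has the same shape as the feedforward bank; with
    ``feedback_bank == filterbank`` this is the exact transpose of
    :func:`conv_forward`.  Gate application is the caller's job.
    """
    g = np.asarray(feedback_bank, dtype=float).reshape(geom.out_channels, geom.taps)
    d = np.asarray(delta, dtype=float)
    b = d.shape[0]
    dmat = d.reshape(b, geom.out_channels, geom.height * geom.width)
    cols = np.einsum("ot,bop->btp", g, dmat)
    return _col2im(cols, geom)


def conv_update_tied(
    delta: np.ndarray, x_prev: np.ndarray, geom: ConvGeometry
) -> np.ndarray:
    """Tied filter increment: sum over locations, mean over the batch.

    Each tap accumulates ``sum_i delta[i] * x_prev[i + k]`` across all
    spatial positions i (the tied-weight gradient).
    """
    d = np.asarray(delta, dtype=float)
    x = np.asarray(x_prev, dtype=float)
    b = d.shape[0]
    cols = _im2col(x, geom)
    dmat = d.reshape(b, geom.out_channels, geom.height * geom.width)
    df = np.einsum("bop,btp->ot", dmat, cols) / b
    return df.reshape(geom.out_channels, geom.in_channels, geom.kernel, geom.kernel)


# Untied (locally connected) layers -----------------------------------------


class LocalWeights:
    """Sparse weights with a convolution's connectivity but free values.

    The pattern (which input unit feeds which output unit) is fixed by
    the geometry; every stored entry is an independent synapse.  ``W``
    values live in ``w_data`` ordered like the CSR matrix built from
    (row=out unit, col=in unit); feedback values ``r_data`` share the
    transposed pattern, aligned entry-for-entry with ``w_data``.
    """

    def __init__(self, geom: ConvGeometry, w_data: np.ndarray,
                 r_data: np.ndarray, mask_w: Optional[np.ndarray] = None,
                 mask_r: Optional[np.ndarray] = None):
        self.geom = geom
        rows, cols = _conv_pattern(geom)
        order = np.lexsort((cols, rows))  # CSR order of W
        self.rows = rows[order]
        self.cols = cols[order]
        self.nnz = len(self.rows)
        if len(w_data) != self.nnz or len(r_data) != self.nnz:
            raise ValueError("data length does not match connectivity pattern")
        self.w_data = np.asarray(w_data, dtype=float).copy()
        self.r_data = np.asarray(r_data, dtype=float).copy()
        self.mask_w = (np.ones(self.nnz) if mask_w is None
                       else np.asarray(mask_w, dtype=float).copy())
        self.mask_r = (np.ones(self.nnz) if mask_r is None
                       else np.asarray(mask_r, dtype=float).copy())
        self.w_data *= self.mask_w
        self.r_data *= self.mask_r
        self._w_csr = sparse.csr_matrix(
            (self.w_data, (self.rows, self.cols)),
            shape=(geom.out_units, geom.in_units),
        )
        # R has the transposed pattern; keep the permutation that maps
        # w_data order to R's CSR order so increments stay aligned.
        probe = sparse.csr_matrix(
            (np.arange(self.nnz, dtype=float) + 1.0, (self.cols, self.rows)),
            shape=(geom.in_units, geom.out_units),
        )
        self._r_perm = (probe.data - 1.0).astype(int)
        self._r_csr = probe
        self._refresh_r()
        # tap index of each stored entry, for filter extraction/updates
        self.tap_index = _tap_indices(geom, self.rows, self.cols)

    def _refresh_w(self) -> None:
        self._w_csr.data[:] = self.w_data * self.mask_w

    def _refresh_r(self) -> None:
        self._r_csr.data[:] = (self.r_data * self.mask_r)[self._r_perm]

    @property
    def w_csr(self) -> sparse.csr_matrix:
        self._refresh_w()
        return self._w_csr

    @property
    def r_csr(self) -> sparse.csr_matrix:
        self._refresh_r()
        return self._r_csr

    def r_csr_from(self, data: np.ndarray) -> sparse.csr_matrix:
        """CSR in R's pattern holding arbitrary per-entry ``data``."""
        m = self._r_csr.copy()
        m.data[:] = np.asarray(data, dtype=float)[self._r_perm]
        return m


def _conv_pattern(geom: ConvGeometry) -> tuple[np.ndarray, np.ndarray]:
    """(row, col) index pairs of the sparse matrix a convolution implies."""
    k, p, h, w = geom.kernel, geom.pad, geom.height, geom.width
    oy, ox = np.meshgrid(np.arange(h), np.arange(w), indexing="ij")
    rows, cols = [], []
    for oc in range(geom.out_channels):
        for ic in range(geom.in_channels):
            for dy in range(k):
                for dx in range(k):
                    iy = oy + dy - p
                    ix = ox + dx - p
                    ok = (iy >= 0) & (iy < h) & (ix >= 0) & (ix < w)
                    r = (oc * h + oy[ok]) * w + ox[ok]
                    c = (ic * h + iy[ok]) * w + ix[ok]
                    rows.append(r)
                    cols.append(c)
    return np.concatenate(rows), np.concatenate(cols)


def _tap_indices(geom: ConvGeometry, rows: np.ndarray, cols: np.ndarray) -> np.ndarray:
    """Flat tap index (oc, ic, dy, dx) of every stored sparse entry."""
    k, p, h, w = geom.kernel, geom.pad, geom.height, geom.width
    oc, rrem = np.divmod(rows, h * w)
    oy, ox = np.divmod(rrem, w)
    ic, crem = np.divmod(cols, h * w)
    iy, ix = np.divmod(crem, w)
    dy = iy - oy + p
    dx = ix - ox + p
    return ((oc * geom.in_channels + ic) * k + dy) * k + dx


def conv_to_local(filterbank: np.ndarray, geom: ConvGeometry) -> LocalWeights:
    """Replicate a tied filter bank into untied sparse weights.

    The result's forward map equals :func:`conv_forward` with the bank;
    the feedback values replicate the bank too.
    """
    f = np.asarray(filterbank, dtype=float).ravel()
    rows, cols = _conv_pattern(geom)
    order = np.lexsort((cols, rows))
    taps = _tap_indices(geom, rows[order], cols[order])
    vals = f[taps]
    return LocalWeights(geom, vals, vals.copy())


def local_forward(lw: LocalWeights, x_prev: np.ndarray) -> np.ndarray:
    """Sparse matrix-vector product; ``x_prev`` is ``(batch, C, H, W)``."""
    g = lw.geom
    x = np.asarray(x_prev, dtype=float)
    if x.shape[1:] != (g.in_channels, g.height, g.width):
        raise ValueError(f"input shape {x.shape} inconsistent with geometry")
    flat = x.reshape(x.shape[0], g.in_units)
    h = lw.w_csr @ flat.T
    return h.T.reshape(x.shape[0], g.out_channels, g.height, g.width)


def local_feedback(lw: LocalWeights, delta: np.ndarray) -> np.ndarray:
    """Errors mapped down through the untied feedback values (no gate)."""
    g = lw.geom
    d = np.asarray(delta, dtype=float).reshape(-1, g.out_units)
    out = lw.r_csr @ d.T
    return out.T.reshape(d.shape[0], g.in_channels, g.height, g.width)


def local_update(
    lw: LocalWeights, delta: np.ndarray, x_prev: np.ndarray
) -> np.ndarray:
    """Per-entry increments ``mean_b(delta_i * x_j)`` — no tying across space.

    Returns one increment per stored entry in ``w_data`` order; the
    feedback entry connecting the same two units gets the same value.
    """
    g = lw.geom
    d = np.asarray(delta, dtype=float).reshape(-1, g.out_units)
    x = np.asarray(x_prev, dtype=float).reshape(-1, g.in_units)
    return np.einsum("bn,bn->n", d[:, lw.rows], x[:, lw.cols]) / d.shape[0]


# Max pooling ---------------------------------------------------------------


def maxpool_forward(
    x_prev: np.ndarray, window: int, stride: int
) -> tuple[np.ndarray, np.ndarray]:
    """Zero-padded centered max pooling.

    Returns the pooled maps and, for feedback routing, the flat index
    (into the padded input plane) of each window's argmax.  Ties break
    to the first position in row-major scan order.  Windows whose max is
    a padding zero route their error into padding, where it is dropped.
    """
    x = np.asarray(x_prev, dtype=float)
    b, c, h, w = x.shape
    p = (window - 1) // 2
    q = window - 1 - p
    xp = np.pad(x, ((0, 0), (0, 0), (p, q), (p, q)))
    win = sliding_window_view(xp, (window, window), axis=(2, 3))
    win = win[:, :, ::stride, ::stride]  # (b, c, oh, ow, k, k)
    oh, ow = win.shape[2], win.shape[3]
    flat = win.reshape(b, c, oh, ow, window * window)
    arg = flat.argmax(axis=-1)
    pooled = np.take_along_axis(flat, arg[..., None], axis=-1)[..., 0]
    # convert window-local argmax to flat padded-plane index
    ky, kx = np.divmod(arg, window)
    oy = np.arange(oh)[None, None, :, None] * stride
    ox = np.arange(ow)[None, None, None, :] * stride
    wp = w + window - 1
    pool_argmax = (oy + ky) * wp + (ox + kx)
    return pooled, pool_argmax


def maxpool_feedback(
    delta: np.ndarray, pool_argmax: np.ndarray, input_shape: tuple, window: int
) -> np.ndarray:
    """Route each pooled unit's error to its argmax input location.

    Overlapping windows sharing an argmax accumulate by summation.
    """
    b, c, h, w = input_shape
    d = np.asarray(delta, dtype=float)
    if d.shape != pool_argmax.shape:
        raise ValueError(
            f"delta shape {d.shape} does not match recorded argmax "
            f"{pool_argmax.shape}; forward/feedback sequencing violated"
        )
    hp, wp = h + window - 1, w + window - 1
    p = (window - 1) // 2
    out = np.zeros((b, c, hp * wp))
    bi = np.arange(b)[:, None, None, None]
    ci = np.arange(c)[None, :, None, None]
    np.add.at(out, (bi, ci, pool_argmax), d)
    out = out.reshape(b, c, hp, wp)
    return out[:, :, p : p + h, p : p + w]


# Dropout -------------------------------------------------------------------


def dropout_mask(shape: tuple, rate: float, rng: np.random.Generator,
                 per_example: bool = False) -> np.ndarray:
    """Binary keep-mask zeroing an exact ``rate`` fraction of units.

    By default one mask is drawn per batch and shared across its
    examples; ``per_example`` draws independent masks per row.
    """
    if not 0.0 <= rate < 1.0:
        raise ValueError(f"dropout rate must be in [0, 1), got {rate}")
    unit_shape = shape[1:]
    n = int(np.prod(unit_shape))
    k = int(round(rate * n))

    def one() -> np.ndarray:
        m = np.ones(n)
        m[rng.choice(n, size=k, replace=False)] = 0.0
        return m.reshape(unit_shape)

    if per_example:
        return np.stack([one() for _ in range(shape[0])])
    return np.broadcast_to(one(), shape).copy()


def dropout_apply(
    x: np.ndarray, rate: float, rng: np.random.Generator,
    per_example: bool = False,
) -> tuple[np.ndarray, np.ndarray]:
    """Zero a random fraction ``rate`` of units; no rescaling."""
    mask = dropout_mask(np.asarray(x).shape, rate, rng, per_example)
    return x * mask, mask


def dropout_feedback(delta: np.ndarray, drop_mask: np.ndarray) -> np.ndarray:
    """Dropped units pass no error, so their synapses receive no update."""
    return delta * drop_mask


# Residual sum --------------------------------------------------------------


def residual_sum_forward(x_a: np.ndarray, x_b: np.ndarray) -> np.ndarray:
    if np.shape(x_a) != np.shape(x_b):
        raise ValueError(
            f"residual operands differ in shape: {np.shape(x_a)} vs {np.shape(x_b)}"
        )
    return x_a + x_b


def residual_sum_feedback(delta: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    return delta, delta.copy()
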