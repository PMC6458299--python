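"""Alignment and filter-similarity diagnostics.

Alignment is the Pearson correlation between a layer's feedforward
matrix and its transposed feedback matrix; under updated feedback it
grows during training until the network effectively back-propagates.
For untied locally connected layers, filters reconstructed at different
grid locations can be compared the same way, quantifying how much
spatial homogeneity emerges from translation-consistent data alone.
"""

from __future__ import annotations

from typing import Optional, Sequence

import numpy as np

from .layers import LocalWeights, WeightPair

__all__ = [
    "alignment_correlation",
    "network_alignment",
    "filter_similarity",
    "extract_filter",
    "permutation_pvalue",
]


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    a = np.asarray(a, dtype=float).ravel()
    b = np.asarray(b, dtype=float).ravel()
    sa, sb = a.std(), b.std()
    if sa == 0.0 or sb == 0.0:
        return 0.0  # degenerate (constant) input, by convention
    return float(np.mean((a - a.mean()) * (b - b.mean())) / (sa * sb))


def _cosine(a: np.ndarray, b: np.ndarray) -> float:
    a = np.asarray(a, dtype=float).ravel()
    b = np.asarray(b, dtype=float).ravel()
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0.0 or nb == 0.0:
        return 0.0
    return float(a @ b / (na * nb))


def alignment_correlation(pair, method: str = "pearson") -> float:
    """Correlation of flattened W against flattened R transposed.

    For sparse layers only coordinates present in *both* connectivity
    masks enter the correlation (absent synapses carry no signal).
    Accepts a dense :class:`WeightPair`, a conv stage's ``(F, G)`` filter
    banks, or :class:`LocalWeights`.
    """
    fn = {"pearson": _pearson, "cosine": _cosine}[method]
    if isinstance(pair, WeightPair):
        w = pair.W
        rt = pair.R.T
        if pair.mask_W is not None or pair.mask_R is not None:
            mw = pair.mask_W if pair.mask_W is not None else np.ones_like(w)
            mr = pair.mask_R if pair.mask_R is not None else np.ones_like(pair.R)
            keep = (mw * mr.T) > 0
            return fn(w[keep], rt[keep])
        return fn(w, rt)
    if isinstance(pair, LocalWeights):
        keep = (pair.mask_w * pair.mask_r) > 0
        return fn(pair.w_data[keep], pair.r_data[keep])
    w, r = pair  # (F, G) banks share one layout: no transposition needed
    return fn(np.asarray(w), np.asarray(r))


def network_alignment(net, method: str = "pearson") -> list[float]:
    """Per-trainable-layer alignment, bottom to top."""
    from .network import ConvStage, DenseStage, LocalStage

    out = []
    for stage in net.trainable_stages:
        if isinstance(stage, DenseStage):
            out.append(alignment_correlation(stage.pair, method))
        elif isinstance(stage, ConvStage):
            banks = (stage.F, stage.G)
            if stage.mask_F is not None or stage.mask_G is not None:
                mf = stage.mask_F if stage.mask_F is not None else np.ones_like(stage.F)
                mg = stage.mask_G if stage.mask_G is not None else np.ones_like(stage.G)
                keep = (mf * mg) > 0
                fn = {"pearson": _pearson, "cosine": _cosine}[method]
                out.append(fn(stage.F[keep], stage.G[keep]))
            else:
                out.append(alignment_correlation(banks, method))
        elif isinstance(stage, LocalStage):
            out.append(alignment_correlation(stage.lw, method))
    return out


def extract_filter(lw: LocalWeights, location: tuple[int, int],
                   out_channel: int = 0) -> np.ndarray:
    """Reconstruct the (in_channels, k, k) filter at one grid location.

    Only interior locations, whose window lies fully inside the grid,
    are valid — boundary windows are truncated by the connectivity.
    """
    g = lw.geom
    y, x = location
    p = g.pad
    if not (p <= y < g.height - (g.kernel - 1 - p)
            and p <= x < g.width - (g.kernel - 1 - p)):
        raise ValueError(
            f"location {location} has a truncated window; "
            f"valid rows/cols: [{p}, {g.height - (g.kernel - 1 - p)})"
        )
    row = (out_channel * g.height + y) * g.width + x
    sel = lw.rows == row
    taps = lw.tap_index[sel] % (g.in_channels * g.kernel * g.kernel)
    filt = np.zeros(g.in_channels * g.kernel * g.kernel)
    filt[taps] = lw.w_data[sel]
    return filt.reshape(g.in_channels, g.kernel, g.kernel)


def filter_similarity(
    lw: LocalWeights,
    locations: Sequence[tuple[int, int]],
    out_channel: int = 0,
    method: str = "pearson",
) -> np.ndarray:
    """Pairwise correlation matrix of filters at the requested locations."""
    fn = {"pearson": _pearson, "cosine": _cosine}[method]
    filters = [extract_filter(lw, loc, out_channel) for loc in locations]
    n = len(filters)
    out = np.eye(n)
    for i in range(n):
        for j in range(i + 1, n):
            out[i, j] = out[j, i] = fn(filters[i], filters[j])
    return out


def mean_offdiag(mat: np.ndarray) -> float:
    n = mat.shape[0]
    mask = ~np.eye(n, dtype=bool)
    return float(mat[mask].mean())


def permutation_pvalue(
    lw: LocalWeights,
    locations: Sequence[tuple[int, int]],
    out_channels: Optional[Sequence[int]] = None,
    n_perm: int = 999,
    seed: int = 0,
) -> tuple[float, float]:
    """Permutation test of cross-location filter similarity.

    Observed statistic: mean pairwise correlation of filters across
    locations (averaged over the given output channels).  Null: tap
    values shuffled independently within each filter vector, destroying
    spatial structure while preserving each filter's value distribution.
    Returns (observed mean correlation, one-sided p-value).
    """
    rng = np.random.default_rng(seed)
    g = lw.geom
    if out_channels is None:
        out_channels = range(g.out_channels)
    all_filters = [
        [extract_filter(lw, loc, oc).ravel() for loc in locations]
        for oc in out_channels
    ]

    def stat(filter_sets) -> float:
        vals = []
        for fs in filter_sets:
            for i in range(len(fs)):
                for j in range(i + 1, len(fs)):
                    vals.append(_pearson(fs[i], fs[j]))
        return float(np.mean(vals))

    observed = stat(all_filters)
    count = 0
    for _ in range(n_perm):
        shuffled = [
            [rng.permutation(f) for f in fs] for fs in all_filters
        ]
        if stat(shuffled) >= observed:
            count += 1
    pval = (count + 1) / (n_perm + 1)
    return observed, pval
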