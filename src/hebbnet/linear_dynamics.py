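"""Gradient-flow dynamics of deep linear networks with asymmetric feedback.

For a chain ``W_k ... W_1`` approximating a target ``T`` under quadratic
loss, the feedback matrices start at random ``R_i(0)`` and, receiving
``epsilon`` times the transposed feedforward increment, satisfy
``R_i(t) = R_i(0) + epsilon * W_i(t)^T`` when the ``W_i`` start at zero.
``epsilon = 0`` is fixed random feedback, ``epsilon = 1`` updated random
feedback; ``epsilon = 1`` with ``R(0) = 0`` is plain gradient flow.

Layer i's flow (explicit Euler here) is::

    dW_i/dt = (R_{i+1}(0) + eps W_{i+1}^T) ... (R_k(0) + eps W_k^T)
              * E * W_1^T ... W_{i-1}^T,       E = T - W_k ... W_1
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "LinearSimConfig",
    "SimTrace",
    "make_target",
    "make_factors",
    "step_deep",
    "simulate",
    "sweep",
    "trace_to_frame",
]

DEFAULT_DIMS = (40, 100, 100, 10)
DEFAULT_SD = 0.2
DEFAULT_STEPS = 1000
DEFAULT_DT = 0.005


@dataclass
class LinearSimConfig:
    dims: Sequence[int] = DEFAULT_DIMS
    epsilon: float = 1.0
    sd: float = DEFAULT_SD
    steps: int = DEFAULT_STEPS
    dt: float = DEFAULT_DT
    seed: int = 0
    init: str = "zero"  # "zero" (feedback modes) or "random" (bp comparator)
    r_sd: float = DEFAULT_SD  # scale of the random R_i(0) draws
    blowup_factor: float = 1e6

    def __post_init__(self) -> None:
        self.dims = tuple(int(n) for n in self.dims)
        if len(self.dims) < 3:
            raise ValueError("need at least two weight matrices (k >= 2)")
        if not 0.0 <= self.epsilon <= 1.0:
            raise ValueError("epsilon must lie in [0, 1]")
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.init not in ("zero", "random"):
            raise ValueError("init must be 'zero' or 'random'")


@dataclass
class SimTrace:
    config: LinearSimConfig
    error: np.ndarray  # (steps+1,), e = tr(E^T E)
    correlations: np.ndarray  # (steps+1, k): Pearson(W_i, R_i(t)^T)
    W: list[np.ndarray] = field(default_factory=list)  # final matrices

    @property
    def log_error(self) -> np.ndarray:
        return np.log10(np.maximum(self.error, 1e-300))

    def steps_to_threshold(self, ratio: float = 1e-3) -> Optional[int]:
        """First step index at which e <= ratio * e(0), or None."""
        hit = np.nonzero(self.error <= ratio * self.error[0])[0]
        return int(hit[0]) if hit.size else None


def make_factors(
    dims: Sequence[int], sd: float, rng: np.random.Generator
) -> list[np.ndarray]:
    """Target factors W*_i of shape (n_i, n_{i-1}), i.i.d. normal entries."""
    dims = tuple(dims)
    return [
        rng.normal(0.0, sd, (dims[i + 1], dims[i]))
        for i in range(len(dims) - 1)
    ]


def make_target(
    dims: Sequence[int], sd: float, seed: int | np.random.Generator
) -> np.ndarray:
    """T = W*_k ... W*_1, assuming uncorrelated inputs (X = I)."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    return _chain(make_factors(dims, sd, rng))


def _chain(mats: Sequence[np.ndarray]) -> np.ndarray:
    """Product mats[-1] @ ... @ mats[0] (layer composition order)."""
    out = mats[0]
    for m in mats[1:]:
        out = m @ out
    return out


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    a = np.asarray(a).ravel()
    b = np.asarray(b).ravel()
    sa, sb = a.std(), b.std()
    if sa == 0.0 or sb == 0.0:
        return 0.0
    return float(np.mean((a - a.mean()) * (b - b.mean())) / (sa * sb))


def step_deep(
    W: list[np.ndarray],
    R0: list[np.ndarray],
    T: np.ndarray,
    epsilon: float,
    dt: float,
) -> list[np.ndarray]:
    """One explicit-Euler step; derivatives evaluated at the current state.

    ``W[i]`` is layer i+1's matrix, shape (dims[i+1], dims[i]).
    ``R0[i]`` is layer i+1's initial feedback matrix, shape
    (dims[i], dims[i+1]); only layers 2..k (``R0[1:]``) enter the flow —
    no error is fed back into the input layer.
    """
    k = len(W)
    if len(R0) < k:
        raise ValueError("need one R0 per layer")
    E = T - _chain(W)
    # B[i] = R_{i+1}(0) + eps W_{i+1}^T in code indexing (layer i+1 -> B[i])
    B = [R0[i] + epsilon * W[i].T for i in range(k)]
    dW: list[np.ndarray] = []
    for i in range(k):
        upper = E
        for j in range(k - 1, i, -1):  # B[i+1] @ ... @ B[k-1] @ E
            upper = B[j] @ upper
        lower = None  # W_1^T @ ... @ W_{i-1}^T
        for j in range(i):
            lower = W[j].T if lower is None else lower @ W[j].T
        dW.append(upper if lower is None else upper @ lower)
    return [W[i] + dt * dW[i] for i in range(k)]


def simulate(config: LinearSimConfig) -> SimTrace:
    """Integrate the flow, recording error and per-layer W-R alignment.

    ``init='random'`` runs the plain gradient-flow comparator, whose
    feedback is the transposed feedforward matrix itself (correlation
    identically 1 once the weights move).
    """
    rng = np.random.default_rng(config.seed)
    dims = config.dims
    k = len(dims) - 1
    T = make_target(dims, config.sd, rng)
    bp = config.init == "random"
    if bp:
        W = [rng.normal(0.0, config.r_sd, (dims[i + 1], dims[i])) for i in range(k)]
    else:
        W = [np.zeros((dims[i + 1], dims[i])) for i in range(k)]
    R0 = [rng.normal(0.0, config.r_sd, (dims[i], dims[i + 1])) for i in range(k)]
    if bp:
        R0 = [np.zeros_like(r) for r in R0]

    def correlations() -> np.ndarray:
        out = np.empty(k)
        for i in range(k):
            if bp:
                out[i] = 1.0 if np.any(W[i]) else 0.0
            else:
                R_i = R0[i] + config.epsilon * W[i].T
                out[i] = _pearson(W[i], R_i.T)
        return out

    err = np.empty(config.steps + 1)
    corr = np.empty((config.steps + 1, k))
    E = T - _chain(W)
    err[0] = float(np.trace(E.T @ E))
    corr[0] = correlations()
    guard = config.blowup_factor * max(err[0], 1.0)
    eps_eff = 1.0 if bp else config.epsilon
    for t in range(1, config.steps + 1):
        W = step_deep(W, R0, T, eps_eff, config.dt)
        E = T - _chain(W)
        err[t] = float(np.trace(E.T @ E))
        corr[t] = correlations()
        if not np.isfinite(err[t]) or err[t] > guard:
            raise FloatingPointError(
                f"error blew up at step {t} (e={err[t]:.3g}); reduce dt"
            )
    return SimTrace(
        config=config, error=err, correlations=corr, W=[w.copy() for w in W]
    )


def sweep(
    config: LinearSimConfig,
    epsilons: Sequence[float],
    include_bp: bool = True,
) -> list[SimTrace]:
    """One trace per epsilon, sharing seed (hence T and R(0)) across runs.

    Optionally appends the randomly initialized gradient-flow comparator.
    """
    traces = []
    for eps in epsilons:
        c = LinearSimConfig(
            dims=config.dims, epsilon=eps, sd=config.sd, steps=config.steps,
            dt=config.dt, seed=config.seed, init="zero", r_sd=config.r_sd,
        )
        traces.append(simulate(c))
    if include_bp:
        c = LinearSimConfig(
            dims=config.dims, epsilon=1.0, sd=config.sd, steps=config.steps,
            dt=config.dt, seed=config.seed, init="random", r_sd=config.r_sd,
        )
        traces.append(simulate(c))
    return traces


def trace_to_frame(trace: SimTrace) -> pd.DataFrame:
    """Per-step table: step, e, log_e, corr_layer_1..k."""
    k = trace.correlations.shape[1]
    data = {
        "step": np.arange(len(trace.error)),
        "e": trace.error,
        "log_e": trace.log_error,
    }
    for i in range(k):
        data[f"corr_layer_{i + 1}"] = trace.correlations[:, i]
    return pd.DataFrame(data)
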