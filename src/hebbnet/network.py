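"""Network assembly and the sequenced forward / feedback / update loop.

Architectures are declared in a compact string notation, e.g.::

    Conv 32 5x5; Maxpool 3; Drop .8; Full 500; Drop .3; Output

Three training modes share one code path:

* ``bp``   — feedback through a contiguous copy of W transposed,
* ``urfb`` — separate feedback weights R, updated with the same Hebbian
  increment as W,
* ``frfb`` — separate feedback weights R, never updated.

The feedback signal replaces a unit's feedforward activity top-down, so
weight increments always pair the top-down error of the upper unit with
the *original* feedforward activity of the lower unit.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from . import layers as L
from .activations import HingeParams, batch_loss, satlin, satlin_gate, top_error

__all__ = [
    "NetworkSpec",
    "TrainingConfig",
    "MetricsRow",
    "Network",
    "PRESETS",
    "parse_architecture",
    "build_network",
    "forward_pass",
    "feedback_pass",
    "apply_updates",
    "train",
    "evaluate",
    "component_rngs",
]

MODES = ("bp", "urfb", "frfb")

PRESETS = {
    "simpnet": "Conv 32 5x5; Maxpool 3; Drop .8; Full 500; Drop .3; Output",
    "deepnet": (
        "Conv 32 5x5; Maxpool 3; Conv 32 3x3; Conv 32 3x3; Maxpool 3; "
        "Drop .8; Conv 32 3x3; Conv 32 3x3; Maxpool 3; Drop .3; "
        "Full 500; Output"
    ),
    "deepernet": (
        "conv 16 3x3; conv 16 3x3; SUM; conv 32 3x3; conv 32 3x3; SUM; "
        "maxpool 3; drop .5; conv 64 3x3; conv 64 3x3; SUM; maxpool 3; "
        "conv 128 3x3; conv 128 3x3; SUM; maxpool 3; drop .8; "
        "full conn. 500; output"
    ),
    "deepnet_s": (
        "conv 16 3x3; conv 16 3x3; SUM; maxpool 3, stride 3; drop .5; "
        "conv 64 3x3; conv 64 3x3; SUM; maxpool 2, stride 2; "
        "conv 64 2x2; conv 64 2x2; SUM; maxpool 2, stride 2; drop .5; "
        "full conn. 500; output"
    ),
}


@dataclass
class TrainingConfig:
    eta: float = 0.1
    batch_size: int = 500
    epochs: int = 1
    seed: int = 0
    mu: float = 1.0

    def __post_init__(self) -> None:
        if self.eta <= 0:
            raise ValueError("eta must be positive")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")


@dataclass
class MetricsRow:
    epoch: int
    train_error: float
    val_error: float
    train_loss: float
    alignment: list[float] = field(default_factory=list)


# Architecture parsing ------------------------------------------------------


@dataclass
class _Desc:
    kind: str  # conv | local | maxpool | drop | full | sum | output
    channels: int = 0
    kernel: int = 0
    window: int = 0
    stride: int = 0
    rate: float = 0.0
    units: int = 0


@dataclass
class NetworkSpec:
    descriptors: list[_Desc]
    input_shape: tuple  # (C, H, W) or (n,)
    n_classes: int
    mode: str = "bp"
    sparsity: float = 0.0
    loss: str = "hinge"
    init: str = "independent"  # or "mirrored"
    local_init: str = "replicated"  # or "random": untied layers start
    # from a spatially replicated filter bank (the convolution's matrix
    # form) or from fully independent per-entry draws
    per_example_dropout: bool = False

    def __post_init__(self) -> None:
        if self.mode not in MODES:
            raise ValueError(f"mode must be one of {MODES}, got {self.mode!r}")
        if not 0.0 <= self.sparsity < 1.0:
            raise ValueError("sparsity must be in [0, 1)")
        if self.descriptors[-1].kind != "output":
            raise ValueError("last descriptor must be Output")


_CONV_RE = re.compile(r"^(conv|local)\s+(\d+)\s+(\d+)x(\d+)$")
_POOL_RE = re.compile(r"^maxpool\s+(\d+)\s*(?:[,;]?\s*stride\s+(\d+))?$")
_DROP_RE = re.compile(r"^drop\s+(\.?\d*\.?\d+)$")
_FULL_RE = re.compile(r"^full(?:\s+conn\.?)?\s+(\d+)$")


def _parse_descriptor(token: str, untied: bool) -> _Desc:
    t = token.strip().lower()
    m = _CONV_RE.match(t)
    if m:
        kind, ch, ky, kx = m.group(1), int(m.group(2)), int(m.group(3)), int(m.group(4))
        if ky != kx:
            raise ValueError(f"only square kernels supported: {token!r}")
        if untied and kind == "conv":
            kind = "local"
        return _Desc(kind=kind, channels=ch, kernel=ky)
    m = _POOL_RE.match(t)
    if m:
        window = int(m.group(1))
        stride = int(m.group(2)) if m.group(2) else 2
        return _Desc(kind="maxpool", window=window, stride=stride)
    m = _DROP_RE.match(t)
    if m:
        return _Desc(kind="drop", rate=float(m.group(1)))
    m = _FULL_RE.match(t)
    if m:
        return _Desc(kind="full", units=int(m.group(1)))
    if t == "sum":
        return _Desc(kind="sum")
    if t == "output":
        return _Desc(kind="output")
    raise ValueError(f"unknown layer descriptor: {token!r}")


def parse_architecture(
    text: str,
    input_shape: tuple,
    n_classes: int,
    mode: str = "bp",
    sparsity: float = 0.0,
    loss: str = "hinge",
    init: str = "independent",
    untied: bool = False,
    local_init: str = "replicated",
) -> NetworkSpec:
    """Parse an architecture string (or preset name) into a NetworkSpec."""
    text = PRESETS.get(text.strip().lower(), text)
    tokens = [t for t in text.split(";") if t.strip()]
    if not tokens:
        raise ValueError("empty architecture string")
    descs = [_parse_descriptor(t, untied) for t in tokens]
    spec = NetworkSpec(
        descriptors=descs,
        input_shape=tuple(input_shape),
        n_classes=n_classes,
        mode=mode,
        sparsity=sparsity,
        loss=loss,
        init=init,
        local_init=local_init,
    )
    _infer_shapes(spec)  # raises on inconsistency
    return spec


def _infer_shapes(spec: NetworkSpec) -> list[tuple]:
    """Output shape of every stage; validates SUM operands and shapes."""
    shapes: list[tuple] = []
    prev = spec.input_shape
    for i, d in enumerate(spec.descriptors):
        if d.kind in ("conv", "local"):
            if len(prev) != 3:
                raise ValueError(f"stage {i}: conv needs a (C,H,W) input, got {prev}")
            out = (d.channels, prev[1], prev[2])
        elif d.kind == "maxpool":
            if len(prev) != 3:
                raise ValueError(f"stage {i}: maxpool needs a (C,H,W) input")
            out = (
                prev[0],
                -(-prev[1] // d.stride),
                -(-prev[2] // d.stride),
            )
        elif d.kind == "drop":
            out = prev
        elif d.kind == "sum":
            if i < 2:
                raise ValueError("SUM needs two preceding stages")
            a, b = shapes[i - 1], shapes[i - 2]
            if a != b:
                raise ValueError(f"SUM operands differ in shape: {a} vs {b}")
            out = a
        elif d.kind == "full":
            out = (d.units,)
        elif d.kind == "output":
            out = (spec.n_classes,)
        else:  # pragma: no cover
            raise AssertionError(d.kind)
        shapes.append(out)
        prev = out
    return shapes


# Stages --------------------------------------------------------------------


def _glorot_bound(fan_in: int, fan_out: int) -> float:
    return float(np.sqrt(6.0 / (fan_in + fan_out)))


class _Stage:
    """Base class; subclasses set trainable/out_shape and the three passes."""

    trainable = False
    input_indices: tuple[int, ...] = ()

    def forward(self, xs: list[np.ndarray], training: bool, rng) -> tuple[np.ndarray, dict]:
        raise NotImplementedError

    def feedback(self, d_out: np.ndarray, cache: dict) -> list[np.ndarray]:
        """Deltas w.r.t. each input, in input_indices order (no gating here)."""
        raise NotImplementedError


class DenseStage(_Stage):
    trainable = True

    def __init__(self, pair: L.WeightPair, in_shape: tuple, is_output: bool):
        self.pair = pair
        self.in_shape = in_shape
        self.is_output = is_output
        self.out_shape = (pair.W.shape[0],)
        self._r_eff: Optional[L.WeightPair] = None

    def forward(self, xs, training, rng):
        x = xs[0].reshape(xs[0].shape[0], -1)
        h = L.dense_forward(self.pair, x)
        x_out = h if self.is_output else satlin(h)
        return x_out, {"h": h, "x_in_flat": x}

    def effective_pair(self, mode: str) -> L.WeightPair:
        if mode == "bp":
            return L.WeightPair(
                self.pair.W.copy(),
                np.ascontiguousarray(self.pair.masked_W.T),
                mask_W=self.pair.mask_W,
                mask_R=None if self.pair.mask_W is None
                else np.ascontiguousarray(self.pair.mask_W.T),
            )
        return self.pair

    def gate(self, cache) -> np.ndarray:
        if self.is_output:
            return np.ones_like(cache["h"])
        return satlin_gate(cache["h"])

    def feedback_with(self, pair: L.WeightPair, delta: np.ndarray, cache) -> list[np.ndarray]:
        d_in = delta @ pair.masked_R.T
        return [d_in.reshape((delta.shape[0],) + self.in_shape)]

    def increments(self, delta: np.ndarray, cache) -> tuple:
        dW, dR = L.hebbian_increments(delta, cache["x_in_flat"])
        return dW, dR

    def apply(self, incs, eta: float, mode: str) -> None:
        dW, dR = incs
        if self.pair.mask_W is not None:
            dW = dW * self.pair.mask_W
        self.pair.W += eta * dW
        if mode == "urfb":
            if self.pair.mask_R is not None:
                dR = dR * self.pair.mask_R
            self.pair.R += eta * dR
        elif mode == "bp":
            self.pair.R = np.ascontiguousarray(self.pair.masked_W.T)


class ConvStage(_Stage):
    trainable = True

    def __init__(self, F: np.ndarray, G: np.ndarray, geom: L.ConvGeometry,
                 mask_F: Optional[np.ndarray], mask_G: Optional[np.ndarray]):
        self.geom = geom
        self.mask_F = mask_F
        self.mask_G = mask_G
        self.F = F if mask_F is None else F * mask_F
        self.G = G if mask_G is None else G * mask_G
        self.out_shape = (geom.out_channels, geom.height, geom.width)

    def _masked(self, A, m):
        return A if m is None else A * m

    def forward(self, xs, training, rng):
        h = L.conv_forward(self._masked(self.F, self.mask_F), self.geom, xs[0])
        return satlin(h), {"h": h, "x_in": xs[0]}

    def gate(self, cache) -> np.ndarray:
        return satlin_gate(cache["h"])

    def effective_bank(self, mode: str) -> np.ndarray:
        if mode == "bp":
            return self._masked(self.F, self.mask_F).copy()
        return self._masked(self.G, self.mask_G)

    def feedback_bank_with(self, bank: np.ndarray, delta: np.ndarray, cache) -> list[np.ndarray]:
        return [L.conv_feedback(bank, self.geom, delta)]

    def increments(self, delta: np.ndarray, cache):
        dF = L.conv_update_tied(delta, cache["x_in"], self.geom)
        return (dF,)

    def apply(self, incs, eta: float, mode: str) -> None:
        (dF,) = incs
        self.F += eta * self._masked(dF, self.mask_F)
        if mode == "urfb":
            self.G += eta * self._masked(dF, self.mask_G)
        elif mode == "bp":
            self.G = self._masked(self.F, self.mask_F).copy()


class LocalStage(_Stage):
    trainable = True

    def __init__(self, lw: L.LocalWeights):
        self.lw = lw
        g = lw.geom
        self.geom = g
        self.out_shape = (g.out_channels, g.height, g.width)

    def forward(self, xs, training, rng):
        h = L.local_forward(self.lw, xs[0])
        return satlin(h), {"h": h, "x_in": xs[0]}

    def gate(self, cache) -> np.ndarray:
        return satlin_gate(cache["h"])

    def feedback_local(self, mode: str, delta: np.ndarray) -> list[np.ndarray]:
        if mode == "bp":
            g = self.lw.geom
            d = delta.reshape(-1, g.out_units)
            r = self.lw.r_csr_from(self.lw.w_data * self.lw.mask_w)
            out = (r @ d.T).T
            return [out.reshape(d.shape[0], g.in_channels, g.height, g.width)]
        return [L.local_feedback(self.lw, delta)]

    def increments(self, delta: np.ndarray, cache):
        return (L.local_update(self.lw, delta, cache["x_in"]),)

    def apply(self, incs, eta: float, mode: str) -> None:
        (dvals,) = incs
        self.lw.w_data += eta * dvals * self.lw.mask_w
        if mode == "urfb":
            self.lw.r_data += eta * dvals * self.lw.mask_r
        elif mode == "bp":
            self.lw.r_data = self.lw.w_data.copy()


class MaxPoolStage(_Stage):
    def __init__(self, window: int, stride: int, in_shape: tuple):
        self.window = window
        self.stride = stride
        self.in_shape = in_shape
        c, h, w = in_shape
        self.out_shape = (c, -(-h // stride), -(-w // stride))

    def forward(self, xs, training, rng):
        pooled, argmax = L.maxpool_forward(xs[0], self.window, self.stride)
        return pooled, {"pool_argmax": argmax, "batch": xs[0].shape[0]}

    def feedback(self, d_out, cache):
        shape = (cache["batch"],) + self.in_shape
        return [L.maxpool_feedback(d_out, cache["pool_argmax"], shape, self.window)]


class DropStage(_Stage):
    def __init__(self, rate: float, per_example: bool = False):
        self.rate = rate
        self.per_example = per_example
        self.out_shape = None  # same as input; set by builder

    def forward(self, xs, training, rng):
        if not training or self.rate == 0.0:
            return xs[0], {"drop_mask": None}
        x, mask = L.dropout_apply(xs[0], self.rate, rng, self.per_example)
        return x, {"drop_mask": mask}

    def feedback(self, d_out, cache):
        if cache["drop_mask"] is None:
            return [d_out]
        return [L.dropout_feedback(d_out, cache["drop_mask"])]


class SumStage(_Stage):
    def __init__(self):
        self.out_shape = None

    def forward(self, xs, training, rng):
        return L.residual_sum_forward(xs[0], xs[1]), {}

    def feedback(self, d_out, cache):
        return list(L.residual_sum_feedback(d_out))


class Network:
    """An assembled network: ordered stages plus wiring and mode."""

    def __init__(self, stages: list[_Stage], spec: NetworkSpec,
                 hinge: HingeParams):
        self.stages = stages
        self.spec = spec
        self.hinge = hinge
        self.mode = spec.mode
        self.loss = spec.loss

    @property
    def trainable_stages(self) -> list[_Stage]:
        return [s for s in self.stages if s.trainable]


def component_rngs(seed: int) -> dict[str, np.random.Generator]:
    """One global seed fanned out to fixed named streams.

    Toggling dropout or reshuffling data never shifts the init stream.
    """
    base = np.random.SeedSequence(seed)
    names = ("init", "dropout", "shuffle", "data")
    children = base.spawn(len(names))
    return {n: np.random.default_rng(c) for n, c in zip(names, children)}


def build_network(
    spec: NetworkSpec,
    config: TrainingConfig,
    rng: Optional[np.random.Generator] = None,
) -> Network:
    """Draw weights (Glorot uniform), feedback weights, and masks.

    W is drawn first for every layer so that runs differing only in
    mode/init share W(0) exactly.  R is drawn independently from the
    same law unless ``init == "mirrored"`` (then R = W transposed).
    Connectivity masks for W and R are drawn independently, so pruned
    connectivity itself is asymmetric.
    """
    if rng is None:
        rng = component_rngs(config.seed)["init"]
    shapes = _infer_shapes(spec)
    stages: list[_Stage] = []
    prev_shape = spec.input_shape
    sp = spec.sparsity

    def mask(shape):
        if sp == 0.0:
            return None
        return (rng.random(shape) >= sp).astype(float)

    for i, d in enumerate(spec.descriptors):
        out_shape = shapes[i]
        if d.kind in ("full", "output"):
            n_in = int(np.prod(prev_shape))
            n_out = out_shape[0]
            b = _glorot_bound(n_in, n_out)
            W = rng.uniform(-b, b, (n_out, n_in))
            R = rng.uniform(-b, b, (n_in, n_out))
            if spec.init == "mirrored" or spec.mode == "bp":
                R = np.ascontiguousarray(W.T)
            mW, mR = mask(W.shape), mask(R.shape)
            if spec.mode == "bp" and mW is not None:
                mR = np.ascontiguousarray(mW.T)
            pair = L.WeightPair(W, R, mask_W=mW, mask_R=mR)
            stages.append(DenseStage(pair, prev_shape, d.kind == "output"))
        elif d.kind in ("conv", "local"):
            cin, h, w = prev_shape
            geom = L.ConvGeometry(cin, d.channels, d.kernel, h, w)
            fan_in = cin * d.kernel**2
            fan_out = d.channels * d.kernel**2
            b = _glorot_bound(fan_in, fan_out)
            if d.kind == "conv":
                F = rng.uniform(-b, b, (d.channels, cin, d.kernel, d.kernel))
                G = rng.uniform(-b, b, F.shape)
                if spec.init == "mirrored" or spec.mode == "bp":
                    G = F.copy()
                mF, mG = mask(F.shape), mask(F.shape)
                if spec.mode == "bp":
                    mG = None if mF is None else mF.copy()
                stages.append(ConvStage(F, G, geom, mF, mG))
            else:
                rows, cols = _conv_pattern_cached(geom)
                nnz = len(rows)
                if spec.local_init == "replicated":
                    order = np.lexsort((cols, rows))
                    taps = L._tap_indices(geom, rows[order], cols[order])
                    bank_w = rng.uniform(-b, b, (d.channels, cin, d.kernel, d.kernel))
                    bank_r = rng.uniform(-b, b, bank_w.shape)
                    wv = bank_w.ravel()[taps]
                    rv = bank_r.ravel()[taps]
                else:
                    wv = rng.uniform(-b, b, nnz)
                    rv = rng.uniform(-b, b, nnz)
                if spec.init == "mirrored" or spec.mode == "bp":
                    rv = wv.copy()
                mw = mask((nnz,))
                mr = mask((nnz,))
                if spec.mode == "bp":
                    mr = None if mw is None else mw.copy()
                lw = L.LocalWeights(geom, wv, rv, mask_w=mw, mask_r=mr)
                stages.append(LocalStage(lw))
        elif d.kind == "maxpool":
            stages.append(MaxPoolStage(d.window, d.stride, prev_shape))
        elif d.kind == "drop":
            st = DropStage(d.rate, spec.per_example_dropout)
            st.out_shape = out_shape
            stages.append(st)
        elif d.kind == "sum":
            st = SumStage()
            st.out_shape = out_shape
            stages.append(st)
        stages[-1].input_indices = (
            (i - 1, i - 2) if d.kind == "sum" else (i - 1,)
        )
        prev_shape = out_shape
    return Network(stages, spec, HingeParams(mu=config.mu))


def _conv_pattern_cached(geom: L.ConvGeometry):
    return L._conv_pattern(geom)


# Forward / feedback / update -----------------------------------------------


@dataclass
class ForwardTrace:
    x0: np.ndarray
    outputs: list[np.ndarray]
    caches: list[dict]

    @property
    def scores(self) -> np.ndarray:
        return self.outputs[-1]


@dataclass
class FeedbackTrace:
    deltas: dict[int, np.ndarray]  # stage index -> gated delta (trainable only)


def forward_pass(
    net: Network, batch: np.ndarray, training: bool = False,
    rng: Optional[np.random.Generator] = None,
) -> ForwardTrace:
    """Run the batch bottom-up; the trace keeps everything feedback needs."""
    x = np.asarray(batch, dtype=float)
    if rng is None:
        rng = np.random.default_rng(0)
    outputs: list[np.ndarray] = []
    caches: list[dict] = []
    for i, stage in enumerate(net.stages):
        xs = [x if j < 0 else outputs[j] for j in stage.input_indices]
        out, cache = stage.forward(xs, training, rng)
        outputs.append(out)
        caches.append(cache)
    return ForwardTrace(x0=x, outputs=outputs, caches=caches)


def feedback_pass(
    net: Network, trace: ForwardTrace, labels: np.ndarray
) -> FeedbackTrace:
    """Propagate the error signal strictly top-down.

    The top-layer delta comes from the loss; each trainable stage gates
    the incoming error by its saturation state, records it for the
    Hebbian update, and maps it down through its feedback weights.
    """
    n = len(net.stages)
    if len(trace.outputs) != n:
        raise ValueError("forward trace does not match network; run forward_pass first")
    pending: list[Optional[np.ndarray]] = [None] * n
    pending[-1] = top_error(trace.scores, labels, net.loss, net.hinge)
    deltas: dict[int, np.ndarray] = {}
    for i in range(n - 1, -1, -1):
        stage = net.stages[i]
        d_out = pending[i]
        if d_out is None:
            d_out = np.zeros_like(trace.outputs[i])
        cache = trace.caches[i]
        if stage.trainable:
            if isinstance(stage, DenseStage):
                delta = d_out if stage.is_output else stage.gate(cache) * d_out
                deltas[i] = delta
                d_ins = stage.feedback_with(
                    stage.effective_pair(net.mode), delta, cache
                )
            elif isinstance(stage, ConvStage):
                delta = stage.gate(cache) * d_out
                deltas[i] = delta
                d_ins = stage.feedback_bank_with(
                    stage.effective_bank(net.mode), delta, cache
                )
            else:  # LocalStage
                delta = stage.gate(cache) * d_out
                deltas[i] = delta
                d_ins = stage.feedback_local(net.mode, delta)
        else:
            d_ins = stage.feedback(d_out, cache)
        for j, d_in in zip(stage.input_indices, d_ins):
            if j < 0:
                continue  # error reaching the input layer is discarded
            if pending[j] is None:
                pending[j] = d_in
            else:
                pending[j] = pending[j] + d_in
    return FeedbackTrace(deltas=deltas)


def apply_updates(
    net: Network, trace: ForwardTrace, fb: FeedbackTrace, config: TrainingConfig
) -> None:
    """``W += eta * dW`` everywhere; R per mode (urfb: same increment)."""
    for i, stage in enumerate(net.stages):
        if not stage.trainable or i not in fb.deltas:
            continue
        incs = stage.increments(fb.deltas[i], trace.caches[i])
        stage.apply(incs, config.eta, net.mode)


def train_step(
    net: Network, batch: np.ndarray, labels: np.ndarray,
    config: TrainingConfig, rng: np.random.Generator,
) -> float:
    """One forward/feedback/update cycle; returns the pre-update batch loss."""
    trace = forward_pass(net, batch, training=True, rng=rng)
    loss = batch_loss(trace.scores, labels, net.loss, net.hinge)
    fb = feedback_pass(net, trace, labels)
    apply_updates(net, trace, fb, config)
    return loss


def evaluate(net: Network, images: np.ndarray, labels: np.ndarray,
             batch_size: int = 1000) -> float:
    """Fraction misclassified under argmax (ties -> lowest class index)."""
    images = np.asarray(images, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if len(images) == 0:
        raise ValueError("empty dataset")
    wrong = 0
    for lo in range(0, len(images), batch_size):
        trace = forward_pass(net, images[lo : lo + batch_size], training=False)
        pred = np.argmax(trace.scores, axis=1)
        wrong += int((pred != labels[lo : lo + batch_size]).sum())
    return wrong / len(images)


def train(
    net: Network,
    train_set: tuple[np.ndarray, np.ndarray],
    val_set: tuple[np.ndarray, np.ndarray],
    config: TrainingConfig,
    rngs: Optional[dict[str, np.random.Generator]] = None,
    record_alignment: bool = True,
) -> list[MetricsRow]:
    """Seeded epoch loop: shuffle, batch updates, then evaluation.

    Evaluation (train and validation error) runs with dropout disabled.
    Alignment correlations are recorded once per epoch.
    """
    from .diagnostics import network_alignment

    x_tr, y_tr = train_set
    x_val, y_val = val_set
    if rngs is None:
        rngs = component_rngs(config.seed)
    shuffle_rng, drop_rng = rngs["shuffle"], rngs["dropout"]
    history: list[MetricsRow] = []
    for epoch in range(config.epochs):
        order = shuffle_rng.permutation(len(x_tr))
        losses = []
        for lo in range(0, len(x_tr), config.batch_size):
            idx = order[lo : lo + config.batch_size]
            losses.append(
                train_step(net, x_tr[idx], y_tr[idx], config, drop_rng)
            )
        row = MetricsRow(
            epoch=epoch + 1,
            train_error=evaluate(net, x_tr, y_tr),
            val_error=evaluate(net, x_val, y_val),
            train_loss=float(np.mean(losses)),
            alignment=network_alignment(net) if record_alignment else [],
        )
        history.append(row)
    return history
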