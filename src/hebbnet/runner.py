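"""Experiment orchestration: config resolution, artifacts, reproducibility.

A run is fully described by its manifest (resolved config + seed); the
same manifest reproduces the same metrics bytes.  One global seed fans
out to named per-component streams (init / dropout / shuffle / data) so
that, e.g., toggling dropout does not shift weight initialization.
"""

from __future__ import annotations

import copy
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as hio
from .network import (
    TrainingConfig,
    build_network,
    component_rngs,
    evaluate,
    parse_architecture,
    train,
)
from .synthetic import ToyDatasetConfig, make_toy_dataset, split

__all__ = ["DEFAULTS", "resolve_config", "load_data", "run_experiment", "compare_modes"]

DEFAULTS: dict = {
    "arch": "simpnet",
    "mode": "bp",
    "loss": "hinge",
    "init": "independent",
    "local_init": "replicated",
    "untied": False,
    "sparsity": 0.0,
    "lr": 0.1,
    "epochs": 1,
    "batch_size": 500,
    "mu": 1.0,
    "seed": 0,
    "val_fraction": 0.1,
    "data": {
        "source": "toy",
        "path": None,
        "n_classes": 3,
        "image_size": 16,
        "channels": 1,
        "n_per_class": 500,
        "jitter": 1,
        "noise_sd": 0.1,
    },
}


def resolve_config(overrides: dict | None = None) -> dict:
    cfg = copy.deepcopy(DEFAULTS)
    for k, v in (overrides or {}).items():
        if k == "data" and isinstance(v, dict):
            cfg["data"].update(v)
        elif v is not None:
            cfg[k] = v
    unknown = set(cfg) - set(DEFAULTS)
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    return cfg


def load_data(cfg: dict):
    """(train, val) pairs per the config's data block, seeded by the run."""
    d = cfg["data"]
    if d.get("source") == "file" or d.get("path"):
        images, labels, _ = hio.load_dataset(d["path"])
    else:
        toy = ToyDatasetConfig(
            n_classes=d["n_classes"],
            image_size=d["image_size"],
            channels=d["channels"],
            n_per_class=d["n_per_class"],
            jitter=d["jitter"],
            noise_sd=d["noise_sd"],
            seed=cfg["seed"],
        )
        images, labels = make_toy_dataset(toy)
    return split((images, labels), cfg["val_fraction"], seed=cfg["seed"])


def _build(cfg: dict, input_shape: tuple, n_classes: int):
    spec = parse_architecture(
        cfg["arch"],
        input_shape=input_shape,
        n_classes=n_classes,
        mode=cfg["mode"],
        sparsity=cfg["sparsity"],
        loss=cfg["loss"],
        init=cfg["init"],
        untied=cfg["untied"],
        local_init=cfg["local_init"],
    )
    tc = TrainingConfig(
        eta=cfg["lr"],
        batch_size=cfg["batch_size"],
        epochs=cfg["epochs"],
        seed=cfg["seed"],
        mu=cfg["mu"],
    )
    rngs = component_rngs(cfg["seed"])
    net = build_network(spec, tc, rng=rngs["init"])
    return net, tc, rngs


def run_experiment(cfg: dict, out_dir, log=print):
    """Train per config; write metrics.csv, checkpoint.h5, manifest.json."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (tr, va) = load_data(cfg)
    net, tc, rngs = _build(cfg, tr[0].shape[1:], int(np.max(tr[1])) + 1)
    history = []
    for row in _train_epochs(net, tr, va, tc, rngs):
        history.append(row)
        if log:
            align = " ".join(f"{a:+.3f}" for a in row.alignment)
            log(
                f"epoch {row.epoch:4d}  train_err {row.train_error:.4f}  "
                f"val_err {row.val_error:.4f}  loss {row.train_loss:.4f}  "
                f"align [{align}]"
            )
    hio.write_metrics(history, out / "metrics.csv")
    hio.save_checkpoint(net, out / "checkpoint.h5")
    hio.write_manifest(out / "manifest.json", cfg)
    return net, history


def _train_epochs(net, tr, va, tc, rngs):
    one = TrainingConfig(
        eta=tc.eta, batch_size=tc.batch_size, epochs=1, seed=tc.seed, mu=tc.mu
    )
    for epoch in range(tc.epochs):
        (row,) = train(net, tr, va, one, rngs=rngs)
        row.epoch = epoch + 1
        yield row


def compare_modes(cfg: dict, modes: list[str], out_dir=None, log=print):
    """Matched-seed runs across modes; side-by-side error-curve table.

    All runs share W(0) (the init stream draws W before R) and the same
    data, shuffling, and dropout streams.
    """
    (tr, va) = load_data(cfg)
    columns: dict[str, list[float]] = {}
    for mode in modes:
        mcfg = copy.deepcopy(cfg)
        mcfg["mode"] = mode
        net, tc, rngs = _build(mcfg, tr[0].shape[1:], int(np.max(tr[1])) + 1)
        history = train(net, tr, va, tc, rngs=rngs)
        columns[f"train_error_{mode}"] = [r.train_error for r in history]
        columns[f"val_error_{mode}"] = [r.val_error for r in history]
        if log:
            log(f"mode {mode}: final val_err {history[-1].val_error:.4f}")
    frame = pd.DataFrame(columns)
    frame.insert(0, "epoch", np.arange(1, len(frame) + 1))
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        frame.to_csv(out / "compare.csv", index=False)
        hio.write_manifest(out / "manifest.json", {**cfg, "modes": modes})
    return frame


def evaluate_checkpoint(cfg: dict, checkpoint_path) -> float:
    """Rebuild the architecture, restore weights, return validation error."""
    (tr, va) = load_data(cfg)
    net, _, _ = _build(cfg, tr[0].shape[1:], int(np.max(tr[1])) + 1)
    hio.load_checkpoint_into(net, checkpoint_path)
    return evaluate(net, va[0], va[1])
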