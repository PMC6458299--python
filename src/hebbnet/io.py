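"""Checkpoints, datasets, metrics tables, and run manifests.

Checkpoints are HDF5 containers with one group per stage; weight arrays
round-trip bit-exactly.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from . import layers as L
from .network import (
    ConvStage,
    DenseStage,
    DropStage,
    LocalStage,
    MaxPoolStage,
    MetricsRow,
    Network,
    SumStage,
)

__all__ = [
    "save_checkpoint",
    "load_checkpoint_into",
    "save_dataset",
    "load_dataset",
    "metrics_to_frame",
    "write_metrics",
    "write_manifest",
]


def _write_opt(g: h5py.Group, name: str, arr) -> None:
    if arr is not None:
        g.create_dataset(name, data=np.asarray(arr))


def _read_opt(g: h5py.Group, name: str):
    return g[name][()] if name in g else None


def save_checkpoint(net: Network, path) -> None:
    """One group per stage holding W, R, masks, and geometry attributes."""
    with h5py.File(path, "w") as f:
        f.attrs["n_stages"] = len(net.stages)
        f.attrs["mode"] = net.mode
        f.attrs["loss"] = net.loss
        for i, stage in enumerate(net.stages):
            g = f.create_group(f"stage_{i:03d}")
            g.attrs["kind"] = type(stage).__name__
            if isinstance(stage, DenseStage):
                g.create_dataset("W", data=stage.pair.W)
                g.create_dataset("R", data=stage.pair.R)
                _write_opt(g, "mask_W", stage.pair.mask_W)
                _write_opt(g, "mask_R", stage.pair.mask_R)
                g.attrs["is_output"] = stage.is_output
                g.attrs["in_shape"] = stage.in_shape
            elif isinstance(stage, ConvStage):
                g.create_dataset("W", data=stage.F)
                g.create_dataset("R", data=stage.G)
                _write_opt(g, "mask_W", stage.mask_F)
                _write_opt(g, "mask_R", stage.mask_G)
                _write_geom(g, stage.geom)
            elif isinstance(stage, LocalStage):
                g.create_dataset("W", data=stage.lw.w_data)
                g.create_dataset("R", data=stage.lw.r_data)
                g.create_dataset("mask_W", data=stage.lw.mask_w)
                g.create_dataset("mask_R", data=stage.lw.mask_r)
                _write_geom(g, stage.lw.geom)
            elif isinstance(stage, MaxPoolStage):
                g.attrs["window"] = stage.window
                g.attrs["stride"] = stage.stride
            elif isinstance(stage, DropStage):
                g.attrs["rate"] = stage.rate


def _write_geom(g: h5py.Group, geom: L.ConvGeometry) -> None:
    for k in ("in_channels", "out_channels", "kernel", "height", "width"):
        g.attrs[k] = getattr(geom, k)


def load_checkpoint_into(net: Network, path) -> Network:
    """Restore weights into a structurally matching network (bit-exact)."""
    with h5py.File(path, "r") as f:
        if f.attrs["n_stages"] != len(net.stages):
            raise ValueError("checkpoint does not match network structure")
        for i, stage in enumerate(net.stages):
            g = f[f"stage_{i:03d}"]
            if g.attrs["kind"] != type(stage).__name__:
                raise ValueError(
                    f"stage {i}: checkpoint has {g.attrs['kind']}, "
                    f"network has {type(stage).__name__}"
                )
            if isinstance(stage, DenseStage):
                stage.pair.W = g["W"][()]
                stage.pair.R = g["R"][()]
                stage.pair.mask_W = _read_opt(g, "mask_W")
                stage.pair.mask_R = _read_opt(g, "mask_R")
            elif isinstance(stage, ConvStage):
                stage.F = g["W"][()]
                stage.G = g["R"][()]
                stage.mask_F = _read_opt(g, "mask_W")
                stage.mask_G = _read_opt(g, "mask_R")
            elif isinstance(stage, LocalStage):
                stage.lw.w_data = g["W"][()]
                stage.lw.r_data = g["R"][()]
                stage.lw.mask_w = g["mask_W"][()]
                stage.lw.mask_r = g["mask_R"][()]
    return net


def save_dataset(path, images: np.ndarray, labels: np.ndarray,
                 attrs: dict | None = None) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("images", data=images)
        f.create_dataset("labels", data=labels)
        for k, v in (attrs or {}).items():
            f.attrs[k] = v


def load_dataset(path) -> tuple[np.ndarray, np.ndarray, dict]:
    with h5py.File(path, "r") as f:
        return f["images"][()], f["labels"][()], dict(f.attrs)


def load_cifar_archive(directory) -> tuple[np.ndarray, np.ndarray]:
    """Optional reader for the standard pickled CIFAR batch layout.

    Looks for ``data_batch_*`` / ``train`` pickle files under
    ``directory``; returns images as (N, 3, 32, 32) floats in [0, 1] and
    integer labels.  Provided for convenience only — no test exercises
    it and no experiment in the suite depends on external data.
    """
    import pickle

    directory = Path(directory)
    batches = sorted(directory.glob("data_batch_*")) or [directory / "train"]
    images, labels = [], []
    for path in batches:
        if not path.exists():
            raise FileNotFoundError(f"no CIFAR batch files under {directory}")
        with open(path, "rb") as fh:
            d = pickle.load(fh, encoding="bytes")
        data = d[b"data"] if b"data" in d else d["data"]
        labs = (d.get(b"labels") or d.get(b"fine_labels")
                if isinstance(d, dict) and b"data" in d
                else d.get("labels") or d.get("fine_labels"))
        images.append(np.asarray(data).reshape(-1, 3, 32, 32) / 255.0)
        labels.append(np.asarray(labs, dtype=int))
    return np.concatenate(images), np.concatenate(labels)


def metrics_to_frame(history: list[MetricsRow]) -> pd.DataFrame:
    n_align = max((len(r.alignment) for r in history), default=0)
    rows = []
    for r in history:
        row = {
            "epoch": r.epoch,
            "train_error": r.train_error,
            "val_error": r.val_error,
            "train_loss": r.train_loss,
        }
        for i in range(n_align):
            row[f"align_corr_layer_{i + 1}"] = (
                r.alignment[i] if i < len(r.alignment) else np.nan
            )
        rows.append(row)
    return pd.DataFrame(rows)


def write_metrics(history: list[MetricsRow], path) -> None:
    metrics_to_frame(history).to_csv(path, index=False)


def write_manifest(path, config: dict) -> None:
    """JSON manifest with the fully resolved configuration and seed."""
    path = Path(path)
    path.write_text(json.dumps(config, indent=2, sort_keys=True, default=str) + "\n")
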