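"""HDF5/JSON persistence for weights, trials and rasters.

Weights round-trip bit-exactly: every array of the WeightSet is stored as an
HDF5 dataset alongside a JSON sidecar holding the generating NetworkConfig.
Rasters are stored as sparse (unit, time) triplets.
"""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path

import h5py
import numpy as np

from .config import NetworkConfig
from .network import WeightSet
from .task import Trial


def save_weights(path, ws: WeightSet, config: NetworkConfig | None = None) -> None:
    path = Path(path)
    with h5py.File(path, "w") as f:
        for name in ("W_in", "W_rec", "W_out", "mask_in", "mask_rec", "mask_out",
                     "sign", "input_pool", "regrow_forbidden"):
            f.create_dataset(name, data=getattr(ws, name))
        f.attrs["dale_enforced"] = ws.dale_enforced
    if config is not None:
        path.with_suffix(".json").write_text(json.dumps(asdict(config), indent=2))


def load_weights(path) -> WeightSet:
    with h5py.File(path, "r") as f:
        kw = {name: f[name][()] for name in
              ("W_in", "W_rec", "W_out", "mask_in", "mask_rec", "mask_out",
               "sign", "input_pool", "regrow_forbidden")}
        for name in ("mask_in", "mask_rec", "mask_out", "input_pool", "regrow_forbidden"):
            kw[name] = kw[name].astype(bool)
        return WeightSet(dale_enforced=bool(f.attrs["dale_enforced"]), **kw)


def save_trials(path, trials: list[Trial]) -> None:
    with h5py.File(path, "w") as f:
        for k, tr in enumerate(trials):
            g = f.create_group(f"trial_{k:06d}")
            g.create_dataset("spikes", data=tr.spikes, compression="gzip")
            g.create_dataset("target", data=tr.target)
            g.create_dataset("rates", data=tr.rates)
            g.create_dataset("entropy_seq", data=tr.entropy_seq)
            g.attrs["change_time"] = -1 if tr.change_time is None else tr.change_time
            g.attrs["label_map"] = json.dumps({str(k_): v for k_, v in tr.label_map.items()})


def load_trials(path) -> list[Trial]:
    trials = []
    with h5py.File(path, "r") as f:
        for key in sorted(f.keys()):
            g = f[key]
            ct = int(g.attrs["change_time"])
            trials.append(Trial(
                spikes=g["spikes"][()], target=g["target"][()],
                rates=g["rates"][()], entropy_seq=g["entropy_seq"][()],
                change_time=None if ct < 0 else ct,
                label_map={int(k): v for k, v in json.loads(g.attrs["label_map"]).items()}))
    return trials


def save_dot_video(path, frames: np.ndarray) -> None:
    """Write a (T, H, W) uint8 frame stack as a multi-page grayscale TIFF."""
    import tifffile
    tifffile.imwrite(path, np.asarray(frames, dtype=np.uint8),
                     photometric="minisblack")


def save_rasters(path, rasters: np.ndarray, metadata: dict | None = None) -> None:
    """Store (n_trials, units, T) binary rasters as sparse triplets."""
    rasters = np.asarray(rasters)
    with h5py.File(path, "w") as f:
        trial, unit, time = np.nonzero(rasters)
        f.create_dataset("trial", data=trial.astype(np.int32), compression="gzip")
        f.create_dataset("unit", data=unit.astype(np.int32), compression="gzip")
        f.create_dataset("time", data=time.astype(np.int32), compression="gzip")
        f.attrs["shape"] = rasters.shape
        if metadata:
            f.attrs["metadata"] = json.dumps(metadata)


def load_rasters(path) -> np.ndarray:
    with h5py.File(path, "r") as f:
        shape = tuple(f.attrs["shape"])
        z = np.zeros(shape, dtype=np.uint8)
        z[f["trial"][()], f["unit"][()], f["time"][()]] = 1
    return z
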