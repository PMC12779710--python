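"""Spike-time jitter perturbation of trained-network rasters.

Each recurrent-unit spike is shifted by an independent integer offset drawn
uniformly from [-half_width, +half_width]; offsets that would push a spike
outside the trial or onto an already-occupied millisecond for that unit are
redrawn (bounded retries, then the nearest free slot), so per-unit spike
counts -- and hence all rates -- are exactly preserved.  The perturbed raster
is then re-read with the original output weights without re-simulating the
recurrent dynamics, and task loss is compared overall and on the no-change
'1'- and '0'-labeled trial subsets.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .dynamics import SpikeRaster, readout_array
from .training import task_loss


@dataclass
class JitterConfig:
    """Jitter window and tie-breaking rules."""

    half_width: int = 5     # ms
    max_retries: int = 100  # redraws before falling back to the nearest free slot
    seed: int | None = None

    def window_fraction(self, T: int) -> float:
        """Window width relative to the trial duration (e.g. 0.245% at defaults)."""
        return 2 * self.half_width / T

    def validate(self) -> None:
        if self.half_width < 0:
            raise ValueError("half_width must be >= 0")


def jitter_spikes(raster, cfg: JitterConfig, rng: np.random.Generator):
    """Jitter every spike of a (units x T) binary raster, preserving counts."""
    cfg.validate()
    z = raster.z if isinstance(raster, SpikeRaster) else np.asarray(raster)
    n, T = z.shape
    out = np.zeros_like(z)
    if cfg.half_width == 0:
        out[:] = z
        return SpikeRaster(out, raster.dt) if isinstance(raster, SpikeRaster) else out
    w = cfg.half_width
    for u in range(n):
        times = np.flatnonzero(z[u])
        occupied = np.zeros(T, dtype=bool)
        for t in times:
            placed = False
            for _ in range(cfg.max_retries):
                t_new = t + int(rng.integers(-w, w + 1))
                if 0 <= t_new < T and not occupied[t_new]:
                    occupied[t_new] = True
                    placed = True
                    break
            if not placed:  # nearest free slot to the original time
                free = np.flatnonzero(~occupied)
                t_new = free[np.argmin(np.abs(free - t))]
                occupied[t_new] = True
        out[u, occupied] = 1
    return SpikeRaster(out, raster.dt) if isinstance(raster, SpikeRaster) else out


def evaluate_jittered(W_out: np.ndarray, rasters: np.ndarray,
                      targets: np.ndarray, cfg: JitterConfig,
                      rng: np.random.Generator,
                      change_flags: np.ndarray | None = None,
                      labels: np.ndarray | None = None) -> pd.DataFrame:
    """Loss comparison table for original vs jittered rasters.

    ``rasters``: (n_trials, units, T); ``targets``: (n_trials, T, n_out) as
    the task loss consumes them; ``change_flags``: per-trial bool, True if the
    trial contained an entropy change; ``labels``: per-trial constant label of
    no-change trials (ignored for change trials).  Rows: overall, and -- when
    the metadata is given -- the no-change '1'- and '0'-labeled subsets.
    """
    cfg.validate()
    rasters = np.asarray(rasters)
    n_trials = rasters.shape[0]
    jittered = np.stack([jitter_spikes(rasters[k], cfg, rng) for k in range(n_trials)])
    y_orig = readout_array(rasters, W_out)
    y_jit = readout_array(jittered, W_out)
    loss_orig = np.atleast_1d(task_loss(y_orig, targets))
    loss_jit = np.atleast_1d(task_loss(y_jit, targets))

    rows = [{"subset": "all", "unjittered_loss": float(loss_orig.mean()),
             "jittered_loss": float(loss_jit.mean()), "n_trials": n_trials,
             "seed": cfg.seed}]
    if change_flags is not None and labels is not None:
        change_flags = np.asarray(change_flags, bool)
        labels = np.asarray(labels)
        for lab in (1, 0):
            sel = ~change_flags & (labels == lab)
            rows.append({"subset": f"no_change_label{lab}",
                         "unjittered_loss": float(loss_orig[sel].mean()) if sel.any() else np.nan,
                         "jittered_loss": float(loss_jit[sel].mean()) if sel.any() else np.nan,
                         "n_trials": int(sel.sum()), "seed": cfg.seed})
    return pd.DataFrame(rows)
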