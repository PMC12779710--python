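"""Pipeline orchestration: init -> dataset -> train -> analyze -> jitter.

Each stage reads the artifacts of its predecessors from the run directory and
persists its own, so a run is resumable stage by stage.  A RunManifest (JSON)
records the configuration snapshot, seeds, stage timestamps and a checksummed
file inventory; a fixed seed reproduces every artifact bit-identically.
"""

from __future__ import annotations

import datetime
import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__, io
from .analysis import (classify_modulation, cross_within_ratio,
                       input_modulation_ratio, ratio_trajectory,
                       top_quantile_persistence, weight_summary)
from .config import RunConfig
from .dynamics import simulate_trial
from .network import initialize_network
from .perturb import JitterConfig, evaluate_jittered
from .task import balanced_eval_trials, stack_trials
from .training import train

STAGES = ("init", "dataset", "train", "analyze", "jitter")
N_EVAL_TRIALS = 60  # held-out classification set: 30 per initial entropy level


@dataclass
class RunManifest:
    config: dict
    seed: int
    version: str = __version__
    stages: dict = field(default_factory=dict)     # stage -> ISO timestamp
    files: dict = field(default_factory=dict)      # relative path -> sha256

    def save(self, path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2, sort_keys=True))


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _require(path: Path, stage: str, needed_by: str) -> Path:
    if not path.exists():
        raise FileNotFoundError(
            f"stage '{needed_by}' needs {path.name}; run stage '{stage}' first")
    return path


def run_pipeline(config: RunConfig, out_dir, seed: int = 0,
                 stages=STAGES, jitter_half_width: int = 5) -> RunManifest:
    """Execute the requested pipeline stages in order under ``out_dir``.

    Sub-seeds for each stage are derived deterministically from ``seed``, so
    re-running any stage subset with the same seed reproduces its artifacts.
    """
    config.validate()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest_path = out / "manifest.json"
    if manifest_path.exists():
        manifest = RunManifest(**json.loads(manifest_path.read_text()))
        manifest.config = config.to_dict()
        manifest.seed = seed
    else:
        manifest = RunManifest(config=config.to_dict(), seed=seed)
    ss = np.random.SeedSequence(seed)
    sub = {name: np.random.default_rng(s)
           for name, s in zip(STAGES, ss.spawn(len(STAGES)))}
    config.save(out / "config.yaml")

    if "init" in stages:
        ws = initialize_network(config.network, sub["init"])
        io.save_weights(out / "weights_init.h5", ws, config.network)
        _stamp(manifest, "init")

    if "dataset" in stages:
        trials = balanced_eval_trials(config.channels, N_EVAL_TRIALS,
                                      sub["dataset"],
                                      change_prob=config.training.change_prob)
        io.save_trials(out / "eval_trials.h5", trials)
        _stamp(manifest, "dataset")

    if "train" in stages:
        _require(out / "weights_init.h5", "init", "train")
        est = train(config, rng=sub["train"])
        io.save_weights(out / "weights_trained.h5", est.weights_, config.network)
        est.loss_history_.to_csv(out / "losses.csv", index=False)
        with open(out / "rewire_events.log", "w") as fh:
            for ev in est.rewire_events_:
                fh.write(f"batch={ev.batch} layer={ev.layer} pruned={ev.pruned} "
                         f"regrown={ev.regrown} w={ev.new_weight}\n")
        snaps = out / "snapshots"
        snaps.mkdir(exist_ok=True)
        for upd, ws in est.snapshots_:
            io.save_weights(snaps / f"weights_{upd:06d}.h5", ws)
        _stamp(manifest, "train")

    if "analyze" in stages:
        ws = io.load_weights(_require(out / "weights_trained.h5", "train", "analyze"))
        ws0 = io.load_weights(_require(out / "weights_init.h5", "init", "analyze"))
        trials = io.load_trials(_require(out / "eval_trials.h5", "dataset", "analyze"))
        x, _ = stack_trials(trials)
        rasters, outputs = simulate_trial(ws, x, config.neuron, sub["analyze"])
        targets = np.stack([tr.target for tr in trials])
        prof = classify_modulation(rasters, targets, input_spikes=x)
        io.save_rasters(out / "eval_rasters.h5", rasters)
        np.save(out / "eval_targets.npy", targets)

        summary = {
            "modulation_counts": prof.counts(),
            "cross_within": cross_within_ratio(ws.W_rec, prof, mask=ws.mask_rec,
                                               sign=ws.sign).ratio,
            "cross_within_initial": cross_within_ratio(ws0.W_rec, prof,
                                                       mask=ws0.mask_rec,
                                                       sign=ws0.sign).ratio,
            "input_ratio": (input_modulation_ratio(ws.W_in, prof.channel_label, ws.sign)
                            if prof.channel_label is not None else None),
            "top_decile_persistence": top_quantile_persistence(
                ws0.W_rec, ws.W_rec, 0.10),
            "top_quartile_persistence": top_quantile_persistence(
                ws0.W_rec, ws.W_rec, 0.25),
        }
        (out / "analysis_summary.json").write_text(
            json.dumps(summary, indent=2, default=float))
        weight_summary(ws, prof).to_csv(out / "weight_summary.csv", index=False)

        snaps = sorted((out / "snapshots").glob("weights_*.h5"))
        if snaps:
            snapshots = [(int(p.stem.split("_")[1]), io.load_weights(p)) for p in snaps]
            ratio_trajectory(snapshots, prof, ws.sign).to_csv(
                out / "ratio_trajectory.csv", index=False)
        _stamp(manifest, "analyze")

    if "jitter" in stages:
        ws = io.load_weights(_require(out / "weights_trained.h5", "train", "jitter"))
        rasters = io.load_rasters(_require(out / "eval_rasters.h5", "analyze", "jitter"))
        trials = io.load_trials(out / "eval_trials.h5")
        enc = config.network.output_encoding
        target_series = np.stack([tr.target_series(enc) for tr in trials])
        cfg = JitterConfig(half_width=jitter_half_width, seed=seed)
        table = evaluate_jittered(
            ws.W_out, rasters, target_series, cfg, sub["jitter"],
            change_flags=np.array([tr.change_time is not None for tr in trials]),
            labels=np.array([tr.target[0] for tr in trials]))
        table.to_csv(out / "jitter_comparison.csv", index=False)
        _stamp(manifest, "jitter")

    manifest.files = {p.relative_to(out).as_posix(): _sha256(p)
                      for p in sorted(out.rglob("*"))
                      if p.is_file() and p.name != "manifest.json"}
    manifest.save(manifest_path)
    return manifest


def _stamp(manifest: RunManifest, stage: str) -> None:
    manifest.stages[stage] = datetime.datetime.now(datetime.timezone.utc).isoformat()
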