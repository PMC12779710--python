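"""Reference experiments: self-contained routines reproducing the study's
headline quantities at their stated conditions.

These are the computations behind ``scripts/acceptance.py`` and the
acceptance-level tests; each builds its own inputs from the synthetic task
generator and runs the package end to end.
"""

from __future__ import annotations

import numpy as np

from .analysis import (classify_modulation, cross_within_ratio,
                       random_modulation_profile)
from .config import ALIFParams, ChannelProfile, NetworkConfig, preset_config
from .dynamics import simulate_trial
from .network import initialize_network
from .task import HIGH, LOW, balanced_eval_trials, make_trial, stack_trials
from .training import task_loss, train


def untrained_task_loss(seed: int, n_networks: int = 10, n_trials: int = 30) -> dict:
    """Mean per-trial task loss of freshly initialized, untrained networks.

    Each network is evaluated on balanced synthetic full-length trials (half
    containing an entropy change); the entropy-to-label assignment is swapped
    for half of the networks, as in the reference protocol.
    """
    ss = np.random.SeedSequence([seed, 4])
    params = ALIFParams()
    profile = ChannelProfile()
    losses = []
    for k, child in enumerate(ss.spawn(n_networks)):
        rng = np.random.default_rng(child)
        ws = initialize_network(NetworkConfig(), rng)
        label_map = {HIGH: 0, LOW: 1} if k % 2 == 0 else {HIGH: 1, LOW: 0}
        trials = [make_trial(profile, label_map, 0.5, rng) for _ in range(n_trials)]
        x, y = stack_trials(trials)
        _, outputs = simulate_trial(ws, x, params, rng)
        losses.extend(np.atleast_1d(task_loss(outputs, y)))
    return {"value": float(np.mean(losses)), "sd": float(np.std(losses)),
            "n": len(losses)}


def null_inhibitory_ratio(seed: int, n_networks: int = 20) -> dict:
    """Pooled i across/within-modulation ratio on initialized weights under
    random modulation labels drawn at trained-state population proportions."""
    ss = np.random.SeedSequence([seed, 10])
    cfg = NetworkConfig()
    ratios = []
    for child in ss.spawn(n_networks):
        rng = np.random.default_rng(child)
        ws = initialize_network(cfg, rng)
        prof = random_modulation_profile(cfg.n_e, cfg.n_i, rng)
        rs = cross_within_ratio(ws.W_rec, prof, mask=ws.mask_rec, sign=ws.sign)
        ratios.append(rs.ratio["i_pooled"])
    return {"value": float(np.mean(ratios)), "sd": float(np.std(ratios)),
            "n": n_networks}


def _bootstrap_ratio_ci(W, mask, sign, profile, key: str,
                        rng: np.random.Generator, n_boot: int = 1000,
                        alpha: float = 0.05):
    """Percentile bootstrap CI of a pooled across/within ratio, resampling
    active classified connections."""
    lab = profile.unit_label
    pre_is_i = sign < 0 if key == "i_pooled" else sign > 0
    sel = mask & (lab >= 0)[:, None] & (lab >= 0)[None, :] & pre_is_i[:, None]
    same = lab[:, None] == lab[None, :]
    w = np.abs(W[sel])
    s = same[sel]
    if w.size == 0 or s.all() or not s.any():
        return (np.nan, np.nan)
    vals = []
    for _ in range(n_boot):
        idx = rng.integers(0, w.size, size=w.size)
        wi, si = w[idx], s[idx]
        if si.all() or not si.any():
            continue
        vals.append(wi[~si].mean() / wi[si].mean())
    lo, hi = np.percentile(vals, [100 * alpha / 2, 100 * (1 - alpha / 2)])
    return float(lo), float(hi)


def scaled_down_emergence(seed: int, n_updates: int = 4000,
                          learning_rate: float = 4e-3,
                          n_e: int = 96, n_i: int = 24,
                          one_hot: bool = False, n_eval: int = 60) -> dict:
    """Dual-loss training at workstation scale and the resulting circuit motifs.

    Runs a 120-unit variant of the ``desk`` preset (96e/24i at the full
    connection statistics, 20-block trials, batches of 10), classifies
    modulation on held-out balanced trials, and reports initial and final
    task loss, the pooled inhibitory and excitatory across/within ratios, and
    bootstrap confidence intervals of the final ratios.
    """
    cfg = preset_config("desk")
    cfg.network.n_e, cfg.network.n_i = n_e, n_i
    cfg.training.learning_rate = learning_rate
    if one_hot:
        cfg.network.output_encoding = "one_hot"
    rng = np.random.default_rng(np.random.SeedSequence([seed, 6]))
    est = train(cfg, rng=rng, n_updates=n_updates)
    lh = est.loss_history_
    epoch = max(1, n_updates // 10)
    task_first = float(lh.task.iloc[:epoch].mean())
    task_last = float(lh.task.iloc[-epoch:].mean())

    ev = balanced_eval_trials(cfg.channels, n_eval, rng,
                              change_prob=cfg.training.change_prob)
    x, y = stack_trials(ev, encoding=cfg.network.output_encoding)
    rasters, outputs = est.simulate(x)
    targets = np.stack([tr.target for tr in ev])
    prof = classify_modulation(rasters, targets, input_spikes=x)

    ws, ws0 = est.weights_, est.initial_weights_
    final = cross_within_ratio(ws.W_rec, prof, mask=ws.mask_rec, sign=ws.sign)
    initial = cross_within_ratio(ws0.W_rec, prof, mask=ws0.mask_rec, sign=ws0.sign)
    ci_i = _bootstrap_ratio_ci(ws.W_rec, ws.mask_rec, ws.sign, prof,
                               "i_pooled", rng)
    ci_e = _bootstrap_ratio_ci(ws.W_rec, ws.mask_rec, ws.sign, prof,
                               "e_pooled", rng)
    return {
        "task_loss_first_epoch": task_first,
        "task_loss_last_epoch": task_last,
        "eval_task_loss": float(np.mean(task_loss(outputs, y))),
        "i_ratio_final": final.ratio["i_pooled"],
        "e_ratio_final": final.ratio["e_pooled"],
        "i_ratio_initial": initial.ratio["i_pooled"],
        "e_ratio_initial": initial.ratio["e_pooled"],
        "i_ratio_ci": ci_i,
        "e_ratio_ci": ci_e,
        "modulation_counts": prof.counts(),
        "n_updates": n_updates,
    }
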