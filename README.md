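# pushpull

Biologically constrained recurrent spiking neural networks: construction,
surrogate-gradient training, and analysis of the excitatory/inhibitory circuit
motifs that emerge when such networks learn a simple perceptual task.

## The problem

How does a sparse, recurrently connected network of spiking neurons — built
with the connection statistics of mouse visual cortex — reorganize its
synapses to perform a task? This package implements a complete in-silico
experiment around that question, for computational neuroscientists studying
trained spiking-network models:

* **Model**: 300 adaptive leaky integrate-and-fire (ALIF) units, 240
  excitatory and 60 inhibitory, connected sparsely with cortical class-wise
  probabilities (p_e→e = 0.160, p_e→i = 0.205, p_i→e = 0.252, p_i→i = 0.284),
  log-normal excitatory weights (mean 0.6005 mV) and 10× stronger inhibition,
  under Dale's law. Membrane dynamics per millisecond:
  v ← E_m + α(v − E_m) + I − z(v_th − E_m), adaptive threshold
  A = v_th + βa with a ← ρa + z, and a 4-ms refractory period.
* **Task**: report, millisecond by millisecond over a 4080-ms trial, the
  motion-entropy level of a drifting-dot stimulus; in half of the trials the
  level changes once at a random time. The stimulus reaches the network as 16
  Poisson input channels calibrated to the published per-channel rate
  differences between entropy levels.
* **Training**: backpropagation through time with a triangular surrogate in
  place of the spike derivative (ψ = (γ/v_eff) max(0, 1 − |v − A|/v_eff)),
  Adam over 30-trial batches, a dual objective
  E_total = E_task + λ·E_rate (per-ms readout MSE plus a 20-Hz rate
  objective), and DEEP R rewiring that preserves sign constraints and
  class-wise connection counts.
* **Analyses**: classification of units by preferred output label,
  cross-modulation vs within-modulation weight ratios (the "push-pull"
  inhibition signature), input-layer reweighting ratios, persistence of
  initially strong weights, KS comparisons, and a spike-time jitter
  experiment quantifying the role of millisecond coordination.

Everything is synthetic and self-contained: no videos, recordings or
external data are needed. See `docs/methods.md` for the full model
description and the design decisions.

## Worked example

The trainable network is a scikit-learn-style estimator. A reduced-scale
("desk") experiment — 60 units, 20-block trials, the full 16-channel input
model — fits in minutes on a laptop core:

```python
import numpy as np
from pushpull import preset_config
from pushpull.task import make_dataset
from pushpull.estimator import ALIFNetworkRegressor

cfg = preset_config("desk")
rng = np.random.default_rng(0)
trials = make_dataset(cfg.channels, n_unique=60, total=2000 * 10, rng=rng)
est = ALIFNetworkRegressor.from_config(cfg, random_state=0)
est.set_params(learning_rate=1e-2)
est.fit_trials(trials)

lh = est.loss_history_
print("task loss, first/last 200 updates: %.3f -> %.3f"
      % (lh.task.iloc[:200].mean(), lh.task.iloc[-200:].mean()))
print("scaled rate loss, first/last 200 updates: %.3f -> %.4f"
      % (lh.rate_scaled.iloc[:200].mean(), lh.rate_scaled.iloc[-200:].mean()))
rast, _ = est.simulate(np.stack([t.spikes for t in trials[:20]]))
print("mean rate after training: %.4f spikes/ms" % rast.mean())
```

```
task loss, first/last 200 updates: 0.536 -> 0.534
scaled rate loss, first/last 200 updates: 0.798 -> 0.0790
mean rate after training: 0.0187 spikes/ms
```

The rate objective collapses first: the network, nearly silent at
initialization, is pulled to sparse distributed spiking at the 0.020
spikes/ms target. The task loss is still at its chance plateau here (≈ 0.5,
the mean squared binary target) — at reduced scale it starts declining after
a few thousand updates. The longer reference experiment
(`pushpull.experiments.scaled_down_emergence`, 120 units, 4000 updates,
≈ 9 min) shows the decline and the circuit reorganization together; one run
at seed 123 prints

```
task_loss_first_epoch 0.536 -> task_loss_last_epoch 0.510
i_ratio: 1.14 (initial) -> 1.38 (final), 95% CI (1.21, 1.57)
e_ratio: 0.99 (initial) -> 0.79 (final), 95% CI (0.74, 0.83)
```

— inhibitory across/within-modulation weight ratio above 1, excitatory below
1: the push-pull signature, whose full-scale reference values are 2.0 and
0.6.

The same machinery is scriptable from the shell:

```bash
pushpull run --preset desk --seed 0 --out-dir runs/demo     # init→…→jitter
pushpull report --out-dir runs/demo
```

which persists weights (HDF5), losses and analysis tables (CSV), a summary
(JSON) and a checksummed run manifest.

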