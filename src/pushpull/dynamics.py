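"""Time-stepped simulation of the adaptive leaky integrate-and-fire network.

State per unit: membrane potential ``v`` (mV), adaptation variable ``a``
(a dimensionless, exponentially decaying spike-count trace) and a refractory
countdown.  Per step, with decay factors alpha = exp(-dt/tau_m) and
rho = exp(-dt/tau_a):

    v[t] = E_m + alpha (v[t-1] - E_m) + I[t] - z[t-1] (v_th - E_m)
    a[t] = rho a[t-1] + z[t-1]
    A[t] = v_th + beta a[t]
    z[t] = H(v[t] - A[t])    (forced 0 while refractory)

where I[t] sums weighted recurrent spikes from t-1 and weighted input-channel
spikes at t, and spiking subtracts the constant (v_th - E_m) on the following
step.  The readout is a plain weighted sum of spikes per millisecond with no
output nonlinearity.

All arrays carry units first: a raster is units x time.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .config import ALIFParams
from .network import WeightSet


class SimulationError(RuntimeError):
    """Non-finite state encountered during simulation."""


@dataclass
class NeuronState:
    """Hidden state of the population: s = [a, v] plus the refractory counter."""

    v: np.ndarray
    a: np.ndarray
    refrac_count: np.ndarray

    @classmethod
    def initial(cls, n_units: int, params: ALIFParams, rng: np.random.Generator,
                batch_shape: tuple = ()) -> "NeuronState":
        shape = (n_units,) + batch_shape
        v = rng.normal(params.v_init_mean, params.v_init_sd, size=shape)
        return cls(v=v, a=np.zeros(shape), refrac_count=np.zeros(shape, dtype=np.int64))


@dataclass
class SpikeRaster:
    """Binary units x time spike record for one trial."""

    z: np.ndarray  # (n_units, T), {0, 1}
    dt: float = 1.0

    @property
    def n_units(self) -> int:
        return self.z.shape[0]

    @property
    def T(self) -> int:
        return self.z.shape[1]

    def rates(self) -> np.ndarray:
        """Per-unit mean rate in spikes per ms."""
        return self.z.mean(axis=1) / self.dt


def step(state: NeuronState, z_prev: np.ndarray, x_t: np.ndarray,
         weights: WeightSet, params: ALIFParams, t: int | None = None):
    """Advance the network one time step.

    ``z_prev`` are the spikes of the previous step and ``x_t`` the input-channel
    spikes of the current step; both may carry a trailing batch axis.  Returns
    ``(new_state, z)``.
    """
    I = weights.W_rec.T @ z_prev + weights.W_in.T @ x_t
    leak = params.E_m if params.leak_mode == "rest" else 0.0
    v = leak + params.alpha * (state.v - leak) + I - z_prev * (params.v_th - params.E_m)
    a = params.rho * state.a + z_prev
    A = params.v_th + params.beta * a

    refrac = state.refrac_count
    active = refrac == 0
    z = ((v > A) & active).astype(v.dtype)
    refrac = np.where(z > 0, params.t_refrac, np.maximum(refrac - 1, 0))

    if not np.isfinite(v).all():
        bad = np.argwhere(~np.isfinite(v))[0]
        raise SimulationError(f"non-finite membrane potential at unit {bad[0]}"
                              + (f", t={t}" if t is not None else ""))
    return NeuronState(v=v, a=a, refrac_count=refrac), z


def simulate_trial(weights: WeightSet, input_spikes: np.ndarray,
                   params: ALIFParams, rng: np.random.Generator,
                   v_init: np.ndarray | None = None):
    """Simulate one trial (or a batch of trials simultaneously).

    ``input_spikes`` is (channels, T) for a single trial or (B, channels, T)
    for a batch.  Membrane potentials start from Normal(v_init_mean, v_init_sd)
    unless ``v_init`` is given.  Returns ``(raster, outputs)`` where the raster
    is a :class:`SpikeRaster` (single trial) or a (B, units, T) array, and
    outputs are (T, n_out) or (B, T, n_out).
    """
    params.validate()
    batched = input_spikes.ndim == 3
    x = input_spikes if batched else input_spikes[None]
    B, C, T = x.shape
    if T <= 0:
        raise ValueError("trial length must be positive")
    if C != weights.n_channels:
        raise ValueError(f"expected {weights.n_channels} channels, got {C}")
    n = weights.n_units

    state = NeuronState.initial(n, params, rng, batch_shape=(B,))
    if v_init is not None:
        state.v = np.broadcast_to(np.asarray(v_init, dtype=float).reshape(n, -1),
                                  (n, B)).copy()
    z = np.zeros((n, B))
    raster = np.empty((B, n, T), dtype=np.uint8)
    xT = np.ascontiguousarray(np.moveaxis(x, 0, -1))  # (C, T, B)
    for t in range(T):
        state, z = step(state, z, xT[:, t, :], weights, params, t=t)
        raster[:, :, t] = z.T

    outputs = readout_array(raster, weights.W_out)
    if not batched:
        return SpikeRaster(raster[0], dt=params.dt), outputs[0]
    return raster, outputs


def readout_array(raster: np.ndarray, W_out: np.ndarray) -> np.ndarray:
    """Linear readout of a (B, units, T) raster -> (B, T, n_out)."""
    return np.einsum("but,uo->bto", raster.astype(float), W_out)


def readout(raster, W_out: np.ndarray, encoding: str = "single"):
    """Per-ms weighted sum of spikes for each output unit.

    Returns the (T, n_out) output series; for one-hot encoding additionally
    returns the per-ms predicted label (argmax over the two outputs).
    """
    z = raster.z if isinstance(raster, SpikeRaster) else np.asarray(raster)
    n_out = W_out.shape[1]
    expected = 2 if encoding == "one_hot" else 1
    if n_out != expected:
        raise ValueError(f"encoding {encoding!r} expects {expected} outputs, "
                         f"W_out has {n_out}")
    if z.shape[0] != W_out.shape[0]:
        raise ValueError("raster and W_out unit counts differ")
    y = z.T.astype(float) @ W_out
    if encoding == "one_hot":
        return y, np.argmax(y, axis=1)
    return y
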