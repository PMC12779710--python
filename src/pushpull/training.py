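"""Dual-loss surrogate-gradient training of the spiking network.

The network is unrolled over the full trial and differentiated in reverse mode
by hand, with the non-differentiable spike nonlinearity H(v - A) replaced in
the backward pass by the triangular pseudo-derivative

    psi = (gamma_pd / v_eff) * max(0, 1 - |v - A| / v_eff),

zero during the refractory period.  Gradients of the task loss (per-ms MSE of
the linear readout against the binary target), and of the rate loss (squared
deviation of the population mean rate from the 0.020 spikes/ms target, scaled
by ``lam_rate``), are accumulated over a batch of trials before a single Adam
step.  After every update, Dale's sign constraint is restored by DEEP R
rewiring: any active connection whose weight crossed zero is pruned and a
replacement is drawn uniformly from the free slots of the same layer and
presynaptic sign class, with a fresh weight from the initial distribution, so
per-class connection counts are conserved.

For gradient verification the spike nonlinearity can be replaced by its
differentiable surrogate (``spike_mode="soft"``: the piecewise-quadratic
antiderivative of psi, refractory dynamics disabled), making the whole forward
graph differentiable so the reverse pass can be checked against finite
differences.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .config import ALIFParams, NetworkConfig, TrainConfig
from .network import WeightSet

try:  # optional JIT acceleration; the NumPy path is the reference
    from numba import njit as _njit
    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    _HAVE_NUMBA = False

    def _njit(*a, **k):
        def wrap(f):
            return f
        return wrap

LAYERS = ("W_in", "W_rec", "W_out")


class GradientError(RuntimeError):
    """Non-finite gradient encountered."""


@dataclass
class LossRecord:
    """Losses of one batch (means over its trials)."""

    batch: int
    mode: str
    task: float
    rate_naive: float      # (mean rate - target)^2, unscaled, (spikes/ms)^2
    rate_scaled: float     # lam_rate * rate_naive
    total: float           # mode-dependent combination actually optimized


@dataclass
class RewireEvent:
    """One prune/regrow pair produced by DEEP R."""

    layer: str
    pruned: tuple
    regrown: tuple | None
    new_weight: float | None
    batch: int


def task_loss(y_pred: np.ndarray, y_target: np.ndarray):
    """Per-ms MSE between readout and target, averaged over time (and outputs).

    Accepts (T, n_out) for one trial (returns a scalar) or (B, T, n_out) for a
    batch (returns the per-trial vector).
    """
    y_pred, y_target = np.asarray(y_pred, float), np.asarray(y_target, float)
    if y_pred.shape != y_target.shape:
        raise ValueError(f"shape mismatch {y_pred.shape} vs {y_target.shape}")
    err = (y_pred - y_target) ** 2
    return err.mean(axis=(-2, -1))


def rate_loss(z: np.ndarray, target_rate: float, dt: float = 1.0):
    """Squared deviation of the population mean spike rate from the target.

    ``z`` is (units, T) or (B, units, T); rates are in spikes per ms.
    """
    if target_rate < 0:
        raise ValueError("target_rate must be >= 0")
    z = np.asarray(z, float)
    mean_rate = z.mean(axis=(-2, -1)) / dt
    return (mean_rate - target_rate) ** 2


def pseudo_derivative(v: np.ndarray, A: np.ndarray, refrac_count: np.ndarray,
                      params: ALIFParams) -> np.ndarray:
    """Surrogate gradient of the spike nonlinearity, zero while refractory."""
    veff = params.v_eff
    psi = (params.gamma_pd / veff) * np.maximum(0.0, 1.0 - np.abs((v - A) / veff))
    return np.where(refrac_count > 0, 0.0, psi)


def _soft_spike(u: np.ndarray, params: ALIFParams) -> np.ndarray:
    """Antiderivative of the triangular pseudo-derivative; d(soft)/du = psi(u)."""
    g, veff = params.gamma_pd, params.v_eff
    s = np.clip(u / veff, -1.0, 1.0)
    return np.where(s < 0, g * (0.5 + s + s**2 / 2), g * (0.5 + s - s**2 / 2))


@_njit(cache=True)
def _forward_hard_jit(Wr, Xdrive, v0, B, alpha, rho, beta, v_th, leak, reset,
                      t_refrac, gamma, veff):  # pragma: no cover - numba
    # Flat time-major layout: column t*B+b of the (n, T*B) outputs is step t,
    # trial b.  Avoids any transposition before the BLAS gradient assembly.
    # Recurrent propagation accumulates presynaptic rows only for units that
    # actually spiked (binary spikes are sparse at the ~2% target rate).
    n, TB = Xdrive.shape
    T = TB // B
    Z = np.zeros((n, TB))
    PSI = np.zeros((n, TB))
    v = v0.copy()
    a = np.zeros((n, B))
    z = np.zeros((n, B))
    refrac = np.zeros((n, B), dtype=np.int64)
    I = np.zeros((B, n))
    for t in range(T):
        I[:, :] = 0.0
        for b in range(B):
            for j in range(n):
                if z[j, b] != 0.0:
                    for i in range(n):
                        I[b, i] += Wr[j, i]
        base = t * B
        for i in range(n):
            for b in range(B):
                vi = leak + alpha * (v[i, b] - leak) + I[b, i] \
                    + Xdrive[i, base + b] - z[i, b] * reset
                ai = rho * a[i, b] + z[i, b]
                A = v_th + beta * ai
                if refrac[i, b] == 0:
                    znew = 1.0 if vi > A else 0.0
                    tmp = 1.0 - abs((vi - A) / veff)
                    if tmp > 0.0:
                        PSI[i, base + b] = gamma / veff * tmp
                    if znew > 0.0:
                        refrac[i, b] = t_refrac
                else:
                    znew = 0.0
                    refrac[i, b] -= 1
                v[i, b] = vi
                a[i, b] = ai
                z[i, b] = znew
                Z[i, base + b] = znew
    return Z, PSI


@_njit(cache=True)
def _backward_jit(Wr, gyW, c_rate, PSI, B, alpha, rho, beta,
                  reset):  # pragma: no cover - numba
    n, TB = PSI.shape
    T = TB // B
    GV = np.zeros((n, TB))
    gv_next = np.zeros((n, B))
    ga_next = np.zeros((n, B))
    for t in range(T - 1, -1, -1):
        prop = np.dot(Wr, gv_next)
        base = t * B
        for i in range(n):
            for b in range(B):
                gz = gyW[i, base + b] + c_rate[i, b] + prop[i, b] \
                    - reset * gv_next[i, b] + ga_next[i, b]
                gv = PSI[i, base + b] * gz + alpha * gv_next[i, b]
                ga_next[i, b] = -beta * PSI[i, base + b] * gz \
                    + rho * ga_next[i, b]
                GV[i, base + b] = gv
        for i in range(n):
            for b in range(B):
                gv_next[i, b] = GV[i, base + b]
    return GV


@_njit(cache=True)
def _spike_outer_jit(Z, GV, B):  # pragma: no cover - numba
    # gW_rec[j, i] = sum over flat columns c of Z[j, c] * GV[i, c + B];
    # Z is binary and sparse, so accumulate whole adjoint columns per spike.
    n, TB = Z.shape
    g = np.zeros((n, n))
    col = np.empty(n)
    for c in range(TB - B):
        any_spike = False
        for j in range(n):
            if Z[j, c] != 0.0:
                any_spike = True
                break
        if not any_spike:
            continue
        for i in range(n):
            col[i] = GV[i, c + B]
        for j in range(n):
            if Z[j, c] != 0.0:
                for i in range(n):
                    g[j, i] += col[i]
    return g


def forward_backward(ws: WeightSet, x: np.ndarray, y_target: np.ndarray,
                     params: ALIFParams, tcfg: TrainConfig,
                     rng: np.random.Generator, mode: str | None = None,
                     spike_mode: str = "hard", v_init: np.ndarray | None = None,
                     accel: str = "auto"):
    """Run one batch forward and backward through the unrolled dynamics.

    ``x`` is (B, channels, T) input spikes, ``y_target`` (B, T, n_out).
    Returns ``(grads, record, y_pred, raster)`` with gradients averaged over
    the batch and zeroed outside the structural masks.  ``accel="auto"`` uses
    the JIT-compiled kernels for the hard-spiking path when numba is present;
    ``accel="numpy"`` forces the reference implementation.
    """
    mode = mode or tcfg.mode
    include_task = mode in ("task_only", "dual")
    include_rate = mode in ("rate_only", "dual")
    B, C, T = x.shape
    n, n_out = ws.n_units, ws.n_outputs
    alpha, rho, beta = params.alpha, params.rho, params.beta
    reset = params.v_th - params.E_m
    leak = params.E_m if params.leak_mode == "rest" else 0.0
    if spike_mode not in ("hard", "soft"):
        raise ValueError(f"unknown spike_mode {spike_mode!r}")
    use_jit = (_HAVE_NUMBA and spike_mode == "hard" and accel == "auto")

    xT = np.ascontiguousarray(np.moveaxis(np.asarray(x, float), 0, -1))  # (C, T, B)
    x_flat = xT.reshape(C, T * B)
    Wr, Wi, Wo = ws.W_rec, ws.W_in, ws.W_out
    # input-layer drive for every step, flat (n, T*B) time-major layout
    Xdrive = Wi.T @ x_flat

    # ---- forward ----
    if v_init is None:
        v = rng.normal(params.v_init_mean, params.v_init_sd, size=(n, B))
    else:
        v = np.broadcast_to(np.asarray(v_init, float).reshape(n, -1), (n, B)).copy()
    if use_jit:
        Z, PSI = _forward_hard_jit(np.ascontiguousarray(Wr), Xdrive, v, B,
                                   alpha, rho, beta, params.v_th, leak, reset,
                                   params.t_refrac, params.gamma_pd, params.v_eff)
    else:
        a = np.zeros((n, B))
        z = np.zeros((n, B))
        refrac = np.zeros((n, B), dtype=np.int64)
        Z = np.empty((n, T * B))
        PSI = np.empty((n, T * B))
        for t in range(T):
            base = t * B
            I = Wr.T @ z + Xdrive[:, base:base + B]
            v = leak + alpha * (v - leak) + I - z * reset
            a = rho * a + z
            A = params.v_th + beta * a
            if spike_mode == "hard":
                active = refrac == 0
                z = ((v > A) & active).astype(float)
                psi = np.where(active,
                               pseudo_derivative(v, A, np.zeros_like(refrac), params),
                               0.0)
                refrac = np.where(z > 0, params.t_refrac, np.maximum(refrac - 1, 0))
            else:
                z = _soft_spike(v - A, params)
                psi = pseudo_derivative(v, A, np.zeros_like(refrac), params)
            Z[:, base:base + B] = z
            PSI[:, base:base + B] = psi

    Zv = Z.reshape(n, T, B)
    y_pred = np.ascontiguousarray((Wo.T @ Z).reshape(n_out, T, B).transpose(2, 1, 0))
    e_task = task_loss(y_pred, y_target)                      # (B,)
    pop_rate = Zv.mean(axis=(0, 1)) / params.dt               # (B,)
    e_rate_pop = (pop_rate - tcfg.target_rate) ** 2
    unit_rate = Zv.mean(axis=1) / params.dt                   # (n, B)
    e_rate_unit = ((unit_rate - tcfg.target_rate) ** 2).mean(axis=0)
    e_rate = e_rate_unit if tcfg.rate_loss_scope == "per_unit" else e_rate_pop
    record = LossRecord(batch=-1, mode=mode,
                        task=float(e_task.mean()),
                        rate_naive=float(e_rate_pop.mean()),
                        rate_scaled=float(tcfg.lam_rate * e_rate.mean()),
                        total=float((include_task * e_task
                                     + include_rate * tcfg.lam_rate * e_rate).mean()))

    # ---- backward ----
    gy = np.zeros_like(y_pred)
    if include_task:
        gy = 2.0 * (y_pred - np.asarray(y_target, float)) / (T * n_out)
    c_rate = np.zeros((n, B))
    if include_rate:
        if tcfg.rate_loss_scope == "per_unit":
            c_rate = tcfg.lam_rate * 2.0 * (unit_rate - tcfg.target_rate) \
                / (n * T * params.dt)
        else:
            c_rate = np.broadcast_to(
                tcfg.lam_rate * 2.0 * (pop_rate - tcfg.target_rate)
                / (n * T * params.dt), (n, B))

    # readout contribution to dL/dz, flat (n, T*B)
    gy_flat = np.ascontiguousarray(gy.transpose(2, 1, 0)).reshape(n_out, T * B)
    gyW = Wo @ gy_flat
    c_rate = np.ascontiguousarray(c_rate)
    if use_jit:
        GV = _backward_jit(np.ascontiguousarray(Wr), gyW, c_rate, PSI, B,
                           alpha, rho, beta, reset)
    else:
        GV = np.empty((n, T * B))
        gv_next = np.zeros((n, B))
        ga_next = np.zeros((n, B))
        for t in range(T - 1, -1, -1):
            base = t * B
            gz = gyW[:, base:base + B] + c_rate + Wr @ gv_next \
                - reset * gv_next + ga_next
            gv = PSI[:, base:base + B] * gz + alpha * gv_next
            ga_next = -beta * PSI[:, base:base + B] * gz + rho * ga_next
            GV[:, base:base + B] = gv
            gv_next = gv

    # weight gradients as single BLAS products over the flat (T*B) axis;
    # recurrent gradient pairs spikes at t-1 with adjoints at t (shift of B)
    if use_jit and spike_mode == "hard":
        gW_rec = _spike_outer_jit(Z, GV, B)  # binary Z: accumulate per spike
    else:
        gW_rec = Z[:, :T * B - B] @ GV[:, B:].T
    gW_in = x_flat @ GV.T
    gW_out = Z @ gy_flat.T

    grads = {"W_in": gW_in / B, "W_rec": gW_rec / B, "W_out": gW_out / B}
    for name, m in (("W_in", ws.mask_in), ("W_rec", ws.mask_rec), ("W_out", ws.mask_out)):
        grads[name][~m] = 0.0
        if not np.isfinite(grads[name]).all():
            raise GradientError(f"non-finite gradient in {name}")
    raster = Zv.transpose(2, 0, 1)  # (B, n, T) view
    return grads, record, y_pred, raster


@dataclass
class OptimizerState:
    """Adam moment accumulators for the three weight layers."""

    learning_rate: float = 1e-3
    beta1: float = 0.9
    beta2: float = 0.999
    eps: float = 1e-8
    step_count: int = 0
    m: dict = field(default_factory=dict)
    v: dict = field(default_factory=dict)

    @classmethod
    def for_weights(cls, ws: WeightSet, tcfg: TrainConfig) -> "OptimizerState":
        opt = cls(learning_rate=tcfg.learning_rate, beta1=tcfg.adam_beta1,
                  beta2=tcfg.adam_beta2, eps=tcfg.adam_eps)
        for name in LAYERS:
            opt.m[name] = np.zeros_like(getattr(ws, name))
            opt.v[name] = np.zeros_like(getattr(ws, name))
        return opt

    def apply(self, ws: WeightSet, grads: dict) -> None:
        """One Adam step in place; masked-out entries stay exactly zero."""
        self.step_count += 1
        t = self.step_count
        for name in LAYERS:
            g = grads[name]
            self.m[name] = self.beta1 * self.m[name] + (1 - self.beta1) * g
            self.v[name] = self.beta2 * self.v[name] + (1 - self.beta2) * g**2
            m_hat = self.m[name] / (1 - self.beta1**t)
            v_hat = self.v[name] / (1 - self.beta2**t)
            W = getattr(ws, name)
            W -= self.learning_rate * m_hat / (np.sqrt(v_hat) + self.eps)
        ws.W_in[~ws.mask_in] = 0.0
        ws.W_rec[~ws.mask_rec] = 0.0
        ws.W_out[~ws.mask_out] = 0.0


def _rewire_layer(W, mask, eligible, pre_sign, config: NetworkConfig,
                  rng: np.random.Generator, layer: str, batch: int,
                  draw, events: list) -> None:
    """Prune sign-crossing connections and regrow within the same sign class."""
    for cls_sign in np.unique(pre_sign[mask]) if mask.any() else []:
        cls_rows = pre_sign == cls_sign
        crossing = mask & cls_rows & (W * cls_sign <= 0)
        pruned = np.argwhere(crossing)
        if len(pruned) == 0:
            continue
        W[crossing] = 0.0
        mask[crossing] = False
        free = np.argwhere(eligible & cls_rows & ~mask)
        k = min(len(pruned), len(free))
        if k < len(pruned):
            warnings.warn(f"{layer}: only {k} free slots for {len(pruned)} pruned "
                          "connections; pruning without replacement")
        chosen = free[rng.choice(len(free), size=k, replace=False)] if k else []
        for idx, (pr, rg) in enumerate(zip(pruned, list(chosen) + [None] * (len(pruned) - k))):
            if rg is None:
                events.append(RewireEvent(layer, tuple(pr), None, None, batch))
                continue
            w_new = draw(cls_sign, rng)
            W[tuple(rg)] = w_new
            mask[tuple(rg)] = True
            events.append(RewireEvent(layer, tuple(pr), tuple(rg), float(w_new), batch))


def deepr_rewire(ws: WeightSet, config: NetworkConfig, rng: np.random.Generator,
                 batch: int = -1):
    """DEEP R pass: enforce signs by pruning crossings and regrowing replacements.

    Skipped entirely when Dale's law is not enforced (signs are then free).
    Regrowth never targets the diagonal, a removed e->e slot, or a slot outside
    the layer's structural eligibility (input pool / output pool), and new
    weights come from the layer's initial distribution.  Returns the list of
    :class:`RewireEvent`.
    """
    events: list[RewireEvent] = []
    if not ws.dale_enforced:
        return events

    def draw_rec(cls_sign, rng):
        w = rng.lognormal(config.lognormal_mu, config.lognormal_sigma)
        return w if cls_sign > 0 else -config.i_scale * w

    def draw_in(cls_sign, rng):
        return rng.uniform(config.input_w_min, config.input_w_max)

    in_eligible = np.broadcast_to(ws.input_pool[None, :], ws.mask_in.shape).copy()
    _rewire_layer(ws.W_in, ws.mask_in, in_eligible, np.ones(ws.mask_in.shape),
                  config, rng, "W_in", batch, draw_in, events)
    _rewire_layer(ws.W_rec, ws.mask_rec, ~ws.regrow_forbidden,
                  np.broadcast_to(ws.sign[:, None], ws.W_rec.shape).copy(),
                  config, rng, "W_rec", batch, draw_rec, events)
    out_eligible = np.broadcast_to(ws.output_pool[:, None], ws.mask_out.shape).copy()
    _rewire_layer(ws.W_out, ws.mask_out, out_eligible,
                  np.broadcast_to(ws.sign[:, None], ws.W_out.shape).copy(),
                  config, rng, "W_out", batch, draw_rec, events)
    return events


def batch_update(x: np.ndarray, y_target: np.ndarray, ws: WeightSet,
                 opt: OptimizerState, params: ALIFParams, tcfg: TrainConfig,
                 config: NetworkConfig, rng: np.random.Generator,
                 batch: int = -1, mode: str | None = None):
    """One training iteration: accumulate batch gradients, Adam step, DEEP R pass.

    Mutates ``ws`` and ``opt`` in place; returns ``(record, events)``.
    """
    grads, record, _, _ = forward_backward(ws, x, y_target, params, tcfg, rng, mode=mode)
    record.batch = batch
    opt.apply(ws, grads)
    events = deepr_rewire(ws, config, rng, batch=batch)
    return record, events


def train(config, rng: np.random.Generator | int | None = None,
          mode: str | None = None, n_updates: int | None = None):
    """Train a network under a :class:`~pushpull.config.RunConfig`.

    Thin wrapper over :class:`pushpull.estimator.ALIFNetworkRegressor`: builds
    the shuffled trial stream, fits the estimator, and returns it (snapshots in
    ``snapshots_``, loss series in ``loss_history_``).
    """
    from .estimator import ALIFNetworkRegressor
    from .task import make_dataset

    tcfg = config.training
    n_updates = tcfg.n_updates if n_updates is None else n_updates
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    est = ALIFNetworkRegressor.from_config(config, mode=mode,
                                           random_state=int(rng.integers(2**31)))
    if n_updates == 0:
        est.initialize()
        return est
    stream = make_dataset(config.channels, tcfg.n_unique_trials,
                          n_updates * tcfg.batch_size, rng,
                          change_prob=tcfg.change_prob)
    return est.fit_trials(stream)
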