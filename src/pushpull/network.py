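"""Construction of the constrained recurrent network.

Units are partitioned into excitatory (e) and inhibitory (i) populations.
Ordered pairs are connected independently with the Bernoulli probability of
their (presynaptic-type, postsynaptic-type) class; excitatory weights are drawn
from a long-tailed log-normal distribution and inhibitory weights are the same
draw negated and scaled by ``i_scale``.  Input channels are treated as
excitatory afferents (density ``p_ee`` onto e units, ``p_ei`` onto i units)
with uniformly distributed weights; the output layer reuses the recurrent
statistics (``p_ee`` from e units, ``p_ie`` from i units).

Units are split into disjoint input- and output-eligible pools before any
Bernoulli sampling so that no unit that receives input can project to output.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .config import ConfigurationError, NetworkConfig


class ConstructionError(RuntimeError):
    """Raised when a structural constraint cannot be satisfied."""


@dataclass
class WeightSet:
    """The three signed sparse weight layers plus their structural book-keeping.

    ``W_in`` is channels x units, ``W_rec`` units x units (entry [j, i] is the
    weight from presynaptic j to postsynaptic i; diagonal exactly zero),
    ``W_out`` units x outputs.  ``sign`` is +1 for e units and -1 for i units.
    ``input_pool`` marks units eligible to receive input; its complement is the
    output-eligible pool.  ``regrow_forbidden`` marks recurrent slots that may
    never hold a connection (the diagonal, and the e->e block under the
    ``remove_ee`` variant).
    """

    W_in: np.ndarray
    W_rec: np.ndarray
    W_out: np.ndarray
    mask_in: np.ndarray
    mask_rec: np.ndarray
    mask_out: np.ndarray
    sign: np.ndarray
    input_pool: np.ndarray
    regrow_forbidden: np.ndarray = None
    dale_enforced: bool = True

    def __post_init__(self):
        if self.regrow_forbidden is None:
            self.regrow_forbidden = np.eye(self.n_units, dtype=bool)

    @property
    def n_units(self) -> int:
        return self.W_rec.shape[0]

    @property
    def n_channels(self) -> int:
        return self.W_in.shape[0]

    @property
    def n_outputs(self) -> int:
        return self.W_out.shape[1]

    @property
    def e_mask(self) -> np.ndarray:
        return self.sign > 0

    @property
    def i_mask(self) -> np.ndarray:
        return self.sign < 0

    @property
    def output_pool(self) -> np.ndarray:
        return ~self.input_pool

    def copy(self) -> "WeightSet":
        return WeightSet(
            self.W_in.copy(), self.W_rec.copy(), self.W_out.copy(),
            self.mask_in.copy(), self.mask_rec.copy(), self.mask_out.copy(),
            self.sign.copy(), self.input_pool.copy(),
            self.regrow_forbidden.copy(), self.dale_enforced,
        )

    def validate(self) -> None:
        """Check the structural invariants; raise ``ConstructionError`` if violated."""
        n = self.n_units
        if self.W_rec.shape != (n, n):
            raise ConstructionError("W_rec must be square")
        if np.any(np.diag(self.W_rec) != 0) or np.any(np.diag(self.mask_rec)):
            raise ConstructionError("self-connections are excluded")
        for W, m, name in ((self.W_in, self.mask_in, "in"),
                           (self.W_rec, self.mask_rec, "rec"),
                           (self.W_out, self.mask_out, "out")):
            if np.any(W[~m] != 0):
                raise ConstructionError(f"W_{name} nonzero outside its mask")
        if self.dale_enforced:
            s = self.sign[:, None]
            if np.any(self.W_rec * s < 0):
                raise ConstructionError("recurrent weight with wrong sign")
            if np.any(self.W_out * s < 0):
                raise ConstructionError("output weight with wrong sign")
            if np.any(self.W_in < 0):
                raise ConstructionError("negative input weight")
        receives_input = self.mask_in.any(axis=0)
        projects_out = self.mask_out.any(axis=1)
        if np.any(receives_input & projects_out):
            raise ConstructionError("input-receiving unit projects to output")


def _draw_recurrent_like(config: NetworkConfig, pre_is_e: np.ndarray,
                         rng: np.random.Generator) -> np.ndarray:
    """Draw weights from the recurrent initial distribution for given presynaptic types."""
    w = rng.lognormal(config.lognormal_mu, config.lognormal_sigma, size=pre_is_e.shape)
    return np.where(pre_is_e, w, -config.i_scale * w)


def sample_recurrent_weights(config: NetworkConfig, rng: np.random.Generator):
    """Sample the sparse signed recurrent matrix.

    Returns ``(W_rec, mask_rec, sign)``.  Each ordered pair (j -> i, j != i) is
    connected with the probability of its class; excitatory weights are
    log-normal, inhibitory weights are ``-i_scale`` times a log-normal draw.
    """
    config.validate()
    n = config.n_units
    sign = np.ones(n)
    sign[config.n_e:] = -1.0
    is_e = sign > 0

    p = np.where(is_e[:, None],
                 np.where(is_e[None, :], config.p_ee, config.p_ei),
                 np.where(is_e[None, :], config.p_ie, config.p_ii))
    mask = rng.random((n, n)) < p
    np.fill_diagonal(mask, False)

    W = _draw_recurrent_like(config, is_e[:, None] & np.ones((n, n), bool), rng)
    W = np.where(mask, W, 0.0)
    return W, mask, sign


def build_io_layers(config: NetworkConfig, rng: np.random.Generator,
                    W_rec: np.ndarray, mask_rec: np.ndarray,
                    sign: np.ndarray) -> WeightSet:
    """Add input and output layers around an already-sampled recurrent core.

    Input weights are uniform on [input_w_min, input_w_max] on a sparse mask
    restricted to the input-eligible pool; output weights are drawn from the
    recurrent initial distribution (sign following the source unit) on a mask
    restricted to the complementary pool.
    """
    config.validate()
    n = config.n_units
    is_e = sign > 0

    # Disjoint eligibility pools, fixed before per-connection sampling.
    n_in_pool = int(round(config.input_pool_fraction * n))
    perm = rng.permutation(n)
    input_pool = np.zeros(n, dtype=bool)
    input_pool[perm[:n_in_pool]] = True

    degenerate_input = config.input_w_max == config.input_w_min == 0.0
    if degenerate_input:
        # No unit can "receive input": every unit is output-eligible.
        input_pool[:] = False

    p_in = np.where(is_e, config.p_ee, config.p_ei)[None, :]
    mask_in = (rng.random((config.n_channels, n)) < p_in) & input_pool[None, :]
    if degenerate_input:
        # No unit receives input: every unit is output-eligible.
        mask_in[:] = False
    W_in = rng.uniform(config.input_w_min, config.input_w_max, size=mask_in.shape)
    W_in = np.where(mask_in, W_in, 0.0)

    out_pool = np.ones(n, dtype=bool) if degenerate_input else ~input_pool
    if not out_pool.any():
        raise ConstructionError(
            "output-eligible pool is empty; lower input_pool_fraction "
            f"(currently {config.input_pool_fraction})")
    p_out = np.where(is_e, config.p_ee, config.p_ie)[:, None]
    mask_out = (rng.random((n, config.n_outputs)) < p_out) & out_pool[:, None]
    W_out = _draw_recurrent_like(config, is_e[:, None] & np.ones(mask_out.shape, bool), rng)
    W_out = np.where(mask_out, W_out, 0.0)

    return WeightSet(W_in, W_rec, W_out, mask_in, mask_rec, mask_out,
                     sign, input_pool, dale_enforced=config.dale_enforced)


def apply_variant(weights: WeightSet, config: NetworkConfig) -> WeightSet:
    """Apply the study variants to a constructed WeightSet.

    ``remove_ee`` zeroes the e->e block and flags it non-regrowable;
    ``dale_enforced=False`` drops the sign constraint for subsequent training
    (initial signs are kept as drawn).
    """
    ws = weights.copy()
    ws.dale_enforced = config.dale_enforced
    if config.remove_ee:
        ee = ws.e_mask[:, None] & ws.e_mask[None, :]
        ws.W_rec[ee] = 0.0
        ws.mask_rec[ee] = False
        ws.regrow_forbidden |= ee
    return ws


def initialize_network(config: NetworkConfig, rng: np.random.Generator) -> WeightSet:
    """Construct a complete constrained WeightSet (recurrent + I/O + variants)."""
    W_rec, mask_rec, sign = sample_recurrent_weights(config, rng)
    ws = build_io_layers(config, rng, W_rec, mask_rec, sign)
    ws = apply_variant(ws, config)
    ws.validate()
    return ws
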