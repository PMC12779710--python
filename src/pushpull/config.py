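"""Configuration objects for network construction, neuron dynamics, task and training.

Every constant of the model is a named, defaulted field here; nothing numerical is
hard-coded elsewhere. Defaults reproduce the reference study conditions: a 300-unit
network (240 excitatory, 60 inhibitory; the neocortical 4:1 ratio), mouse-V1
connection probabilities, a long-tailed log-normal excitatory weight distribution
with 10x stronger inhibition, and a 4080-ms binary motion-entropy change-detection
task delivered through 16 Poisson input channels.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass, field, fields

import yaml


class ConfigurationError(ValueError):
    """Raised when a configuration violates its invariants."""


# Per-channel difference in mean firing rate between the two motion-entropy levels
# (high minus low), in spikes/ms, for the 16 input channels of the front-end model.
# Eight channels respond more strongly to high entropy, eight to low entropy.
CHANNEL_ENTROPY_DELTAS = (
    0.0163, 0.0002, 0.0192, 0.0874,
    -0.0176, -0.0163, -0.0063, -0.0170,
    0.0284, 0.0033, 0.0180, -0.0395,
    -0.0336, -0.0118, -0.0166, 0.0071,
)


@dataclass
class NetworkConfig:
    """Structural parameters of the constrained recurrent network.

    Connection probabilities are class-wise Bernoulli probabilities taken from
    mouse visual cortex; ``lognormal_mu``/``lognormal_sigma`` parameterize the
    log-space excitatory weight distribution (mV); inhibitory weights are the
    same draw scaled by ``-i_scale``.
    """

    n_e: int = 240
    n_i: int = 60
    n_channels: int = 16
    p_ee: float = 0.160
    p_ei: float = 0.205
    p_ie: float = 0.252
    p_ii: float = 0.284
    lognormal_mu: float = -0.64
    lognormal_sigma: float = 0.51
    i_scale: float = 10.0           # weak-inhibition variant: 1.5
    input_w_min: float = 0.0
    input_w_max: float = 0.4
    dale_enforced: bool = True
    remove_ee: bool = False
    output_encoding: str = "single"  # or "one_hot"
    # Fraction of units eligible to receive input; the complementary pool is
    # eligible to project to output (input-receiving units may never project to
    # output, so the two pools are disjoint by construction).
    input_pool_fraction: float = 0.5
    seed: int | None = None

    @property
    def n_units(self) -> int:
        return self.n_e + self.n_i

    @property
    def n_outputs(self) -> int:
        return 2 if self.output_encoding == "one_hot" else 1

    def validate(self) -> None:
        if self.n_e < 0 or self.n_i < 0 or self.n_e + self.n_i == 0:
            raise ConfigurationError("need at least one unit; counts non-negative")
        for name in ("p_ee", "p_ei", "p_ie", "p_ii"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ConfigurationError(f"{name}={p} outside [0, 1]")
        if self.lognormal_sigma <= 0:
            raise ConfigurationError("lognormal_sigma must be positive")
        if self.i_scale <= 0:
            raise ConfigurationError("i_scale must be positive")
        if self.input_w_max < self.input_w_min:
            raise ConfigurationError("input_w_max < input_w_min")
        if self.output_encoding not in ("single", "one_hot"):
            raise ConfigurationError(f"unknown output_encoding {self.output_encoding!r}")
        if not 0.0 <= self.input_pool_fraction <= 1.0:
            raise ConfigurationError("input_pool_fraction outside [0, 1]")

    def lognormal_mean(self) -> float:
        """Closed-form mean of the excitatory initial weight distribution (mV)."""
        return math.exp(self.lognormal_mu + self.lognormal_sigma**2 / 2)


@dataclass
class ALIFParams:
    """Adaptive leaky integrate-and-fire neuron and simulation constants.

    The decay factors ``alpha`` (membrane) and ``rho`` (adaptation) are derived
    properties, recomputed from the time constants on every access so they can
    never go stale.
    """

    E_m: float = -70.6        # resting potential, mV
    v_th: float = -50.4       # baseline threshold, mV
    tau_m: float = 20.0       # membrane time constant, ms
    tau_a: float = 100.0      # adaptation time constant, ms
    beta: float = 0.16        # adaptation->threshold coupling, mV per unit of a
    gamma_pd: float = 0.3     # pseudo-derivative amplitude
    dt: float = 1.0           # time step, ms
    t_refrac: int = 4         # refractory period, steps
    v_init_mean: float = -65.0
    v_init_sd: float = 5.0
    # "relative" normalizes the pseudo-derivative by |v_th - E_m| (20.2 mV);
    # "absolute" uses |v_th| as the formula reads literally.
    pd_scale: str = "relative"
    # "rest" leaks the membrane toward E_m; "literal" decays v itself
    # (the equation as printed, which leaks toward 0 mV).
    leak_mode: str = "rest"

    @property
    def alpha(self) -> float:
        return math.exp(-self.dt / self.tau_m)

    @property
    def rho(self) -> float:
        return math.exp(-self.dt / self.tau_a)

    @property
    def v_eff(self) -> float:
        """Normalizing voltage of the pseudo-derivative (mV)."""
        if self.pd_scale == "relative":
            return abs(self.v_th - self.E_m)
        return abs(self.v_th)

    def validate(self) -> None:
        if self.dt <= 0:
            raise ConfigurationError("dt must be positive")
        if self.t_refrac < 0:
            raise ConfigurationError("t_refrac must be >= 0")
        if self.v_th <= self.E_m:
            raise ConfigurationError("v_th must exceed E_m")
        if self.pd_scale not in ("relative", "absolute"):
            raise ConfigurationError(f"unknown pd_scale {self.pd_scale!r}")
        if self.leak_mode not in ("rest", "literal"):
            raise ConfigurationError(f"unknown leak_mode {self.leak_mode!r}")


@dataclass
class DotStimulusParams:
    """Drifting-dot kinematogram parameters."""

    n_dots: int = 460
    speed: float = 10.0              # px per ms
    lifetime: int = 1000             # ms
    coherent_fraction_high: float = 0.15
    coherent_fraction_low: float = 1.0
    frame_size: int = 128            # px, square frames
    cardinal_directions: tuple = (0.0, 90.0, 180.0, 270.0)

    def validate(self) -> None:
        for name in ("coherent_fraction_high", "coherent_fraction_low"):
            f = getattr(self, name)
            if not 0.0 < f <= 1.0:
                raise ConfigurationError(f"{name}={f} outside (0, 1]")
        if self.lifetime <= 0:
            raise ConfigurationError("lifetime must be positive")


@dataclass
class ChannelProfile:
    """Parametric 16-channel Poisson input model standing in for the CNN front-end.

    Each channel's block rate is drawn from a gamma distribution whose mean is
    ``baseline_rate +/- delta/2`` depending on the motion-entropy level of the
    block (high entropy gets ``+delta/2``); ``rate_cv`` sets the block-to-block
    coefficient of variation.
    """

    deltas: tuple = CHANNEL_ENTROPY_DELTAS          # high minus low, spikes/ms
    baseline_rate: float = 0.18                     # spikes/ms
    rate_cv: float = 0.45                           # block-rate dispersion
    block_ms: int = 68
    n_blocks: int = 60
    change_t_min: int = 500                         # entropy-change window, ms
    change_t_max: int = 3500

    @property
    def n_channels(self) -> int:
        return len(self.deltas)

    @property
    def trial_ms(self) -> int:
        return self.block_ms * self.n_blocks

    def validate(self) -> None:
        if self.baseline_rate < 0:
            raise ConfigurationError("baseline_rate must be >= 0")
        if self.rate_cv < 0:
            raise ConfigurationError("rate_cv must be >= 0")
        if self.block_ms <= 0 or self.n_blocks <= 0:
            raise ConfigurationError("block_ms and n_blocks must be positive")
        if not 0 < self.change_t_min <= self.change_t_max < self.trial_ms:
            raise ConfigurationError("change window must lie inside the trial")


@dataclass
class TrainConfig:
    """Optimization settings for dual task/rate training."""

    mode: str = "dual"               # task_only | rate_only | dual
    target_rate: float = 0.020       # spikes/ms
    # The combined loss is E_task + lam_rate * E_rate with E_rate in (spikes/ms)^2.
    # The default 1/target_rate^2 makes the scaled rate loss the squared relative
    # rate deviation, comparable in magnitude to the task loss.
    lam_rate: float = 2500.0
    # "per_unit": E_rate averages each unit's squared rate deviation (every unit
    # is pulled toward the 20 Hz target, keeping activity distributed);
    # "population": squared deviation of the single population-mean rate.
    rate_loss_scope: str = "per_unit"
    learning_rate: float = 1e-3
    adam_beta1: float = 0.9
    adam_beta2: float = 0.999
    adam_eps: float = 1e-8
    batch_size: int = 30
    n_updates: int = 10_000
    change_prob: float = 0.5
    n_unique_trials: int = 600
    snapshot_every: int = 100        # batches per snapshot (one epoch)

    def validate(self) -> None:
        if self.mode not in ("task_only", "rate_only", "dual"):
            raise ConfigurationError(f"unknown training mode {self.mode!r}")
        if self.target_rate < 0:
            raise ConfigurationError("target_rate must be >= 0")
        if self.batch_size <= 0 or self.n_updates < 0:
            raise ConfigurationError("batch_size positive, n_updates non-negative")
        if not 0.0 <= self.change_prob <= 1.0:
            raise ConfigurationError("change_prob outside [0, 1]")
        if self.rate_loss_scope not in ("per_unit", "population"):
            raise ConfigurationError(
                f"unknown rate_loss_scope {self.rate_loss_scope!r}")


_SECTIONS = {
    "network": NetworkConfig,
    "neuron": ALIFParams,
    "stimulus": DotStimulusParams,
    "channels": ChannelProfile,
    "training": TrainConfig,
}


@dataclass
class RunConfig:
    """Full pipeline configuration, one section per module."""

    network: NetworkConfig = field(default_factory=NetworkConfig)
    neuron: ALIFParams = field(default_factory=ALIFParams)
    stimulus: DotStimulusParams = field(default_factory=DotStimulusParams)
    channels: ChannelProfile = field(default_factory=ChannelProfile)
    training: TrainConfig = field(default_factory=TrainConfig)

    def validate(self) -> None:
        for f in fields(self):
            getattr(self, f.name).validate()

    def to_dict(self) -> dict:
        return {f.name: asdict(getattr(self, f.name)) for f in fields(self)}

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        kwargs = {}
        for name, typ in _SECTIONS.items():
            section = dict(d.get(name, {}))
            known = {f.name for f in fields(typ)}
            unknown = set(section) - known
            if unknown:
                raise ConfigurationError(f"unknown keys in [{name}]: {sorted(unknown)}")
            for key in ("deltas", "cardinal_directions"):
                if key in section and isinstance(section[key], list):
                    section[key] = tuple(section[key])
            kwargs[name] = typ(**section)
        return cls(**kwargs)

    def save(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(json.loads(json.dumps(self.to_dict())), fh, sort_keys=False)

    @classmethod
    def load(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})


def preset_config(name: str) -> RunConfig:
    """Return a named scale preset.

    ``full``: the full-scale study conditions (300 units, 4080-ms trials, 10,000
    batch updates of 30 trials).  ``desk``: a reduced configuration for
    workstation-scale experiments (60 units, 20-block trials, small batches)
    with all structural statistics unchanged.
    """
    if name == "full":
        return RunConfig()
    if name == "desk":
        cfg = RunConfig()
        cfg.network.n_e = 48
        cfg.network.n_i = 12
        cfg.channels.n_blocks = 20
        cfg.channels.change_t_min = 170   # same fractional window as full scale
        cfg.channels.change_t_max = 1170
        cfg.training.batch_size = 10
        cfg.training.n_updates = 300
        cfg.training.n_unique_trials = 60
        cfg.training.snapshot_every = 30
        return cfg
    raise ConfigurationError(f"unknown preset {name!r}; choose 'full' or 'desk'")
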