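"""Synthetic binary motion-entropy change-detection task.

Two stimulus representations are provided:

* a drifting-dot kinematogram generator (`generate_dot_video`), kept for
  completeness and testing but not wired into the network path; and
* a parametric 16-channel Poisson input model (`make_channel_rates` /
  `poissonize`) emulating the statistics of a convolutional front-end: each
  channel's firing rate is constant over 68-ms blocks, drawn from a gamma
  distribution whose mean shifts by the channel's entropy-modulation delta
  between the two motion-entropy levels.

A trial is 4080 ms (60 blocks); half of trials contain an entropy change at a
uniform time in the change window, the per-ms binary target follows the
experiment's label map (which entropy level is called '1' is swapped between
experiments), and the target flips exactly once, at the change time.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .config import ChannelProfile, DotStimulusParams

HIGH, LOW = 0, 1  # motion-entropy level codes


@dataclass
class Trial:
    """One episode: per-ms input spikes, per-ms binary target, metadata."""

    spikes: np.ndarray        # (channels, T) uint8
    target: np.ndarray        # (T,) float {0,1} -- the label series
    rates: np.ndarray         # (channels, n_blocks) underlying block rates
    entropy_seq: np.ndarray   # (T,) int, HIGH/LOW level per ms
    change_time: int | None   # ms, or None for no-change trials
    label_map: dict = field(default_factory=lambda: {HIGH: 0, LOW: 1})

    @property
    def T(self) -> int:
        return self.spikes.shape[1]

    def target_series(self, encoding: str = "single") -> np.ndarray:
        """Target as the training loss consumes it: (T, 1) or one-hot (T, 2)."""
        if encoding == "one_hot":
            out = np.zeros((self.T, 2))
            out[np.arange(self.T), self.target.astype(int)] = 1.0
            return out
        return self.target[:, None].astype(float)


def iter_dot_states(params: DotStimulusParams, entropy_seq: np.ndarray,
                    rng: np.random.Generator):
    """Yield per-frame dot state: ``(positions, displacements, ages)``.

    Dots start uniformly placed with random initial remaining lifetimes; each
    frame they move at ``speed`` px/ms, the coherent subset (15% at high
    entropy, 100% at low) along one shared cardinal direction, the remainder
    along independent random headings.  Expired dots are replaced at random
    positions with a fresh lifetime; their displacement entry for the
    replacement frame is NaN.  Positions wrap toroidally.
    """
    params.validate()
    size = params.frame_size
    n = params.n_dots
    pos = rng.uniform(0, size, size=(n, 2))
    remaining = rng.integers(1, params.lifetime + 1, size=n) if n else np.empty(0, int)
    coherent_dir = np.deg2rad(rng.choice(params.cardinal_directions))
    headings = rng.uniform(0, 2 * np.pi, size=n)

    for t in range(len(entropy_seq)):
        frac = (params.coherent_fraction_high if entropy_seq[t] == HIGH
                else params.coherent_fraction_low)
        n_coh = int(round(frac * n))
        theta = headings.copy()
        theta[:n_coh] = coherent_dir  # first n_coh dots form the coherent subset
        disp = params.speed * np.stack([np.cos(theta), np.sin(theta)], axis=-1) \
            if n else np.empty((0, 2))
        pos = (pos + disp) % size

        remaining -= 1
        expired = remaining <= 0
        k = int(expired.sum())
        if k:
            pos[expired] = rng.uniform(0, size, size=(k, 2))
            remaining[expired] = params.lifetime
            headings[expired] = rng.uniform(0, 2 * np.pi, size=k)
            disp[expired] = np.nan
        ages = params.lifetime - remaining
        yield pos.copy(), disp, ages.copy()


def generate_dot_video(params: DotStimulusParams, entropy_seq: np.ndarray,
                       rng: np.random.Generator) -> np.ndarray:
    """Render the drifting-dot stimulus as a (T, H, W) uint8 frame stack."""
    T = len(entropy_seq)
    size = params.frame_size
    frames = np.zeros((T, size, size), dtype=np.uint8)
    if params.n_dots == 0 or T == 0:
        params.validate()
        return frames
    for t, (pos, _, _) in enumerate(iter_dot_states(params, entropy_seq, rng)):
        ij = np.clip(pos.astype(int), 0, size - 1)
        frames[t, ij[:, 1], ij[:, 0]] = 255
    return frames


def make_entropy_seq(profile: ChannelProfile, initial_level: int,
                     change_time: int | None) -> np.ndarray:
    seq = np.full(profile.trial_ms, initial_level, dtype=np.int64)
    if change_time is not None:
        seq[change_time:] = 1 - initial_level
    return seq


def make_channel_rates(profile: ChannelProfile, entropy_seq: np.ndarray,
                       rng: np.random.Generator) -> np.ndarray:
    """Draw per-channel, per-block firing rates conditional on entropy level.

    The entropy level of a block is the level at the block's first ms.  Block
    rates are gamma with mean ``baseline + delta/2`` (high entropy) or
    ``baseline - delta/2`` (low) and coefficient of variation ``rate_cv``;
    negative calibrated means are clipped at zero with a warning.  Returns
    (channels, n_blocks), in spikes/ms.
    """
    profile.validate()
    levels = entropy_seq[:: profile.block_ms][: profile.n_blocks]  # first ms of each block
    deltas = np.asarray(profile.deltas)
    means = profile.baseline_rate + np.where(levels[None, :] == HIGH, 0.5, -0.5) * deltas[:, None]
    if np.any(means < 0):
        warnings.warn("negative calibrated block-rate mean clipped at 0")
        means = np.clip(means, 0.0, None)
    if profile.rate_cv == 0:
        return means
    shape = 1.0 / profile.rate_cv**2
    return rng.gamma(shape, means / shape)


def poissonize(rates: np.ndarray, rng: np.random.Generator,
               block_ms: int = 68, dt: float = 1.0) -> np.ndarray:
    """Expand block rates to per-ms Bernoulli spikes.

    Each block rate is repeated ``block_ms`` times and a spike is drawn per ms
    with probability rate*dt (clipped to 1 with a warning if it exceeds 1).
    """
    rates = np.asarray(rates, dtype=float)
    if np.any(rates < 0):
        raise ValueError("rates must be non-negative")
    p = np.repeat(rates, block_ms, axis=-1) * dt
    if np.any(p > 1):
        warnings.warn("per-step spike probability > 1 clipped")
        p = np.minimum(p, 1.0)
    return (rng.random(p.shape) < p).astype(np.uint8)


def make_trial(profile: ChannelProfile, label_map: dict | None,
               change_prob: float, rng: np.random.Generator) -> Trial:
    """Build one trial: entropy sequence, block rates, spikes and target."""
    if not 0.0 <= change_prob <= 1.0:
        raise ValueError("change_prob outside [0, 1]")
    if label_map is None:
        label_map = {HIGH: 0, LOW: 1}
    initial = int(rng.integers(2))
    change_time = None
    if rng.random() < change_prob:
        change_time = int(rng.integers(profile.change_t_min, profile.change_t_max + 1))
    entropy_seq = make_entropy_seq(profile, initial, change_time)
    rates = make_channel_rates(profile, entropy_seq, rng)
    spikes = poissonize(rates, rng, block_ms=profile.block_ms)
    target = np.array([label_map[lev] for lev in (HIGH, LOW)])[entropy_seq].astype(float)
    return Trial(spikes=spikes, target=target, rates=rates,
                 entropy_seq=entropy_seq, change_time=change_time,
                 label_map=dict(label_map))


def make_dataset(profile: ChannelProfile, n_unique: int, total: int,
                 rng: np.random.Generator, label_map: dict | None = None,
                 change_prob: float = 0.5) -> list[Trial]:
    """Build an ordered training stream of ``total`` trials.

    ``n_unique`` distinct trials are generated, then repeated (each appearing
    floor(total/n_unique) or ceil(total/n_unique) times) and shuffled;
    consecutive disjoint slices of the stream form the training batches.
    """
    if n_unique <= 0 or total < 0:
        raise ValueError("n_unique must be positive, total non-negative")
    unique = [make_trial(profile, label_map, change_prob, rng) for _ in range(n_unique)]
    reps, extra = divmod(total, n_unique)
    counts = np.full(n_unique, reps, dtype=int)
    counts[rng.choice(n_unique, size=extra, replace=False)] += 1
    order = np.repeat(np.arange(n_unique), counts)
    rng.shuffle(order)
    return [unique[k] for k in order]


def stack_trials(trials: list[Trial], encoding: str = "single"):
    """Stack a trial list into (B, C, T) spikes and (B, T, n_out) targets."""
    x = np.stack([tr.spikes for tr in trials])
    y = np.stack([tr.target_series(encoding) for tr in trials])
    return x, y


def balanced_eval_trials(profile: ChannelProfile, n_trials: int,
                         rng: np.random.Generator, label_map: dict | None = None,
                         change_prob: float = 0.0) -> list[Trial]:
    """Evaluation set with both initial entropy levels equally represented."""
    trials = []
    for k in range(n_trials):
        while True:
            tr = make_trial(profile, label_map, change_prob, rng)
            if tr.entropy_seq[0] == k % 2:
                break
        trials.append(tr)
    return trials
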