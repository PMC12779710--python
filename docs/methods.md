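# Methods

`pushpull` builds, trains, and dissects sparse recurrent spiking neural
networks constrained by mouse-neocortical connectivity statistics, on a binary
motion-entropy change-detection task. This note documents the model, the
synthetic data, the numerical choices, and the points where the design was
genuinely open.

## Network model

**Populations and connectivity.** The default network has 300 adaptive leaky
integrate-and-fire (ALIF) units, 240 excitatory (e) and 60 inhibitory (i) —
the neocortical 4:1 ratio. Ordered pairs (j → i, j ≠ i) are connected by
independent Bernoulli draws with class-wise probabilities taken from mouse
visual cortex: p(e→e) = 0.160, p(e→i) = 0.205, p(i→e) = 0.252,
p(i→i) = 0.284. Self-connections are excluded. Excitatory weights are drawn
from a long-tailed log-normal distribution, ln w ~ N(µ = −0.64, σ = 0.51)
(mean e^{µ+σ²/2} = 0.6005 mV per spike); inhibitory weights are the same draw
negated and scaled by `i_scale` (default 10; the weak-inhibition variant uses
1.5). Under Dale's law (default) every unit's outgoing weights keep one sign
throughout training.

**Input and output layers.** Sixteen Poisson input channels project with
excitatory-afferent statistics (density p(e→e) onto e targets, p(e→i) onto i
targets) and uniform weights on [0, 0.4] mV. The output layer reuses the
recurrent statistics (p(e→e) from e units, p(i→e) from i units), with weights
from the recurrent initial distribution signed by the source unit. Units that
receive input may not project to output. Because at the stated channel
densities nearly every unit would otherwise receive input, units are first
split into an input-eligible pool and a disjoint output-eligible pool (default
fraction 0.5, seeded) and per-connection sampling happens within pools; this
enforces the stated disjointness while preserving within-pool densities. The
fraction of units that receive input is not pinned down by the reference
description; the pooling rule is one consistent reading and is configurable.

**ALIF dynamics.** Time is discrete at δt = 1 ms. Per unit,

    v[t]   = E_m + α (v[t−1] − E_m) + I[t] − z[t−1] (v_th − E_m)
    a[t]   = ρ a[t−1] + z[t−1]
    A[t]   = v_th + β a[t]
    z[t]   = H(v[t] − A[t])        (0 during the 4-ms refractory period)

with E_m = −70.6 mV, v_th = −50.4 mV, α = e^{−δt/τ_m} (τ_m = 20 ms),
ρ = e^{−δt/τ_a} (τ_a = 100 ms), β = 0.16 mV per unit of the adaptation trace,
and I[t] the weighted sum of presynaptic spikes from t−1 plus weighted input
spikes at t. Membrane potentials start at N(−65, 5) mV each trial; spiking
subtracts the constant v_th − E_m = 20.2 mV on the following step. The
readout is a plain per-ms weighted sum of spikes, with no output nonlinearity;
the one-hot variant uses two readout columns and argmax for the predicted
label.

The equation family that these constants come from can be written with the
leak anchored at the resting potential (as above) or in a shifted-voltage
convention where v decays toward 0 mV. We implement leak-to-rest as the
default — it is the only reading under which every stated constant
(E_m < v_init < v_th) is meaningful — and keep `leak_mode="literal"` as a
flag. The choice matters: leak-to-rest networks are nearly silent before
training (activity must be built by the rate objective), whereas the shifted
convention fires spontaneously. The headline initial-state quantities
reproduced by this package (initial task loss ≈ 0.5, initial inhibitory
cross/within ratio ≈ 1) are insensitive to this choice because the initial
output weights are too weak for spiking to drive the readout either way.

## Task and synthetic inputs

**Stimulus.** The nominal stimulus is a 4080-ms kinematogram of 460 white
dots drifting at 10 px/ms, with 1000-ms lifetimes and random replacement; at
low motion entropy 100% of dots share one cardinal direction, at high entropy
15% do. A generator for these videos is included (`task.iter_dot_states` /
`generate_dot_video`) for completeness, but the network never consumes
pixels.

**Channel model.** The trained convolutional front-end that converted videos
to 16 channel activations is replaced by a parametric model of its output
statistics. Each channel's firing rate is constant over 68-ms blocks (60
blocks = 4080 ms). Block rates are gamma-distributed with coefficient of
variation 0.45 and mean `baseline ± δ_c/2`, where the sign follows the
motion-entropy level of the block's first millisecond and δ_c is the
channel's calibrated high-minus-low rate difference. The 16 δ_c values (8
positive, 8 negative, mean |δ_c| = 0.021 spikes/ms) are the table the model
is calibrated to; the baseline defaults to 0.18 spikes/ms, the high-entropy
group mean. The CV was chosen so the per-level rate spreads are of the order
of the reported group SDs (≈ 0.08–0.17 spikes/ms); per-channel baselines and
dispersions are not individually published, so the generator matches group
statistics, not per-channel distribution shapes (the real front-end's
low-entropy distributions are multimodal; the gamma model is unimodal).
Spikes are Bernoulli per millisecond at rate·δt. Consequences for
interpretation: passing tests show the statistics the network is given —
block structure, calibrated mean differences, realistic dispersion — are
sufficient for the studied phenomena; they say nothing about features of the
real front-end the gamma model lacks (multimodality, temporal correlation
within blocks).

**Trials.** A trial is 4080 ms; the initial entropy level is uniform; with
probability 0.5 the level flips once at a uniform time in [500, 3500] ms.
Rates snap to the block grid; the binary target flips at the exact
millisecond. Which entropy level is labeled '1' is an experiment-level
`label_map`, swapped between experiments. Training streams contain 600 unique
trials repeated and shuffled (each appearing ⌊total/600⌋ or ⌈total/600⌉
times) and are consumed in disjoint batches of 30.

## Training

**Objectives.** The task loss is the per-ms MSE between readout and target,
averaged over the 4080 steps (and the two outputs, for one-hot). The rate
loss penalizes deviation of firing rates from the 0.020 spikes/ms (20 Hz)
target. Two granularities are implemented:

* `per_unit` (default): E_rate = mean over units of (r_u − r*)², each unit's
  trial-mean rate pulled to the target;
* `population`: E_rate = (r̄ − r*)² on the single population-mean rate (this
  is also what the standalone `rate_loss` function computes).

The protocol this package reimplements specifies only an MSE between the
target rate and the network's average spike rate, which does not distinguish
the two. We default to per-unit because in our scaled-down experiments the population form is
gamed by degenerate solutions — a handful of units firing near the
refractory ceiling while most units stay silent, which contradicts the broad
per-unit rate distributions reported for trained networks and makes
modulation analysis impossible. The combined objective is
E_total = E_task + λ_rate · E_rate with λ_rate = 1/r*² = 2500 by default, so
the scaled rate term is the squared *relative* rate deviation (1.0 for a
silent network) and sits on the same O(1) scale as the initial task loss
(≈ 0.5). λ_rate is not derivable from the reference values (the printed
initial rate loss of 0.39 is inconsistent with any (spikes/ms)² reading we
tried); the unscaled population value is always logged alongside.

**Surrogate-gradient BPTT.** Gradients flow through the unrolled dynamics in
reverse mode, implemented directly in NumPy. The spike nonlinearity's
derivative is replaced by the triangular pseudo-derivative
ψ = (γ/v_eff) max(0, 1 − |v − A|/v_eff) with γ = 0.3, zero during
refractoriness. The normalizing voltage v_eff defaults to
|v_th − E_m| = 20.2 mV (the relative-voltage convention; the printed formula's
1/v_th would be negative), switchable to |v_th|. The adjoint recursion
carries dL/dv and dL/da backward through the leak (α), adaptation (ρ),
threshold coupling (−β ψ), recurrent fan-out (W ψ), and the post-spike reset;
weight gradients accumulate over time and are averaged over the 30-trial
batch before a single Adam step (defaults lr 10⁻³, β₁ 0.9, β₂ 0.999,
ε 10⁻⁸; the reference protocol leaves them unstated). Correctness is verified
against central finite differences on a fully differentiable variant of the
same graph (`spike_mode="soft"`, the piecewise-quadratic antiderivative of ψ
in place of the Heaviside step, refractory gating off) at 10⁻⁴ relative
tolerance, for all three training modes.

**Structure maintenance.** Structurally absent connections receive zero
gradient and stay exactly zero. After every update (cadence not stated in the
reference; per-batch chosen) a DEEP R pass prunes any active connection whose
weight crossed or reached zero and regrows, per layer and presynaptic sign
class, an equal number of connections drawn uniformly from the free eligible
slots (never the diagonal, a removed e→e slot, or a slot outside the
input/output pools), with fresh weights from the layer's initial
distribution. Connection counts per class are therefore conserved through
training. When Dale's law is disabled, signs are free and rewiring is off.

## Analyses

**Modulation classification.** On a held-out, seeded evaluation set (60
balanced trials by default; the reference does not state its evaluation-set
size) each unit's mean rate over target-'1' milliseconds is compared with its
rate over target-'0' milliseconds, pooled across trials; the larger defines
the preferred label. Silent units and exact ties are unclassified and
excluded. Input channels are classified identically from their spike trains.

**Cross/within-modulation ratios.** Active recurrent connections between
classified units are partitioned by (pre-label, post-label); the ratio is the
mean |weight| of across-label connections over the mean |weight| of
within-label connections, per class (e→e, e→i, i→e, i→i) and pooled by
presynaptic e/i identity. Absolute weights are used throughout (the reported
inhibitory ratios exceed 1 for strengthening negative weights, so magnitudes
are the only consistent reading); means are over active connections only.
Empty partitions yield NaN, never 0. With the final profile the ratio can be
evaluated retroactively on every stored weight snapshot. For sign-free
(no-Dale) networks a signed variant pools by current weight sign instead.

**Other analyses.** Input-layer modulation ratios divide the mean nonzero
input weight from '1'-preferring channels by that from '0'-preferring
channels, separately for e and i targets. Top-quantile persistence ranks
active connections by |weight| at two checkpoints and reports the overlap of
the top-q sets (1 under identity, ≈ q under independent shuffling).
Distribution comparisons use the two-sample Kolmogorov–Smirnov test
(`scipy.stats.ks_2samp`, asymptotic p).

**Spike-time jitter.** Each spike of a trained evaluation raster is shifted
by an independent integer offset uniform on [−5, +5] ms (0.245% of the
trial). Offsets that would leave the trial or collide with another spike of
the same unit are redrawn (bounded retries, then nearest free slot), so
per-unit counts — hence all rates — are exactly preserved; the reference
asserts preserved rates but not the mechanism, and this is the strictest
count-preserving rule. The jittered raster is re-read through the original
output weights without re-simulating the recurrent dynamics, and task loss is
compared overall and on the no-change '1'- and '0'-labeled subsets.
Input-channel spikes are not jittered.

## Scales and reproducibility

Two presets ship: `full` — the full-scale protocol (300 units, 4080-ms trials,
10,000 updates × 30 trials) — and `desk`, the reduced configuration used for
quick experiments and tests: 60 units (48e/12i, same connection statistics),
20-block (1360-ms) trials with the change window scaled proportionally
([170, 1170] ms), batches of 10; all 16 channels and every neuron constant
are unchanged. The `scaled_down_emergence` experiment uses a 120-unit
(96e/24i) variant of this preset — enough inhibitory units for stable
partition statistics — trained for 4000 updates at Adam step 4·10⁻³ (≈ 8–10
minutes on one CPU core), classifies modulation on 60 held-out balanced
trials, and reports task-loss movement plus the pooled across/within ratios
with percentile-bootstrap CIs over connections. In repeated runs the
inhibitory ratio reaches ≈ 1.2–1.5 (CI excluding 1 from roughly update 1000
onward) and the excitatory ratio ≈ 0.8–0.9 (CI below 1) — the direction and
separation of the full-scale reference values (2.0 and 0.6) at a fraction of
their magnitude, as expected for a 25-fold smaller experiment. The same
experiment with the one-hot two-unit readout reproduces the motif with
similar strength (full-scale references 3.1 and 0.57); at this reduced
update budget the one-hot task loss itself has not yet left its chance
plateau — the motif emerges ahead of measurable readout improvement, driven
by the joint objective.

The sequential simulation and adjoint recursions are implemented twice: a
NumPy reference and numerically identical numba-compiled kernels (used
automatically when numba is importable) that exploit the sparsity of binary
spike rasters; all tests of gradient correctness run against the reference
path, and an equivalence check ties the two together.

Every stochastic step draws from an explicit `numpy.random.Generator`; a
single pipeline seed spawns per-stage substreams, so a fixed seed reproduces
every artifact (weights, trials, rasters, CSVs) bit-identically. Weights and
rasters round-trip exactly through HDF5.

## Known limitations

* No synaptic delays, conductance synapses, interneuron subtypes, or noise
  currents; inputs are current-based spikes.
* The channel model reproduces group-level front-end statistics only; no
  video actually drives the network.
* The absolute recurrent weight scale is internally inconsistent in the
  reference values (the stated log-normal parameters imply a mean ≈ 30×
  larger than the tabulated initial class means); this package follows the
  stated distribution, so tabulated absolute weight values are not
  reproduced, while distribution-shape, ratio, and initial-state results
  are.
* Desk-scale training shows the direction of the reported circuit changes,
  not their full-scale magnitudes (i cross/within toward 2.0, e toward 0.6);
  run the `full` preset (GPU-class budget) for full-scale figures.
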