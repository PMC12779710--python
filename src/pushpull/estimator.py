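"""Scikit-learn-style estimator wrapping network construction and training.

`ALIFNetworkRegressor` treats the spiking network as a supervised sequence
regressor: ``X`` is an array of input-channel spike trains, ``y`` the per-ms
binary target series, and ``fit`` runs surrogate-gradient BPTT with Adam,
Dale enforcement and DEEP R rewiring over mini-batches of trials.  Fitted
state lives in trailing-underscore attributes (``weights_``,
``loss_history_``, ``snapshots_``) and the estimator composes with sklearn
model selection via ``get_params``/``set_params``.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .config import ALIFParams, NetworkConfig, TrainConfig
from .dynamics import simulate_trial
from .network import initialize_network
from .training import OptimizerState, batch_update, task_loss


class ALIFNetworkRegressor(BaseEstimator):
    """Recurrent ALIF network trained with surrogate-gradient BPTT.

    Parameters mirror the network construction and optimization settings; see
    :class:`~pushpull.config.NetworkConfig` and
    :class:`~pushpull.config.TrainConfig` for semantics and defaults.
    ``neuron`` accepts an :class:`~pushpull.config.ALIFParams`; ``None`` means
    the standard constants.

    Attributes after ``fit``:

    weights_ : WeightSet
        Trained weights (masks, signs and pools included).
    initial_weights_ : WeightSet
        Snapshot taken before the first update.
    snapshots_ : list[(int, WeightSet)]
        Per-epoch weight copies, ``(update_index, weights)``.
    loss_history_ : pandas.DataFrame
        One row per batch update: task, naive and scaled rate loss, total.
    rewire_events_ : list[RewireEvent]
        All DEEP R prune/regrow events.
    """

    def __init__(self, n_e=240, n_i=60, n_channels=16,
                 p_ee=0.160, p_ei=0.205, p_ie=0.252, p_ii=0.284,
                 lognormal_mu=-0.64, lognormal_sigma=0.51, i_scale=10.0,
                 input_w_min=0.0, input_w_max=0.4, input_pool_fraction=0.5,
                 dale_enforced=True, remove_ee=False, output_encoding="single",
                 mode="dual", target_rate=0.020, lam_rate=2500.0,
                 learning_rate=1e-3, batch_size=30, n_epochs=1,
                 snapshot_every=100, neuron=None, random_state=None):
        self.n_e = n_e
        self.n_i = n_i
        self.n_channels = n_channels
        self.p_ee = p_ee
        self.p_ei = p_ei
        self.p_ie = p_ie
        self.p_ii = p_ii
        self.lognormal_mu = lognormal_mu
        self.lognormal_sigma = lognormal_sigma
        self.i_scale = i_scale
        self.input_w_min = input_w_min
        self.input_w_max = input_w_max
        self.input_pool_fraction = input_pool_fraction
        self.dale_enforced = dale_enforced
        self.remove_ee = remove_ee
        self.output_encoding = output_encoding
        self.mode = mode
        self.target_rate = target_rate
        self.lam_rate = lam_rate
        self.learning_rate = learning_rate
        self.batch_size = batch_size
        self.n_epochs = n_epochs
        self.snapshot_every = snapshot_every
        self.neuron = neuron
        self.random_state = random_state

    @classmethod
    def from_config(cls, config, mode=None, random_state=None) -> "ALIFNetworkRegressor":
        """Build an estimator from a :class:`~pushpull.config.RunConfig`."""
        net, tcfg = config.network, config.training
        return cls(
            n_e=net.n_e, n_i=net.n_i, n_channels=net.n_channels,
            p_ee=net.p_ee, p_ei=net.p_ei, p_ie=net.p_ie, p_ii=net.p_ii,
            lognormal_mu=net.lognormal_mu, lognormal_sigma=net.lognormal_sigma,
            i_scale=net.i_scale, input_w_min=net.input_w_min,
            input_w_max=net.input_w_max, input_pool_fraction=net.input_pool_fraction,
            dale_enforced=net.dale_enforced, remove_ee=net.remove_ee,
            output_encoding=net.output_encoding,
            mode=mode or tcfg.mode, target_rate=tcfg.target_rate,
            lam_rate=tcfg.lam_rate, learning_rate=tcfg.learning_rate,
            batch_size=tcfg.batch_size, snapshot_every=tcfg.snapshot_every,
            neuron=config.neuron,
            random_state=random_state if random_state is not None else net.seed,
        )

    # -- configuration assembly -------------------------------------------------

    def _network_config(self) -> NetworkConfig:
        return NetworkConfig(
            n_e=self.n_e, n_i=self.n_i, n_channels=self.n_channels,
            p_ee=self.p_ee, p_ei=self.p_ei, p_ie=self.p_ie, p_ii=self.p_ii,
            lognormal_mu=self.lognormal_mu, lognormal_sigma=self.lognormal_sigma,
            i_scale=self.i_scale, input_w_min=self.input_w_min,
            input_w_max=self.input_w_max, dale_enforced=self.dale_enforced,
            remove_ee=self.remove_ee, output_encoding=self.output_encoding,
            input_pool_fraction=self.input_pool_fraction)

    def _train_config(self) -> TrainConfig:
        return TrainConfig(mode=self.mode, target_rate=self.target_rate,
                           lam_rate=self.lam_rate, learning_rate=self.learning_rate,
                           batch_size=self.batch_size,
                           snapshot_every=self.snapshot_every)

    def _neuron_params(self) -> ALIFParams:
        return self.neuron if self.neuron is not None else ALIFParams()

    # -- fitting ----------------------------------------------------------------

    def initialize(self, rng: np.random.Generator | None = None) -> "ALIFNetworkRegressor":
        """Construct initial weights without training (``n_updates=0`` run)."""
        rng = rng or np.random.default_rng(self.random_state)
        cfg = self._network_config()
        cfg.validate()
        self._train_config().validate()
        self._neuron_params().validate()
        self.weights_ = initialize_network(cfg, rng)
        self.initial_weights_ = self.weights_.copy()
        self.snapshots_ = [(0, self.weights_.copy())]
        self.loss_history_ = pd.DataFrame(
            columns=["batch", "mode", "task", "rate_naive", "rate_scaled", "total"])
        self.rewire_events_ = []
        self.n_updates_ = 0
        self._rng = rng
        return self

    def _validate_X_y(self, X, y=None):
        X = np.asarray(X)
        if X.ndim != 3 or X.shape[1] != self.n_channels:
            raise ValueError(f"X must be (n_trials, {self.n_channels}, T); got {X.shape}")
        if not np.isin(np.unique(X), (0, 1)).all():
            raise ValueError("X must be binary spike trains")
        if y is None:
            return X, None
        y = np.asarray(y, dtype=float)
        n_out = 2 if self.output_encoding == "one_hot" else 1
        if y.ndim == 2:
            if n_out == 2:
                onehot = np.zeros(y.shape + (2,))
                idx = np.indices(y.shape)
                onehot[idx[0], idx[1], y.astype(int)] = 1.0
                y = onehot
            else:
                y = y[:, :, None]
        if y.shape[:2] != (X.shape[0], X.shape[2]) or y.shape[2] != n_out:
            raise ValueError(f"y shape {y.shape} inconsistent with X {X.shape}")
        return X, y

    def fit(self, X, y) -> "ALIFNetworkRegressor":
        """Train on trials ``X`` (n_trials, channels, T) against targets ``y``.

        ``y`` may be (n_trials, T) label series (one-hot expanded internally
        when needed) or already (n_trials, T, n_out).  Trials are consumed in
        order, in batches of ``batch_size``, for ``n_epochs`` passes.
        """
        X, y = self._validate_X_y(X, y)
        n_batches = X.shape[0] // self.batch_size

        def batches():
            for _ in range(self.n_epochs):
                for b in range(n_batches):
                    sl = slice(b * self.batch_size, (b + 1) * self.batch_size)
                    yield X[sl], y[sl]

        return self._fit_batches(batches())

    def fit_trials(self, trials) -> "ALIFNetworkRegressor":
        """Train on an ordered trial stream, stacking one batch at a time.

        Memory-friendly variant of :meth:`fit` for long shuffled-repeat
        streams, where the stream holds repeated references to a small set of
        unique trials.
        """
        from .task import stack_trials
        n_batches = len(trials) // self.batch_size

        def batches():
            for _ in range(self.n_epochs):
                for b in range(n_batches):
                    chunk = trials[b * self.batch_size:(b + 1) * self.batch_size]
                    yield stack_trials(chunk, encoding=self.output_encoding)

        return self._fit_batches(batches())

    def _fit_batches(self, batch_iter) -> "ALIFNetworkRegressor":
        rng = np.random.default_rng(self.random_state)
        self.initialize(rng)
        net_cfg = self._network_config()
        tcfg = self._train_config()
        params = self._neuron_params()
        opt = OptimizerState.for_weights(self.weights_, tcfg)

        records = []
        update = 0
        for xb, yb in batch_iter:
            rec, events = batch_update(xb, yb, self.weights_, opt,
                                       params, tcfg, net_cfg, rng,
                                       batch=update, mode=self.mode)
            records.append(rec)
            self.rewire_events_.extend(events)
            update += 1
            if self.snapshot_every and update % self.snapshot_every == 0:
                self.snapshots_.append((update, self.weights_.copy()))
        if not self.snapshots_ or self.snapshots_[-1][0] != update:
            self.snapshots_.append((update, self.weights_.copy()))
        self.n_updates_ = update
        self.loss_history_ = pd.DataFrame([vars(r) for r in records])
        self.opt_state_ = opt
        return self

    # -- inference --------------------------------------------------------------

    def _check_fitted(self):
        if not hasattr(self, "weights_"):
            raise RuntimeError("estimator is not fitted; call fit() or initialize()")

    def simulate(self, X, rng: np.random.Generator | None = None):
        """Simulate fitted weights on trials ``X``; returns (rasters, outputs)."""
        self._check_fitted()
        X, _ = self._validate_X_y(X)
        rng = rng or np.random.default_rng(self.random_state)
        return simulate_trial(self.weights_, X, self._neuron_params(), rng)

    def predict(self, X) -> np.ndarray:
        """Readout series for each trial: (n_trials, T) or (n_trials, T, 2)."""
        _, outputs = self.simulate(X)
        return outputs[:, :, 0] if self.output_encoding == "single" else outputs

    def score(self, X, y) -> float:
        """Negative mean task loss (higher is better), not R^2."""
        X, y = self._validate_X_y(X, y)
        _, outputs = self.simulate(X)
        return -float(np.mean(task_loss(outputs, y)))
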