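"""Losses, surrogate gradients, Adam updates, Dale enforcement and DEEP R."""

import numpy as np
import pytest

from pushpull.config import ALIFParams, NetworkConfig, TrainConfig
from pushpull.network import initialize_network
from pushpull.training import (LAYERS, OptimizerState, batch_update,
                               deepr_rewire, forward_backward,
                               pseudo_derivative, rate_loss, task_loss, train)


@pytest.fixture
def toy_setup(rng):
    """5-unit network with short trials for gradient-level tests."""
    cfg = NetworkConfig(n_e=4, n_i=1, n_channels=2, p_ee=0.9, p_ei=0.9,
                        p_ie=0.9, p_ii=0.9, i_scale=2.0, input_w_max=2.0,
                        input_pool_fraction=0.4)
    ws = initialize_network(cfg, rng)
    T, B = 10, 3
    x = (rng.random((B, 2, T)) < 0.4).astype(np.uint8)
    y = (rng.random((B, T, 1)) < 0.5).astype(float)
    v0 = np.full(5, -62.0)
    return cfg, ws, x, y, v0


class TestLosses:
    def test_task_loss_values(self):
        y = np.ones((20, 1))
        assert task_loss(y, y) == 0.0
        assert task_loss(np.zeros((20, 1)), y) == 1.0
        with pytest.raises(ValueError):
            task_loss(np.zeros((10, 1)), y)

    def test_task_loss_batched_per_trial(self):
        y_pred = np.zeros((2, 10, 1))
        y_t = np.stack([np.zeros((10, 1)), np.ones((10, 1))])
        np.testing.assert_allclose(task_loss(y_pred, y_t), [0.0, 1.0])

    def test_rate_loss_values(self):
        z = np.zeros((10, 1000))
        z[:, ::50] = 1  # 0.020 spikes/ms exactly
        assert rate_loss(z, 0.020) == pytest.approx(0.0, abs=1e-12)
        z2 = np.zeros((10, 1000))
        z2[:, ::50] = 1
        z2[:, 1::100] = 1  # +100 spikes -> 0.030 spikes/ms
        assert rate_loss(z2, 0.020) == pytest.approx(1e-4, rel=1e-9)
        with pytest.raises(ValueError):
            rate_loss(z, -1.0)


class TestPseudoDerivative:
    def test_peak_at_threshold(self, params):
        v = np.array([params.v_th])
        A = np.array([params.v_th])
        psi = pseudo_derivative(v, A, np.zeros(1), params)
        assert psi[0] == pytest.approx(params.gamma_pd / params.v_eff)

    def test_zero_beyond_support(self, params):
        v = np.array([params.v_th + params.v_eff, params.v_th - 2 * params.v_eff])
        A = np.full(2, params.v_th)
        np.testing.assert_array_equal(
            pseudo_derivative(v, A, np.zeros(2), params), 0.0)

    def test_zero_during_refractory(self, params):
        v = A = np.array([params.v_th])
        assert pseudo_derivative(v, A, np.array([2]), params)[0] == 0.0

    def test_normalizing_voltage_conventions(self):
        assert ALIFParams().v_eff == pytest.approx(20.2)
        assert ALIFParams(pd_scale="absolute").v_eff == pytest.approx(50.4)


class TestGradients:
    @pytest.mark.parametrize("mode", ["dual", "task_only", "rate_only"])
    def test_backward_matches_finite_differences(self, toy_setup, mode):
        """Reverse-mode gradients through the differentiable-surrogate graph
        agree with central finite differences to 1e-4 relative error."""
        cfg, ws, x, y, v0 = toy_setup
        params = ALIFParams()
        tcfg = TrainConfig(mode=mode)
        rng = np.random.default_rng(0)

        grads, _, _, _ = forward_backward(ws, x, y, params, tcfg, rng,
                                          mode=mode, spike_mode="soft", v_init=v0)

        def loss_at(ws_mod):
            _, rec, _, _ = forward_backward(ws_mod, x, y, params, tcfg, rng,
                                            mode=mode, spike_mode="soft", v_init=v0)
            return rec.total

        h = 1e-5
        checked = 0
        for name in LAYERS:
            mask = getattr(ws, f"mask_{name.split('_')[1]}")
            idx = np.argwhere(mask)
            for flat in idx[:: max(1, len(idx) // 6)]:
                ws_p, ws_m = ws.copy(), ws.copy()
                getattr(ws_p, name)[tuple(flat)] += h
                getattr(ws_m, name)[tuple(flat)] -= h
                fd = (loss_at(ws_p) - loss_at(ws_m)) / (2 * h)
                an = grads[name][tuple(flat)]
                scale = max(abs(fd), abs(an), 1e-8)
                assert abs(fd - an) / scale < 1e-4, (name, tuple(flat), fd, an)
                checked += 1
        assert checked >= 10

    def test_hard_mode_gradients_finite_and_masked(self, toy_setup):
        cfg, ws, x, y, v0 = toy_setup
        grads, rec, _, _ = forward_backward(ws, x, y, ALIFParams(), TrainConfig(),
                                            np.random.default_rng(0), v_init=v0)
        for name in LAYERS:
            mask = getattr(ws, f"mask_{name.split('_')[1]}")
            assert np.isfinite(grads[name]).all()
            assert np.all(grads[name][~mask] == 0)
        assert rec.total == pytest.approx(rec.task + rec.rate_scaled)


class TestUpdates:
    def test_zero_learning_rate_leaves_weights_unchanged(self, toy_setup):
        cfg, ws, x, y, _ = toy_setup
        tcfg = TrainConfig(learning_rate=0.0)
        opt = OptimizerState.for_weights(ws, tcfg)
        before = ws.copy()
        batch_update(x, y, ws, opt, ALIFParams(), tcfg, cfg,
                     np.random.default_rng(0))
        for name in LAYERS:
            np.testing.assert_array_equal(getattr(ws, name), getattr(before, name))

    def test_masked_weights_stay_exactly_zero(self, toy_setup):
        cfg, ws, x, y, _ = toy_setup
        tcfg = TrainConfig(learning_rate=0.05)
        opt = OptimizerState.for_weights(ws, tcfg)
        frozen = ~ws.mask_rec.copy()
        structurally_zero = frozen & ~np.eye(ws.n_units, dtype=bool)
        rng = np.random.default_rng(0)
        for b in range(5):
            batch_update(x, y, ws, opt, ALIFParams(), tcfg, cfg, rng, batch=b)
        # every slot never activated by rewiring is still exactly zero
        never_active = structurally_zero & ~ws.mask_rec
        assert np.all(ws.W_rec[never_active] == 0)
        assert np.all(np.diag(ws.W_rec) == 0)

    def test_dale_signs_conserved_through_updates(self, rng):
        cfg = NetworkConfig(n_e=16, n_i=4, n_channels=4, input_w_max=2.0)
        ws = initialize_network(cfg, rng)
        tcfg = TrainConfig(learning_rate=0.05)
        opt = OptimizerState.for_weights(ws, tcfg)
        x = (rng.random((4, 4, 60)) < 0.3).astype(np.uint8)
        y = (rng.random((4, 60, 1)) < 0.5).astype(float)
        for b in range(8):
            batch_update(x, y, ws, opt, ALIFParams(), tcfg, cfg, rng, batch=b)
        ws.validate()  # includes sign homogeneity per unit

    def test_connection_counts_conserved_by_rewiring(self, rng):
        cfg = NetworkConfig(n_e=16, n_i=4, n_channels=4, input_w_max=2.0)
        ws = initialize_network(cfg, rng)
        counts0 = {n: int(getattr(ws, f"mask_{n.split('_')[1]}").sum()) for n in LAYERS}
        e0 = int(ws.mask_rec[ws.e_mask].sum())
        tcfg = TrainConfig(learning_rate=0.1)
        opt = OptimizerState.for_weights(ws, tcfg)
        x = (rng.random((4, 4, 60)) < 0.3).astype(np.uint8)
        y = (rng.random((4, 60, 1)) < 0.5).astype(float)
        for b in range(10):
            batch_update(x, y, ws, opt, ALIFParams(), tcfg, cfg, rng, batch=b)
        for n in LAYERS:
            assert int(getattr(ws, f"mask_{n.split('_')[1]}").sum()) == counts0[n]
        assert int(ws.mask_rec[ws.e_mask].sum()) == e0  # per sign class too


class TestDeepR:
    def test_no_crossing_is_identity(self, tiny_network, tiny_config, rng):
        before = tiny_network.copy()
        events = deepr_rewire(tiny_network, tiny_config, rng)
        assert events == []
        np.testing.assert_array_equal(before.W_rec, tiny_network.W_rec)

    def test_two_crossings_two_regrows(self, tiny_network, tiny_config, rng):
        ws = tiny_network
        e_active = np.argwhere(ws.mask_rec & (ws.sign[:, None] > 0))
        flip = e_active[:2]
        for j, i in flip:
            ws.W_rec[j, i] = -0.5  # excitatory weight gone negative
        n_before = int(ws.mask_rec.sum())
        events = deepr_rewire(ws, tiny_config, rng)
        rec_events = [e for e in events if e.layer == "W_rec"]
        assert len(rec_events) == 2
        assert all(e.regrown is not None for e in rec_events)
        assert int(ws.mask_rec.sum()) == n_before
        ws.validate()

    def test_regrow_respects_forbidden_slots(self, rng):
        cfg = NetworkConfig(n_e=6, n_i=2, n_channels=2, remove_ee=True,
                            p_ee=0.9, p_ei=0.9, p_ie=0.9, p_ii=0.9)
        ws = initialize_network(cfg, rng)
        ee = ws.e_mask[:, None] & ws.e_mask[None, :]
        # force every e->i weight to cross zero; regrowth must avoid e->e
        ei = ws.mask_rec & ws.e_mask[:, None]
        ws.W_rec[ei] = -1.0
        deepr_rewire(ws, cfg, rng)
        assert not ws.mask_rec[ee].any()
        assert np.all(np.diag(ws.W_rec) == 0)

    def test_skipped_without_dale(self, tiny_config, rng):
        cfg = NetworkConfig(**{**vars(tiny_config), "dale_enforced": False})
        ws = initialize_network(cfg, rng)
        ws.W_rec[ws.mask_rec] = -ws.W_rec[ws.mask_rec]  # wrong signs everywhere
        assert deepr_rewire(ws, cfg, rng) == []


class TestTrainLoop:
    def test_zero_updates_returns_initial_weights_only(self):
        from pushpull.config import preset_config
        cfg = preset_config("desk")
        est = train(cfg, rng=3, n_updates=0)
        assert est.n_updates_ == 0
        assert len(est.snapshots_) == 1
        np.testing.assert_array_equal(est.weights_.W_rec,
                                      est.initial_weights_.W_rec)

    def test_rate_only_training_improves_rate_loss(self):
        """Short rate-only optimization pulls the population rate toward the
        20 Hz target from near-silence."""
        from pushpull.config import preset_config
        cfg = preset_config("desk")
        cfg.network.n_e, cfg.network.n_i = 24, 6
        cfg.channels.n_blocks = 10
        cfg.channels.change_t_min, cfg.channels.change_t_max = 100, 500
        cfg.training.learning_rate = 1e-2
        cfg.training.batch_size = 5
        cfg.training.n_unique_trials = 20
        est = train(cfg, rng=3, mode="rate_only", n_updates=120)
        lh = est.loss_history_
        first = lh.rate_naive.iloc[:10].mean()
        last = lh.rate_naive.iloc[-10:].mean()
        assert last < first


class TestAcceleratedPath:
    def test_jit_kernels_match_reference_exactly(self, rng):
        """The numba-compiled forward/backward kernels reproduce the NumPy
        reference gradients and losses on an actively spiking network."""
        pytest.importorskip("numba")
        cfg = NetworkConfig(n_e=24, n_i=6, n_channels=8, input_w_max=4.0)
        ws = initialize_network(cfg, rng)
        x = (rng.random((4, 8, 120)) < 0.3).astype(np.uint8)
        y = (rng.random((4, 120, 1)) < 0.5).astype(float)
        v0 = np.full(30, -60.0)
        args = (ws, x, y, ALIFParams(), TrainConfig(), np.random.default_rng(0))
        g_ref, rec_ref, yp_ref, rast_ref = forward_backward(
            *args, v_init=v0, accel="numpy")
        g_jit, rec_jit, yp_jit, rast_jit = forward_backward(
            *args, v_init=v0, accel="auto")
        assert rast_ref.sum() > 0
        np.testing.assert_array_equal(np.asarray(rast_ref), np.asarray(rast_jit))
        assert rec_ref.total == pytest.approx(rec_jit.total, rel=1e-12)
        for name in LAYERS:
            np.testing.assert_allclose(g_ref[name], g_jit[name],
                                       rtol=1e-10, atol=1e-14)
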