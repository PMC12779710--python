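"""Modulation classification, weight ratios, persistence, KS comparisons."""

import numpy as np
import pandas as pd
import pytest

from pushpull.analysis import (UNCLASSIFIED, ModulationProfile,
                               classify_modulation, cross_within_ratio,
                               input_modulation_ratio, ks_compare,
                               random_modulation_profile, ratio_trajectory,
                               signed_cross_within_ratio,
                               top_quantile_persistence, weight_summary)
from pushpull.config import NetworkConfig
from pushpull.network import initialize_network


class TestClassification:
    def test_unit_spiking_only_during_label1_prefers_1(self):
        z = np.zeros((1, 3, 100))
        targets = np.zeros((1, 100))
        targets[0, 50:] = 1
        z[0, 0, 60:80] = 1          # spikes only in label-1 ms
        z[0, 1, 10:30] = 1          # spikes only in label-0 ms
        prof = classify_modulation(z, targets)
        assert prof.unit_label[0] == 1
        assert prof.unit_label[1] == 0
        assert prof.unit_label[2] == UNCLASSIFIED  # silent

    def test_rates_match_direct_averaging(self):
        """Toy rates 0.02 vs 0.01 computed by explicit masking."""
        rng = np.random.default_rng(0)
        targets = (rng.random((4, 500)) < 0.5).astype(float)
        z = (rng.random((4, 6, 500)) < 0.015).astype(float)
        prof = classify_modulation(z, targets)
        m1 = targets > 0.5
        for u in range(6):
            r1 = z[:, u, :][m1].mean()
            r0 = z[:, u, :][~m1].mean()
            assert prof.rate1[u] == pytest.approx(r1)
            assert prof.rate0[u] == pytest.approx(r0)
            if r1 != r0:
                assert prof.unit_label[u] == int(r1 > r0)

    def test_missing_label_state_raises(self):
        z = np.zeros((1, 2, 50))
        with pytest.raises(ValueError):
            classify_modulation(z, np.zeros((1, 50)))

    def test_channels_classified_from_input_spikes(self):
        z = np.zeros((1, 2, 100))
        z[0, :, ::7] = 1
        targets = np.zeros((1, 100))
        targets[0, 50:] = 1
        x = np.zeros((1, 3, 100))
        x[0, 0, 55:90] = 1
        x[0, 1, 5:40] = 1
        prof = classify_modulation(z, targets, input_spikes=x)
        assert prof.channel_label[0] == 1
        assert prof.channel_label[1] == 0
        assert prof.channel_label[2] == UNCLASSIFIED


class TestCrossWithinRatio:
    def test_exact_hand_computed_toy(self):
        """4 units (2e, 2i), labels [0,1,0,1], weights enumerated by hand."""
        sign = np.array([1.0, 1.0, -1.0, -1.0])
        lab = np.array([0, 1, 0, 1])
        W = np.array([
            [0.0, 1.0, 2.0, 3.0],    # e0 -> (e1 across, i0 within, i1 across)
            [4.0, 0.0, 5.0, 6.0],    # e1 -> (e0 across, i0 across, i1 within)
            [-7.0, -8.0, 0.0, -9.0],  # i0 -> (e0 within, e1 across, i1 across)
            [-10.0, -11.0, -12.0, 0.0],
        ])
        prof = ModulationProfile(unit_label=lab)
        rs = cross_within_ratio(W, prof, sign=sign)
        # independent enumeration over ordered pairs
        within_i, across_i = [], []
        for j in (2, 3):
            for i in range(4):
                if i == j or W[j, i] == 0:
                    continue
                (within_i if lab[j] == lab[i] else across_i).append(abs(W[j, i]))
        expected = np.mean(across_i) / np.mean(within_i)
        assert rs.ratio["i_pooled"] == pytest.approx(expected)
        # e->e has no within-pairs here (the two e labels differ) -> NaN, never 0
        assert np.isnan(rs.ratio["ee"])

    def test_random_labels_give_unit_ratio_on_average(self, rng):
        """Exchangeability null: labels independent of weights => pooled
        ratios are ~1 on average over 200 resamples."""
        cfg = NetworkConfig(n_e=40, n_i=10, n_channels=4)
        ws = initialize_network(cfg, rng)
        ratios = []
        for _ in range(200):
            lab = rng.integers(0, 2, size=ws.n_units)
            prof = ModulationProfile(unit_label=lab)
            rs = cross_within_ratio(ws.W_rec, prof, mask=ws.mask_rec, sign=ws.sign)
            ratios.append([rs.ratio["e_pooled"], rs.ratio["i_pooled"]])
        mean = np.nanmean(ratios, axis=0)
        sem = np.nanstd(ratios, axis=0) / np.sqrt(200)
        assert np.all(np.abs(mean - 1.0) < 4 * sem + 0.02)

    def test_profile_must_cover_all_units(self):
        with pytest.raises(ValueError):
            cross_within_ratio(np.zeros((4, 4)),
                               ModulationProfile(unit_label=np.array([0, 1])),
                               sign=np.ones(4))

    def test_signed_ratio_for_free_sign_networks(self):
        W = np.array([[0.0, 0.5], [-0.5, 0.0]])
        prof = ModulationProfile(unit_label=np.array([0, 1]))
        rs = signed_cross_within_ratio(W, prof)
        # only across-pairs exist -> within mean NaN -> ratio NaN
        assert np.isnan(rs.ratio["positive"])


class TestInputRatio:
    def test_identical_weights_unit_ratio(self):
        W = np.full((4, 6), 0.3)
        lab = np.array([0, 0, 1, 1])
        sign = np.array([1.0, 1.0, 1.0, -1.0, -1.0, -1.0])
        r = input_modulation_ratio(W, lab, sign)
        assert r["onto_e"] == pytest.approx(1.0)
        assert r["onto_i"] == pytest.approx(1.0)

    def test_doubled_one_modulated_weights(self):
        lab = np.array([0, 1])
        sign = np.array([1.0, 1.0, -1.0])
        W = np.array([[0.2, 0.2, 0.2],
                      [0.4, 0.4, 0.2]])  # '1' channel 2x onto e only
        r = input_modulation_ratio(W, lab, sign)
        assert r["onto_e"] == pytest.approx(2.0)
        assert r["onto_i"] == pytest.approx(1.0)

    def test_missing_zero_channels_give_nan(self):
        r = input_modulation_ratio(np.ones((2, 2)) * 0.1, np.array([1, 1]),
                                   np.array([1.0, -1.0]))
        assert np.isnan(r["onto_e"])


class TestPersistence:
    def test_identity_is_total_persistence(self, rng):
        W = rng.lognormal(size=(30, 30)) * (rng.random((30, 30)) < 0.3)
        assert top_quantile_persistence(W, W, 0.1) == 1.0

    def test_random_permutation_approaches_q(self, rng):
        """Permuting weights over the active slots leaves ~q of the top-q set
        in place, estimated over repeated permutations."""
        n_active = 600
        vals = rng.lognormal(size=n_active)
        W = np.zeros((40, 40))
        slots = rng.choice(40 * 40, size=n_active, replace=False)
        W.ravel()[slots] = vals
        fracs = []
        for _ in range(60):
            Wp = np.zeros(40 * 40)
            Wp[slots] = rng.permutation(vals)
            fracs.append(top_quantile_persistence(W, Wp.reshape(40, 40), 0.1))
        assert np.mean(fracs) == pytest.approx(0.1, abs=0.02)

    def test_too_few_connections_raises(self):
        W = np.zeros((5, 5))
        W[0, 1] = 1.0
        with pytest.raises(ValueError):
            top_quantile_persistence(W, W, 0.01)


class TestWeightSummary:
    def test_single_connection_toy(self, rng):
        cfg = NetworkConfig(n_e=2, n_i=1, n_channels=1, p_ee=0, p_ei=0,
                            p_ie=0, p_ii=0)
        ws = initialize_network(cfg, rng)
        ws.W_rec[0, 1] = 0.7
        ws.mask_rec[0, 1] = True
        df = weight_summary(ws).set_index("class")
        assert df.loc["ee", "mean"] == pytest.approx(0.7)
        assert df.loc["ee", "sd"] == 0.0
        assert df.loc["ee", "n"] == 1

    def test_lognormal_mean_recovered_at_scale(self, rng):
        cfg = NetworkConfig(n_e=300, n_i=60, n_channels=4, p_ee=1.0)
        ws = initialize_network(cfg, rng)
        df = weight_summary(ws).set_index("class")
        assert df.loc["ee", "mean"] == pytest.approx(cfg.lognormal_mean(), rel=5e-3)
        assert df.loc["ie", "mean"] == pytest.approx(-10 * cfg.lognormal_mean(), rel=0.05)

    def test_modulation_split_rows_present(self, rng, tiny_network):
        prof = ModulationProfile(
            unit_label=np.random.default_rng(0).integers(0, 2, tiny_network.n_units))
        df = weight_summary(tiny_network, prof)
        assert set(df[df["pairing"].notna()]["pairing"]) == {"0->0", "1->1", "0->1", "1->0"}


class TestKS:
    def test_identical_samples_zero_distance(self):
        a = np.arange(50, dtype=float)
        d, p = ks_compare(a, a)
        assert d == 0.0

    def test_disjoint_supports_full_distance(self):
        d, p = ks_compare(np.zeros(30), np.ones(30) * 5)
        assert d == 1.0
        assert p < 1e-6

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            ks_compare(np.array([]), np.ones(3))


class TestNullProfile:
    def test_trained_state_proportions_scaled(self, rng):
        prof = random_modulation_profile(240, 60, rng)
        counts = prof.counts()
        lab_e = prof.unit_label[:240]
        assert (lab_e == 0).sum() == 27
        assert (lab_e == 1).sum() == 194
        lab_i = prof.unit_label[240:]
        assert (lab_i == 0).sum() == 21
        assert (lab_i == 1).sum() == 22
        assert counts["unclassified"] == 300 - 27 - 194 - 21 - 22

    def test_scales_to_other_population_sizes(self, rng):
        prof = random_modulation_profile(24, 6, rng)
        assert prof.n_units == 30
        assert (prof.unit_label[:24] >= 0).sum() <= 24


class TestTrajectory:
    def test_retroactive_snapshot_consistency(self, rng, tiny_network):
        """The ratio computed on a stored snapshot equals the value from
        replaying the trajectory with the final profile."""
        ws0 = tiny_network.copy()
        ws1 = tiny_network.copy()
        ws1.W_rec[ws1.mask_rec] *= 2.0
        prof = ModulationProfile(
            unit_label=np.random.default_rng(1).integers(0, 2, ws0.n_units))
        df = ratio_trajectory([(0, ws0), (10, ws1)], prof, ws0.sign)
        direct = cross_within_ratio(ws0.W_rec, prof, mask=ws0.mask_rec,
                                    sign=ws0.sign).ratio["i_pooled"]
        got = df[(df["epoch"] == 0) & (df["class"] == "i_pooled")]["ratio"].iloc[0]
        assert got == pytest.approx(direct)
        # uniform scaling leaves the ratio invariant
        got10 = df[(df["epoch"] == 10) & (df["class"] == "i_pooled")]["ratio"].iloc[0]
        assert got10 == pytest.approx(direct)
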