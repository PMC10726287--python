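"""Gamma-renewal, burst, population and beta-modulated spike trains."""

import numpy as np
import pytest

from vmthal import spiketrains as st


class TestGammaTrain:
    def test_cv_matches_inverse_sqrt_shape(self):
        # shape 5, 3-ms refractory at 50 Hz: pooled CV stays at 1/sqrt(5)
        isis = []
        for seed in range(20):
            tr = st.gen_gamma_train(st.GammaTrainConfig(
                rate=50, shape=5, refractory=3, duration=50, seed=seed))
            isis.append(np.diff(tr))
        isis = np.concatenate(isis)
        assert np.std(isis) / np.mean(isis) == pytest.approx(0.447, abs=0.02)

    def test_poisson_limit(self):
        tr = st.gen_gamma_train(st.GammaTrainConfig(
            rate=40, shape=1, refractory=0, duration=200, seed=3))
        isi = np.diff(tr)
        assert np.std(isi) / np.mean(isi) == pytest.approx(1.0, abs=0.05)

    def test_refractory_respected(self):
        tr = st.gen_gamma_train(st.GammaTrainConfig(
            rate=100, shape=2, refractory=4, duration=30, seed=7))
        assert np.diff(tr).min() >= 4e-3

    def test_rate_close_to_nominal(self):
        tr = st.gen_gamma_train(st.GammaTrainConfig(
            rate=50, shape=5, refractory=3, duration=200, seed=11))
        assert tr.size / 200.0 == pytest.approx(50.0, rel=0.03)

    def test_determinism_and_seed_sensitivity(self):
        cfg = dict(rate=30, shape=5, refractory=3, duration=10)
        a = st.gen_gamma_train(st.GammaTrainConfig(**cfg, seed=5))
        b = st.gen_gamma_train(st.GammaTrainConfig(**cfg, seed=5))
        c = st.gen_gamma_train(st.GammaTrainConfig(**cfg, seed=6))
        assert np.array_equal(a, b)
        assert not (a.size == c.size and np.allclose(a, c))

    def test_infeasible_rate_rejected(self):
        with pytest.raises(ValueError, match="infeasible"):
            st.GammaTrainConfig(rate=400, shape=5, refractory=3)


class TestBurstTrain:
    def test_nigral_configuration_statistics(self):
        rates, cvs = [], []
        for seed in range(15):
            tr = st.gen_burst_train(None, st.BurstConfig(), 60.0, seed)
            d = st.train_stats(tr, 60.0)
            rates.append(d["rate"])
            cvs.append(d["cv_isi"])
        assert np.mean(rates) == pytest.approx(55.7, abs=2.5)
        assert np.mean(cvs) == pytest.approx(0.69, abs=0.04)

    def test_degenerate_no_bursts_equals_baseline(self):
        cfg = st.BurstConfig()
        tr = st.gen_burst_train(None, cfg, 30.0, 5,
                                onsets=np.empty(0))
        d = st.train_stats(tr, 30.0)
        assert d["rate"] == pytest.approx(cfg.interburst_rate, rel=0.1)
        assert d["cv_isi"] == pytest.approx(
            1.0 / np.sqrt(cfg.interburst_regularity), abs=0.05)

    def test_interval_floor(self):
        cfg = st.BurstConfig()
        rng = np.random.default_rng(0)
        onsets = st._burst_onsets(rng, cfg, 300.0)
        assert np.diff(onsets).min() >= cfg.interburst_interval_min * 1e-3

    def test_rate_template_hook(self):
        prof = [300.0, 100.0]  # decelerating burst
        cfg = st.BurstConfig(rate_template=prof)
        rng = np.random.default_rng(1)
        spikes = np.concatenate(
            [st._one_burst(rng, cfg, 0.0) for _ in range(200)])
        first_half = (spikes < 0.075).sum()
        second_half = ((spikes >= 0.075) & (spikes < 0.15)).sum()
        assert first_half > 2 * second_half


class TestPopulation:
    def test_full_sync_shares_onsets(self):
        ens = st.gen_population(5, st.BurstConfig(), 1.0, 20.0, seed=2)
        onsets = ens.meta["shared_onsets"]
        # every train must spike within each shared burst window
        for tr in ens.trains:
            for t0 in onsets[:-1]:
                assert ((tr >= t0) & (tr <= t0 + 0.16)).any()

    def test_zero_sync_bursts_independent(self):
        ens = st.gen_population(6, st.BurstConfig(), 0.0, 20.0, seed=3)
        assert ens.meta["n_sync"] == 0
        # trains differ pairwise
        sizes = {tr.size for tr in ens.trains}
        assert len(sizes) > 1 or not np.allclose(ens.trains[0],
                                                 ens.trains[1])

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            st.gen_population(0, st.BurstConfig(), 0.5, 10.0, 1)
        with pytest.raises(ValueError):
            st.gen_population(5, st.BurstConfig(), 1.5, 10.0, 1)


class TestBetaModulation:
    def test_zero_depth_matches_plain_gamma(self):
        cfg = st.GammaTrainConfig(rate=50, shape=5, refractory=3,
                                  duration=20, seed=4)
        a = st.apply_beta(cfg, st.BetaConfig(depth=0.0), 20.0, seed=4)
        b = st.gen_gamma_train(cfg)
        assert np.allclose(a, b)

    def test_rate_conservation(self):
        cfg = st.GammaTrainConfig(rate=50, shape=5, refractory=3)
        tr = st.apply_beta(cfg, st.BetaConfig(12.5, 0.1), 200.0, seed=9)
        assert tr.size / 200.0 == pytest.approx(50.0, rel=0.03)

    def test_folded_histogram_modulation_depth(self):
        cfg = st.GammaTrainConfig(rate=50, shape=5, refractory=3)
        spikes = np.concatenate([
            st.apply_beta(cfg, st.BetaConfig(12.5, 0.1), 100.0, seed=s)
            for s in range(20)])
        phase = np.mod(spikes * 12.5, 1.0)
        hist, _ = np.histogram(phase, bins=20)
        rel = hist / hist.mean() - 1.0
        # fit a sinusoid at the modulation frequency
        centers = (np.arange(20) + 0.5) / 20
        amp = 2.0 * np.abs(np.mean(rel * np.exp(-2j * np.pi * centers)))
        assert amp == pytest.approx(0.1, abs=0.025)

    def test_antiphase_peaks_anti_aligned(self):
        cfg = st.GammaTrainConfig(rate=50, shape=5, refractory=3)
        a = np.concatenate([st.apply_beta(cfg, st.BetaConfig(12.5, 0.3, 0.0),
                                          50.0, seed=s) for s in range(10)])
        b = np.concatenate([st.apply_beta(cfg, st.BetaConfig(12.5, 0.3, 180.0),
                                          50.0, seed=s + 50)
                            for s in range(10)])

        def peak_phase(sp):
            ph = 2 * np.pi * np.mod(sp * 12.5, 1.0)
            return np.angle(np.exp(1j * ph).mean())

        dphi = np.angle(np.exp(1j * (peak_phase(a) - peak_phase(b))))
        assert abs(abs(dphi) - np.pi) < 0.5


class TestTrainStats:
    def test_periodic_cv_zero(self):
        d = st.train_stats(np.arange(0.0, 10.0, 0.1), 10.0)
        assert d["cv_isi"] == pytest.approx(0.0, abs=1e-12)

    def test_rate_estimate(self):
        d = st.train_stats(np.linspace(0.05, 9.95, 100), 10.0)
        assert d["rate"] == pytest.approx(10.0)

    def test_undefined_cv_flagged(self):
        d = st.train_stats(np.array([1.0]), 10.0)
        assert d["cv_defined"] is False
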