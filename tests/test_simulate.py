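"""Simulator: couplings, latent dynamics, and conditional spike sampling."""

import numpy as np
import pytest

from latent_avalanches import (
    SimulationConfig,
    draw_couplings,
    firing_probability,
    sample_raster,
    simulate_latents,
    simulate_population_counts,
)


def _cfg(**kw):
    base = dict(
        n_neurons=32, n_fields=1, eta=1.0, epsilon=0.0, tau_F=100.0, n_steps=1000, seed=1
    )
    base.update(kw)
    return SimulationConfig(**base)


class TestConfig:
    def test_yaml_round_trip(self, tmp_path):
        cfg = _cfg(tau_F="quasistatic", n_steps=60, n_segments=3, bin_seconds=0.003)
        path = tmp_path / "cfg.yaml"
        cfg.to_yaml(path)
        assert SimulationConfig.from_yaml(path) == cfg

    @pytest.mark.parametrize(
        "kw",
        [
            dict(n_neurons=0),
            dict(eta=-1.0),
            dict(tau_F=0.0),
            dict(tau_F="quasistatic", n_steps=10, n_segments=3),
            dict(n_segments=4),  # segmenting outside quasi-static mode
        ],
    )
    def test_invalid_config_rejected(self, kw):
        with pytest.raises(ValueError):
            _cfg(**kw)


class TestCouplings:
    def test_seed_reproducibility(self):
        cfg = _cfg(n_neurons=1024, n_fields=5)
        a = draw_couplings(cfg, np.random.default_rng(7)).values
        b = draw_couplings(cfg, np.random.default_rng(7)).values
        assert a.shape == (1024, 5)
        np.testing.assert_array_equal(a, b)

    def test_standard_normal_moments(self):
        cfg = _cfg(n_neurons=100_000, n_fields=1)
        J = draw_couplings(cfg, np.random.default_rng(3)).values
        assert abs(J.mean()) < 4 / np.sqrt(100_000)
        assert abs(J.var() - 1.0) < 0.05

    def test_degenerate_dimensions_rejected(self):
        with pytest.raises(ValueError):
            _cfg(n_neurons=0, n_fields=1)


class TestLatents:
    def test_frozen_limit(self):
        # per-step innovation sqrt(2/tau) must leave the trajectory constant
        cfg = _cfg(tau_F=1e14, n_steps=10_000)
        h = simulate_latents(cfg, np.random.default_rng(2)).values[0]
        assert np.max(np.abs(h - h[0])) < 1e-4

    def test_ou_autocorrelation_matches_closed_form(self):
        tau = 100.0
        cfg = _cfg(tau_F=tau, n_steps=1_000_000)
        h = simulate_latents(cfg, np.random.default_rng(4)).values[0]
        lag = 100
        ac = np.corrcoef(h[:-lag], h[lag:])[0, 1]
        assert abs(ac - np.exp(-lag / tau)) < 0.02

    def test_ou_stationarity(self):
        cfg = _cfg(tau_F=50.0, n_steps=100_000)
        h = simulate_latents(cfg, np.random.default_rng(5)).values[0]
        t_eff = cfg.n_steps / 50.0  # effective number of independent samples
        assert abs(h.mean()) < 4 / np.sqrt(t_eff)
        assert abs(h.var() - 1.0) < 0.05

    def test_quasistatic_structure(self):
        cfg = _cfg(tau_F="quasistatic", n_steps=15, n_segments=3)
        traj = simulate_latents(cfg, np.random.default_rng(6))
        h = traj.values[0]
        assert traj.segment_boundaries == (5, 10)
        segs = h.reshape(3, 5)
        for seg in segs:
            assert np.all(seg == seg[0])
        assert len(np.unique(segs[:, 0])) == 3


class TestFiringProbability:
    def test_symmetric_point(self, coupling_column):
        p = firing_probability(coupling_column, np.zeros(1), eta=2.0, epsilon=0.0)
        np.testing.assert_allclose(p, 0.5)

    def test_bias_only_closed_form(self, coupling_column):
        p = firing_probability(coupling_column, np.zeros(1), eta=2.0, epsilon=12.0)
        np.testing.assert_allclose(p, 1.0 / (1.0 + np.exp(12.0)), rtol=1e-12)

    def test_single_neuron_closed_form(self):
        p = firing_probability(np.array([[1.0]]), np.array([1.0]), eta=4.0, epsilon=8.0)
        np.testing.assert_allclose(p, 1.0 / (1.0 + np.exp(12.0)), rtol=1e-12)

    def test_extreme_arguments_saturate(self):
        J = np.array([[1.0], [-1.0]])
        p = firing_probability(J, np.array([1e6]), eta=10.0, epsilon=0.0)
        assert p[0] == 0.0 and p[1] == 1.0

    def test_multifield_drive_normalization(self):
        # one field with h and five identical fields with h/1 each carry the
        # same total drive: eta * J.h / sqrt(NF) with J repeated keeps p equal
        J1 = np.array([[1.2]])
        J5 = np.full((1, 5), 1.2)
        p1 = firing_probability(J1, np.array([0.8]), eta=3.0, epsilon=2.0)
        p5 = firing_probability(J5, np.full(5, 0.8) / np.sqrt(5), eta=3.0, epsilon=2.0)
        np.testing.assert_allclose(p1, p5, rtol=1e-12)


class TestRaster:
    def test_silence_and_saturation_limits(self, small_quasistatic_config, rng):
        cfg = _cfg(n_steps=200)
        J = draw_couplings(cfg, rng)
        lat = simulate_latents(cfg, rng)
        silent = sample_raster(J, lat, eta=1.0, epsilon=50.0, rng=rng)
        assert silent.spikes.sum() == 0
        saturated = sample_raster(J, lat, eta=1.0, epsilon=-50.0, rng=rng)
        assert saturated.spikes.all()

    def test_unbiased_coin_rate(self):
        cfg = _cfg(n_neurons=1, eta=0.0, epsilon=0.0, n_steps=100_000)
        rng = np.random.default_rng(8)
        J = draw_couplings(cfg, rng)
        lat = simulate_latents(cfg, rng)
        r = sample_raster(J, lat, eta=0.0, epsilon=0.0, rng=rng)
        assert abs(r.spikes.mean() - 0.5) < 0.005

    def test_rates_match_probabilities_at_fixed_h(self):
        # quasi-static single segment -> h constant; binomial check per neuron
        cfg = _cfg(
            n_neurons=200, eta=2.0, epsilon=2.0, tau_F="quasistatic",
            n_steps=20_000, n_segments=1, seed=9,
        )
        rng = np.random.default_rng(9)
        J = draw_couplings(cfg, rng)
        lat = simulate_latents(cfg, rng)
        r = sample_raster(J, lat, cfg.eta, cfg.epsilon, rng=rng)
        p = firing_probability(J, lat.values[:, 0], cfg.eta, cfg.epsilon)
        se = np.sqrt(p * (1 - p) / cfg.n_steps)
        z = np.abs(r.spikes.mean(axis=1) - p) / np.maximum(se, 1e-12)
        assert np.mean(z < 4) >= 0.99

    def test_counts_path_matches_raster_path(self, rng):
        cfg = _cfg(n_neurons=40, n_fields=2, epsilon=3.0, n_steps=500)
        J = draw_couplings(cfg, np.random.default_rng(1))
        lat = simulate_latents(cfg, np.random.default_rng(2))
        r = sample_raster(J, lat, 2.0, 3.0, np.random.default_rng(3))
        c = simulate_population_counts(J, lat, 2.0, 3.0, np.random.default_rng(3))
        np.testing.assert_array_equal(r.spikes.sum(axis=0), c)

    def test_shape_mismatch_rejected(self, rng):
        cfg1 = _cfg(n_fields=1)
        cfg2 = _cfg(n_fields=2)
        J = draw_couplings(cfg2, rng)
        lat = simulate_latents(cfg1, rng)
        with pytest.raises(ValueError):
            sample_raster(J, lat, 1.0, 0.0, rng)

    def test_full_run_bit_reproducible(self, small_quasistatic_config):
        def run(cfg):
            rng = np.random.default_rng(cfg.seed)
            J = draw_couplings(cfg, rng)
            lat = simulate_latents(cfg, rng)
            return simulate_population_counts(J, lat, cfg.eta, cfg.epsilon, rng)

        a = run(small_quasistatic_config)
        b = run(small_quasistatic_config)
        np.testing.assert_array_equal(a, b)
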