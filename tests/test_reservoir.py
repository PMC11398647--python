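"""Reservoir dynamics: initialization, state update, Oja plasticity, ESP."""

import numpy as np
import pytest

from selcon import reservoir as res
from selcon.reservoir import (
    PlasticityConfig,
    ReservoirConfig,
    ReservoirNetwork,
    init_reservoir,
    oja_update,
    run_trial,
    spectral_radius,
    step,
)


def tiny_net(W, W_in=None, **cfg_kwargs):
    W = np.asarray(W, dtype=float)
    n = W.shape[0]
    defaults = dict(n_neurons=n, density=1.0, spectral_radius=1.0,
                    noise_sigma=0.0)
    defaults.update(cfg_kwargs)
    return ReservoirNetwork(
        W=W.copy(),
        W_in=np.zeros(n) if W_in is None else np.asarray(W_in, float),
        mask=np.ones((n, n), dtype=bool),
        config=ReservoirConfig(**defaults),
    )


class TestInit:
    def test_spectral_radius_rescaling_exact(self):
        cfg = ReservoirConfig(n_neurons=200, spectral_radius=1.4, init_seed=0)
        net = init_reservoir(cfg)
        assert abs(net.spectral_radius() - 1.4) / 1.4 < 1e-10

    def test_density_within_3_sigma(self):
        cfg = ReservoirConfig(n_neurons=500, density=0.1, init_seed=1)
        net = init_reservoir(cfg)
        p = net.mask.mean()
        sigma = np.sqrt(0.1 * 0.9 / 500**2)
        assert abs(p - 0.1) < 3 * sigma

    def test_input_weights_in_range(self):
        net = init_reservoir(ReservoirConfig(n_neurons=100, init_seed=2))
        assert net.W_in.min() >= -1 and net.W_in.max() <= 1

    def test_rescaling_of_symmetric_permutation(self):
        # [[0,1],[1,0]] has eigenvalues +-1, radius 1; halving the radius
        # halves every entry
        W = np.array([[0.0, 1.0], [1.0, 0.0]])
        rho = spectral_radius(W)
        assert rho == pytest.approx(1.0)
        W_scaled = W * (0.5 / rho)
        np.testing.assert_allclose(W_scaled, [[0, 0.5], [0.5, 0]])
        assert spectral_radius(W_scaled) == pytest.approx(0.5)

    def test_invalid_configs(self):
        with pytest.raises(ValueError):
            ReservoirConfig(density=0.0)
        with pytest.raises(ValueError):
            ReservoirConfig(spectral_radius=-1.0)
        with pytest.raises(ValueError):
            ReservoirConfig(update_rule="leaky")


class TestStep:
    def test_integrator_zero_drive_identity(self):
        net = tiny_net(np.zeros((3, 3)), update_rule="integrator")
        x = np.array([0.3, -0.2, 0.5])
        np.testing.assert_array_equal(step(x, net, 0.0), x)

    def test_standard_zero_drive_resets(self):
        net = tiny_net(np.zeros((3, 3)))
        x = np.array([0.3, -0.2, 0.5])
        np.testing.assert_array_equal(step(x, net, 0.0), np.zeros(3))

    def test_scalar_tanh_value(self):
        net = tiny_net([[0.0]], W_in=[1.0])
        out = step(np.array([0.0]), net, 0.5)
        assert out[0] == pytest.approx(np.tanh(0.5), abs=1e-12)
        assert out[0] == pytest.approx(0.46212, abs=1e-5)

    def test_deterministic_without_noise(self):
        net = init_reservoir(ReservoirConfig(n_neurons=50, noise_sigma=0.0,
                                             init_seed=3))
        x = np.random.default_rng(0).uniform(-1, 1, 50)
        a = step(x, net, 0.2)
        b = step(x, net, 0.2)
        np.testing.assert_array_equal(a, b)


class TestOja:
    def test_zero_alpha_no_change(self):
        net = init_reservoir(ReservoirConfig(n_neurons=30, init_seed=4))
        W0 = net.W.copy()
        oja_update(net, np.random.default_rng(1).uniform(-1, 1, 30), 0.0)
        np.testing.assert_array_equal(net.W, W0)

    def test_fixed_point(self):
        # x_i = x_j = W_ij = 1: the Hebbian and forgetting terms cancel
        net = tiny_net([[0.0, 1.0], [0.0, 0.0]])
        net.mask[:] = [[False, True], [False, False]]
        oja_update(net, np.array([1.0, 1.0]), alpha=0.1)
        assert net.W[0, 1] == pytest.approx(1.0)

    def test_forgetting_term(self):
        # x_i=1, x_j=0: pure decay, W <- W - alpha * W
        net = tiny_net([[0.0, 1.0], [0.0, 0.0]])
        net.mask[:] = [[False, True], [False, False]]
        oja_update(net, np.array([1.0, 0.0]), alpha=0.1)
        assert net.W[0, 1] == pytest.approx(0.9)

    def test_sparsity_pattern_conserved(self):
        net = init_reservoir(ReservoirConfig(n_neurons=80, density=0.1,
                                             init_seed=5))
        mask = net.mask.copy()
        for s in range(20):
            x = np.random.default_rng(s).uniform(-1, 1, 80)
            oja_update(net, x, alpha=0.05)
        assert (net.W[~mask] == 0).all()

    def test_weights_bounded_under_repeated_updates(self):
        net = init_reservoir(ReservoirConfig(n_neurons=60, init_seed=6))
        rng = np.random.default_rng(0)
        for _ in range(500):
            oja_update(net, rng.uniform(-1, 1, 60), alpha=0.05)
        assert np.isfinite(net.W).all()
        assert np.abs(net.W).max() < 100


class TestRunTrial:
    @pytest.fixture()
    def small_net(self):
        return init_reservoir(ReservoirConfig(
            n_neurons=40, density=0.3, spectral_radius=0.8,
            noise_sigma=1e-3, init_seed=7))

    def test_no_plasticity_leaves_weights(self, small_net):
        W0 = small_net.W.copy()
        u = np.random.default_rng(0).standard_normal(300)
        rec, net = run_trial(small_net, u, init_seed=1, noise_seed=2)
        np.testing.assert_array_equal(net.W, W0)
        assert rec.states.shape == (300, 40)

    def test_deterministic(self, small_net):
        u = np.random.default_rng(0).standard_normal(200)
        rec1, _ = run_trial(small_net.copy(), u, init_seed=1, noise_seed=2)
        rec2, _ = run_trial(small_net.copy(), u, init_seed=1, noise_seed=2)
        np.testing.assert_array_equal(rec1.states, rec2.states)

    def test_compiled_matches_reference(self, small_net):
        u = np.random.default_rng(3).standard_normal(80)
        plast = PlasticityConfig(enabled=True, alpha=1e-4)
        net_a = small_net.copy()
        net_b = small_net.copy()
        rec_a, net_a = run_trial(net_a, u, 5, plast, 6, engine="compiled")
        rec_b, net_b = run_trial(net_b, u, 5, plast, 6, engine="reference")
        np.testing.assert_allclose(rec_a.states, rec_b.states, rtol=1e-9,
                                   atol=1e-12)
        np.testing.assert_allclose(net_a.W, net_b.W, rtol=1e-9, atol=1e-12)

    def test_overflow_reported_with_diagnostics(self):
        # a corrupted (non-finite) state must not propagate silently
        net = tiny_net([[0.5, 0.0], [0.0, 0.5]])
        with pytest.raises(FloatingPointError) as exc:
            step(np.array([np.nan, 0.0]), net, 0.0)
        assert "spectral radius" in str(exc.value)


class TestConsistencyRegimes:
    """Echo-state property at low radius, chaos at high radius."""

    def _two_trials(self, rho, seed=11):
        net = init_reservoir(ReservoirConfig(
            n_neurons=200, density=0.1, spectral_radius=rho,
            noise_sigma=0.0, init_seed=seed))
        u = np.random.default_rng(1).standard_normal(2000) * 0.14
        rec1, _ = run_trial(net.copy(), u, init_seed=100)
        rec2, _ = run_trial(net.copy(), u, init_seed=200)
        return rec1.states, rec2.states

    def test_esp_convergence_at_low_radius(self):
        s1, s2 = self._two_trials(0.1)
        window = slice(200, 1000)
        rs = [np.corrcoef(s1[window, i], s2[window, i])[0, 1]
              for i in range(0, 200, 17)]
        assert min(rs) > 0.99

    def test_divergence_at_high_radius(self):
        rs = []
        for seed in range(12, 22):
            s1, s2 = self._two_trials(2.0, seed=seed)
            window = slice(200, 1000)
            rs += [np.corrcoef(s1[window, i], s2[window, i])[0, 1]
                   for i in range(0, 200, 40)]
        rs = np.array(rs)
        # mean pair correlation statistically indistinguishable from zero
        assert abs(rs.mean()) < 3 * rs.std() / np.sqrt(rs.size)
        assert np.abs(rs).mean() < 0.5


def test_snapshot_roundtrip(tmp_path):
    net = init_reservoir(ReservoirConfig(n_neurons=50, init_seed=8))
    res.save_network(net, tmp_path / "net")
    back = res.load_network(tmp_path / "net")
    np.testing.assert_array_equal(back.W, net.W)
    np.testing.assert_array_equal(back.W_in, net.W_in)
    np.testing.assert_array_equal(back.mask, net.mask)
    assert back.config == net.config
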