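"""ZINB likelihood: oracle checks, normalization, NB limit, network heads."""

import numpy as np
import pytest
from scipy.special import gammaln as sp_gammaln

from scunite import _autodiff as ad
from scunite.network import NetworkConfig, ZINBAutoencoder
from scunite.zinb import (ZINBParams, nb_log_pmf, reconstruction_loss,
                          zinb_log_pmf, zinb_nll_t)

RNG = np.random.default_rng(7)


def oracle_nb_log_pmf(x, mu, theta):
    """Independent log-gamma evaluation of the NB pmf."""
    return (sp_gammaln(x + theta) - sp_gammaln(x + 1) - sp_gammaln(theta)
            + theta * np.log(theta / (theta + mu))
            + x * np.log(mu / (theta + mu)))


class TestZinbLogPmf:
    def test_all_mass_at_zero(self):
        assert zinb_log_pmf(0, 1 - 1e-12, 2.0, 1.0) == pytest.approx(0.0, abs=1e-5)

    def test_zero_with_no_dropout_equals_nb_zero(self):
        # NB(0 | mu=2, theta=1) = (1/3)^1
        val = zinb_log_pmf(0, 0.0, 2.0, 1.0)
        assert val == pytest.approx(np.log(1 / 3), abs=1e-5)

    def test_positive_count_matches_oracle(self):
        val = zinb_log_pmf(5, 0.3, 4.0, 2.0)
        expected = np.log(0.7) + oracle_nb_log_pmf(5, 4.0, 2.0)
        assert val == pytest.approx(expected, abs=1e-10)

    def test_random_grid_matches_oracle(self):
        x = RNG.integers(0, 50, size=200)
        mu = RNG.uniform(0.1, 30, size=200)
        theta = RNG.uniform(0.2, 20, size=200)
        pi = RNG.uniform(0.01, 0.99, size=200)
        got = zinb_log_pmf(x, pi, mu, theta)
        mix = pi * (x == 0) + (1 - pi) * np.exp(oracle_nb_log_pmf(x, mu, theta))
        np.testing.assert_allclose(got, np.log(mix), atol=1e-8)

    def test_nb_limit_as_pi_vanishes(self):
        """ZINB with clamped-to-zero dropout reproduces NB for x > 0."""
        x = np.arange(1, 30)
        got = zinb_log_pmf(x, 0.0, 3.0, 1.5)
        np.testing.assert_allclose(got, nb_log_pmf(x, 3.0, 1.5), atol=1e-6)

    @pytest.mark.parametrize("pi,mu,theta", [(0.3, 2.0, 1.0),
                                             (0.05, 10.0, 5.0),
                                             (0.8, 0.5, 0.3)])
    def test_probability_normalization(self, pi, mu, theta):
        x = np.arange(0, 10_000)
        total = np.exp(zinb_log_pmf(x, pi, mu, theta)).sum()
        assert total == pytest.approx(1.0, abs=1e-6)

    def test_nb_moments_monte_carlo(self):
        """NB samples match the (mu, mu + mu^2/theta) moments."""
        mu, theta = 5.0, 2.0
        rng = np.random.default_rng(123)
        lam = rng.gamma(theta, mu / theta, size=200_000)
        x = rng.poisson(lam)
        assert x.mean() == pytest.approx(mu, rel=0.02)
        assert x.var() == pytest.approx(mu + mu ** 2 / theta, rel=0.05)


class TestReconstructionLoss:
    def test_certain_zero_gives_zero_loss(self):
        params = ZINBParams(pi=[[1 - 1e-12]], mu=[[2.0]], theta=[[1.0]])
        assert reconstruction_loss([[0]], params) == pytest.approx(0.0, abs=1e-5)

    def test_matches_elementwise_oracle(self):
        n, m = 7, 5
        x = RNG.integers(0, 20, size=(n, m))
        params = ZINBParams(pi=RNG.uniform(0.1, 0.9, (n, m)),
                            mu=RNG.uniform(0.5, 10, (n, m)),
                            theta=RNG.uniform(0.5, 5, (n, m)))
        acc = 0.0
        for i in range(n):
            for j in range(m):
                acc += zinb_log_pmf(x[i, j], params.pi[i, j],
                                    params.mu[i, j], params.theta[i, j])
        assert reconstruction_loss(x, params) == pytest.approx(-acc / (n * m),
                                                               abs=1e-8)

    def test_mean_invariance_under_stacking(self):
        x = RNG.integers(0, 10, size=(4, 3))
        params = ZINBParams(pi=RNG.uniform(0.2, 0.8, (4, 3)),
                            mu=RNG.uniform(1, 5, (4, 3)),
                            theta=RNG.uniform(1, 5, (4, 3)))
        double = ZINBParams(pi=np.vstack([params.pi] * 2),
                            mu=np.vstack([params.mu] * 2),
                            theta=np.vstack([params.theta] * 2))
        assert reconstruction_loss(np.vstack([x] * 2), double) == pytest.approx(
            reconstruction_loss(x, params), abs=1e-12)

    def test_shape_mismatch_raises(self):
        params = ZINBParams(pi=[[0.5]], mu=[[1.0]], theta=[[1.0]])
        with pytest.raises(ValueError, match="shape"):
            reconstruction_loss([[1, 2]], params)

    def test_autodiff_path_matches_numpy_path(self):
        n, m = 6, 4
        x = RNG.integers(0, 15, size=(n, m)).astype(float)
        pi = RNG.uniform(0.1, 0.9, (n, m))
        mu = RNG.uniform(0.5, 8, (n, m))
        theta = RNG.uniform(0.5, 5, (n, m))
        loss_t = zinb_nll_t(x, ad.Tensor(pi), ad.Tensor(mu), ad.Tensor(theta))
        loss_np = reconstruction_loss(x, ZINBParams(pi, mu, theta))
        assert loss_t.item() == pytest.approx(loss_np, abs=1e-8)


class TestForward:
    @pytest.fixture()
    def net(self):
        return ZINBAutoencoder(n_genes=20, n_batches=2, n_types=3,
                               config=NetworkConfig(encoder_sizes=(16, 8),
                                                    d_latent=4, seed=0))

    def test_zero_weight_network_activation_identities(self, net):
        for k, t in net.weights.items():
            t.data[:] = 0.0
        x = np.zeros((3, 20))
        b = np.eye(2)[[0, 1, 0]]
        out = net.forward(x, b, np.ones(3))
        np.testing.assert_allclose(out["pi"].data, 0.5)
        np.testing.assert_allclose(out["theta"].data, np.log(2), atol=1e-6)

    def test_head_ranges_on_random_input(self, net):
        x = RNG.standard_normal((10, 20))
        b = np.eye(2)[RNG.integers(0, 2, 10)]
        _, params, probs = net.predict(x, b, RNG.uniform(0.5, 2, 10))
        assert params.pi.min() > 0 and params.pi.max() < 1
        assert params.mu.min() >= 1e-5 and params.mu.max() <= 1e6
        assert params.theta.min() >= 1e-5 and params.theta.max() <= 1e6
        np.testing.assert_allclose(probs.sum(axis=1), 1.0, atol=1e-6)

    def test_batch_flip_is_local_to_the_cell(self, net):
        """Flipping one cell's batch changes its decoder output only."""
        x = RNG.standard_normal((4, 20))
        b = np.eye(2)[[0, 0, 1, 1]]
        sf = np.ones(4)
        out1 = net.forward(x, b, sf)
        b2 = b.copy()
        b2[0] = [0, 1]
        out2 = net.forward(x, b2, sf)
        assert not np.allclose(out1["mu"].data[0], out2["mu"].data[0])
        np.testing.assert_array_equal(out1["mu"].data[1:], out2["mu"].data[1:])

    def test_one_adam_step_decreases_reconstruction(self, net):
        rng = np.random.default_rng(0)
        x_raw = rng.integers(0, 12, size=(16, 20))
        x_in = np.log1p(x_raw) - np.log1p(x_raw).mean(axis=0)
        b = np.eye(2)[rng.integers(0, 2, 16)]
        sf = x_raw.sum(axis=1) / np.median(x_raw.sum(axis=1))
        opt = ad.Adam(net.parameters(), lr=1e-3)
        losses = []
        for _ in range(2):
            out = net.forward(x_in, b, sf)
            loss = zinb_nll_t(x_raw, out["pi"], out["mu"], out["theta"])
            losses.append(loss.item())
            opt.zero_grad()
            loss.backward()
            opt.step()
        assert losses[1] < losses[0]

    def test_batchnorm_centers_training_latent(self, net):
        """Training-mode batch norm gives the bottleneck near-zero feature
        means, and running statistics move toward the batch statistics."""
        x = RNG.standard_normal((64, 20)) * 3 + 1
        b = np.eye(2)[RNG.integers(0, 2, 64)]
        before = net.bn_stats["latent_mean"].copy()
        out = net.forward(x, b, np.ones(64), training=True)
        z = out["z"].data
        np.testing.assert_allclose(z.mean(axis=0), 0.0, atol=1e-4)
        np.testing.assert_allclose(z.var(axis=0), 1.0, atol=1e-3)
        assert not np.allclose(net.bn_stats["latent_mean"], before)

    def test_inference_uses_running_statistics(self, net):
        """Eval-mode output for one cell is independent of its batchmates."""
        x = RNG.standard_normal((8, 20))
        b = np.eye(2)[[0] * 8]
        sf = np.ones(8)
        full = net.forward(x, b, sf)["z"].data
        solo = net.forward(x[:1], b[:1], sf[:1])["z"].data
        np.testing.assert_allclose(full[0], solo[0], atol=1e-6)

    def test_checkpoint_roundtrip_bit_identical(self, net, tmp_path):
        path = tmp_path / "ckpt.npz"
        net.save(path)
        clone = ZINBAutoencoder.load(path)
        for k in net.weights:
            np.testing.assert_array_equal(net.weights[k].data,
                                          clone.weights[k].data)
        x = RNG.standard_normal((3, 20))
        b = np.eye(2)[[0, 1, 1]]
        np.testing.assert_array_equal(net.encode(x, b), clone.encode(x, b))
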