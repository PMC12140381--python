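"""Encoder forward passes, VGAE loss and contrastive loss vs independent oracles."""

import numpy as np
import pytest
import scipy.sparse as sp

from stgcl import (GCNEncoder, VGAEModel, contrastive_loss, draw_augmentations,
                   gcn_forward, vgae_encode, vgae_loss)
from stgcl.autodiff import Tensor
from stgcl.networks import node_kl


def random_norm_adj(n, rng, density=0.3):
    a = (rng.uniform(size=(n, n)) < density).astype(float)
    a = np.triu(a, 1)
    a = a + a.T + np.eye(n)
    d = a.sum(axis=1)
    return a / np.sqrt(np.outer(d, d))


class TestGCNForward:
    def test_zero_weights_give_zero_output(self, rng):
        enc = GCNEncoder(4, (3,), rng=rng)
        enc.layer_weights[0].data[:] = 0.0
        z = gcn_forward(enc, sp.identity(5, format="csr"), rng.uniform(size=(5, 4)))
        np.testing.assert_array_equal(z.data, 0.0)

    def test_identity_propagation(self, rng):
        enc = GCNEncoder(4, (4,), rng=rng)
        enc.layer_weights[0].data = np.eye(4)
        x = np.abs(rng.normal(size=(6, 4)))
        z = gcn_forward(enc, sp.identity(6, format="csr"), x)
        np.testing.assert_allclose(z.data, x)

    def test_matches_dense_oracle_on_path_graph(self, rng):
        n = 5
        a = np.zeros((n, n))
        for i in range(n - 1):
            a[i, i + 1] = a[i + 1, i] = 1
        at = a + np.eye(n)
        d = at.sum(axis=1)
        ahat = at / np.sqrt(np.outer(d, d))
        x = rng.normal(size=(n, 7))
        enc = GCNEncoder(7, (3,), rng=rng)
        z = gcn_forward(enc, sp.csr_matrix(ahat), x)
        expected = np.maximum(ahat @ x @ enc.layer_weights[0].data, 0.0)
        np.testing.assert_allclose(z.data, expected, atol=1e-6)

    def test_shape_mismatch_raises(self, rng):
        enc = GCNEncoder(4, (3,), rng=rng)
        with pytest.raises(ValueError):
            gcn_forward(enc, sp.identity(5, format="csr"), rng.uniform(size=(5, 6)))

    def test_linear_final_layer_option(self, rng):
        enc = GCNEncoder(3, (2,), final_activation=False, rng=rng)
        x = rng.normal(size=(4, 3))
        z = gcn_forward(enc, sp.identity(4, format="csr"), x)
        np.testing.assert_allclose(z.data, x @ enc.layer_weights[0].data, atol=1e-12)


class TestVGAE:
    def test_zero_weights_give_standard_normal_posterior(self, rng):
        v = VGAEModel(4, 3, 2, rng=rng)
        for p in v.parameters():
            p.data[:] = 0.0
        mu, logvar = vgae_encode(v, sp.identity(5, format="csr"),
                                 rng.uniform(size=(5, 4)))
        np.testing.assert_array_equal(mu.data, 0.0)
        np.testing.assert_array_equal(logvar.data, 0.0)

    def test_first_layer_is_shared_object(self, rng):
        v = VGAEModel(4, 3, 2, rng=rng)
        assert v.parameters()[0] is v.shared_first_layer_weights

    def test_mean_branch_perturbation_leaves_sigma_branch_unchanged(self, rng):
        v = VGAEModel(4, 3, 2, rng=rng)
        adj = sp.identity(6, format="csr")
        x = rng.normal(size=(6, 4))
        _, logvar_before = vgae_encode(v, adj, x)
        v.mean_weights.data += 1.0
        _, logvar_after = vgae_encode(v, adj, x)
        np.testing.assert_array_equal(logvar_before.data, logvar_after.data)

    def test_matches_dense_two_layer_oracle(self, rng):
        n = 6
        ahat = random_norm_adj(n, rng)
        x = rng.normal(size=(n, 5))
        v = VGAEModel(5, 4, 3, rng=rng)
        mu, logvar = vgae_encode(v, sp.csr_matrix(ahat), x)
        h0 = np.maximum(ahat @ x @ v.shared_first_layer_weights.data, 0.0)
        np.testing.assert_allclose(mu.data, ahat @ h0 @ v.mean_weights.data,
                                   atol=1e-6)
        np.testing.assert_allclose(
            logvar.data,
            np.clip(ahat @ h0 @ v.logvar_weights.data, -10, 10), atol=1e-6)

    def test_kl_zero_for_standard_normal(self):
        mu = Tensor(np.zeros((4, 3)))
        logvar = Tensor(np.zeros((4, 3)))
        np.testing.assert_allclose(node_kl(mu, logvar).data, 0.0, atol=1e-15)

    def test_kl_half_for_unit_mean_shift(self):
        mu = np.zeros((3, 4))
        mu[1, 0] = 1.0
        kl = node_kl(Tensor(mu), Tensor(np.zeros((3, 4))))
        np.testing.assert_allclose(kl.data, [0.0, 0.5, 0.0], atol=1e-15)

    def test_loss_matches_scalar_loop_oracle(self, rng):
        n, d = 8, 3
        a = (rng.uniform(size=(n, n)) < 0.3).astype(float)
        a = np.triu(a, 1)
        a = a + a.T + np.eye(n)
        mu = Tensor(rng.normal(size=(n, d)))
        logvar = Tensor(rng.normal(size=(n, d)))
        h = Tensor(rng.normal(size=(n, d)))
        loss = vgae_loss(mu, logvar, h, a)

        e = a.sum()
        w = (n * n - e) / e
        norm = n * n / (2.0 * (n * n - e))
        acc = 0.0
        for i in range(n):
            for j in range(n):
                x = float(h.data[i] @ h.data[j])
                p = 1.0 / (1.0 + np.exp(-x))
                acc += (-w * np.log(p) if a[i, j] else -np.log(1.0 - p))
        recon = norm * acc / (n * n)
        kl = sum(0.5 * (mu.data[i] ** 2 + np.exp(logvar.data[i]) - 1
                        - logvar.data[i]).sum() for i in range(n)) / n
        np.testing.assert_allclose(loss.data, recon + kl, atol=1e-6)


class TestAugmentations:
    def test_degenerate_sigma_returns_mean(self, rng):
        mu = rng.normal(size=(5, 3))
        aug = draw_augmentations(mu, np.full((5, 3), -1e9), M=4,
                                 rng=np.random.default_rng(0))
        # log-variance clamps at -10, so sigma ~ exp(-5) ~ 0.007
        np.testing.assert_allclose(aug, np.broadcast_to(mu, (4, 5, 3)), atol=0.05)

    def test_fixed_seed_reproducible(self, rng):
        mu, lv = rng.normal(size=(6, 2)), rng.normal(size=(6, 2))
        a = draw_augmentations(mu, lv, 3, np.random.default_rng(77))
        b = draw_augmentations(mu, lv, 3, np.random.default_rng(77))
        np.testing.assert_array_equal(a, b)

    def test_sample_mean_concentrates_on_mu(self):
        mu = np.array([[1.5, -2.0]])
        logvar = np.zeros((1, 2))  # sigma = 1
        aug = draw_augmentations(mu, logvar, 10_000, np.random.default_rng(5))
        se = 1.0 / np.sqrt(10_000)
        assert np.all(np.abs(aug.mean(axis=0) - mu) < 3 * se)


class TestContrastiveLoss:
    def test_identical_embeddings_give_log_n(self):
        n, d = 7, 4
        z = np.tile(np.array([[1.0, 0.5, -0.2, 0.3]]), (n, 1))
        loss = contrastive_loss(Tensor(z), z[None], tau=1.0)
        np.testing.assert_allclose(loss.data, np.log(n), atol=1e-10)

    def test_two_orthonormal_anchors_closed_form(self):
        z = np.eye(2)
        loss = contrastive_loss(Tensor(z), z[None], tau=1.0)
        expected = -np.log(np.e / (np.e + 1.0))
        np.testing.assert_allclose(loss.data, expected, atol=1e-10)

    def test_matches_double_loop_oracle(self, rng):
        n, d, m, tau = 16, 5, 3, 0.7
        z = rng.normal(size=(n, d))
        aug = rng.normal(size=(m, n, d))
        loss = contrastive_loss(Tensor(z), aug, tau)
        acc = 0.0
        for nn in range(n):
            for mm in range(m):
                num = np.exp(z[nn] @ aug[mm, nn] / tau)
                den = sum(np.exp(z[k] @ aug[mm, nn] / tau) for k in range(n))
                acc += -np.log(num / den)
        np.testing.assert_allclose(loss.data, acc / (n * m), rtol=1e-6)

    def test_nonpositive_temperature_rejected(self, rng):
        z = rng.normal(size=(4, 2))
        with pytest.raises(ValueError):
            contrastive_loss(Tensor(z), z[None], tau=0.0)

    def test_loss_decreases_as_positive_similarity_grows(self):
        rng = np.random.default_rng(3)
        z = rng.normal(size=(8, 4))
        z /= np.linalg.norm(z, axis=1, keepdims=True)
        losses = []
        for lam in [0.0, 0.5, 1.0]:
            aug = (1 - lam) * rng.normal(size=(8, 4)) * 0.1 + lam * z
            losses.append(float(contrastive_loss(Tensor(z), aug[None], 0.5).data))
        assert losses[0] > losses[1] > losses[2]
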