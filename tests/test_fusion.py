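"""Attention fusion and the DEC operations against loop oracles."""

import numpy as np
import pytest

from stgcl import (AttentionFuser, fuse_views, hard_labels, init_centroids,
                   kl_loss, soft_assign, target_distribution)
from stgcl.autodiff import Tensor


def make_fuser(dim, seed=0, nonzero_q=True):
    f = AttentionFuser(dim, rng=np.random.default_rng(seed))
    if nonzero_q:
        f.q.data = np.random.default_rng(seed + 1).normal(size=(dim, 1)) * 0.3
    return f


class TestFuseViews:
    def test_identical_views_get_half_half(self, rng):
        z = rng.normal(size=(10, 4))
        fused, a1, a2 = fuse_views(make_fuser(4), z, z)
        np.testing.assert_allclose(a1.data, 0.5, atol=1e-12)
        np.testing.assert_allclose(a2.data, 0.5, atol=1e-12)
        np.testing.assert_allclose(fused.data, z, atol=1e-12)

    def test_zero_attention_vector_gives_uniform_weights(self, rng):
        f = make_fuser(4, nonzero_q=False)  # q stays at its zero init
        z1, z2 = rng.normal(size=(6, 4)), rng.normal(size=(6, 4))
        fused, a1, a2 = fuse_views(f, z1, z2)
        np.testing.assert_allclose(a1.data, 0.5, atol=1e-12)
        np.testing.assert_allclose(fused.data, 0.5 * (z1 + z2), atol=1e-12)

    def test_matches_per_spot_loop_oracle(self, rng):
        f = make_fuser(5, seed=2)
        z1, z2 = rng.normal(size=(20, 5)), rng.normal(size=(20, 5))
        fused, a1, a2 = fuse_views(f, z1, z2)
        q = f.q.data.ravel()
        for i in range(20):
            v1, v2 = q @ z1[i], q @ z2[i]
            e1, e2 = np.exp(v1 - max(v1, v2)), np.exp(v2 - max(v1, v2))
            w1 = e1 / (e1 + e2)
            np.testing.assert_allclose(a1.data[i, 0], w1, atol=1e-6)
            np.testing.assert_allclose(fused.data[i],
                                       w1 * z1[i] + (1 - w1) * z2[i], atol=1e-6)

    def test_coefficients_sum_to_one_and_fused_on_segment(self, rng):
        f = make_fuser(3, seed=5)
        z1, z2 = rng.normal(size=(15, 3)), rng.normal(size=(15, 3))
        fused, a1, a2 = fuse_views(f, z1, z2)
        np.testing.assert_allclose(a1.data + a2.data, 1.0, atol=1e-9)
        # fused row lies on the segment between the two view rows
        for i in range(15):
            t = a1.data[i, 0]
            assert 0.0 <= t <= 1.0
            np.testing.assert_allclose(fused.data[i],
                                       t * z1[i] + (1 - t) * z2[i], atol=1e-9)

    def test_shape_mismatch_raises(self, rng):
        with pytest.raises(ValueError):
            fuse_views(make_fuser(3), rng.normal(size=(4, 3)),
                       rng.normal(size=(5, 3)))


class TestCentroids:
    def test_separated_blobs_recovered(self, rng):
        a = rng.normal(size=(50, 2)) * 0.05 + np.array([0.0, 0.0])
        b = rng.normal(size=(50, 2)) * 0.05 + np.array([5.0, 5.0])
        z = np.vstack([a, b])
        cents = init_centroids(z, 2, seed=0)
        got = sorted(cents.tolist())
        np.testing.assert_allclose(got[0], a.mean(axis=0), atol=0.1)
        np.testing.assert_allclose(got[1], b.mean(axis=0), atol=0.1)

    def test_fixed_seed_deterministic(self, rng):
        z = rng.normal(size=(40, 3))
        np.testing.assert_array_equal(init_centroids(z, 4, seed=9),
                                      init_centroids(z, 4, seed=9))

    def test_invalid_counts_rejected(self, rng):
        z = rng.normal(size=(5, 2))
        with pytest.raises(ValueError):
            init_centroids(z, 0, seed=0)
        with pytest.raises(ValueError):
            init_centroids(z, 6, seed=0)


class TestSoftAssign:
    def test_equidistant_point_splits_evenly(self):
        z = np.array([[0.0, 0.0]])
        cents = np.array([[1.0, 0.0], [-1.0, 0.0]])
        np.testing.assert_allclose(soft_assign(z, cents), [[0.5, 0.5]], atol=1e-12)

    def test_plugin_arithmetic_example(self):
        # z at centroid 1, squared distance 3 to centroid 2:
        # q1 = 1 / (1 + 1/4) = 0.8
        z = np.array([[0.0, 0.0]])
        cents = np.array([[0.0, 0.0], [np.sqrt(3.0), 0.0]])
        np.testing.assert_allclose(soft_assign(z, cents), [[0.8, 0.2]], atol=1e-12)

    def test_rows_sum_to_one(self, rng):
        q = soft_assign(rng.normal(size=(30, 6)), rng.normal(size=(4, 6)))
        np.testing.assert_allclose(q.sum(axis=1), 1.0, atol=1e-12)

    def test_tensor_input_returns_tensor_with_gradients(self, rng):
        z = Tensor(rng.normal(size=(5, 3)), requires_grad=True)
        cents = Tensor(rng.normal(size=(2, 3)), requires_grad=True)
        q = soft_assign(z, cents)
        assert isinstance(q, Tensor)
        q.sum().backward()
        assert z.grad is not None and cents.grad is not None


class TestTargetDistribution:
    def test_one_hot_is_fixed_point(self):
        q = np.eye(4)[[0, 1, 2, 3, 0, 1]]
        np.testing.assert_allclose(target_distribution(q), q, atol=1e-12)

    def test_uniform_stays_uniform(self):
        q = np.full((6, 3), 1.0 / 3.0)
        np.testing.assert_allclose(target_distribution(q), q, atol=1e-12)

    def test_matches_element_loop_and_sharpens(self, rng):
        q = rng.dirichlet(np.ones(3), size=10)
        p = target_distribution(q)
        f = q.sum(axis=0)
        for i in range(10):
            den = sum(q[i, jj] ** 2 / f[jj] for jj in range(3))
            for j in range(3):
                np.testing.assert_allclose(p[i, j], (q[i, j] ** 2 / f[j]) / den,
                                           atol=1e-12)
        np.testing.assert_allclose(p.sum(axis=1), 1.0, atol=1e-12)

    def test_sharpening_with_balanced_clusters(self):
        rng = np.random.default_rng(0)
        # equal cluster frequencies: sharpening must not decrease the max entry
        q = rng.dirichlet(np.ones(4), size=100)
        q = np.vstack([q, q[:, ::-1]])  # symmetrize frequencies
        p = target_distribution(q)
        assert np.all(p.max(axis=1) >= q.max(axis=1) - 1e-12)


class TestKLLoss:
    def test_identical_distributions_zero(self, rng):
        q = rng.dirichlet(np.ones(4), size=8)
        assert kl_loss(q, q) == pytest.approx(0.0, abs=1e-12)

    def test_one_hot_vs_uniform_closed_form(self):
        n = 5
        p = np.tile([1.0, 0.0], (n, 1))
        q = np.full((n, 2), 0.5)
        assert kl_loss(p, q) == pytest.approx(n * np.log(2.0), abs=1e-12)

    def test_matches_scalar_double_loop(self, rng):
        p = rng.dirichlet(np.ones(3), size=12)
        q = rng.dirichlet(np.ones(3), size=12)
        expected = sum(p[i, j] * np.log(p[i, j] / q[i, j])
                       for i in range(12) for j in range(3) if p[i, j] > 0)
        assert kl_loss(p, q) == pytest.approx(expected, abs=1e-10)

    def test_zero_q_with_positive_p_raises(self):
        p = np.array([[0.5, 0.5]])
        q = np.array([[1.0, 0.0]])
        with pytest.raises(ValueError, match="infinite"):
            kl_loss(p, q)

    def test_tensor_path_matches_numpy_path(self, rng):
        p = rng.dirichlet(np.ones(4), size=6)
        q = rng.dirichlet(np.ones(4), size=6)
        t = kl_loss(p, Tensor(q, requires_grad=True))
        assert float(t.data) == pytest.approx(kl_loss(p, q), abs=1e-12)


class TestHardLabels:
    def test_argmax_and_tiebreak(self):
        q = np.array([[0.2, 0.5, 0.3], [0.5, 0.5, 0.0]])
        np.testing.assert_array_equal(hard_labels(q), [1, 0])

    def test_invariant_to_row_rescaling(self, rng):
        q = rng.dirichlet(np.ones(5), size=20)
        scale = rng.uniform(0.1, 10.0, size=(20, 1))
        np.testing.assert_array_equal(hard_labels(q), hard_labels(q * scale))
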