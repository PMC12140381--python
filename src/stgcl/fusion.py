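"""Attention fusion of view embeddings and deep embedded clustering (DEC).

The two view embeddings Z^(1), Z^(2) are merged per spot by a learned
attention: a shared vector q scores each view embedding (v_i^(j) = q·z_i^(j)),
a two-way softmax turns the scores into coefficients α_i^(1) + α_i^(2) = 1,
and the fused embedding is the convex combination
Z_i = α_i^(1) z_i^(1) + α_i^(2) z_i^(2).

Clustering follows DEC: centroids are initialized by k-means on the fused
embedding; a Student's-t kernel (one degree of freedom) gives soft
assignments Q; the sharpened target distribution P emphasizes
high-confidence assignments; training minimizes KL(P ‖ Q) with P held
constant between periodic refreshes.
"""

from __future__ import annotations

import numpy as np
from sklearn.cluster import KMeans

from .autodiff import Parameter, Tensor

__all__ = ["AttentionFuser", "ClusterState", "fuse_views", "init_centroids",
           "soft_assign", "target_distribution", "kl_loss", "hard_labels"]

_EPS = 1e-12


from dataclasses import dataclass  # noqa: E402


@dataclass
class ClusterState:
    """Centroids, soft and target assignments, and hard labels."""

    centroids: np.ndarray      # (C, d)
    Q: np.ndarray              # (N, C), rows sum to 1
    P: np.ndarray              # (N, C), rows sum to 1
    labels: np.ndarray         # (N,) = argmax_j Q[i, j]
    C: int


class AttentionFuser:
    """Shared attention vector over views, with an optional projection.

    With `use_projection=True` the score is q·tanh(W z); by default it is
    the plain inner product q·z.
    """

    def __init__(self, dim: int, use_projection: bool = False,
                 rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng()
        # zero init starts every spot at uniform 0.5/0.5 attention
        self.q = Parameter(np.zeros((dim, 1)))
        scale = 1.0 / np.sqrt(dim)
        self.projection = (Parameter(rng.uniform(-scale, scale, size=(dim, dim)))
                           if use_projection else None)

    def parameters(self):
        ps = [self.q]
        if self.projection is not None:
            ps.append(self.projection)
        return ps


def fuse_views(fuser: AttentionFuser, Z1, Z2):
    """Attention-weighted convex combination of two view embeddings.

    Returns (Z, α1, α2); the coefficients are (N, 1) and sum to 1 per spot.
    The two-way softmax is evaluated as α1 = σ(v1 − v2) via softplus for
    stability.
    """
    Z1 = Z1 if isinstance(Z1, Tensor) else Tensor(Z1)
    Z2 = Z2 if isinstance(Z2, Tensor) else Tensor(Z2)
    if Z1.shape != Z2.shape:
        raise ValueError(f"view shapes differ: {Z1.shape} vs {Z2.shape}")

    def score(z):
        h = (z @ fuser.projection).tanh() if fuser.projection is not None else z
        return h @ fuser.q  # (N, 1)

    v1, v2 = score(Z1), score(Z2)
    # softmax over the two views: α1 = exp(v1)/(exp(v1)+exp(v2)) = exp(-softplus(v2-v1))
    a1 = (-((v2 - v1).softplus())).exp()
    a2 = (-((v1 - v2).softplus())).exp()
    fused = a1 * Z1 + a2 * Z2
    return fused, a1, a2


def init_centroids(Z, C: int, seed: int) -> np.ndarray:
    """k-means++ centroids (20 restarts) on the fused embedding."""
    z = Z.data if isinstance(Z, Tensor) else np.asarray(Z, dtype=float)
    if C < 1:
        raise ValueError(f"cluster count must be >= 1, got {C}")
    if C > z.shape[0]:
        raise ValueError(f"C={C} exceeds the number of spots {z.shape[0]}")
    km = KMeans(n_clusters=C, n_init=20, random_state=int(seed)).fit(z)
    return km.cluster_centers_.astype(float)


def soft_assign(Z, centroids):
    """Student's-t soft assignment q_ij ∝ (1 + ‖z_i − μ_j‖²)^{-1}.

    Accepts numpy arrays or autodiff tensors; the return type follows Z
    (a Tensor input keeps the computation differentiable with respect to
    both the embedding and the centroids).
    """
    tensor_in = isinstance(Z, Tensor) or isinstance(centroids, Tensor)
    z = Z if isinstance(Z, Tensor) else Tensor(Z)
    mu = centroids if isinstance(centroids, Tensor) else Tensor(centroids)
    d2 = (z.pow(2.0).sum(axis=1, keepdims=True)
          - 2.0 * (z @ mu.T)
          + mu.pow(2.0).sum(axis=1, keepdims=True).T)
    # guard tiny negative round-off in the expanded square
    d2 = d2.clamp(0.0, np.inf)
    kernel = (1.0 + d2).pow(-1.0)
    q = kernel * kernel.sum(axis=1, keepdims=True).pow(-1.0)
    return q if tensor_in else q.data


def target_distribution(Q: np.ndarray) -> np.ndarray:
    """Sharpened target P: p_ij = (q_ij²/f_j) / Σ_{j'} (q_ij'²/f_j'), f_j = Σ_i q_ij."""
    q = Q.data if isinstance(Q, Tensor) else np.asarray(Q, dtype=float)
    f = q.sum(axis=0)
    w = q * q / np.maximum(f, _EPS)
    return w / w.sum(axis=1, keepdims=True)


def kl_loss(P: np.ndarray, Q):
    """KL(P ‖ Q) = Σ_ij p_ij log(p_ij/q_ij), with 0·log 0 = 0.

    P is treated as a constant target; Q may be an autodiff tensor, in
    which case the result is differentiable.  An exact zero in Q where P
    is positive makes the divergence infinite and raises.
    """
    p = np.asarray(P.data if isinstance(P, Tensor) else P, dtype=float)
    q_data = Q.data if isinstance(Q, Tensor) else np.asarray(Q, dtype=float)
    if np.any((q_data == 0) & (p > 0)):
        raise ValueError("infinite KL divergence: Q has zero mass where P > 0")
    logp = np.where(p > 0, np.log(np.where(p > 0, p, 1.0)), 0.0)
    if isinstance(Q, Tensor):
        # where p == 0 the term vanishes; shift those q to 1 so log stays finite
        shift = ((p == 0) & (q_data == 0)).astype(float)
        loss = (Tensor(p) * (Tensor(logp) - (Q + Tensor(shift)).log())).sum()
        return loss
    with np.errstate(divide="ignore", invalid="ignore"):
        logq = np.where(p > 0, np.log(np.where(q_data > 0, q_data, 1.0)), 0.0)
    return float(np.sum(p * (logp - logq)))


def hard_labels(Q) -> np.ndarray:
    """argmax_j q_ij per spot; ties resolve to the lowest cluster index."""
    q = Q.data if isinstance(Q, Tensor) else np.asarray(Q)
    return np.argmax(q, axis=1)
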