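"""Per-view encoders and the implicit contrastive objective.

Each view (spatial graph, feature graph) gets two networks over the same
expression features X:

* a graph-convolutional encoder producing the view embedding
  Z = ReLU(Â X W) (single layer by default), used for fusion and
  clustering;
* a variational graph autoencoder (VGAE) whose GCN encoder outputs a
  Gaussian posterior N(μ_n, diag(σ_n²)) per spot, with the first layer
  shared between the mean and log-variance branches, and an inner-product
  decoder σ(a_i·a_j) reconstructing the adjacency.

Samples from the VGAE posterior act as *implicit augmentations*: for spot
n, (a_n^m, z_n) is a positive pair and the other spots' embeddings are
in-batch negatives, scored by a temperature-scaled InfoNCE loss.  The
VGAE is trained only by its own reconstruction + KL objective; the
augmentations enter the contrastive loss as constants, so no gradient
flows between the two parameter groups.
"""

from __future__ import annotations

import numpy as np
import scipy.sparse as sp

from .autodiff import Parameter, Tensor, spmm

__all__ = ["GCNEncoder", "VGAEModel", "gcn_forward", "vgae_encode",
           "node_kl", "vgae_loss", "draw_augmentations", "contrastive_loss"]

LOGVAR_CLAMP = 10.0


def _glorot(rng: np.random.Generator, fan_in: int, fan_out: int) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=(fan_in, fan_out))


class GCNEncoder:
    """Graph convolutional encoder: Z_l = ReLU(Â Z_{l-1} W_{l-1}), Z_0 = X.

    `dims` gives the layer output sizes; with `final_activation=False` the
    last layer is linear instead of rectified.
    """

    def __init__(self, in_dim: int, dims=(64,), final_activation: bool = True,
                 rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng()
        self.final_activation = final_activation
        self.layer_weights: list[Parameter] = []
        prev = in_dim
        for d in dims:
            self.layer_weights.append(Parameter(_glorot(rng, prev, d)))
            prev = d

    def parameters(self):
        return list(self.layer_weights)


def gcn_forward(enc: GCNEncoder, norm_adj: sp.spmatrix, X) -> Tensor:
    """Forward pass through every layer of `enc` on the normalized adjacency."""
    z = X if isinstance(X, Tensor) else Tensor(X)
    if norm_adj.shape[1] != z.shape[0]:
        raise ValueError(f"adjacency {norm_adj.shape} does not conform "
                         f"with features {z.shape}")
    for li, w in enumerate(enc.layer_weights):
        if z.shape[1] != w.shape[0]:
            raise ValueError(f"layer {li}: features {z.shape} vs weights {w.shape}")
        z = spmm(norm_adj, z) @ w
        if li < len(enc.layer_weights) - 1 or enc.final_activation:
            z = z.relu()
    return z


class VGAEModel:
    """Two-branch GCN encoder with a shared first layer.

    H^(0) = ReLU(Â X W^(0)) feeds both the mean branch (→ μ, linear) and
    the log-variance branch (→ log σ², linear, clamped to ±10).  The
    shared first layer means a single Parameter object serves both
    branches.
    """

    def __init__(self, in_dim: int, hidden_dim: int = 64, latent_dim: int = 64,
                 rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng()
        self.latent_dim = latent_dim
        self.shared_first_layer_weights = Parameter(_glorot(rng, in_dim, hidden_dim))
        self.mean_weights = Parameter(_glorot(rng, hidden_dim, latent_dim))
        self.logvar_weights = Parameter(_glorot(rng, hidden_dim, latent_dim))

    def parameters(self):
        return [self.shared_first_layer_weights, self.mean_weights,
                self.logvar_weights]


def vgae_encode(v: VGAEModel, norm_adj: sp.spmatrix, X) -> tuple[Tensor, Tensor]:
    """Return (μ, log σ²), each N x D, for the per-node Gaussian posteriors."""
    x = X if isinstance(X, Tensor) else Tensor(X)
    if x.shape[1] != v.shared_first_layer_weights.shape[0]:
        raise ValueError(f"features {x.shape} vs first-layer weights "
                         f"{v.shared_first_layer_weights.shape}")
    h0 = (spmm(norm_adj, x) @ v.shared_first_layer_weights).relu()
    ah0 = spmm(norm_adj, h0)
    mu = ah0 @ v.mean_weights
    logvar = (ah0 @ v.logvar_weights).clamp(-LOGVAR_CLAMP, LOGVAR_CLAMP)
    return mu, logvar


def node_kl(mu: Tensor, logvar: Tensor) -> Tensor:
    """Per-node KL[N(μ_n, diag(σ_n²)) ‖ N(0, I)] = ½ Σ_d (μ² + σ² − 1 − log σ²)."""
    return (mu.pow(2.0) + logvar.exp() - 1.0 - logvar).sum(axis=1) * 0.5


def bce_class_weights(adj_with_self_loops) -> tuple[np.ndarray, float, float]:
    """Dense 0/1 target plus the class-balance constants (pos_weight, norm)."""
    target = np.asarray(adj_with_self_loops.todense()
                        if sp.issparse(adj_with_self_loops)
                        else adj_with_self_loops, dtype=float)
    n = target.shape[0]
    e = target.sum()
    if e == 0 or e == n * n:
        return target, 1.0, 0.5
    return target, (n * n - e) / e, n * n / (2.0 * (n * n - e))


def _weighted_bce_mean(logits: Tensor, target: np.ndarray, pos_weight: float,
                       norm: float) -> Tensor:
    """norm · mean over all pairs of the class-weighted BCE with logits.

    Per element: w·y·softplus(−x) + (1−y)·softplus(x), written as
    (1+(w−1)y)·softplus(x) − w·y·x so a single softplus pass suffices; the
    gradient is (1+(w−1)y)·σ(x) − w·y, applied in one fused backward step
    (the decoder logits are N×N, so avoiding intermediate tensors matters).
    """
    x = logits.data
    w1 = 1.0 + (pos_weight - 1.0) * target
    # stable softplus: max(x,0) + log1p(exp(-|x|))
    sp_x = np.maximum(x, 0.0) + np.log1p(np.exp(-np.abs(x)))
    val = norm * float((w1 * sp_x - pos_weight * target * x).mean())

    def bwd(g):
        if logits.requires_grad:
            from scipy.special import expit
            grad = expit(x)
            grad *= w1
            grad -= pos_weight * target
            grad *= float(g) * norm / x.size
            logits._accum(grad)

    return Tensor(val, logits.requires_grad, parents=(logits,), backward=bwd)


def vgae_loss(mu: Tensor, logvar: Tensor, sampled_H: Tensor,
              adj_with_self_loops) -> Tensor:
    """Negative ELBO of the VGAE.

    Reconstruction: class-balanced binary cross-entropy between the
    inner-product decoder logits a_i·a_j and the self-loop adjacency, with
    positive-edge weight (N²−E)/E and overall scale N²/(2(N²−E)) — without
    this balance a sparse graph drives the decoder to predict no edges.
    Regularizer: the Gaussian KL to the standard-normal prior, averaged
    over nodes.
    """
    target, pos_weight, norm = bce_class_weights(adj_with_self_loops)
    logits = sampled_H @ sampled_H.T
    recon = _weighted_bce_mean(logits, target, pos_weight, norm)
    n = target.shape[0]
    kl = node_kl(mu, logvar).sum() * (1.0 / n)
    loss = recon + kl
    if not np.isfinite(loss.data):
        bad = "reconstruction" if not np.isfinite(recon.data) else "KL"
        raise FloatingPointError(f"non-finite VGAE loss ({bad} term)")
    return loss


def draw_augmentations(mu, logvar, M: int, rng: np.random.Generator) -> np.ndarray:
    """Draw M reparameterized samples a^m = μ + σ ⊙ ε per node, ε ~ N(0, I).

    Returns an (M, N, D) array of constants — gradients never flow through
    augmentations.
    """
    if M < 1:
        raise ValueError("M must be >= 1")
    mu = mu.data if isinstance(mu, Tensor) else np.asarray(mu, dtype=float)
    logvar = logvar.data if isinstance(logvar, Tensor) else np.asarray(logvar, dtype=float)
    sigma = np.exp(0.5 * np.clip(logvar, -LOGVAR_CLAMP, LOGVAR_CLAMP))
    eps = rng.standard_normal(size=(M,) + mu.shape)
    return mu[None] + sigma[None] * eps


def contrastive_loss(Z: Tensor, augmentations: np.ndarray, tau: float) -> Tensor:
    """Temperature-scaled InfoNCE over implicit augmentations.

    L = (1/N) Σ_n (1/M) Σ_m −log[ exp(z_n·a_n^m/τ) / Σ_{n'} exp(z_{n'}·a_n^m/τ) ];
    the denominator runs over all anchors in the batch, so the negatives of
    (a_n^m, z_n) are the other spots' anchor embeddings.  Stabilized through
    log-sum-exp.
    """
    if tau <= 0:
        raise ValueError(f"temperature must be positive, got {tau}")
    Z = Z if isinstance(Z, Tensor) else Tensor(Z)
    aug = np.asarray(augmentations, dtype=float)
    if aug.ndim == 2:
        aug = aug[None]
    m_count = aug.shape[0]
    if aug.shape[1:] != tuple(Z.shape):
        raise ValueError(f"augmentations {aug.shape} vs anchors {Z.shape}")
    total = None
    for m in range(m_count):
        logits = (Z @ Tensor(aug[m]).T) * (1.0 / tau)  # [n', n] = z_n'·a_n / τ
        lse = logits.logsumexp(axis=0)                 # over anchors n'
        pos = logits.diag_part()
        term = (lse - pos).mean()
        total = term if total is None else total + term
    return total * (1.0 / m_count)
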