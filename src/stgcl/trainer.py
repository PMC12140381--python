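"""End-to-end training loop.

One iteration interleaves two parameter groups that never exchange
gradients:

* Φ^(i) — each view's VGAE, updated by its own reconstruction + KL loss;
* Θ — the per-view GCN encoders, the attention vector and the DEC
  centroids, updated by L = α·KL(P‖Q) + β·(L_CL^(1) + L_CL^(2)), where the
  contrastive positives are fresh samples from the VGAE posteriors treated
  as constants.

Centroids are initialized by k-means on the fused embedding of the
initial forward pass.  Every T iterations the target distribution P is
refreshed from the current soft assignment and the hard labels are
compared with the previous checkpoint's; training stops when the fraction
of changed labels falls below δ.  Between refreshes P is held fixed
(stale), and it is always a constant with respect to gradients.

Ablations: ``wo_S`` drops the spatial view, ``wo_F`` the feature view
(the remaining view's embedding is used directly), ``wo_A`` replaces
attention by an unweighted mean of the two views.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .autodiff import Adam, Parameter, Tensor
from .data import STDataset
from .fusion import (AttentionFuser, ClusterState, fuse_views, hard_labels,
                     init_centroids, kl_loss, soft_assign, target_distribution)
from .graphs import build_feature_graph, build_spatial_graph
from .metrics import ari, nmi
from .networks import GCNEncoder, VGAEModel, contrastive_loss, draw_augmentations

__all__ = ["TrainConfig", "TrainLog", "EmbeddingSet", "fit", "run_ablation"]

ABLATIONS = ("full", "wo_F", "wo_S", "wo_A")


@dataclass
class TrainConfig:
    """Every knob of the training schedule.

    Graph construction: radius `r` (coordinate units) and neighbor count
    `k`.  Architecture: GCN embedding size `gcn_dim`, VGAE hidden/latent
    sizes.  Contrastive: temperature `tau`, `M` posterior samples per
    anchor, batch size `b`.  Objective: weights `alpha` (KL) and `beta`
    (contrastive).  Optimization: Adam with `lr`/`weight_decay`, at most
    `max_iter` iterations, target refresh every `T`, stop when fewer than
    a fraction `delta` of labels change at a checkpoint.
    """

    C: int = 0
    r: float = 700.0
    k: int = 20
    gcn_dim: int = 64
    vgae_hidden: int = 64
    vgae_latent: int = 64
    gcn_final_activation: bool = True
    tau: float = 0.5
    M: int = 5
    b: int = 512
    alpha: float = 1.0
    beta: float = 1.0
    lr: float = 0.003
    weight_decay: float = 0.001
    max_iter: int = 1000
    T: int = 50
    delta: float = 1e-3
    seed: int = 0
    ablation: str = "full"

    def validate(self, n_spots: int):
        if self.ablation not in ABLATIONS:
            raise ValueError(f"unknown ablation {self.ablation!r}; "
                             f"expected one of {ABLATIONS}")
        if self.C < 1:
            raise ValueError("cluster count C must be set (>= 1)")
        if self.C > n_spots:
            raise ValueError(f"C={self.C} exceeds N={n_spots}")
        if not (0.0 <= self.delta <= 1.0):
            raise ValueError("delta must lie in [0, 1]")
        for name in ("r", "tau", "lr", "M", "b", "T"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.vgae_latent != self.gcn_dim:
            raise ValueError(
                "the contrastive loss scores anchors against posterior samples "
                "by inner product, so vgae_latent must equal gcn_dim")


@dataclass
class EmbeddingSet:
    """Per-view embeddings, the fused embedding, and attention coefficients."""

    per_view: list
    fused: np.ndarray
    attention: Optional[np.ndarray] = None  # (N, n_views), rows sum to 1


@dataclass
class TrainLog:
    records: list = field(default_factory=list)

    def append(self, **kv):
        self.records.append(kv)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.records)

    def write_tsv(self, path: str):
        self.to_dataframe().to_csv(path, sep="\t", index=False)


class _View:
    """Bundles one view's graph, networks and precomputed products."""

    def __init__(self, graph, X: np.ndarray, cfg: TrainConfig,
                 rng: np.random.Generator):
        self.graph = graph
        g = X.shape[1]
        self.gcn = GCNEncoder(g, (cfg.gcn_dim,),
                              final_activation=cfg.gcn_final_activation, rng=rng)
        self.vgae = VGAEModel(g, cfg.vgae_hidden, cfg.vgae_latent, rng=rng)
        self.norm_adj = graph.norm_adj
        # Â X is constant throughout training; both nets share it as layer-0 input
        self.ax = Tensor(self.norm_adj @ X)
        from .networks import bce_class_weights
        adj_self = graph.adj + sp.identity(graph.n_spots)
        adj_self.data[:] = np.minimum(adj_self.data, 1.0)
        self.bce_target, self.bce_pos_weight, self.bce_norm = \
            bce_class_weights(adj_self)
        self.opt = Adam(self.vgae.parameters(), lr=cfg.lr,
                        weight_decay=cfg.weight_decay)

    # single-layer fast paths over the cached Â X product -------------------

    def gcn_embed(self) -> Tensor:
        z = self.ax @ self.gcn.layer_weights[0]
        return z.relu() if self.gcn.final_activation else z

    def vgae_posterior(self) -> tuple[Tensor, Tensor]:
        h0 = (self.ax @ self.vgae.shared_first_layer_weights).relu()
        from .autodiff import spmm
        ah0 = spmm(self.norm_adj, h0)
        mu = ah0 @ self.vgae.mean_weights
        logvar = (ah0 @ self.vgae.logvar_weights).clamp(-10.0, 10.0)
        return mu, logvar

    def vgae_step(self, rng: np.random.Generator) -> tuple[float, Tensor, Tensor]:
        from .networks import _weighted_bce_mean, node_kl
        mu, logvar = self.vgae_posterior()
        eps = Tensor(rng.standard_normal(mu.shape))
        h = mu + (logvar * 0.5).exp() * eps
        logits = h @ h.T
        recon = _weighted_bce_mean(logits, self.bce_target,
                                   self.bce_pos_weight, self.bce_norm)
        kl = node_kl(mu, logvar).sum() * (1.0 / mu.shape[0])
        loss = recon + kl
        if not np.isfinite(loss.data):
            raise FloatingPointError("non-finite VGAE loss")
        self.opt.zero_grad()
        loss.backward()
        self.opt.step()
        return float(loss.data), mu, logvar


def _build_views(ds: STDataset, cfg: TrainConfig,
                 rng: np.random.Generator) -> list[_View]:
    X = ds.expr_dense().astype(float)
    # encoders see per-gene standardized features so that embedding,
    # attention-score and inner-product magnitudes stay O(1) regardless of
    # the normalization target sum; the feature graph keeps the raw
    # preprocessed matrix (cosine similarity on non-centered expression)
    sd = X.std(axis=0)
    Xenc = (X - X.mean(axis=0)) / np.where(sd > 0, sd, 1.0)
    views = []
    if cfg.ablation != "wo_S":
        views.append(_View(build_spatial_graph(ds.coords, r=cfg.r), Xenc, cfg, rng))
    if cfg.ablation != "wo_F":
        views.append(_View(build_feature_graph(X, k=cfg.k), Xenc, cfg, rng))
    return views


def _fuse(views: list[_View], zs: list[Tensor], fuser: Optional[AttentionFuser],
          cfg: TrainConfig):
    """Combine view embeddings; returns (Z, attention or None)."""
    if len(zs) == 1:
        return zs[0], None
    if cfg.ablation == "wo_A" or fuser is None:
        return (zs[0] + zs[1]) * 0.5, np.full((zs[0].shape[0], 2), 0.5)
    z, a1, a2 = fuse_views(fuser, zs[0], zs[1])
    return z, np.column_stack([a1.data.ravel(), a2.data.ravel()])


def _leiden_cluster_count(ds: STDataset, cfg: TrainConfig) -> int:
    """Estimate C by Leiden community detection on the expression kNN graph."""
    import igraph as ig
    import leidenalg

    adj = build_feature_graph(ds.expr_dense().astype(float), k=cfg.k).adj.tocoo()
    edges = [(int(i), int(j)) for i, j in zip(adj.row, adj.col) if i < j]
    graph = ig.Graph(n=ds.n_spots, edges=edges)
    part = leidenalg.find_partition(graph, leidenalg.RBConfigurationVertexPartition,
                                    seed=cfg.seed)
    return len(part)


def fit(ds: STDataset, cfg: TrainConfig) -> tuple[EmbeddingSet, ClusterState, TrainLog]:
    """Train on one (preprocessed) section and return embeddings, clusters, log."""
    if cfg.C < 1:
        cfg = replace(cfg, C=_leiden_cluster_count(ds, cfg))
        warnings.warn(f"cluster count not set; using C={cfg.C} from Leiden "
                      "pre-clustering of the expression kNN graph")
    cfg.validate(ds.n_spots)
    n = ds.n_spots
    ss = np.random.SeedSequence(cfg.seed)
    rng_init, rng_vgae, rng_aug, rng_batch = (
        np.random.default_rng(s) for s in ss.spawn(4))
    kmeans_seed = int(np.random.default_rng(ss.spawn(1)[0]).integers(2 ** 31))

    views = _build_views(ds, cfg, rng_init)
    fuser = (AttentionFuser(cfg.gcn_dim, rng=rng_init)
             if len(views) == 2 and cfg.ablation != "wo_A" else None)

    # centroid init on the initial fused embedding
    zs0 = [v.gcn_embed() for v in views]
    z0, _ = _fuse(views, zs0, fuser, cfg)
    centroids = Parameter(init_centroids(z0.data, cfg.C, kmeans_seed))

    theta = [w for v in views for w in v.gcn.parameters()]
    if fuser is not None:
        theta += fuser.parameters()
    theta.append(centroids)
    opt_theta = Adam(theta, lr=cfg.lr, weight_decay=cfg.weight_decay)

    log = TrainLog()
    s_old: Optional[np.ndarray] = None
    P: Optional[np.ndarray] = None
    stopped = False

    for it in range(cfg.max_iter):
        # -- VGAE updates (Φ), one per view --------------------------------
        vgae_losses, posteriors = [], []
        for v in views:
            lv, mu, logvar = v.vgae_step(rng_vgae)
            vgae_losses.append(lv)
            posteriors.append((mu.data, logvar.data))

        # -- backbone forward (Θ) ------------------------------------------
        zs = [v.gcn_embed() for v in views]

        batch = rng_batch.choice(n, size=min(cfg.b, n), replace=False)
        l_cl = None
        for (mu_d, lv_d), z in zip(posteriors, zs):
            aug = draw_augmentations(mu_d[batch], lv_d[batch], cfg.M, rng_aug)
            # score on the unit sphere (standard InfoNCE practice) so the
            # temperature keeps its usual meaning
            aug = aug / np.maximum(np.linalg.norm(aug, axis=2, keepdims=True), 1e-12)
            zb = z.gather_rows(batch)
            zb = zb * (zb.pow(2.0).sum(axis=1, keepdims=True) + 1e-12).pow(-0.5)
            term = contrastive_loss(zb, aug, cfg.tau)
            l_cl = term if l_cl is None else l_cl + term

        z_fused, att = _fuse(views, zs, fuser, cfg)

        # -- T-checkpoint: refresh P, labels, test stopping ----------------
        if it % cfg.T == 0:
            q_np = soft_assign(z_fused.data, centroids.data)
            P = target_distribution(q_np)
            s_new = hard_labels(q_np)
            if s_old is not None:
                frac = float(np.mean(s_old != s_new))
                log.append(iteration=it, event="checkpoint", label_change=frac)
                if frac < cfg.delta:
                    s_old = s_new
                    stopped = True
                    break
            s_old = s_new

        # -- Θ update -------------------------------------------------------
        q_t = soft_assign(z_fused, centroids)
        l_kl = kl_loss(P, q_t)
        loss = cfg.alpha * l_kl + cfg.beta * l_cl
        if not np.isfinite(loss.data):
            raise FloatingPointError(f"training diverged at iteration {it}")
        opt_theta.zero_grad()
        loss.backward()
        opt_theta.step()

        log.append(iteration=it, event="step",
                   l_vgae=float(np.sum(vgae_losses)),
                   **{f"l_vgae_{i + 1}": lv for i, lv in enumerate(vgae_losses)},
                   l_cl=float(l_cl.data), l_kl=float(l_kl.data),
                   l_total=float(loss.data),
                   att_mean=(float(att[:, 0].mean()) if att is not None else 1.0))

    # -- final state --------------------------------------------------------
    zs = [v.gcn_embed() for v in views]
    z_fused, att = _fuse(views, zs, fuser, cfg)
    q_np = soft_assign(z_fused.data, centroids.data)
    if P is None:
        P = target_distribution(q_np)
    state = ClusterState(centroids=centroids.data.copy(), Q=q_np,
                         P=P, labels=hard_labels(q_np), C=cfg.C)
    emb = EmbeddingSet(per_view=[z.data for z in zs], fused=z_fused.data,
                       attention=att)
    log.append(iteration=cfg.max_iter, event="final", stopped_early=stopped)
    return emb, state, log


def run_ablation(ds: STDataset, cfg: TrainConfig,
                 variants: list[str]) -> pd.DataFrame:
    """Fit each ablation variant with a shared seed; score against ds.labels."""
    if ds.labels is None:
        raise ValueError("ablation study needs ground-truth labels")
    rows = []
    for variant in variants:
        if variant not in ABLATIONS:
            raise ValueError(f"unknown ablation variant {variant!r}")
        _, state, _ = fit(ds, replace(cfg, ablation=variant))
        rows.append({"variant": variant,
                     "ari": ari(state.labels, ds.labels),
                     "nmi": nmi(state.labels, ds.labels)})
    return pd.DataFrame(rows)
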