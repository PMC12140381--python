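"""Construction of the two spot graphs and their normalized operators.

Two complementary views of a tissue section are used downstream: a
*spatial* graph connecting spots whose Euclidean distance is strictly
below a radius ``r`` (default 700, in the coordinate units of the input,
e.g. Visium pixels), and a *feature* graph connecting each spot to its
``k`` most cosine-similar spots in expression space (default k=20),
symmetrized by union.  Graph convolutions consume the symmetric
normalization D̃^{-1/2} Ã D̃^{-1/2} with self-loops Ã = A + I.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np
import scipy.sparse as sp
from scipy.spatial import cKDTree

__all__ = ["ViewGraph", "build_spatial_graph", "build_feature_graph",
           "normalize_adjacency"]


@dataclass
class ViewGraph:
    """A 0/1 symmetric spot adjacency for one view, plus its normalized form."""

    adj: sp.csr_matrix
    kind: str                      # "spatial" | "feature"
    params: dict
    norm_adj: Optional[sp.csr_matrix] = None
    norm_with_self_loops: bool = True

    @property
    def n_spots(self) -> int:
        return self.adj.shape[0]

    def to_edge_list(self, path: str) -> None:
        """Write edges as TSV (i, j, weight) for inspection."""
        coo = sp.coo_matrix(sp.triu(self.adj, k=1))
        with open(path, "w") as fh:
            fh.write("i\tj\tweight\n")
            for i, j, w in zip(coo.row, coo.col, coo.data):
                fh.write(f"{i}\t{j}\t{w:g}\n")


def build_spatial_graph(coords: np.ndarray, r: float = 700.0) -> ViewGraph:
    """Radius graph: spots i, j adjacent iff ||coords_i - coords_j|| < r.

    The inequality is strict; a pair at distance exactly ``r`` is not
    connected.  Self-edges are never created.
    """
    if r <= 0:
        raise ValueError(f"radius must be positive, got {r}")
    coords = np.asarray(coords, dtype=float)
    if coords.ndim != 2 or coords.shape[1] != 2:
        raise ValueError(f"coords must be (N, 2), got {coords.shape}")
    if not np.all(np.isfinite(coords)):
        raise ValueError("coordinates contain non-finite values")
    n = coords.shape[0]
    tree = cKDTree(coords)
    pairs = tree.query_pairs(r, output_type="ndarray")  # strict: d < r
    if len(pairs):
        # query_pairs uses d <= r; drop pairs at exactly r
        d = np.linalg.norm(coords[pairs[:, 0]] - coords[pairs[:, 1]], axis=1)
        pairs = pairs[d < r]
    if len(pairs):
        rows = np.concatenate([pairs[:, 0], pairs[:, 1]])
        cols = np.concatenate([pairs[:, 1], pairs[:, 0]])
        adj = sp.csr_matrix((np.ones(len(rows)), (rows, cols)), shape=(n, n))
    else:
        adj = sp.csr_matrix((n, n))
    g = ViewGraph(adj=adj, kind="spatial", params={"r": float(r)})
    return normalize_adjacency(g, add_self_loops=True)


def build_feature_graph(expr, k: int = 20, symmetrize: str = "union") -> ViewGraph:
    """kNN graph on cosine similarity of expression profiles.

    Each spot is linked to the ``k`` other spots with the highest cosine
    similarity; ties resolve to the lower spot index.  The directed kNN
    relation is then symmetrized (``union`` by default, ``mutual``
    optionally).  All-zero rows have similarity 0 against everything and
    receive neighbors purely by tie-break, with a warning.
    """
    x = np.asarray(expr.todense()) if sp.issparse(expr) else np.asarray(expr, dtype=float)
    n = x.shape[0]
    if k <= 0 or k >= n:
        raise ValueError(f"k must be in (0, N); got k={k}, N={n}")
    if symmetrize not in ("union", "mutual"):
        raise ValueError(f"unknown symmetrization {symmetrize!r}")
    norms = np.linalg.norm(x, axis=1)
    zero_rows = norms == 0
    if zero_rows.any():
        warnings.warn(f"{int(zero_rows.sum())} all-zero expression rows; "
                      "their cosine similarity is defined as 0")
    safe = np.where(zero_rows, 1.0, norms)
    xn = x / safe[:, None]
    sim = xn @ xn.T
    sim[zero_rows, :] = 0.0
    sim[:, zero_rows] = 0.0
    np.fill_diagonal(sim, -np.inf)
    # stable sort on (-sim, index): lower index wins on ties
    order = np.argsort(-sim, axis=1, kind="stable")
    nbrs = order[:, :k]
    rows = np.repeat(np.arange(n), k)
    cols = nbrs.ravel()
    directed = sp.csr_matrix((np.ones(n * k), (rows, cols)), shape=(n, n))
    directed.data[:] = 1.0
    if symmetrize == "union":
        adj = directed.maximum(directed.T)
    else:
        adj = directed.minimum(directed.T)
    adj.setdiag(0)
    adj.eliminate_zeros()
    g = ViewGraph(adj=sp.csr_matrix(adj), kind="feature",
                  params={"k": int(k), "symmetrize": symmetrize})
    return normalize_adjacency(g, add_self_loops=True)


def normalize_adjacency(g: ViewGraph, add_self_loops: bool = True) -> ViewGraph:
    """Symmetric normalization D^{-1/2} A D^{-1/2}, on Ã = A + I if requested.

    Isolated nodes: with self-loops their row reduces to the identity row;
    without self-loops their degree is zero and the row stays all-zero
    (never NaN).
    """
    a = sp.csr_matrix(g.adj, dtype=float)
    if add_self_loops:
        a = a + sp.identity(a.shape[0], format="csr")
    deg = np.asarray(a.sum(axis=1)).ravel()
    with np.errstate(divide="ignore"):
        dinv = 1.0 / np.sqrt(deg)
    dinv[~np.isfinite(dinv)] = 0.0
    d = sp.diags(dinv)
    g.norm_adj = sp.csr_matrix(d @ a @ d)
    g.norm_with_self_loops = add_self_loops
    return g
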