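"""Evaluation metrics: ARI, NMI and Moran's I.

ARI and NMI compare a predicted spot partition against an annotated one;
both are computed from the contingency table / entropies directly so the
formulas are explicit (scikit-learn's implementations serve as an
independent cross-check in the test suite).  Moran's I quantifies the
spatial autocorrelation of a single gene's expression over a spot graph.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.special import comb

from .data import STDataset
from .graphs import ViewGraph

__all__ = ["ari", "nmi", "morans_i", "morans_i_per_gene", "SpatialWeights"]


class SpatialWeights:
    """Non-negative spatial weights with zero diagonal."""

    def __init__(self, w, row_standardize: bool = False):
        w = sp.csr_matrix(w, dtype=float)
        if w.shape[0] != w.shape[1]:
            raise ValueError("weights must be square")
        w = w.tolil()
        w.setdiag(0)
        w = sp.csr_matrix(w)
        if w.data.size and w.data.min() < 0:
            raise ValueError("weights must be non-negative")
        if row_standardize:
            rs = np.asarray(w.sum(axis=1)).ravel()
            rs[rs == 0] = 1.0
            w = sp.diags(1.0 / rs) @ w
        self.w = sp.csr_matrix(w)
        self.W_total = float(self.w.sum())
        if self.W_total <= 0:
            raise ValueError("total weight must be positive")


def _contingency(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    _, ai = np.unique(a, return_inverse=True)
    _, bi = np.unique(b, return_inverse=True)
    n = np.zeros((ai.max() + 1, bi.max() + 1), dtype=np.int64)
    np.add.at(n, (ai, bi), 1)
    return n


def ari(predicted, truth) -> float:
    """Adjusted Rand index from the contingency table.

    ARI = [Σ_ij C(n_ij,2) − Σ_i C(a_i,2) Σ_j C(b_j,2)/C(n,2)]
          / [½(Σ_i C(a_i,2) + Σ_j C(b_j,2)) − Σ_i C(a_i,2) Σ_j C(b_j,2)/C(n,2)]
    """
    p = np.asarray(predicted)
    t = np.asarray(truth)
    if p.shape != t.shape:
        raise ValueError(f"partition lengths differ: {p.shape} vs {t.shape}")
    n = p.size
    if n < 2:
        raise ValueError("need at least two samples")
    ct = _contingency(p, t)
    sum_ij = comb(ct, 2).sum()
    a = comb(ct.sum(axis=1), 2).sum()
    b = comb(ct.sum(axis=0), 2).sum()
    expected = a * b / comb(n, 2)
    max_index = 0.5 * (a + b)
    if max_index == expected:  # both partitions trivial
        return 1.0
    return float((sum_ij - expected) / (max_index - expected))


def _entropy(labels: np.ndarray) -> float:
    _, counts = np.unique(labels, return_counts=True)
    p = counts / counts.sum()
    return float(-(p * np.log(p)).sum())


def nmi(predicted, truth) -> float:
    """Normalized mutual information, arithmetic-mean normalization:
    NMI = 2·[H(Y) − H(Y|C)] / [H(Y) + H(C)].

    When both partitions are single-cluster the agreement is total and the
    value is defined as 1.0 (with a warning).
    """
    p = np.asarray(predicted)
    t = np.asarray(truth)
    if p.shape != t.shape:
        raise ValueError(f"partition lengths differ: {p.shape} vs {t.shape}")
    hy, hc = _entropy(t), _entropy(p)
    if hy == 0 and hc == 0:
        import warnings
        warnings.warn("both partitions have a single cluster; NMI defined as 1.0")
        return 1.0
    ct = _contingency(p, t).astype(float)
    n = ct.sum()
    pij = ct / n
    pi = pij.sum(axis=1, keepdims=True)
    pj = pij.sum(axis=0, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        mi = np.where(pij > 0, pij * np.log(pij / (pi * pj)), 0.0).sum()
    return float(2.0 * mi / (hy + hc))


def morans_i(x, sw: "SpatialWeights | sp.spmatrix | np.ndarray") -> float:
    """Moran's I = (N/W) · Σ_ij w_ij (x_i−x̄)(x_j−x̄) / Σ_i (x_i−x̄)².

    Positive values mean spatially clustered expression, negative values
    dispersed expression.  Undefined (raises) for a constant vector.
    """
    if not isinstance(sw, SpatialWeights):
        sw = SpatialWeights(sw)
    x = np.asarray(x, dtype=float).ravel()
    n = x.size
    if sw.w.shape[0] != n:
        raise ValueError(f"weights are {sw.w.shape} but x has {n} values")
    xc = x - x.mean()
    denom = float(xc @ xc)
    if denom == 0:
        raise ValueError("Moran's I undefined: zero variance in x")
    num = float(xc @ (sw.w @ xc))
    return (n / sw.W_total) * num / denom


def morans_i_per_gene(ds: STDataset, graph: ViewGraph,
                      row_standardize: bool = False) -> pd.DataFrame:
    """Moran's I for every gene over a spatial graph.

    Constant genes have an undefined statistic and are reported as NaN.
    Returns a DataFrame with columns (gene_id, morans_i), sorted by the
    statistic descending.
    """
    if graph.kind != "spatial":
        raise ValueError("Moran's I requires the spatial view graph")
    sw = SpatialWeights(graph.adj, row_standardize=row_standardize)
    x = ds.expr_dense().astype(float)
    xc = x - x.mean(axis=0, keepdims=True)
    denom = (xc * xc).sum(axis=0)
    num = (xc * (sw.w @ xc)).sum(axis=0)
    n = ds.n_spots
    with np.errstate(divide="ignore", invalid="ignore"):
        vals = np.where(denom > 0, (n / sw.W_total) * num / np.maximum(denom, 1e-300),
                        np.nan)
    out = pd.DataFrame({"gene_id": ds.gene_ids, "morans_i": vals})
    return out.sort_values("morans_i", ascending=False, ignore_index=True)
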