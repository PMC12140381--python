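"""Dataset container, readers/writers and preprocessing.

A spatial transcriptomics section is represented as an :class:`STDataset`:
a spot-by-gene count matrix, per-spot 2-D coordinates in platform units,
and optional ground-truth domain labels.  Three on-disk forms are
supported: the community-standard HDF5 annotated matrix (``.h5ad``), the
10x-style MatrixMarket triplet plus a positions table, and a plain dense
TSV for toy data.

Preprocessing follows the usual single-cell recipe — remove out-of-tissue
spots, drop genes seen in fewer than `min_spots_per_gene` spots, log1p,
library-size normalization, and dispersion-ranked highly-variable-gene
selection — with the log transform applied *before* normalization by
default (the order this pipeline was designed around; the conventional
normalize-then-log order is available via ``log_before_norm=False``).
"""

from __future__ import annotations

import os
import warnings
from dataclasses import dataclass, field
from typing import Optional

import anndata as ad
import numpy as np
import pandas as pd
import scanpy as sc
import scipy.sparse as sp

__all__ = ["STDataset", "PreprocessReport", "read_dataset", "write_dataset", "preprocess"]

FORMATS = ("h5-annotated", "mtx-triplet", "tsv-dense")


@dataclass
class STDataset:
    """A spot-by-gene expression matrix with spatial coordinates.

    Attributes
    ----------
    expr : (N, G) ndarray or sparse matrix
        Raw counts or transformed values, never negative.
    coords : (N, 2) ndarray
        Spot coordinates in the platform's units (e.g. Visium pixels).
    spot_ids, gene_ids : lists of unique strings.
    labels : optional (N,) integer domain labels.
    in_tissue : optional (N,) boolean mask.
    """

    expr: "np.ndarray | sp.spmatrix"
    coords: np.ndarray
    spot_ids: list = field(default_factory=list)
    gene_ids: list = field(default_factory=list)
    labels: Optional[np.ndarray] = None
    in_tissue: Optional[np.ndarray] = None

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float)
        n, g = self.expr.shape
        if self.coords.shape != (n, 2):
            raise ValueError(
                f"expr has {n} spots but coords has shape {self.coords.shape}")
        if not self.spot_ids:
            self.spot_ids = [f"spot_{i}" for i in range(n)]
        if not self.gene_ids:
            self.gene_ids = [f"gene_{j}" for j in range(g)]
        if len(self.spot_ids) != n:
            raise ValueError(f"{len(self.spot_ids)} spot ids for {n} spots")
        if len(self.gene_ids) != g:
            raise ValueError(f"{len(self.gene_ids)} gene ids for {g} genes")
        if len(set(self.spot_ids)) != n:
            raise ValueError("duplicate spot ids")
        if len(set(self.gene_ids)) != g:
            raise ValueError("duplicate gene ids")
        if self.labels is not None:
            self.labels = np.asarray(self.labels, dtype=int)
            if self.labels.shape != (n,):
                raise ValueError("labels length mismatch")
        if self.in_tissue is not None:
            self.in_tissue = np.asarray(self.in_tissue, dtype=bool)
            if self.in_tissue.shape != (n,):
                raise ValueError("in_tissue length mismatch")

    @property
    def n_spots(self) -> int:
        return self.expr.shape[0]

    @property
    def n_genes(self) -> int:
        return self.expr.shape[1]

    def expr_dense(self) -> np.ndarray:
        x = self.expr
        return np.asarray(x.todense()) if sp.issparse(x) else np.asarray(x)

    def validate_finite(self):
        x = self.expr.data if sp.issparse(self.expr) else np.asarray(self.expr)
        if not np.all(np.isfinite(x)):
            raise ValueError("expression matrix contains non-finite values")
        if x.size and x.min() < 0:
            raise ValueError("expression matrix contains negative values")

    def subset(self, spot_mask=None, gene_mask=None) -> "STDataset":
        sm = np.ones(self.n_spots, bool) if spot_mask is None else np.asarray(spot_mask)
        gm = np.ones(self.n_genes, bool) if gene_mask is None else np.asarray(gene_mask)
        expr = self.expr[sm][:, gm]
        return STDataset(
            expr=expr,
            coords=self.coords[sm],
            spot_ids=[s for s, keep in zip(self.spot_ids, sm) if keep],
            gene_ids=[g for g, keep in zip(self.gene_ids, gm) if keep],
            labels=None if self.labels is None else self.labels[sm],
            in_tissue=None if self.in_tissue is None else self.in_tissue[sm],
        )

    def to_anndata(self) -> ad.AnnData:
        adata = ad.AnnData(
            X=self.expr.copy() if sp.issparse(self.expr) else np.asarray(self.expr).copy(),
            obs=pd.DataFrame(index=pd.Index(self.spot_ids, name="spot_id")),
            var=pd.DataFrame(index=pd.Index(self.gene_ids, name="gene_id")),
        )
        adata.obsm["spatial"] = self.coords.copy()
        if self.labels is not None:
            adata.obs["domain"] = self.labels
        if self.in_tissue is not None:
            adata.obs["in_tissue"] = self.in_tissue
        return adata

    @classmethod
    def from_anndata(cls, adata: ad.AnnData) -> "STDataset":
        if "spatial" not in adata.obsm:
            raise ValueError("AnnData lacks obsm['spatial'] coordinates")
        return cls(
            expr=adata.X.copy() if sp.issparse(adata.X) else np.asarray(adata.X).copy(),
            coords=np.asarray(adata.obsm["spatial"], dtype=float),
            spot_ids=list(map(str, adata.obs_names)),
            gene_ids=list(map(str, adata.var_names)),
            labels=(np.asarray(adata.obs["domain"], dtype=int)
                    if "domain" in adata.obs else None),
            in_tissue=(np.asarray(adata.obs["in_tissue"], dtype=bool)
                       if "in_tissue" in adata.obs else None),
        )


@dataclass
class PreprocessReport:
    n_spots_removed: int = 0
    n_genes_removed: int = 0
    n_hvg_kept: int = 0
    steps_applied: list = field(default_factory=list)


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def read_dataset(path: str, format: str) -> STDataset:
    """Read a dataset from one of the supported on-disk layouts.

    ``h5-annotated``: a single ``.h5ad`` file.
    ``mtx-triplet``: a directory with ``matrix.mtx`` (spots x genes or the 10x
    genes x spots orientation), ``features.tsv``, ``barcodes.tsv`` and
    ``positions.csv`` (barcode, in_tissue, array_row, array_col, pxl_row,
    pxl_col); coordinates are taken from the pixel columns.
    ``tsv-dense``: ``<path>.expr.tsv`` (spots x genes, with ids) and
    ``<path>.coords.tsv`` (spot_id, x, y[, label]).
    """
    if format not in FORMATS:
        raise ValueError(f"unknown format {format!r}; expected one of {FORMATS}")
    if format == "h5-annotated":
        return STDataset.from_anndata(ad.read_h5ad(path))
    if format == "mtx-triplet":
        return _read_mtx_triplet(path)
    return _read_tsv_dense(path)


def _read_mtx_triplet(path: str) -> STDataset:
    import scipy.io as sio

    mtx = sp.csr_matrix(sio.mmread(os.path.join(path, "matrix.mtx")))
    features = pd.read_csv(os.path.join(path, "features.tsv"),
                           sep="\t", header=None)
    barcodes = pd.read_csv(os.path.join(path, "barcodes.tsv"),
                           sep="\t", header=None)
    gene_ids = features.iloc[:, 0].astype(str).tolist()
    spot_ids = barcodes.iloc[:, 0].astype(str).tolist()
    if mtx.shape == (len(gene_ids), len(spot_ids)) and mtx.shape[0] != mtx.shape[1]:
        mtx = mtx.T.tocsr()  # 10x stores genes x barcodes
    if mtx.shape != (len(spot_ids), len(gene_ids)):
        raise ValueError(
            f"matrix shape {mtx.shape} does not match "
            f"{len(spot_ids)} barcodes x {len(gene_ids)} features")
    pos = pd.read_csv(os.path.join(path, "positions.csv"), header=None,
                      names=["barcode", "in_tissue", "array_row", "array_col",
                             "pxl_row", "pxl_col"])
    pos = pos.set_index(pos["barcode"].astype(str))
    missing = [b for b in spot_ids if b not in pos.index]
    if missing:
        raise ValueError(f"no coordinates for barcode {missing[0]!r}"
                         + (f" (+{len(missing) - 1} more)" if len(missing) > 1 else ""))
    pos = pos.loc[spot_ids]
    coords = pos[["pxl_col", "pxl_row"]].to_numpy(dtype=float)
    return STDataset(expr=mtx, coords=coords, spot_ids=spot_ids, gene_ids=gene_ids,
                     in_tissue=pos["in_tissue"].to_numpy(dtype=bool))


def _read_tsv_dense(path: str) -> STDataset:
    expr_df = pd.read_csv(path + ".expr.tsv", sep="\t", index_col=0)
    coord_df = pd.read_csv(path + ".coords.tsv", sep="\t", index_col=0)
    coord_df.index = coord_df.index.astype(str)
    expr_df.index = expr_df.index.astype(str)
    missing = [s for s in expr_df.index if s not in coord_df.index]
    if missing:
        raise ValueError(f"no coordinates for spot id {missing[0]!r}")
    coord_df = coord_df.loc[expr_df.index]
    labels = (coord_df["label"].to_numpy(dtype=int)
              if "label" in coord_df.columns else None)
    return STDataset(
        expr=expr_df.to_numpy(dtype=float),
        coords=coord_df[["x", "y"]].to_numpy(dtype=float),
        spot_ids=list(expr_df.index),
        gene_ids=list(map(str, expr_df.columns)),
        labels=labels,
    )


def write_dataset(ds: STDataset, path: str, format: str) -> None:
    """Write a dataset so that :func:`read_dataset` recovers it losslessly."""
    if format not in FORMATS:
        raise ValueError(f"unknown format {format!r}; expected one of {FORMATS}")
    ds.validate_finite()
    if format == "h5-annotated":
        ds.to_anndata().write_h5ad(path)
        return
    if format == "mtx-triplet":
        _write_mtx_triplet(ds, path)
        return
    _write_tsv_dense(ds, path)


def _write_mtx_triplet(ds: STDataset, path: str) -> None:
    import scipy.io as sio

    os.makedirs(path, exist_ok=True)
    mtx = sp.coo_matrix(ds.expr)
    sio.mmwrite(os.path.join(path, "matrix.mtx"), mtx)
    pd.DataFrame({0: ds.gene_ids}).to_csv(
        os.path.join(path, "features.tsv"), sep="\t", header=False, index=False)
    pd.DataFrame({0: ds.spot_ids}).to_csv(
        os.path.join(path, "barcodes.tsv"), sep="\t", header=False, index=False)
    in_tissue = (ds.in_tissue if ds.in_tissue is not None
                 else np.ones(ds.n_spots, dtype=bool))
    pos = pd.DataFrame({
        "barcode": ds.spot_ids,
        "in_tissue": in_tissue.astype(int),
        "array_row": np.zeros(ds.n_spots, dtype=int),
        "array_col": np.zeros(ds.n_spots, dtype=int),
        "pxl_row": ds.coords[:, 1],
        "pxl_col": ds.coords[:, 0],
    })
    pos.to_csv(os.path.join(path, "positions.csv"), header=False, index=False)


def _write_tsv_dense(ds: STDataset, path: str) -> None:
    expr = pd.DataFrame(ds.expr_dense(), index=ds.spot_ids, columns=ds.gene_ids)
    expr.to_csv(path + ".expr.tsv", sep="\t")
    coord = pd.DataFrame({"x": ds.coords[:, 0], "y": ds.coords[:, 1]},
                         index=pd.Index(ds.spot_ids, name="spot_id"))
    if ds.labels is not None:
        coord["label"] = ds.labels
    coord.to_csv(path + ".coords.tsv", sep="\t")


# ---------------------------------------------------------------------------
# preprocessing
# ---------------------------------------------------------------------------

def preprocess(
    ds: STDataset,
    min_spots_per_gene: int = 3,
    n_hvg: int = 3000,
    do_log: bool = True,
    do_libsize_norm: bool = True,
    log_before_norm: bool = True,
    target_sum: float = 1e4,
) -> tuple[STDataset, PreprocessReport]:
    """Filter, transform and select highly variable genes.

    Steps, in order: drop out-of-tissue spots; drop genes expressed in fewer
    than `min_spots_per_gene` spots; log1p transform; library-size
    normalization to `target_sum` counts per spot (swap the last two with
    ``log_before_norm=False``); keep the `n_hvg` genes with the highest
    Seurat-style normalized dispersion, ties at the cutoff broken by gene id.
    """
    ds.validate_finite()
    report = PreprocessReport()
    n0, g0 = ds.n_spots, ds.n_genes

    if ds.in_tissue is not None:
        ds = ds.subset(spot_mask=ds.in_tissue)
        report.steps_applied.append("filter_spots_in_tissue")
    report.n_spots_removed = n0 - ds.n_spots

    x = ds.expr
    n_expressed = np.asarray((x > 0).sum(axis=0)).ravel()
    gene_mask = n_expressed >= min_spots_per_gene
    if not gene_mask.any():
        raise ValueError("all genes removed by the expression filter")
    ds = ds.subset(gene_mask=gene_mask)
    report.n_genes_removed = g0 - ds.n_genes
    report.steps_applied.append("filter_genes_min_spots")

    adata = ds.to_anndata()
    if sp.issparse(adata.X):
        adata.X = adata.X.astype(np.float64)
    else:
        adata.X = np.asarray(adata.X, dtype=np.float64)

    def _log():
        sc.pp.log1p(adata)
        report.steps_applied.append("log1p")

    def _norm():
        sc.pp.normalize_total(adata, target_sum=target_sum)
        report.steps_applied.append("libsize_normalize")

    if log_before_norm:
        if do_log:
            _log()
        if do_libsize_norm:
            _norm()
    else:
        if do_libsize_norm:
            _norm()
        if do_log:
            _log()

    n_keep = min(n_hvg, adata.n_vars)
    if n_hvg >= adata.n_vars:
        warnings.warn(
            f"requested {n_hvg} highly variable genes but only "
            f"{adata.n_vars} genes remain; keeping all")
        hvg_mask = np.ones(adata.n_vars, dtype=bool)
    else:
        disp = _normalized_dispersion(
            adata.X.toarray() if sp.issparse(adata.X) else np.asarray(adata.X))
        # rank by (-dispersion, gene_id) so cutoff ties resolve lexicographically
        order = sorted(range(adata.n_vars),
                       key=lambda j: (-disp[j], str(adata.var_names[j])))
        hvg_mask = np.zeros(adata.n_vars, dtype=bool)
        hvg_mask[order[:n_keep]] = True
    report.steps_applied.append("select_hvg")
    report.n_hvg_kept = int(hvg_mask.sum())

    out = STDataset.from_anndata(adata)
    out = out.subset(gene_mask=hvg_mask)
    out.validate_finite()
    return out, report


def _normalized_dispersion(x: np.ndarray, n_bins: int = 20) -> np.ndarray:
    """Seurat-flavor normalized dispersion: dispersion z-scored within mean bins."""
    mean = x.mean(axis=0)
    var = x.var(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        disp = np.where(mean > 0, var / np.maximum(mean, 1e-12), 0.0)
    if np.unique(mean).size < 2:
        return disp
    bins = np.quantile(mean, np.linspace(0, 1, n_bins + 1))
    bins = np.unique(bins)
    idx = np.clip(np.digitize(mean, bins[1:-1]), 0, len(bins) - 2)
    out = np.zeros_like(disp)
    for b in np.unique(idx):
        sel = idx == b
        mu, sd = disp[sel].mean(), disp[sel].std()
        out[sel] = (disp[sel] - mu) / sd if sd > 0 else 0.0
    return out
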