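"""Synthetic layered-tissue sections with known domain structure.

The generator emulates the geometry and count statistics of laminar
cortical sections: spots on a regular grid, domains as horizontal bands
(or rectangular blocks), each domain carrying a private program of marker
genes whose log-mean is shifted by `effect_size`, and counts drawn from a
gamma-Poisson (negative binomial) to reproduce UMI overdispersion.  The
``shuffled`` layout draws expression and labels exactly as ``laminar``
does and then permutes the coordinates across spots, so the
expression-label joint distribution is identical and only the spatial
coherence is destroyed — the construction that makes spatial-view vs
feature-view ablation comparisons well-posed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .data import STDataset

__all__ = ["SimSpec", "simulate", "plant_svg"]

LAYOUTS = ("laminar", "blocks", "shuffled")


@dataclass
class SimSpec:
    """Parameters of a synthetic section.

    Defaults give a 40x50 grid (2000 spots), six laminar domains, 200
    genes with 10 markers per domain shifted by 1.5 on the log scale,
    negative-binomial dispersion 0.3, and 100-unit spot spacing (so the
    default spatial radius of 700 spans a ~7-spot neighborhood).
    """

    n_rows: int = 40
    n_cols: int = 50
    layout: str = "laminar"
    C: int = 6
    G: int = 200
    n_program_genes: int = 10
    effect_size: float = 1.5
    dispersion: float = 0.3
    libsize_range: tuple = (0.7, 1.3)
    spacing: float = 100.0
    seed: int = 0

    def validate(self):
        if self.layout not in LAYOUTS:
            raise ValueError(f"unknown layout {self.layout!r}")
        if self.C < 2:
            raise ValueError("need at least two domains")
        if self.n_program_genes * self.C > self.G:
            raise ValueError("marker programs exceed the gene count")
        if self.effect_size <= 0:
            raise ValueError("effect size must be positive")
        if self.dispersion < 0:
            raise ValueError("dispersion must be non-negative")
        lo, hi = self.libsize_range
        if not (0 < lo <= hi):
            raise ValueError("invalid library-size range")


def _domain_of_spot(spec: SimSpec, rows: np.ndarray, cols: np.ndarray) -> np.ndarray:
    if spec.layout in ("laminar", "shuffled"):
        # C horizontal bands of (nearly) equal height
        edges = np.linspace(0, spec.n_rows, spec.C + 1)
        return np.clip(np.searchsorted(edges, rows, side="right") - 1, 0, spec.C - 1)
    # blocks: tile the grid with ceil(sqrt(C)) columns of tiles
    t_cols = int(np.ceil(np.sqrt(spec.C)))
    t_rows = int(np.ceil(spec.C / t_cols))
    re = np.linspace(0, spec.n_rows, t_rows + 1)
    ce = np.linspace(0, spec.n_cols, t_cols + 1)
    ri = np.clip(np.searchsorted(re, rows, side="right") - 1, 0, t_rows - 1)
    ci = np.clip(np.searchsorted(ce, cols, side="right") - 1, 0, t_cols - 1)
    return np.minimum(ri * t_cols + ci, spec.C - 1)


def _nb_counts(rng: np.random.Generator, mean: np.ndarray,
               dispersion: float) -> np.ndarray:
    """Gamma-Poisson draw with Var = m + dispersion·m²  (Poisson at 0)."""
    if dispersion == 0:
        return rng.poisson(mean)
    shape = 1.0 / dispersion
    lam = rng.gamma(shape, mean / shape)
    return rng.poisson(lam)


def simulate(spec: SimSpec) -> STDataset:
    """Generate one section with planted domain labels."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    rows, cols = np.meshgrid(np.arange(spec.n_rows), np.arange(spec.n_cols),
                             indexing="ij")
    rows, cols = rows.ravel(), cols.ravel()
    n = rows.size
    coords = np.column_stack([cols * spec.spacing, rows * spec.spacing]).astype(float)
    labels = _domain_of_spot(spec, rows, cols)

    # baseline gene abundances: lognormal, as in UMI data
    base = rng.lognormal(mean=0.0, sigma=0.5, size=spec.G)
    logmean = np.log(np.tile(base, (spec.C, 1)))  # (C, G) per-domain log-means
    marker_of = np.full(spec.G, -1)
    perm = rng.permutation(spec.G)
    for c in range(spec.C):
        genes = perm[c * spec.n_program_genes:(c + 1) * spec.n_program_genes]
        logmean[c, genes] += spec.effect_size
        marker_of[genes] = c

    lib = rng.uniform(*spec.libsize_range, size=n)
    mean = lib[:, None] * np.exp(logmean[labels])
    expr = _nb_counts(rng, mean, spec.dispersion).astype(np.int64)

    if spec.layout == "shuffled":
        # identical expression/label draw; only the coordinate assignment moves
        coords = coords[rng.permutation(n)]

    return STDataset(
        expr=expr,
        coords=coords,
        spot_ids=[f"spot_{r}_{c}" for r, c in zip(rows, cols)],
        gene_ids=[f"gene_{j:04d}" for j in range(spec.G)],
        labels=labels,
    )


def plant_svg(ds: STDataset, pattern: str = "band", amplitude: float = 2.0,
              dispersion: float = 0.3, seed: int = 0) -> STDataset:
    """Append one gene whose mean follows a smooth spatial pattern.

    ``band``: log-mean varies sinusoidally along the y axis; ``hotspot``:
    a Gaussian bump at the section center.  ``amplitude`` scales the
    log-mean modulation; 0 gives a spatially unstructured control gene.
    """
    if pattern not in ("band", "hotspot"):
        raise ValueError(f"unknown pattern {pattern!r}")
    rng = np.random.default_rng(seed)
    xy = ds.coords
    span = np.maximum(xy.max(axis=0) - xy.min(axis=0), 1e-9)
    u = (xy - xy.min(axis=0)) / span  # normalized to [0, 1]^2
    if pattern == "band":
        profile = np.sin(2.0 * np.pi * u[:, 1])
    else:
        profile = np.exp(-(((u - 0.5) ** 2).sum(axis=1)) / (2 * 0.15 ** 2))
    mean = np.exp(np.log(5.0) + amplitude * profile)
    gene = _nb_counts(rng, mean, dispersion).astype(np.int64)

    import scipy.sparse as sp
    if sp.issparse(ds.expr):
        expr = sp.hstack([sp.csr_matrix(ds.expr), sp.csr_matrix(gene[:, None])])
        expr = sp.csr_matrix(expr)
    else:
        expr = np.column_stack([np.asarray(ds.expr), gene])
    return STDataset(
        expr=expr,
        coords=ds.coords.copy(),
        spot_ids=list(ds.spot_ids),
        gene_ids=list(ds.gene_ids) + ["planted_svg"],
        labels=None if ds.labels is None else ds.labels.copy(),
        in_tissue=None if ds.in_tissue is None else ds.in_tissue.copy(),
    )
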