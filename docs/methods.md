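# Methods

## Problem and model

Spatial transcriptomics assays measure a gene-expression profile at each
of N capture spots together with the spot's 2-D position on the tissue
section. The analysis goal addressed here is *spatial-domain
identification*: partitioning the spots into C regions that are coherent
both in expression and in space (cortical layers, tumor compartments,
olfactory-bulb laminae, ...).

The model combines four ingredients:

**Two graph views.** A *spatial* graph connects spots whose Euclidean
distance is strictly below a radius r (default 700, in the coordinate
units of the platform, e.g. Visium pixels), and a *feature* graph
connects each spot to its k = 20 most cosine-similar spots in expression
space, symmetrized by union. Both are consumed through the symmetric
normalization D̃^{-1/2}(A + I)D̃^{-1/2}.

**Per-view GCN encoders.** Each view has a single-layer graph
convolutional encoder Z^(i) = ReLU(Â^(i) X W^(i)) producing a d = 64
dimensional embedding per spot.

**Implicit contrastive learning.** Each view also carries a variational
graph autoencoder: a two-layer GCN encoder whose first layer is shared
between a mean branch and a log-variance branch (linear outputs,
log-variance clamped to ±10), giving a Gaussian posterior
N(μ_n, diag(σ_n²)) per spot, and an inner-product decoder σ(a_i·a_j)
reconstructing the adjacency. Its loss is the class-balanced
reconstruction cross-entropy (positive-edge weight (N²−E)/E, overall
scale N²/(2(N²−E))) plus the Gaussian KL to the standard-normal prior
averaged over nodes. M = 5 reparameterized samples per spot act as
*implicit augmentations*: sample a_n^m pairs with anchor z_n as a
positive, the other anchors in a batch of b = 512 are negatives, scored
by a temperature-scaled (τ = 0.5) InfoNCE loss, summed over the two
views. Anchors and augmentations are projected to the unit sphere before
scoring, the standard practice that keeps the temperature's meaning
independent of embedding scale. Because the inner-product pairing
requires conformant dimensions, the VGAE latent size equals the GCN
embedding size (64); `fit` validates this.

**Attention fusion and deep embedded clustering.** A shared vector q
scores each view embedding per spot; a two-way softmax yields
coefficients α_i^(1)+α_i^(2)=1 and the fused embedding is the convex
combination. q is initialized at zero so training starts from uniform
0.5/0.5 attention. Clustering follows DEC: k-means (k-means++, 20
restarts) initializes centroids on the initial fused embedding; the
Student's-t kernel gives soft assignments Q; the sharpened target
P ∝ Q²/column-mass is refreshed every T = 50 iterations and held
constant (no gradient) in between; the clustering loss is KL(P‖Q),
differentiated with respect to embeddings and centroids.

## Training schedule

Per iteration: (1) each view's VGAE takes one Adam step on its own loss;
(2) the backbone (GCN weights, attention vector, centroids) takes one
Adam step on α·KL(P‖Q) + β·(L_CL^(1)+L_CL^(2)), with the augmentations
treated as constants — the two parameter groups never exchange
gradients. All optimizers are Adam(lr = 0.003, weight decay = 0.001).
At every T-th iteration the hard labels are compared with those of the
previous checkpoint and training stops when the changed fraction falls
below δ = 0.001; the iteration-0 checkpoint only initializes the
reference labels, so the first possible stop is at iteration T. With
`max_iter = 0` the output is exactly the k-means initialization.

Defaults α = β = 1, MaxIter = 1000. With β = 0 the trainer reduces to
DEC on fused embeddings; with α = 0 labels come from the centroids'
initialization applied to contrastively trained embeddings; both
degenerate modes are supported and tested.

## Preprocessing

Out-of-tissue spots are removed, genes expressed in fewer than 3 spots
are dropped, a log1p transform is applied and then library-size
normalization to 10⁴ per spot — this log-before-normalize order is the
pipeline's default, with `log_before_norm=False` giving the conventional
order — and the top 3000 genes by Seurat-style binned normalized
dispersion are retained (ties at the cutoff broken by gene id). The
trainer additionally standardizes each gene column of the encoder input
to zero mean and unit variance; the feature graph is built on the
non-centered preprocessed matrix, where cosine similarity of count-like
profiles is meaningful.

## Numerical engine

Gradients are computed by a small reverse-mode autodiff module over
numpy arrays (`stgcl.autodiff`) providing exactly the operators the
losses need. Backward closures never reference their own output (no
reference cycles) and intermediate gradients are freed eagerly, keeping
the peak memory of the N×N decoder loss near its forward cost. The
decoder's class-weighted cross-entropy is a single fused operator with a
closed-form gradient. All operator gradients are validated against
central finite differences in the test suite.

Numerical choices: log-variance clamped to [−10, 10]; softplus evaluated
as max(x,0)+log1p(e^{−|x|}); InfoNCE stabilized by log-sum-exp; the
Student's-t distance matrix clipped at 0 against round-off; an ε = 10⁻¹²
guards empty-cluster columns in the target distribution (they cannot
occur exactly with t-kernels on finite data); kNN similarity ties break
to the lower spot index; spots at distance exactly r are *not*
neighbors; isolated spots get an identity row under self-loop
normalization and an all-zero row without.

## Synthetic sections

The generator emulates laminar cortical data: spots on a regular grid
(spacing 100 units, so r = 700 spans a ≈7-spot neighborhood), C = 6
horizontal bands by default, G = 200 genes of which 10 per domain are
markers with a +1.5 shift on the log-mean scale, per-spot library-size
factors uniform in [0.7, 1.3], and gamma-Poisson counts with dispersion
0.3 (Var = m + 0.3 m²) reproducing UMI overdispersion. The ``shuffled``
layout draws expression and labels exactly as ``laminar`` does and then
permutes coordinates across spots, so expression-label structure is
preserved while spatial coherence is destroyed — this makes the
view-ablation comparisons well-posed. ``plant_svg`` appends one gene
whose log-mean follows a sinusoidal band or a Gaussian hotspot, for
spatial-autocorrelation checks.

What the generator does *not* emulate: hexagonal Visium geometry,
zero-inflation beyond NB sampling, segmentation errors, spatial
gradients within a domain, batch effects, or histology. Passing the
recovery tests therefore demonstrates correctness of the machinery and
sensible behaviour under idealized laminar structure, not performance on
real tissue.

## Evaluation

ARI is computed from the contingency table with the pair-counting
adjustment; NMI uses arithmetic-mean normalization
2·I(Y;C)/(H(Y)+H(C)); when both partitions are single-cluster NMI is
defined as 1 with a warning. Moran's I uses binary radius-graph
adjacency by default (row-standardized weights optional); constant genes
are undefined and reported as missing.

## Problem sizes used in the checks

The parameter-recovery experiment runs the full pipeline on the default
40×50-spot section (2000 spots, 200 genes) — about two minutes on one
CPU core, stopping well before the iteration cap. The ablation
directionality study uses 24×30-spot sections (720 spots, 120 genes, 4
domains) over five seeds per layout, with weak programs (effect 0.8) on
laminar sections — where spatial structure must carry part of the signal
— and strong programs (effect 1.5) on shuffled sections, where only
expression is informative.

## Known limitations

The dense N×N decoder target makes memory quadratic in the spot count;
sections beyond ~10⁴ spots need subsampled reconstruction, which is not
implemented. The number of domains C should be supplied (the annotated
domain count in evaluations); when absent it is estimated by Leiden
community detection on the expression kNN graph, with a warning — a
heuristic, not a calibrated model-selection rule. Attention can
saturate toward one view on strongly view-asymmetric data; this is
by design (it is what the coefficients report). The α/β loss weights and
the contrastive batch size were not re-tuned per dataset.
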