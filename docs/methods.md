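# Methods

`morphollr` asks whether a conserved allometric pattern — craniofacial
evolutionary allometry (CREA), where larger species carry proportionally
longer faces — behaves as an evolutionary *line of least resistance* (LLR):
a direction in shape space along which both within-species variation and
between-species divergence are channelled. This note documents the models,
the estimators, the synthetic data the package is tested on, and the design
choices made where the design was genuinely open.

## Shape model

Specimens are p × 3 landmark configurations. Generalized Procrustes analysis
(GPA) removes position (translation to a common centroid), scale (unit
centroid size, CS = sqrt of summed squared landmark distances from the
centroid), and orientation (orthogonal Procrustes rotation to an iteratively
updated consensus; reflections are excluded because crania are chiral).
Statistics are computed in the linear tangent space at the consensus. The
tangent basis spans the orthogonal complement of the seven degenerate
directions (3 translations, 3 infinitesimal rotations generated by the skew
matrices applied to the consensus, 1 scaling along the consensus itself), so
k = 3p − 7. GPA iterations stop when the summed squared Procrustes distance
to the consensus changes by less than 1e−10 (max 100 iterations; the result
carries a `converged` flag).

## Phylogenetic regression and the CREA vector

Under Brownian motion (BM) on a rooted tree, species values covary by the
depth of their most recent common ancestor, giving the n × n matrix
C_tree. Multivariate phylogenetic regression of tangent shape Y on log CS is
GLS: B = (XᵀC⁻¹X)⁻¹XᵀC⁻¹Y, computed by Cholesky-whitening (L⁻¹X, L⁻¹Y with
C = LLᵀ) and ordinary least squares. All sums of squares — and hence R² and
F — live in the whitened space, measured about the GLS (phylogenetic) mean.
The **CREA vector x** is the unit-normalized coefficient row of log CS: the
direction of shape change per unit increase in log size.

Significance uses residual randomization (RRPP): whitened residuals of the
reduced model (intercept-only, or the main-effects model for the
subfamily-interaction test) are permuted, added back to the reduced fitted
values, and F is recomputed; P = (1 + #{F_null ≥ F_obs}) / (n_perm + 1), so
the smallest attainable P is 1/(n_perm+1) and P is never zero. The effect
size Z standardizes observed F against the permutation null; by default on
the F scale itself (a log-F option exists — published effect sizes from
permutation frameworks differ in this transform, and the two are reported
distinctly). The slope-heterogeneity test compares the size × subfamily
interaction model to the common-slope model by the nested-model F in the
whitened metric, permuting common-slope residuals.

Zero-length terminal branches are inflated by 1e−8 × tree depth (with a
warning) to keep C_tree invertible; GLS estimates are invariant to overall
branch-length scaling.

## Ordinations

* **PCA** — eigendecomposition of the sample covariance of centered species
  means (via SVD); scores preserve Euclidean distances.
* **pPCA** — covariance estimated in the GLS metric (whitened residuals about
  the GLS mean, which equals the BM root estimate); with `transform=True`
  scores are computed from the whitened residuals so downstream distances
  are phylogenetically independent.
* **PACA** — axes are eigenvectors of Yᵀ C_tree Y (centered data aligned to
  the phylogenetic covariance), ordered by phylogenetic signal explained.

All three collapse to ordinary PCA on a star phylogeny. Axes are oriented so
each vector's largest-magnitude loading is positive (a reproducibility
convention; PCA signs are otherwise arbitrary). Specimens are projected into
a morphospace as (specimen − center) · vectors. Per-family score densities
weight each specimen by 1/(specimens of its species), so heavily sampled
species do not dominate; bandwidth is Silverman's rule on the weighted
sample.

## BM rate matrix and morphospace contours

The evolutionary rate matrix **C** (m × m, default m = 5 leading PCs; more
axes make the matrix-normal fit rank-deficient at these sample sizes) is the
ML estimator C = (Y − 1aᵀ)ᵀ C_tree⁻¹ (Y − 1aᵀ)/n with root state a the GLS
mean (REML divisor n − 1 available; the REML form is the unbiased one and is
what the recovery tests check). A tip at root-to-tip depth t is then
N(a, t·C); its confidence region at level q is the set of points whose
squared Mahalanobis distance is at most the χ²(m′) quantile of q. Contours
are *marginalized* from the fitted m-dimensional C to the two plotted axes
rather than refit in 2-D, and species are flagged inside/outside in that
plotted plane, each at its own depth (for ultrametric trees all depths
coincide).

A caution the package's own simulations make visible: ordination axes are
estimated from the same tip data the rate matrix is fit to, and axes chosen
to maximize cross-sectional variance are conditionally overdispersed
relative to the GLS rate along them. Even data generated by pure BM place
well over 5% of species outside the "95%" contour in the PC1/PC2 plane.
The contours are therefore a visualization of where lineages sit relative
to the BM expectation, not a calibrated test; the calibrated coverage
property (95/99% of matrix-normal draws inside, each tip at its own depth)
is verified separately on fixed axes in the acceptance suite.

## Line-of-least-resistance statistics

For each species with at least `min_n = 27` specimens, **P** is the sample
covariance (divisor n−1) of its specimens' tangent coordinates. The core
statistic is the projected variance

  V_proj = xᵀ P x,

the variance of P in unit direction x (the single-direction evolvability of
P). Raw V_proj and the trace-normalized fraction V_proj/tr(P) are both
reported: the defining equation is the raw form, but the quantity is
interpreted as the *proportion* of within-species variance along x, so the
normalized form feeds the downstream comparisons by default. Its reference
distribution is V_proj over 499 random unit vectors per species (i.i.d.
standard normal coordinates, normalized — the only rotation-invariant
choice), whose analytic mean is tr(P)/k.

Morphological integration is the relative eigenvalue variance
Vrel ∈ [0, 1]: the variance of P's eigenvalues divided by its maximum given
trace and dimension (0 = isotropic, 1 = rank-1; for two equal-variance
traits with correlation r, Vrel = r²). Its effect size Z_rel is the Fisher
z-transform of sqrt(Vrel) scaled by sqrt(n − 3) — the reciprocal Fisher-z
standard error at the species' sample size — so equal eccentricity estimated
from more specimens is a stronger effect. The unscaled atanh(sqrt(Vrel)) is
available where sample-size weighting is unwanted.

Divergence is measured from each species' *subfamily* MRCA (estimated by
the BM conditional expectation given the tips), not its immediate parent
node, whose position would rest on only two descendants in an incompletely
sampled clade. Magnitude D is the Euclidean distance in ordination-score
space; the divergence *direction* is the species-minus-ancestor difference
in full tangent space (both bases are carried and labelled). The angle θ
between divergence and CREA is arccos of the cosine similarity, reported
unfolded in [0°, 180°] (folding to [0°, 90°] is a config flag). Angle
significance compares θ to 10,000 angles between independent random
unit-vector pairs in k dimensions — a null centered at 90° whose spread
shrinks as ~1/sqrt(k); at k = 2 it is uniform on [0°, 180°]. The alignment
test is one-sided (smaller angle = more aligned), +1 convention. The set of
per-species divergence angles is compared to the same null by a two-sample
two-sided Kolmogorov–Smirnov test.

The browser–grazer axis is the unit-normalized coefficient row of a PGLS of
shape on percent grass in diet over the species with diet data; its angle
to CREA goes through the same random-angle test, and a second-degree
polynomial surface (basis {1, u, v, u², uv, v²}) of percent grass over the
PC1/PC2 scores is fit by least squares with a permutation P on R².

## Synthetic studies and what they do (not) show

The generator produces a pure-birth tree rescaled to unit depth; a final
pendant extension floored at 2% of depth keeps the youngest divergence at
species-level separation (an analysis of museum species samples does not
contain subspecies-age splits, and GLS contrasts across near-zero branches
would otherwise be dominated by species-mean estimation error). Species
means evolve by matrix-normal BM with a rate matrix carrying a fraction
(default 0.35) of its total rate (default trace 0.01) along a designated
"face elongation" basis vector; log CS is the species' projection on that
direction divided by the allometric slope (default 0.15) plus independent
BM noise (sd 0.15 per unit depth); percent grass is a logistic readout of
standardized size (coupling 2.0) with unit noise, missing for a quarter of
species. Specimens add draws from a per-species P (trace 0.01, leading
eigenvalue fraction 0.2, leading axis at a uniform 20–70° angle to the
allometric direction), isotropic digitizing noise of 1% of the reference
centroid size, and an arbitrary rigid motion plus the species' size, so the
superimposition is doing real work. Specimen counts (49 species at
U(27, 60), the rest at U(3, 15)) put the expected total near 2,900 crania
over 130 species.

These defaults were set so the simulated study reproduces the magnitudes a
real ruminant-scale dataset shows — interspecific allometry R² ≈ 0.2, PC1
carrying ≈ 25–35% of variance, V_proj(CREA) fractions of roughly 2–18%
against a random-vector mean of 1/k ≈ 1.3%. An optional `llr_coupling`
parameter adds non-phylogenetic displacement along the allometric direction
in proportion to each species' P-alignment, creating the
divergence-predicted-by-V_proj signature; it is off by default, so the
default study is a *pure-BM* world in which the KS angle test still rejects
(divergence is biased toward CREA by the elongated rate matrix alone) but
per-species divergence regressions are weak.

What passing tests on these data do **not** show: real crania violate the
generator's isotropic-remainder covariance (real P matrices have many
structured axes), tangent-space linearity is only as good as the shape
variation is small, the tree is known without error here, and measurement
error is i.i.d. Gaussian. Results on the synthetic bundle validate the
estimators, not any biological claim.

## Problem sizes and numerical choices

Monte-Carlo components run at fixed, seeded sizes chosen as the package's
standard verification scale: coverage checks use 200 replicate BM datasets
on a 50-tip tree (SE computed from between-replicate variance, since tips
within a replicate are phylogenetically correlated); rate-matrix recovery
uses 200 replicates with the REML divisor and a Bonferroni-adjusted
simultaneous band over the 6 unique matrix elements; type-I error checks
use 300–500 simulations at 99–199 permutations. Ties and degenerate cases:
zero divergence vectors are flagged and excluded from angle statistics
rather than assigned an angle; a constant diet column or a rank-deficient
polynomial basis is an error; P-matrix estimation requires at least two
specimens; eigenvalues are clipped at zero when factor-izing PSD matrices
for simulation.
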