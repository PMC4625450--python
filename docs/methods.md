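# Methods

This note records the models, conventions and numerical choices behind
the pipeline, and what the synthetic data can and cannot establish.

## Outline preprocessing

A specimen enters as an ordered polyline digitized along the mandible
margin (TPS `CURVES`/`POINTS` blocks; `SCALE=` applied when present —
scale cancels under Procrustes superimposition, so this only affects raw
coordinate output).  The polyline is resampled to *k* points (default 50)
at equal arc-length spacing with linear interpolation; the first and last
points are anchored to the curve endpoints, which are treated as fixed
landmarks at the mandible apex and base.  No spline smoothing and no
semi-landmark sliding (neither minimum bending energy nor minimum
Procrustes distance) is applied: resampled points are fixed landmarks
downstream.  This is a known methodological choice — sliding would change
distances slightly — made because the standard import path for outline
points into CVA-style software treats them as fixed.

Left/right comparability is the user's responsibility: the
`standardize_orientation` step offers `force_ccw_signed_area` (reflect
across the x axis whenever the closed outline's shoelace area is
negative; idempotent) and `reflect_x`, with `none` the default.  The
digitization start point must be consistent across specimens; the
pipeline does not guess it.

## Superimposition

Generalized Procrustes analysis: center, scale to unit centroid size,
then iteratively rotate each configuration to the running consensus
(initially the first configuration) and recompute the consensus as the
coordinate-wise mean rescaled to unit size.  Iteration stops when the
Procrustes distance between successive consensuses falls below 1e-10
(cap 100 iterations; non-convergence is flagged, not raised — the result
is still usable).  Rotations are proper (det +1) by default because
mandibles are chiral; `allow_reflection` exists for deliberately mirrored
comparisons.  Unit centroid size is maintained every iteration (no
per-pair scale re-optimization).

Shape coordinates are the orthogonal projection of the aligned, flattened
configurations onto the tangent space at the consensus.  Because the
consensus is proportional to the mean of the aligned configurations, the
tangent coordinates sum to (numerically) zero.  The Procrustes distance
is the partial form: root summed squared differences after centering,
unit scaling and optimal rotation, without scale re-optimization — this
keeps it a metric (triangle inequality holds), which the tests check.

## Ordination and discrimination

PCA is the eigendecomposition of the tangent-coordinate covariance
(divisor n−1), computed by SVD; retained components m = min(n−1, 2k)
always capture the full rank, so variance proportions sum to 1.
Relative warps are computed with uniform weighting (no bending-energy
weighting of the partial warps); analyses that weight by bending energy
will differ slightly in the warp scores, not in distances.

Per-group total variance is the trace of the group's tangent covariance,
equal to the sum of the group-restricted PCA eigenvalues.  The 90%
equal-frequency ellipse of a 2D score scatter is the fitted bivariate
normal contour: center at the mean, semi-axes sqrt(λ_i · χ²₂(0.90)) from
the covariance eigendecomposition.

CVA needs an invertible pooled within-group covariance, but with 50 2D
semi-landmarks the shape space has ≤ 2k−4 = 96 dimensions and desk-scale
samples are rank-deficient.  Rank rule (auto): project onto the leading
principal components whose eigenvalue exceeds 1e-9 × the largest,
additionally capped at n − g − 1 so the pooled covariance (divisor n−g)
stays invertible; `retained_dims` overrides.  At desk scale this cap
keeps barely one degree of freedom per retained dimension, which inflates
Mahalanobis distances relative to a large-sample analysis of the same
populations — the distances are internally consistent and test-verified
against the explicit-inverse formula, but their absolute magnitude is a
function of the retained rank.  Canonical axes solve the generalized
eigenproblem of between-group versus pooled within-group covariance and
are reported back-projected into tangent space.  Procrustes distances
between groups are computed between the group mean shapes in full shape
space, independent of the rank rule.

Permutation tests are pairwise (two groups at a time, matching how the
distances are reported): pooled labels are reassigned with group sizes
preserved, and p = (#{permuted ≥ observed} + 1)/(n_perm + 1), so p is
never 0, ties count toward p, and the smallest attainable p at 10,000
rounds is 1/10001 ≈ 0.0001.  The Mahalanobis statistic is fully
recomputed per permutation (two-group means and pooled covariance).  For
this pairwise statistic the subspace is chosen from the pair's own pooled
data and capped at half the pair's sample size minus one, keeping at
least ~2 within-group degrees of freedom per dimension: retaining every
technically nonzero component would make the permuted statistic so
ill-conditioned that its null distribution develops heavy tails and the
test loses power (the calibration experiments in the acceptance suite
exercise exactly this).  The Procrustes statistic is the distance between
permuted group mean shapes.  No multiple-testing correction is applied
across the three pairs; raw p-values are reported.

## Ancestral reconstruction and classification

Terminal taxa carry mean shapes (coordinate-wise means of their aligned
specimens, rescaled to unit size).  All branch lengths are set to 1.0
regardless of the input newick (with a warning): the evolutionary model
assumes the same expected morphological change on every branch.  Internal
node coordinates minimize Σ_edges ‖x_parent − x_child‖²; with tips fixed
the normal equations are a sparse symmetric system in the tree Laplacian,
solved exactly per coordinate.  This equals the Brownian-motion ML
ancestral states under equal branch lengths, is linear in the tip data,
and handles polytomies natively.  Unlabeled internal nodes are numbered
by post-order traversal (`node1`, `node2`, …).

Each reconstructed node is compared with the extant feeding-type groups:
Procrustes distance to each group mean shape, and Mahalanobis distance in
the CVA-retained subspace using the extant pooled within-group covariance
(ancestors are out-of-sample and contribute nothing to the covariance;
raw-tangent-space distances can be computed by overriding the retained
basis).  The reciprocal transformation turns distances into support
proportions: support(g) = (1/d_g)/Σ_h(1/d_h) — the only parameter-free
normalization of "closer means more support" that yields pie-chart
proportions; a zero distance takes support 1 (ties among zeros split
equally).  By construction the support order is the reverse of the
distance order and the Procrustes argmax equals the nearest-mean
classifier.

Node shapes are also projected into the extant PCA space (tangent
projection at the extant consensus, then the extant axes); the map is
linear, so a star-tree root projects to the mean of its tip projections,
and an extant specimen projects exactly to its own score.

## Cross sections

The voxel model's long axis is the dominant eigenvector of the occupied
voxels' second-moment matrix (a warning is issued when the top two
eigenvalues are within 5% — the axis is then poorly determined).  The
distal tip is the end with the smaller occupied cross-section in the
terminal 5% slab, overridable.  The grid is rotation-resampled
(nearest-neighbour) so the axis is grid-aligned, the occupied axial
extent is divided into six equal sections from tip to base, and the area
at each boundary position i/6 (i = 1..4) is the occupied voxel count of
the one-voxel slab at that position times the in-plane voxel area —
a planar cross-section, not a slab-averaged volume.  Ratios are
percentages of the 4/6 area.  Nearest-neighbour resampling and tip
truncation (voxels thinner than half a voxel vanish) bias the smallest
sections by a few percentage points at 128 voxels of axial resolution;
the convergence test shows the bias shrinking with resolution.

## Synthetic data

The generators stand in for the undeposited specimen data.

* **Templates** — three deterministic 50-point blade outlines encoding
  the real contrasts: coprophagous = elongate, narrow, distally slim
  (largest length/width aspect); phytophagous = shorter with a strongly
  curved hooked tip; omnivorous = short, broad, blunt.  Pairwise
  Procrustes distances 0.25–0.60.
* **Groups** — specimen = template + isotropic Gaussian noise (sd 0.02
  per coordinate, in aligned shape space, then re-centered/rescaled).
  Noise in shape space keeps the variance parameter directly comparable
  to the per-group total variance (~96 · sd², minus a little for the 4
  similarity degrees of freedom).  Default 30 specimens per group over 5
  terminals per group — a desk-scale stand-in for the original
  187-specimen, ~50-terminal design.
* **Brownian motion** — child = parent + Gaussian step of per-coordinate
  variance rate × branch length on the equal-length tree; both tip shapes
  and true internal states are returned, so reconstruction error is
  measurable.
* **Solids** — exact-geometry voxelizations (voxel occupied iff its
  center is inside) of a cylinder, a cone and a tapered blade, with
  optional rigid pose.

What passing tests show: the implementation is internally correct
(invariances, oracles, calibration) and recovers known ground truth under
its own generating model.  What they do not show: that real mandible
outlines satisfy the model (isotropic within-group variation, Brownian
shape evolution, equal branch lengths), nor the original study's printed
distance values, which depend on the undeposited 187-specimen data.

## Problem sizes and determinism

Tests and the acceptance script use desk-scale sizes chosen to make the
statistical checks sharp but quick: 3 × 30 specimens for the study
conditions, 500 simulations × 499 permutations for null calibration, 200
replicates per tip count for root-recovery, 128-voxel solids.  Every
stochastic step takes an explicit seed; a run's config (including the
seed) is serialized into its output manifest, and two runs with the same
config are byte-identical in their numeric outputs (written at 12
significant digits).
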