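# Methods

This note documents the models, procedures and numerical choices behind
`morphogrid`: what each stage computes, which decisions were genuinely
open, and what the synthetic-data tests do and do not demonstrate.

## Pose normalization

Artifacts are brought into a canonical pose in three steps.

1. **Centering.** The area-weighted surface centroid (mean of face
   centroids weighted by face area) is translated to the origin.  A
   plain vertex mean would be biased by non-uniform scanner
   tessellation; the area-weighted centroid is not.
2. **Planform orientation.** Let `n_f` be the unit normal and `a_f` the
   area of face `f`.  The leading eigenvector of the normal scatter
   matrix `S = Σ a_f n_f n_fᵀ` is the direction most of the surface
   faces; for a flat bifacial piece that is the axis through its two
   large faces.  The minimal rotation (about an axis in the XY plane,
   hence a composition of X and Y rotations) maps it onto +Z.  If the
   two leading eigenvalues of `S` differ by less than 1 % the object has
   no usable planform (e.g. a sphere) and a `planform ambiguous` flag is
   raised.
3. **Bilateral symmetry.** The planform silhouette is sampled at `K`
   stations equidistant along the length axis (default `K = 256`).  At
   station `y` the outline extremes `x_min(y)`, `x_max(y)` are the
   extreme crossings of mesh edges with the plane `y = const` after
   projecting to XY.  The asymmetry score at Z-rotation `θ` is

       A(θ) = Σ_j |x_max(y_j) + x_min(y_j)| · Δy   [mm²],

   zero exactly when the outline is mirror-symmetric about `x = 0`.
   `A` is 180°-periodic; it is minimized by an exhaustive coarse grid
   over [0°, 180°) (default step 0.5°) followed by golden-section
   refinement to 10⁻³ degrees.  Competing local minima within 1 % of
   the optimum raise a tie flag and the smallest angle wins.  Because
   minimizing `A` makes the Y axis the symmetry axis, and a biface's
   symmetry axis is its length axis, the canonical pose has length on
   Y and the faces toward ±Z.

The protocol cannot distinguish dorsal from ventral or distal from
proximal: the pose is determined only up to the Klein group of
half-turns about the three axes.  `apply_review` applies a reviewer's
batch corrections (180° Y-flip, 90° Z-quarter-turns) as exact
sign/permutation matrices, replacing the interactive confirmation step
of GUI tools with a review CSV.

Implementation detail: the scorer buckets each projected edge into the
few stations its y-span covers instead of testing every edge against
every station; the scores are identical and the cost drops by about two
orders of magnitude, which is what makes the 100-pose invariance
harness and the Monte-Carlo recovery harness affordable.

## Semi-landmark grid

On a positioned mesh, `L` cross-sections (latitudes) are taken at
stations equidistant along Y.  The exact length extremes degenerate to
single points, so the end latitudes are inset by
`δ = (y_max − y_min) / (20 (L − 1))` (configurable); the end sections
are then small closed outlines around the tips.  If an end section is
still empty the inset is doubled once before giving up.

Within a section, `M` stations are placed equidistant in X across the
section's width — "equidistant relative to the artifact's width at that
position", not equidistant in arc length.  At each interior station the
vertical line meets the section outline in an upper (max Z) and lower
(min Z) crossing: the two semi-landmarks of that grid point, one per
face.  For non-convex sections with more than two crossings the extreme
crossings are kept (the outermost surfaces are the faces being
described).  Stations 1 and `M` sit on the lateral edges, where the two
semi-landmarks coincide.  A station with no crossing (strongly concave
outline) falls back to the nearest outline point and is flagged.

The canonical ordering — upper-face block then lower-face block, both
latitude-major from +Y with stations from −X — is identical for every
item, so homology is positional.  The landmark count is exactly
`2·L·M` for every mesh and configuration; a 50 × 50 grid gives 5000
landmarks.  Sections are computed with `trimesh`'s multi-plane
intersection; meshes are never resampled, so runtime scales with face
count.

## Superimposition and shape space

Configurations are centered, scaled to unit centroid size
(`CS = √Σ‖p_i − p̄‖²`), and iteratively rotated onto the consensus with
the Kabsch solution constrained to proper rotations — artifacts have a
fixed handedness after positioning, so reflections are never admitted.
The consensus is the arithmetic mean, re-normalized to unit size each
sweep; iteration stops when it moves less than 10⁻¹⁰ RMS (at most 100
sweeps; the Procrustes objective is non-increasing and its trace is
kept on the result).  The initial reference is the first item in the
(lexicographically sorted) sample, which makes runs deterministic.
Scaling to unit size rather than mean size was an open convention; unit
size is the common choice and is what the tests pin down.  No tangent-
space projection is applied: downstream PCA operates on Procrustes
coordinates directly, which at the shape distances involved here
(≈ 0.03–0.06) differs negligibly from the tangent construction.

PCA is covariance PCA of the flattened `n × 3k` matrix, computed by
economy SVD (dual mode — with `3k ≈ 15 000 ≫ n` this is both exact and
cheap).  At most `n − 1` components carry variance; eigenvalues use the
`n − 1` normalization so they sum to the total Procrustes variance.
Component signs follow a fixed convention (the largest-magnitude entry
of each component is made positive) so exports are reproducible.  The
warp tool reconstructs `mean + s · component`, and a component's
per-landmark loading magnitudes (normalized to max 1) color where on
the artifact the trend acts.

## Group statistics

- **Within-group shape variability**: mean Euclidean distance of the
  group's members from the group mean, in the full flattened Procrustes
  space (dimensionless; ≈ 0.03–0.06 for handaxe-like assemblages).
- **Dimension decomposition**: summed squared deviations from the group
  mean apportioned among X, Y, Z; always totals 100 %.
- **Between-group structure**: Euclidean distances between group means,
  with a UPGMA (average-linkage) dendrogram — the linkage was
  unspecified and UPGMA is the conventional default; trees are exported
  as Newick text.
- **Confidence ellipses**: Gaussian 90 % ellipses on 2-D PC scores,
  boundary `(x − μ)ᵀ S⁻¹ (x − μ) = χ²₂(0.9) ≈ 4.605`.
- **Significance tests** (two-sided Wilcoxon rank-sum; the reported
  statistic is the first sample's mid-rank sum):
  - *variability*: group A's own-mean distance set vs group B's;
  - *mean shape*: every item's distance to its own group mean vs its
    distance to the opposite group mean, pooled across both groups
    (n₁ = n₂ = n_A + n_B).  The alternative construction using only
    opposite-mean distances yields a pooled sample too small to produce
    the rank-sum magnitudes this kind of analysis reports, so the
    own-vs-opposite construction is used;
  - *size*: the two groups' centroid-size sets (mm, pre-scaling).

  P-values are exact (no ties, pooled n ≤ 20) or use the normal
  approximation with tie and continuity corrections; a sample with all
  values identical returns p = 1.  No multiple-testing correction is
  applied across the three tests; that is left to the user and said so
  here.

## Synthetic assemblages

The generator emulates bifacially worked, bilaterally quasi-symmetric
artifacts.  A biface is a superellipse planform (exponent `p`, length
on Y) carrying a biconvex thickness profile `z = ±(T/2)(1 − ρ^q)` on
the normalized planform radius, with linear width taper toward tip and
base, optional planform shear (breaking bilateral symmetry), a smooth
random "flake-scar relief" field, and Gaussian vertex jitter.  The mesh
is a closed 2-manifold from a polar grid whose equator ring both faces
share.  The relief field is a low-order harmonic series in (ρ, θ) with
random coefficients per item, vanishing at the center and at the edge
ring (seam-safe, silhouette-preserving), normalized to a prescribed RMS
amplitude; it stands in for knapping scars, the high-dimensional part
of real shape variation.  Without it, a purely parametric generator
has ~6 effective shape dimensions and produces unrealistically
overlapping distance distributions.

Default two-group conditions (the study conditions all stochastic tests
use): 20 "basalt" items vs 9 "flint" items.  Group dispersion applies
to dimensionless shape descriptors — elongation, flatness, planform
exponent, tip taper, edge convexity, relief amplitude — at relative SD
0.075 (basalt) vs 0.05 (flint), a 1.5 dispersion ratio.  Dispersion on
absolute dimensions would be partly size dispersion, which GPA scaling
removes; applying it to shape ratios makes the stated ratio the shape
dispersion ratio.  Size (length) gets a separate common 5 % SD.  Mean
shapes differ mildly (flint more elongated, flatter, less convex-edged,
relief 1.0 mm vs 1.5 mm RMS), matching the qualitative contrast the
method is used to detect.  Vertex jitter is 0.1 mm, the accuracy scale
of structured-light artifact scanners.  One root seed spawns per-item
child streams (NumPy `SeedSequence`/`default_rng`, PCG64), so
assemblages are bitwise reproducible.

A measured property worth knowing: the grid protocol amplifies vertex
noise by roughly 5×, because station positions derive from the noisy
silhouette extremes and the upper/lower crossings are extremes over
noisy edges.  Realized shape-variability ratios therefore undershoot
the nominal dispersion ratio somewhat (typically 1.2–1.6 for nominal
1.5 under the defaults).

What the synthetic fixtures do *not* show: real scan meshes have
200 000+ faces, holes, and flake-scar geometry with sharp arrises; the
generator's relief is smooth and its planform convex.  Passing tests
demonstrate the correctness and statistical calibration of the
pipeline, not scanner-grade robustness.

## Problem sizes used by the test suite

The heavy harnesses run at a reduced scale chosen as a package default
for routine verification: mesh resolution 10 (~1.5 k faces), 96
silhouette stations, 2° coarse angular step, 20 × 20 grids.  The
positioning-invariance harness uses 100 random rigid poses of one
specimen; the recovery harness runs 200 independent end-to-end
two-group analyses; rank-sum exactness is enumerated exhaustively for
all pooled sizes ≤ 12.  The acceptance script runs one assemblage at
full scale: 256 stations, 0.5° step, 50 × 50 grid (5000 landmarks per
artifact).

## Known limitations

- VRML reading covers `IndexedFaceSet` geometry only (no transforms,
  materials or textures); the original landmark container formats of
  the GUI tools this reimplements are binary and undocumented, so an
  open JSON container is used instead.
- No semi-landmark sliding (bending-energy or chord minimization): the
  placement protocol itself defines homology.
- Dorsal/ventral and distal/proximal assignment is intentionally left
  to the reviewer (batch review file), as symmetry cannot decide it.
- The asymmetry measure integrates outline mismatch across length
  stations; comparing half-areas would be an alternative reading of
  "difference between the outline's halves", and would differ for
  strongly concave outlines.
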