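# Methods

This note documents the models, numerical choices and limitations behind
`leafmorph`. It describes what the code computes and why the defaults are
what they are; every number quoted here is produced by the test suite or
by `scripts/acceptance.py` at run time.

## Coordinate and unit conventions

All contours live in a y-up Cartesian frame in centimetres, oriented
counterclockwise, with the blade/petiole junction `P` a marked vertex.
Calibration is carried as `px_per_cm / downscale` (a 152 px/cm source
image downscaled by 8 has an effective 19 px/cm). Areas are cm². These
conventions make radial distances, signed areas and cross-population
comparisons unambiguous.

## Synthetic leaf model

A blade is a fan sector about `P = (0, 0)` opening upward:

    rho(theta) = R (1 − f·g(theta)) (1 + a·sin(k·theta)),
    theta ∈ [π/2 − s, π/2 + s],

closed by two straight radial edges to `P`. `R` is blade radius (cm),
`s` the sector half-angle (rad), `f ∈ [0, 1)` the fractional furrow
depth, `g` a sum of raised-cosine bumps of angular width `w` with maximum
1 (one bump per furrow; `n_lobes − 1` furrows), and `a, k` the
crenulation amplitude (fraction of `R`) and count. Radial edges mean the
blade area is exactly `½∫rho²dtheta`, evaluated by Simpson quadrature on
20001 nodes; vertices are placed approximately equally in arc length and
evaluated *on* the model, so ground-truth radii are exact: the profile
maximum is `max rho` and the furrow minimum is `R(1 − f)` times the
crenulation factor.

Defaults for population sampling: `R ~ U(2, 7)` cm and sector half-angle
`U(0.7, 1.3)` rad (areas ≈ 2–50 cm², spanning all four area groups),
`f ~ U(0, 0.6)` (no furrow to deep furrow), furrow width `U(0.3, 0.7)`
rad, crenulation amplitude `U(0, 0.03)` with count 8–20, two lobes, and
radial jitter of sd 0.01 cm. These emulate a mixed short-shoot/long-shoot
population: small deep-furrowed dissected blades through large shallow
ones. Multi-lobed, fossil-like forms use `n_lobes > 2`.

Noise is radial only, smoothed along the contour (Gaussian, σ = 2
vertices) and tapered to zero within `8·noise_sd` of `P`: white
per-vertex jitter at sub-millimetre vertex spacing folds the polygon onto
itself, which no real margin does. Contours failing a simplicity check
raise a degeneracy error rather than propagate.

What the generator does *not* emulate: venation, petiole remnants,
lobe asymmetry, backward-curving basal lobes, imaging artefacts, and the
hand-traced restoration uncertainty of fossil outlines. Passing tests
demonstrate correctness of the machinery on clean fan-shaped blades, not
robustness to damaged real material.

## Image path

Global Otsu threshold with a polarity flag (light-box photographs are
high-contrast), largest connected component kept, interior holes filled.
The petiole is removed by morphological opening with a disk of radius
`max_stalk_width_cm / 2` in calibrated pixels — protrusions narrower than
the threshold vanish, the blade survives; wider stalks are deliberately
retained. The outer boundary is traced at sub-pixel resolution
(marching squares) and resampled to `n_points` equally spaced in arc
length. Resampling iterates to its uniform-chord fixed point (tolerance
1e-12 relative, ≤ 25 passes) so the operation is idempotent. `P` is
located from a user hint (nearest vertex — the recommended path for
photographs) or as the lowest vertex of a base-down blade, ties resolved
to the lowest index with a warning.

## Radial barcode

Distances from every contour vertex to `P`, then zero-dimensional
superlevel persistence: vertices are inserted in decreasing distance
(ties by increasing index) into a union–find over the cyclic adjacency; a
component's birth is its first vertex's distance, and on a merge the
younger component dies at the current threshold (elder rule; birth ties
resolved so the smaller first-vertex index survives). The essential
component closes at death 0, so the longest bar always equals `max d`.
Zero-length bars (birth = death, produced only by exact ties) are
diagonal points and are discarded; `Barcode.significant(min_length)`
additionally filters the machine-precision bars a numerically flat
profile plateau generates. Since `d(P) = 0`, superlevel sets never wrap
through `P` and the cycle/arc distinction is immaterial.

Vectorization sorts bar lengths in decreasing order and zero-pads to the
population maximum bar count `L` (never truncates). Unnormalized vectors
are the within-population setting; normalization (divide by first length,
drop the leading 1) is the setting for mixing populations whose absolute
sizes should not dominate. Ordination is centered PCA without variable
scaling; classical MDS (double-centered Gram eigendecomposition) is
provided as an independent route and agrees with PCA scores up to an
orthogonal transform on Euclidean data — the test suite verifies this to
1e-8.

## Elastic shape analysis

The metric is the first-order elastic (square-root-velocity) metric:
`q = c'/√|c'|` computed by periodic forward differences on the
equal-arc-length discretization, with `‖q‖² = (1/n)Σ|q_k|²` so that
`‖q‖²` equals curve length. The SRV transform linearizes the elastic
geometry — geodesics are straight lines in `q`-space — which keeps
distances, means and mode shoots closed-form and oracle-checkable.
Second-order Sobolev-type metrics, which penalize bending curvature
explicitly, are out of scope; the metric sits behind the module surface
so a different transform can replace it. Quantitative results that are
metric-sensitive (e.g. how many tangent components explain 80% of
variance in a given collection) should be read as specific to this
metric.

Alignment minimizes over the nuisance group:

* translation — removed by centroid centering;
* rotation — 2-D orthogonal Procrustes in closed form (`atan2` of the
  cross/dot sums);
* cyclic seam shift — every integer shift is evaluated;
* reparametrization — dynamic programming on the `(n+1)²` grid with
  moves `(1,1),(1,2),(2,1),(1,3),(3,1),(2,3),(3,2)` (local slope in
  `[1/3, 3]`), both endpoints pinned; edge cost is the discretized
  matching energy with linear interpolation of `q`.

Because the rotation-only energy is a poor predictor of the
post-reparametrization energy, every seam gets one DP pass, and the best
three seams are refined by alternating DP and re-rotation (≤ 10
alternations, stopping when the energy improves by < 1e-10). The test
suite checks this search against an exhaustive no-pruning oracle on a
circle/ellipse pair. Inverting `q` to a curve distributes the closure
defect linearly along arc length and recenters.

`ShapeCurve` resampling starts at the base point, so two copies of one
outline marked at the same `P` discretize identically; quotient
invariance then holds to ~1e-14, and for genuinely re-discretized inputs
the residual is bounded by the correspondence resolution (the DP grid is
integer, so sub-vertex seam offsets cost one vertex spacing of mismatch).

Karcher mean: initialize from the average of curves aligned to the first
sample; iterate align-all → average `q` → re-center until the relative
change of the mean SRV drops below `tol = 1e-6` or `max_iter = 50`.
On heterogeneous noisy populations the iteration can dwell at ~1e-2
relative change for a dozen iterations while seam/correspondence choices
settle, then converge; the pipeline default caps at 20 iterations (30 in
the acceptance script) and warns if the cap binds — the iterate is still
a usable mean. Tangent vectors are aligned SRVs minus the mean SRV;
their PCA provides modes, and shoots map `q_mean + t·σ·component` back
to curves (exactly the mean at `t = 0`).

## Areas and regression

Shoelace area with an optional simplicity check (shapely); orientation
is normalized first, so the result is positive for any vertex order.
Area groups use half-open intervals `(−∞,8], (8,16], (16,24], (24,∞)`:
the boundary value 24 cm² is assigned to the third group so the groups
partition. The area regression is OLS of `area ~ 1 + PC1 + PC2`, `R² =
1 − SSE/SST`, with a rank check on the design matrix.

## Problem sizes

Defaults chosen for the bundled analyses: contours at 200 vertices
(2000 for sub-1% area convergence), shape curves at 60–100 vertices,
populations of 20–150 synthetic leaves, barcode oracle checks on 1000
random profiles of length ≤ 200. The acceptance script uses 150 leaves
for the topological morphospace and 40 for the geometric one.

## Known limitations

* The DP reparametrization is vertex-resolution: correspondences between
  fractional seam offsets cost up to one vertex spacing; increase `n`
  where finer matching matters.
* The tangent-space linearization is first-order; for very dispersed
  populations (distances approaching the curvature scale of shape space)
  PCA in the tangent space underestimates far-field distortion.
* The image path assumes one leaf per image, high contrast, and a mask
  clear of the image border.
* Fossil-style damaged margins are not repaired; broken inputs are
  skipped and recorded per leaf by the pipeline rather than restored.
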