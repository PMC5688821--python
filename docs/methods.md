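# Methods

## Scene model and coordinate systems

A scene is a coloured point cloud of one strawberry pinned on a reference
holder. Multi-view reconstruction gives coordinates in an arbitrary image
space: absolute sizes differ from scan to scan, but ratios are true. All
physical measurements therefore pass through a single calibration factor
`s = 38 mm / e1(holder)`, the true holder height divided by the major
extent of the holder's oriented bounding box. Linear traits scale with
`s`, volume with `s³` (forced by dimensional analysis).

## Segmentation

Colours are converted to HSV and points are assigned by circular hue
windows: holder (blue) [200°, 260°), calyx (green) [70°, 170°), body
(red) [330°, 30°) wrapping through zero, achene spots (yellow-tan)
[30°, 70°), with points below saturation 0.15 left unassigned (rejects
white/specular points). The windows are half-open so adjacent windows
sharing an endpoint stay disjoint, and the achene window takes precedence
over the body window because the spots sit on the body surface. The
thresholds are deliberate defaults matched to the rig's scene colours,
not measured constants; they are fully configurable and printable with
`fragaria3d dump-config`. Segmentation is purely per-point and hue-based —
no adaptivity, no texture — so strongly atypical cultivar colours will
need adjusted windows.

## Oriented bounding box

The major axis is the leading eigenvector of the 1/n mean-centred point
covariance (eigen-ties broken toward the lexicographically larger
eigenvector; axis signs canonicalised so the largest-magnitude component
is positive). The second axis is the direction of the farthest point pair
after projecting every point onto the plane orthogonal to the major axis;
the pair search runs on the 2-D convex hull vertices, which is exact. The
third axis is the cross product. Extents are max − min of point
projections on each axis — deliberately untrimmed, so extreme points and
noise enter directly (see Limitations).

Two consequences of this construction are worth knowing:

- On an exactly square cross-section (the 38 × 19 × 19 mm holder) the
  farthest projected pair is the section *diagonal*, so the holder box
  reports extents 38 : 19√2 : 19√2, not 38 : 19 : 19. Calibration is
  unaffected — it uses only the major extent — and fruit cross-sections
  are elliptical, where the farthest pair does realise the true length.
- Dimension measurements use the box of body ∪ holder; the tall holder
  guarantees the vertical is the major axis, which a box fitted to the
  irregular body alone often misidentifies. Height is the difference of
  the combined and holder major extents. Length ≥ width by sorting the
  second/third extents (ties broken toward the second axis).

## Surface reconstruction and volume

Normals are estimated per point from 30-nearest-neighbour PCA and flipped
to point away from the centroid — reliable because the fruit body is
star-shaped about its centroid, unreliable for strongly non-convex
objects. Reconstruction solves the Poisson indicator-field equation on a
uniform grid of 2^depth (default depth 7, i.e. 128³) cells: unit normals
are splatted trilinearly into a voxel vector field, smoothed with a
Gaussian of 1.5 cells, and the field χ with ∇²χ = ∇·V is obtained
spectrally with a cosine transform (Neumann boundaries). The isosurface
at the mean χ value of the sample points is extracted with marching
cubes; the largest connected component is kept and must be closed (zero
boundary edges) or the reconstruction errors out. The grid domain extends
the cloud's bounding box by 35% of its largest extent on every side:
the Neumann solution decays over the object scale, and a tighter domain
lets the exterior field cross the isolevel beneath broad flat bodies,
leaking the surface into the grid boundary.

Volume is the signed-tetrahedron sum |Σ v₁·(v₂×v₃)|/6 over faces, which
is translation and rotation invariant for closed meshes; area is the
summed half cross-product magnitude. A convex-hull path is available both
as a fallback and as an independent oracle for convex bodies. On 5 000
points of a unit sphere the grid solve recovers volume and area to well
under 1%.

## Achene counting and colour

Achene candidates are clustered by single-linkage connected components
with a physical cut distance (default 1.5 mm, converted to image units
through the calibration, so one default works at any scale); clusters
smaller than 3 points are noise. Spots closer than the cut merge — the
documented failure mode on dense packings. Fruit colour is the *circular*
mean of body hue: ripe strawberry red straddles the 0° wrap, where an
arithmetic mean of hues near 359° and 1° would wrongly report ~180°.

## Synthetic scenes and ground truth

The generator emulates what the camera + reconstruction front end hands
to the pipeline, with exact truth:

- **Holder**: 38 × 19 × 19 mm cuboid sampled on its faces (corners pinned
  exactly), dark blue.
- **Body**: surface of revolution r(t) = sin(π t^q)^p, t ∈ [0, 1] from
  base to nose, elliptical cross-section scaled to the requested
  height/length/width; p and q span conic to globose shapes; the profile
  maximum is exactly 1 so anchor points pin the true length and width.
  True volume is the solid-of-revolution integral π·(L/2)(W/2)·H·∫r²dt by
  adaptive quadrature, never a mesh.
- **Achenes**: blue-noise (dart-throwing) centres with a 2.4 mm minimum
  separation, 9-point patches of 0.35 mm radius sitting slightly proud of
  the surface — separation minus patch spread stays above the 1.5 mm
  clustering cut, so the zero-noise truth count is unambiguous. Requested
  counts beyond the dart-throwing saturation bound (≈ 0.5·area/(π·sep²/4))
  are infeasible and raise an error; batch draws are capped at that bound.
- **Calyx**: 5–8 elliptical lobes radiating from the fruit base,
  uniformly rescaled about their centroid so the exact maximum pairwise
  distance equals the requested span.
- **Defects**: isotropic Gaussian point jitter (default 0.15 mm), Gaussian
  hue jitter (default 3°), optional spherical-cap removal at the nose
  (emulating the blind spot above the fruit), and a per-scene global scale
  (default 0.78/38 units/mm, so the default holder spans 0.78 image units;
  batches draw holder sizes across 0.36–1.73 units).

Point budgets (6 000 holder, 20 000 body, 2 500 calyx) reflect a typical
down-sampled reconstruction and keep the covariance axis stable. Batches
draw height, volume, calyx span, achene count, base hue and scale from
configurable ranges; length·width is solved from the volume integral at a
drawn width:length aspect so height and volume ranges are spanned
simultaneously. Height draws are restricted so the solved width stays
above 28 mm and length below 0.85·(38 + height): the measurement model
assumes the fruit is longer and wider than the holder and that the scene
is taller than it is wide, and outside that domain the box locks onto the
holder diagonal or a horizontal axis by design.

What the generator does **not** emulate: reconstruction outliers and
ghost geometry, background/specular points, uneven colour fields within a
part, point-density variation with viewing angle, and holder occlusion by
the fruit. Passing recovery tests therefore demonstrates the measurement
chain is correct under the stated defect model, not that any particular
rig will reach the same concordances on real fruit.

## Agreement statistics

Lin's CCC with 1/n moment estimators; r² as squared Pearson correlation;
RMSE against the identity line y = x (the relevant reference when two
methods are supposed to agree, not the fitted line); ordinary least
squares of automated on reference values. Batch validation joins on
`sample_id` and drops missing values per trait with a logged count.

## Numerical choices and degenerate inputs

- Covariance eigen-decomposition via symmetric `eigh`; inputs with a
  relative eigenvalue below 1e-12 of the largest are rejected as
  collinear/coplanar.
- Set diameter is exact: brute force over convex-hull vertices (full
  brute force below 17 points or for degenerate hulls).
- Clustering joins points at distance ≤ tolerance exactly (kd-tree range
  search, no approximation); results are index-structure independent and
  verified against an exhaustive-matrix oracle.
- Empty achene sets count zero; an empty holder or body segment fails the
  sample; a missing calyx flags only the calyx trait.
- PLY files are written binary little-endian with float32 coordinates and
  8-bit colour (colour is quantised to 1/255 on write).

## Known limitations

- **Noise-inflated extents.** Max/min extents are order statistics: with
  σ = 0.5 mm point noise the thousands of points on the holder's end
  faces inflate its measured extent by ~3 mm, deflating the calibration
  scale by ~7–8%. Length and width are largely self-compensating (their
  own extents inflate too), but height carries the full scale bias, and
  its concordance under that noise level drops to ~0.88. Percentile
  trimming would fix this at the cost of changing the measurement
  definition; it is deliberately not applied.
- Achene counting merges spots closer than the cut distance and is
  sensitive to point noise comparable to the spot spacing.
- The square-section holder's second/third box extents report the
  diagonal (above); only its major extent is meaningful.
- Poisson reconstruction assumes the body cloud covers a closed surface;
  very large missing regions (beyond a modest nose cap) can produce open
  or distorted meshes, reported as errors rather than silently wrong
  volumes.
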