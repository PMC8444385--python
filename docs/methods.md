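# Methods

This note documents the models, conventions and numerical choices behind
`phenomesh`, and what the synthetic-data tests do and do not demonstrate.

## Scope and conventions

The package starts where dense multi-view reconstruction ends: a colored
point cloud of one potted plant in an arbitrary coordinate frame. All
geometry is carried in millimetres once the reference scaling has been
applied; +z is up and the ground plane is z = 0 after reorientation.
Traits are reported in the units conventional for the phenotype (mm for
lengths, cm² for areas, cm³ for volume, m² m⁻² for plant area index).

**One-sided area.** A dense reconstruction wraps a thin leaf, producing a
surface over both faces, so the raw mesh area is ~twice the botanical leaf
area. All "total surface area" values are therefore the raw triangle-area
sum divided by two. This convention is applied globally — including to the
stem, whose lateral surface is also halved. A consequence worth noting:
the PAI of a *single-sheet* horizontal plate is 0.5, while a *two-faced*
(wrapped) plate — the realistic reconstruction of a leaf — has PAI exactly 1.

## Cleaning chain

- **Reference scaling**: scale = known length (mm) / measured length (model
  units). The pot width is the intended reference; any measured pair of
  points works.
- **Color filter**: keep points with HSV hue in [15°, 170°], saturation
  ≥ 0.15, value ≥ 0.10. The window spans brown (stems) through green
  (leaves) and rejects white/grey backdrop, whose saturation is near zero.
  No published numeric thresholds exist for this step; these defaults are
  this package's choice and are fully configurable.
- **Reorientation**: either an explicit user transform, or RANSAC plane
  fitting (200 iterations, 2 mm inlier tolerance, seeded) on the lowest
  decile of points, refined by total least squares on the inliers; the
  recovered plane is rotated to the x–y plane and shifted to z = 0.
- **SOR**: per-point mean distance to k = 6 nearest neighbors; points above
  mean + 1.0·σ of those means are dropped (the defaults of the tool the
  workflow is modelled on). SOR is run *after* color denoising, so the only
  sparse structure left is genuine speckle.
- **Poisson-disk subsampling**: seeded greedy dart throwing over the input
  cloud (visit points in random order; accept when no accepted point lies
  within the radius, default 0.5 mm). The retained set has minimum pairwise
  spacing ≥ radius and approaches random-sequential-adsorption saturation
  density (~0.55 disk coverage) when the input is dense. The Monte-Carlo
  `oversampling` knob of sample-based implementations is accepted for
  config compatibility but has no effect here: every input point is a
  candidate dart. Interactive removal of residual non-plant points is
  replaced by an optional axis-aligned crop box, for headless
  reproducibility.

Every filter returns the kept sub-cloud plus the retained indices, so
filters compose and labelled clouds can be scored.

## Surface reconstruction

Ball pivoting is implemented in-package (no installed geometry library
provides it). Point normals are estimated by k-NN PCA (k = 10), made
consistent by sign propagation along a minimum spanning tree of the
neighborhood graph weighted by 1 − |nᵢ·nⱼ|, and flipped globally so the
canopy top (top decile of z) faces upward. The pivoting front then grows
triangles wherever a ball of the current radius rests on three points and
contains no other; each front edge pivots at most once per radius, and
edges are capped at two incident faces.

Numerical details that matter:

- Ball centers are recomputed on demand from the triangle circumcenter and
  the stored winding (the ball always lies on the positive side of the
  winding), which makes multi-radius passes trivial.
- Pivot angle θ = 0 is legitimate: on regular grids four points are exactly
  cocircular and the new triangle shares the old ball. Fold-backs onto the
  old side are rejected by requiring the ball center to lie on the positive
  side of the *new* triangle's winding.
- The empty-ball test uses radius·(1 − 1e-7), so points exactly on the
  sphere (cocircular configurations) do not block a valid triangle.
- Radii default to {2, 4, 8} × the median nearest-neighbor distance; later
  (larger) radii re-open boundary edges left by earlier passes and bridge
  sparser regions.

Hole closing finds boundary loops (edges with one incident face) and
triangulates loops of ≤ 50 boundary edges by ear clipping on the loop's
best-fit plane, falling back to a fan when no ear exists. No vertices are
added. Larger loops — typically the open bottom where the plant was cropped
from the pot — are left open.

On analytic shapes the reconstruction recovers a 20×20 unit-grid plane to
+0.3% of its area and a 5000-point sphere to −0.06%, watertight (Euler
characteristic 2).

## Traits

- **Height / width**: axis-aligned extents of the mesh vertices; height is
  the z-extent (the pot is excluded by cleaning, so the base is the stem
  base). This is the bounding-box interpretation of a ruler measurement.
- **Projected area**: each face is orthographically projected along −z and
  rasterized (scan-line polygon fill) into a boolean grid at 0.25 mm/px;
  the union of covered pixels times the pixel area is the silhouette area.
  Union semantics mean overlapping canopy counts once. Rasterization error
  is O(perimeter × pixel size); the default resolution puts a sphere's
  silhouette within 0.2% of πr².
- **Hull volume**: Qhull convex hull of the vertices; degenerate (coplanar)
  inputs return 0 with a warning rather than raising.
- **Per-triangle records**: edge lengths from vertex coordinates, area by
  Heron's formula evaluated in the numerically stable (Kahan) arrangement
  with edges sorted descending — algebraically identical to
  √(s(s−A)(s−B)(s−C)) but immune to cancellation on needle triangles
  (agreement with the cross-product oracle ≤ 1e-10 relative up to aspect
  ratio 10⁴). Negative radicands from rounding clamp to zero and flag the
  face as degenerate.

## Vertical area distributions

Triangles are assigned to height bins by centroid z. Absolute mode uses
half-open 1 mm bins starting at the plant base (minimum vertex z), with the
top edge falling into the last bin, so the bins partition the mesh exactly
and bin sums conserve the total area to floating-point precision.
Normalized mode uses 100 bins of 1% of plant height with areas divided by
the total — both axes dimensionless, so the distribution is invariant to
uniform scaling — and the cumulative curve ends at 1. Display smoothing of
genotype-mean curves is deliberately out of scope; the exported per-bin
values are the data product.

## Growth rates and validation statistics

RGR = (1/t)·ln(A₂/A₁). The percent convention follows field practice: a
weekly RGR of 56.9% means a ln-ratio of 0.569 per week, i.e. 56.9/7 =
8.1% per day — conversion between time bases is a plain division because
the quantity is already a logarithmic rate. Series helpers emit one RGR per
consecutive observation pair, per-interval or per-day.

Validation statistics are RMSE, MAPE = 100·mean(|est−obs|/obs) (requires
nonzero ground truth), Spearman ρ (average ranks for ties) and OLS of
estimate on ground truth; ρ and the regression delegate to scipy.stats.
The package reports per-comparison values; aggregation across plants is
left to the user.

## Synthetic plants and what the tests show

The generator builds a chickpea-like plant from analytic parts: a closed
cylindrical stem (tessellated into ~2 mm vertical segments so height-binned
truth is exact), slender branch prisms confined between the canopy layers,
and elliptical leaflet prisms. Defaults describe a ~2-week-old plant: a
150 mm stem, 30 leaflets of 20 × 12 mm in two layers at 20% and 80% of
plant height holding 75% / 25% of the leaflets, a 150 mm pot, 20% white
backdrop points on the ground plane, and 2% plant-colored outliers on a far
shell (≥ 1.5 × cloud radius). The cloud is delivered in an arbitrary unit
system (scale drawn in [0.005, 0.02]) with a 0.5–3° tilt, like a raw SfM
solve; the sampling density default of 8 points/mm² reflects a dense
reconstruction that oversaturates the 0.5 mm subsampling spacing.

Two deliberate realism choices:

- **Leaflets are thin prisms (1.2 mm), not zero-thickness sheets.** A dense
  reconstruction observes both faces of a real leaf; coincident sheets can
  never be separated by a pivoting ball. Ground-truth one-sided area is the
  exact generated-mesh area / 2 — the same convention the pipeline applies —
  and includes prism rims and stem caps, so truth and measurement refer to
  the same surface.
- **Leaflets do not interpenetrate** (rejection-sampled placement): merged
  leaflet unions would bury surface that no surface-based method could
  recover, which is a property of the scene, not of the algorithm under
  test.

Every point carries a class label (plant / background / outlier) and every
face an organ id, so cleaning precision and recall are directly computable.
On the default plant the chain keeps ≥ 99% of plant points and removes
≥ 95% of outliers, height is recovered essentially exactly, and one-sided
area to within ~3–4% — the residual deficit is the surface reconstruction
slightly chamfering leaf rims at the 0.5 mm sampling limit, not a trait
computation error. A "hard mode" preset (curled leaflets folded 35° about
the minor axis, tighter layers) emulates the curled-leaf regime where 2D
ground-truthing is known to diverge from 3D estimates.

What passing these tests does **not** show: robustness to SfM-specific
artifacts the generator does not emulate — surface noise correlated with
texture, non-uniform point density, color bleeding between leaf and
backdrop, missing regions from occlusion — nor calibration of the color
thresholds for any particular camera or backdrop. The labelled-cloud
metrics bound the cleaning chain's behavior only under the generator's
color and geometry model.

## Problem sizes

Default test and acceptance runs use a single synthetic plant of ~75 cm²
one-sided area, whose cloud is ~155k raw points and ~27k after subsampling
(~55k mesh triangles); analytic-shape checks use a 5k-point sphere, a
subdivision-4 icosphere and small plates. These sizes were chosen as the
smallest at which the canopy-layer structure, the saturation behavior of
the subsampler and the rim-resolution limit of the reconstruction are all
clearly expressed.

## Known limitations

- Ball pivoting assumes locally consistent normal orientation; extremely
  thin structures below ~2× the sampling spacing (tendrils, petioles) may
  reconstruct as ribbons or be missed, biasing area slightly downward.
- Organ-level segmentation (leaf vs. stem) is out of scope; all traits are
  whole-plant.
- The projected-area rasterizer uses pixel-center coverage; sub-pixel
  silhouette features are not resolved below the configured resolution.
- `fit_ground_plane` assumes the ground is the lowest coherent plane in the
  cloud; scenes without ground points need an explicit transform.
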