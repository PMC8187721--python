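# Methods

`reefmetrics` quantifies the three-dimensional structural complexity of a
coral-reef plot from a gridded digital elevation model (DEM) and compares
two surveys of the same plot — typically before and after a disturbance.
This note records the models, conventions, numerical choices, and known
limitations; everything stated here is computed by the package's tests or
scripts, not asserted from outside sources.

## The elevation model

A DEM here is a 2.5-D raster: one elevation per square cell, viewed from
directly overhead, in a local metric coordinate system. Row 0 is the
northernmost row (raster convention); the origin is the lower-left corner.
Overhangs cannot be represented — a table-top coral colony rasterizes as a
level plate bounded by one-cell vertical cliffs. That projection artifact is
not a defect to be corrected: it is exactly the geometry the curvature and
ruggedness metrics respond to, and the synthetic generator reproduces it
deliberately.

Cells without data are masked. Every 3×3-window metric declares a cell valid
only when its full neighborhood is unmasked; border and nodata-adjacent
cells are excluded from all population statistics rather than filled by
padding, so no elevation is ever fabricated. VRM additionally requires each
*neighbor's* normal to be defined, so its valid region sits two cells inside
the data margin.

## Metrics

**Surface complexity (rugosity).** The elevation lattice is tiled into
quads of four adjacent cell centers; each quad contributes `cell_size²` of
planar area and the summed area of its two triangles (split along the
diagonal from the south-west corner, fixed for determinism) of 3-D area.
The ratio `area_3d / area_2d` is ≥ 1, equals 1 for a horizontal plane and
`1/cos(slope)` for a uniform incline. A symmetric four-triangle centroid
split is available (`method="center"`); the two agree closely whenever the
relief is resolved at the cell scale and are compared in the tests.

**Slope and aspect.** Horn's weighted 8-neighbor finite differences give
the gradient components `p = ∂z/∂x` (east) and `q = ∂z/∂y` (north);
`slope = atan(√(p² + q²))` in degrees, `aspect` the compass bearing of
steepest descent in [0, 360). Horn is the default of the common raster
toolchains; unweighted central differences (Zevenbergen–Thorne) are
available behind `algorithm="zevenbergen_thorne"`. Aspect is undefined on a
flat cell: those cells report a −1 sentinel and are *invalid* in the aspect
grid, never "north-facing". Flat is detected as an exactly zero gradient;
no epsilon is applied, because a synthetic plane produces exact zeros and a
photogrammetric surface essentially never does.

**Vector ruggedness measure (VRM).** Each cell's unit surface normal is
`(−p, −q, 1)/√(1 + p² + q²)` — equivalently `(sin θ sin α, sin θ cos α,
cos θ)` from slope θ and aspect α, with the vertical normal at flat cells.
Over a w×w window (default 3×3) the normals are summed; with resultant
magnitude R and n = w², `VRM = 1 − R/n ∈ [0, 1]`. VRM measures orientation
*dispersion*, not steepness: a uniformly inclined plane scores 0. Window
sums use direct convolution; values are clipped to [0, 1] to absorb
last-bit rounding.

**Profile and planform curvature.** The Zevenbergen–Thorne partial quartic
`z = … + Dx² + Ey² + Fxy + Gx + Hy + I` fits a 3×3 window exactly; then

    profile  = −2 (DG² + EH² + FGH) / (G² + H²)
    planform = +2 (DH² + EG² − FGH) / (G² + H²)

Profile curvature tracks slope change parallel to the downslope direction,
planform perpendicular to it. Cells with zero gradient have no downslope
direction and report 0, which also makes flat and uniformly inclined planes
curve-free, as they must be. Both quantities are multiplied by 100 (the
common GIS reporting scale; `scale=1.0` recovers raw 1/m units), and the
profile sign is chosen so convex-upward is positive. Published curvature
values rarely state their sign/scale convention, so cross-study magnitude
comparisons should be made with care; within this package the convention is
fixed and documented.

**Resolution ladder.** Coarser grids are produced by block-mean
aggregation: each factor×factor block of unmasked cells averages to one
output cell, entirely-masked blocks stay masked, and trailing partial
blocks are dropped by default (an `expand` policy keeps them as the mean of
the cells present; dropping is the default because a partial block's mean
covers fewer samples and drags edge statistics). The standard panel
computes VRM at the native, 2× and 4× cell sizes — for a 1-cm DEM: 1, 2 and
4 cm. The ladder matters because fine cells resolve the orientation texture
of rubble and coral branches while coarse cells resolve plate- and
mound-scale geometry; the two scales can respond to a disturbance in
opposite directions.

## Population statistics and comparison

Summaries (mean, SD, min, max, N) are taken over every valid cell — a
census of the plot, not a sample — so the SD uses divisor N and no
inferential test is attached: a pre/post difference over the same plot is a
real change, not an estimate. The comparison artifact pairs the two
surveys' seven-row panels (rugosity, mean slope, VRM ×3 resolutions,
profile/planform curvature), reports deltas (post − pre) and their signs,
and serializes to long-format CSV plus JSON.

Curvature distributions are summarized by a Gaussian KDE (Silverman's
bandwidth, recorded in the report). The KDE is estimated from *all* values
but evaluated only on a fixed display window, default (−100, 100): tail
mass beyond the window is therefore visible as the windowed density
integrating to less than 1. A zero-variance sample is rendered as a narrow
Gaussian spike (width 10⁻⁶ in value units) so degenerate inputs remain
plottable.

## Synthetic scenes

The generator exists so the full pipeline can be exercised and validated
without survey imagery. Two reef states plus three control morphologies:

- **tabulate** (pre-disturbance): a correlated Gaussian base-relief field
  (SD 0.06 m, correlation length 0.20 m — standing in for rugose reef
  framework), covered to a target fraction (default 0.70, mirroring the
  ~70% tabulate coral cover such plots reach) by randomly placed elliptical
  plates, radius 0.3–0.7 m, elevated 0.2–0.4 m, tilted up to 30°, overlap
  resolved by maximum elevation, edges rasterized as one-cell cliffs.
  Correlated fine texture (SD 4 mm, 3 cm correlation) plus 1 mm white noise
  models what centimeter-resolution photogrammetry renders of turf and
  corallite relief — nearly level plates, the "illusion of a flat surface".
- **rubble** (post-disturbance): a flatter correlated base (SD 12 mm,
  0.30 m correlation), spherical-cap clasts (radius 2–6 cm, height
  1.5–4 cm, 250 per m²) outside smooth sand patches occupying a configured
  fraction (default 0.32, mirroring the ~32% sand such plots show), and
  1.5 mm white roughness on the rubble matrix.
- **flat**, **incline**, **mound**: analytic/control morphologies for
  limit tests and the standard five-scene battery.

Every scene couples the DEM to a ground-truth per-cell benthic label map,
so the percent-cover stage can be validated against known fractions.
Plate/clast geometry is an assumption chosen at the order of magnitude of
the organisms, not a measurement; placement is a uniform point process; all
randomness flows from one seeded generator, making scenes bitwise
reproducible.

Default parameters were tuned once so that, at the default 10 × 5 m extent,
the tabulate→rubble transition reproduces the qualitative response pattern
this metric panel is known for — rugosity and mean slope decrease, VRM at
2- and 4-cm resolutions decreases, VRM at 1 cm *increases*, curvature SDs
collapse, and extreme curvature values disappear with the plate edges —
while every scene's mean VRM stays below 0.40, the bound natural terrain
rarely exceeds. They were frozen thereafter. Two tuning choices deserve
emphasis: the correlated base relief and the plate tilts are what give the
tabulate scene its higher mean slope (a perfectly flat base with level
plates would be *less* steep than rubble on average, which no rugose reef
is); and the split between correlated texture (slope-bearing,
orientation-coherent) and white noise (orientation-dispersing) is what
keeps the tabulate scene's 1-cm VRM below the rubble scene's.

What the scenes do **not** emulate: photogrammetric reconstruction error
structure, spatial autocorrelation of real coral canopies, biological
morphology beyond caricature (no branching structure, no interlocking
plates), and any absolute-magnitude claims. A passing directional test
shows the pipeline responds to the modeled geometry the way the metrics
should; it does not validate magnitudes against real reefs.

## Percent cover

Uniform random points over the plot extent (default 1000) are labeled —
from the ground-truth label map for synthetic scenes, or from an external
annotation CSV for real surveys. Labels in the exclusion set (transect
tape, scale bars, mobile fauna) are removed from numerator *and*
denominator; `percent = 100 × count / retained total`. Points are
continuous coordinates assigned to cells by the half-open convention
`[x, x+cell)`; sampling is simple-uniform (unstratified).

## Raster I/O

GeoTIFF (single-band float32; `ModelPixelScaleTag`, `ModelTiepointTag`,
`GDAL_NODATA` honored both ways, via `tifffile`) and ESRI ASCII grid
(`ncols/nrows/xllcorner/yllcorner/cellsize/NODATA_value` header, nodata
sentinel −9999, 10 significant digits). Non-square cells and multi-band
files are rejected with errors naming the offending geometry. No CRS
handling: plots live in local metric coordinates.

## Numerical and design notes

- Grid containers accept any non-empty shape; operations own their size
  preconditions (rugosity needs one fully valid 2×2 quad; 3×3-window
  metrics simply have no valid cells on smaller grids). This keeps
  aggregation closed over grids (a 2×2 grid legitimately aggregates to
  1×1).
- Oracle tests compare every 3×3 metric's center cell on ≥ 100 random 5×5
  grids against independently coded brute-force stencils at 1e-10 relative
  tolerance; surface area against a per-triangle cross-product sum;
  aggregation against an explicit block loop; summaries against a two-pass
  accumulation.
- Reported problem sizes: the study-scale checks run on the default
  10 × 5 m plot at 1-cm cells (500 000 cells per survey); unit tests use
  scenes of 1–2 m extent and 5×5–50×50 grids.
- End-to-end runs are byte-deterministic for a fixed seed: log lines carry
  no timestamps, serialized floats use fixed formats, and the resolved
  config omits the output path so identical runs into different
  directories compare equal.

## Known limitations

- The 2.5-D projection undercounts structure beneath overhangs; metrics
  describe the overhead surface, not the full habitat volume.
- Curvature magnitudes at rasterized cliffs are resolution-bound artifacts
  (the second derivative of a step grows as the cell size shrinks); they
  are meaningful comparatively, not absolutely.
- The KDE display window convention means windowed densities are not
  probability densities over the window; integrate with that in mind.
- Synthetic scenes support directional and bound claims only; no
  conclusion about absolute metric values on real reefs should be drawn
  from them.
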