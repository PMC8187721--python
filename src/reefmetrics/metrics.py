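"""Per-cell and whole-plot structural-complexity metrics.

Implements the habitat metrics used to characterize reef structure from a
gridded elevation model:

* **surface complexity** (rugosity): ratio of true 3-D surface area to
  planar 2-D area, the raster analogue of chain-and-tape rugosity;
* **slope / aspect**: Horn's 8-neighbor finite differences on 3x3 windows;
* **VRM** (vector ruggedness measure): dispersion of unit surface normals
  in a moving window, 0 = uniform orientation, 1 = maximal dispersion
  (Sappington-style). Decouples ruggedness from steepness — an inclined
  plane has VRM 0;
* **profile / planform curvature**: Zevenbergen–Thorne partial-quartic fit
  on 3x3 windows; rate of slope change parallel and perpendicular to the
  downslope direction.

All 3x3-window metrics declare a cell valid only when its full neighborhood
is unmasked: border cells and nodata-adjacent cells are excluded rather than
padded, so no elevation is ever fabricated.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import convolve

from .errors import ValidationError
from .grid import DemGrid, MetricGrid, window_all_valid

#: Sentinel reported in the aspect grid at flat (zero-slope) cells, where
#: the direction of steepest descent is undefined. Such cells are also
#: marked invalid so a flat plate never reads as "north-facing".
FLAT_ASPECT_SENTINEL = -1.0


@dataclass(frozen=True)
class SurfaceComplexity:
    """Rugosity of a DEM: 3-D surface area over 2-D planar area (>= 1)."""

    ratio: float
    area_3d: float
    area_2d: float


# ---------------------------------------------------------------------------
# Surface complexity (rugosity)
# ---------------------------------------------------------------------------

def surface_complexity(dem: DemGrid, method: str = "diagonal") -> SurfaceComplexity:
    """Ratio of triangulated 3-D surface area to planar 2-D area.

    The elevation lattice (cell centers) is tiled into quads of four
    adjacent cells; each quad contributes its planar footprint
    (``cell_size**2``) to the 2-D area and the summed area of its triangles
    to the 3-D area. Only quads whose four corners are all unmasked count.

    Parameters
    ----------
    dem:
        Elevation grid with at least one fully-valid 2x2 quad.
    method:
        ``"diagonal"`` (default): two triangles per quad, split along the
        diagonal from the lower-left (south-west) corner — deterministic and
        the convention used throughout the package. ``"center"``: four
        triangles meeting at the quad centroid, a symmetric alternative that
        removes the diagonal-direction bias.

    Returns
    -------
    SurfaceComplexity
        With ``ratio = area_3d / area_2d``; 1.0 for a horizontal plane,
        ``1/cos(slope)`` for a uniformly inclined plane.
    """
    if method not in ("diagonal", "center"):
        raise ValidationError(f"unknown triangulation method {method!r}")
    z = dem.elevations
    cs = dem.cell_size
    v = dem.valid
    # quad corners: ul = z[r, c], ur = z[r, c+1], ll = z[r+1, c], lr = z[r+1, c+1]
    # (row r+1 is south of row r)
    ul, ur = z[:-1, :-1], z[:-1, 1:]
    ll, lr = z[1:, :-1], z[1:, 1:]
    quad_ok = v[:-1, :-1] & v[:-1, 1:] & v[1:, :-1] & v[1:, 1:]
    n_quads = int(quad_ok.sum())
    if n_quads == 0:
        raise ValidationError("no valid surface: no fully unmasked 2x2 quad")

    if method == "diagonal":
        # triangles (ll, lr, ur) and (ll, ur, ul); diagonal ll -> ur
        a3 = _tri_area(ll, lr, ur, cs, (0, 0), (1, 0), (1, 1)) + _tri_area(
            ll, ur, ul, cs, (0, 0), (1, 1), (0, 1)
        )
    else:
        zc = (ul + ur + ll + lr) / 4.0
        a3 = (
            _tri_area(ll, lr, zc, cs, (0, 0), (1, 0), (0.5, 0.5))
            + _tri_area(lr, ur, zc, cs, (1, 0), (1, 1), (0.5, 0.5))
            + _tri_area(ur, ul, zc, cs, (1, 1), (0, 1), (0.5, 0.5))
            + _tri_area(ul, ll, zc, cs, (0, 1), (0, 0), (0.5, 0.5))
        )
    area_3d = float(a3[quad_ok].sum())
    area_2d = float(n_quads) * cs * cs
    return SurfaceComplexity(ratio=area_3d / area_2d, area_3d=area_3d, area_2d=area_2d)


def _tri_area(z1, z2, z3, cs, p1, p2, p3):
    """Vectorized area of triangles with planar offsets p_i (in cell units)."""
    ux = (p2[0] - p1[0]) * cs
    uy = (p2[1] - p1[1]) * cs
    uz = z2 - z1
    wx = (p3[0] - p1[0]) * cs
    wy = (p3[1] - p1[1]) * cs
    wz = z3 - z1
    cx = uy * wz - uz * wy
    cy = uz * wx - ux * wz
    cz = ux * wy - uy * wx
    return 0.5 * np.sqrt(cx * cx + cy * cy + cz * cz)


# ---------------------------------------------------------------------------
# Slope and aspect
# ---------------------------------------------------------------------------

def _horn_gradients(dem: DemGrid) -> tuple[np.ndarray, np.ndarray]:
    """Horn 8-neighbor dz/dx (east) and dz/dy (north), full-shape arrays.

    Border cells hold garbage; callers must apply the 3x3 validity mask.
    """
    z = dem.elevations
    cs = dem.cell_size
    p = np.full(z.shape, np.nan)
    q = np.full(z.shape, np.nan)
    a, b, c = z[:-2, :-2], z[:-2, 1:-1], z[:-2, 2:]
    d, f = z[1:-1, :-2], z[1:-1, 2:]
    g, h, i = z[2:, :-2], z[2:, 1:-1], z[2:, 2:]
    p[1:-1, 1:-1] = ((c + 2.0 * f + i) - (a + 2.0 * d + g)) / (8.0 * cs)
    q[1:-1, 1:-1] = ((a + 2.0 * b + c) - (g + 2.0 * h + i)) / (8.0 * cs)
    return p, q


def _zt_gradients(dem: DemGrid) -> tuple[np.ndarray, np.ndarray]:
    """Zevenbergen–Thorne 4-neighbor central differences (alternative)."""
    z = dem.elevations
    cs = dem.cell_size
    p = np.full(z.shape, np.nan)
    q = np.full(z.shape, np.nan)
    p[1:-1, 1:-1] = (z[1:-1, 2:] - z[1:-1, :-2]) / (2.0 * cs)
    q[1:-1, 1:-1] = (z[:-2, 1:-1] - z[2:, 1:-1]) / (2.0 * cs)
    return p, q


def slope_aspect(
    dem: DemGrid, algorithm: str = "horn"
) -> tuple[MetricGrid, MetricGrid]:
    """Per-cell slope (degrees) and aspect (compass degrees) on 3x3 windows.

    Slope is ``atan(sqrt(p^2 + q^2))`` with ``p = dz/dx`` (east) and
    ``q = dz/dy`` (north) from Horn's weighted 8-neighbor differences (the
    default of common raster tooling); ``algorithm="zevenbergen_thorne"``
    switches to unweighted central differences. Aspect is the compass
    direction of steepest descent, clockwise from north in [0, 360). Flat
    cells report :data:`FLAT_ASPECT_SENTINEL` and are invalid in the aspect
    grid (direction undefined), but remain valid (slope 0) in the slope grid.
    """
    if algorithm == "horn":
        p, q = _horn_gradients(dem)
    elif algorithm == "zevenbergen_thorne":
        p, q = _zt_gradients(dem)
    else:
        raise ValidationError(f"unknown slope algorithm {algorithm!r}")
    ok = window_all_valid(dem.valid, 3)
    grad = np.hypot(p, q)
    slope = np.degrees(np.arctan(np.where(ok, grad, np.nan)))
    # downslope direction is (-p, -q) in (east, north); compass angle is
    # measured clockwise from north
    with np.errstate(invalid="ignore"):
        aspect = np.degrees(np.arctan2(-p, -q)) % 360.0
    flat = ok & (grad == 0.0)
    aspect_ok = ok & ~flat
    aspect = np.where(aspect_ok, aspect, np.nan)
    aspect[flat] = FLAT_ASPECT_SENTINEL
    slope_grid = MetricGrid(slope, "slope_deg", dem.cell_size, ok)
    aspect_grid = MetricGrid(aspect, "aspect_deg", dem.cell_size, aspect_ok)
    return slope_grid, aspect_grid


# ---------------------------------------------------------------------------
# Vector ruggedness measure
# ---------------------------------------------------------------------------

def surface_normals(
    dem: DemGrid, algorithm: str = "horn"
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Unit surface-normal components (x east, y north, z up) per cell.

    The normal is built from slope θ and aspect α as
    ``(sin θ sin α, sin θ cos α, cos θ)``, which for gradients (p, q)
    reduces to ``(-p, -q, 1) / sqrt(1 + p² + q²)``. Flat cells get the
    vertical normal (0, 0, 1). Returns (nx, ny, nz, valid).
    """
    if algorithm == "horn":
        p, q = _horn_gradients(dem)
    elif algorithm == "zevenbergen_thorne":
        p, q = _zt_gradients(dem)
    else:
        raise ValidationError(f"unknown slope algorithm {algorithm!r}")
    ok = window_all_valid(dem.valid, 3)
    p = np.where(ok, p, 0.0)
    q = np.where(ok, q, 0.0)
    norm = np.sqrt(1.0 + p * p + q * q)
    return -p / norm, -q / norm, 1.0 / norm, ok


def vrm(dem: DemGrid, window: int = 3, algorithm: str = "horn") -> MetricGrid:
    """Vector ruggedness measure on an odd moving window (default 3x3).

    Per cell, the unit surface normals of the window are summed; with
    resultant magnitude R and window cell count n, ``VRM = 1 − R/n``. A
    surface of uniform orientation — horizontal *or* uniformly inclined —
    scores 0; orthogonally dispersed normals approach 1. Values lie in
    [0, 1] by construction. Cells whose window contains any cell without a
    defined normal (border or nodata-adjacent) are invalid.
    """
    if window % 2 != 1 or window < 1:
        raise ValidationError(f"window must be odd, got {window}")
    nx, ny, nz, ok = surface_normals(dem, algorithm=algorithm)
    kernel = np.ones((window, window))
    sx = convolve(nx, kernel, mode="constant", cval=0.0)
    sy = convolve(ny, kernel, mode="constant", cval=0.0)
    sz = convolve(nz, kernel, mode="constant", cval=0.0)
    n = float(window * window)
    resultant = np.sqrt(sx * sx + sy * sy + sz * sz)
    values = np.clip(1.0 - resultant / n, 0.0, 1.0)
    # every normal in the window must itself be defined
    all_ok = window_all_valid(ok, window)
    values = np.where(all_ok, values, np.nan)
    return MetricGrid(values, "vrm", dem.cell_size, all_ok)


# ---------------------------------------------------------------------------
# Curvature (Zevenbergen–Thorne)
# ---------------------------------------------------------------------------

def curvature(
    dem: DemGrid, scale: float = 100.0
) -> tuple[MetricGrid, MetricGrid]:
    """Profile and planform curvature from the Zevenbergen–Thorne surface.

    A partial quartic ``z = ... + Dx² + Ey² + Fxy + Gx + Hy + I`` is fit
    exactly to each 3x3 window; curvatures derive from the second-order
    coefficients:

    * profile curvature — rate of slope change **parallel** to the
      downslope direction; sign convention: convex-upward positive;
    * planform curvature — rate of slope change **perpendicular** to the
      downslope direction (flow convergence/divergence).

    Both are multiplied by ``scale`` (default 100, the common GIS reporting
    convention; pass ``scale=1.0`` for raw 1/m units). Cells with zero
    gradient have no downslope direction and report 0 — a flat or uniformly
    inclined plane has curvature 0 everywhere.
    """
    z = dem.elevations
    L = dem.cell_size
    z1, z2, z3 = z[:-2, :-2], z[:-2, 1:-1], z[:-2, 2:]
    z4, z5, z6 = z[1:-1, :-2], z[1:-1, 1:-1], z[1:-1, 2:]
    z7, z8, z9 = z[2:, :-2], z[2:, 1:-1], z[2:, 2:]
    D = ((z4 + z6) / 2.0 - z5) / (L * L)
    E = ((z2 + z8) / 2.0 - z5) / (L * L)
    F = (-z1 + z3 + z7 - z9) / (4.0 * L * L)
    G = (z6 - z4) / (2.0 * L)
    H = (z2 - z8) / (2.0 * L)
    g2 = G * G + H * H
    with np.errstate(divide="ignore", invalid="ignore"):
        prof = -2.0 * (D * G * G + E * H * H + F * G * H) / g2
        plan = 2.0 * (D * H * H + E * G * G - F * G * H) / g2
    prof = np.where(g2 == 0.0, 0.0, prof) * scale
    plan = np.where(g2 == 0.0, 0.0, plan) * scale
    ok = window_all_valid(dem.valid, 3)
    profile = np.full(z.shape, np.nan)
    planform = np.full(z.shape, np.nan)
    profile[1:-1, 1:-1] = prof
    planform[1:-1, 1:-1] = plan
    profile = np.where(ok, profile, np.nan)
    planform = np.where(ok, planform, np.nan)
    return (
        MetricGrid(profile, "profile_curv", dem.cell_size, ok),
        MetricGrid(planform, "planform_curv", dem.cell_size, ok),
    )
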