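"""Independent brute-force reference implementations.

Every function here recomputes a metric by direct, unvectorized evaluation
of the defining formulas — explicit stencils, per-triangle cross products,
per-block loops — and shares no code path with the package. They exist so
the vectorized implementations can be checked cell-by-cell on small random
grids.
"""

import math

import numpy as np


def horn_gradients_center(z3: np.ndarray, cell: float) -> tuple[float, float]:
    """(dz/dx east, dz/dy north) of the center of a 3x3 window, Horn weights."""
    a, b, c = z3[0]
    d, _, f = z3[1]
    g, h, i = z3[2]
    p = ((c + 2 * f + i) - (a + 2 * d + g)) / (8 * cell)
    q = ((a + 2 * b + c) - (g + 2 * h + i)) / (8 * cell)
    return p, q


def slope_deg_center(z3: np.ndarray, cell: float) -> float:
    p, q = horn_gradients_center(z3, cell)
    return math.degrees(math.atan(math.hypot(p, q)))


def aspect_deg_center(z3: np.ndarray, cell: float) -> float:
    """Compass direction of steepest descent; -1 where slope is zero."""
    p, q = horn_gradients_center(z3, cell)
    if p == 0.0 and q == 0.0:
        return -1.0
    return math.degrees(math.atan2(-p, -q)) % 360.0


def unit_normal_center(z3: np.ndarray, cell: float) -> tuple[float, float, float]:
    """Unit surface normal from slope and aspect, vertical where flat."""
    p, q = horn_gradients_center(z3, cell)
    theta = math.atan(math.hypot(p, q))
    if p == 0.0 and q == 0.0:
        return (0.0, 0.0, 1.0)
    alpha = math.atan2(-p, -q)
    return (
        math.sin(theta) * math.sin(alpha),
        math.sin(theta) * math.cos(alpha),
        math.cos(theta),
    )


def vrm_center(z5: np.ndarray, cell: float) -> float:
    """VRM of the center cell of a 5x5 grid by explicit vector summation."""
    sx = sy = sz = 0.0
    for r in range(1, 4):
        for c in range(1, 4):
            nx, ny, nz = unit_normal_center(z5[r - 1:r + 2, c - 1:c + 2], cell)
            sx += nx
            sy += ny
            sz += nz
    resultant = math.sqrt(sx * sx + sy * sy + sz * sz)
    return 1.0 - resultant / 9.0


def zt_curvature_center(
    z3: np.ndarray, cell: float, scale: float = 100.0
) -> tuple[float, float]:
    """(profile, planform) curvature of a 3x3 center, Zevenbergen–Thorne."""
    L = cell
    z1, z2, z3_ = z3[0]
    z4, z5, z6 = z3[1]
    z7, z8, z9 = z3[2]
    D = ((z4 + z6) / 2 - z5) / (L * L)
    E = ((z2 + z8) / 2 - z5) / (L * L)
    F = (-z1 + z3_ + z7 - z9) / (4 * L * L)
    G = (z6 - z4) / (2 * L)
    H = (z2 - z8) / (2 * L)
    g2 = G * G + H * H
    if g2 == 0.0:
        return 0.0, 0.0
    profile = -2.0 * (D * G * G + E * H * H + F * G * H) / g2
    planform = 2.0 * (D * H * H + E * G * G - F * G * H) / g2
    return profile * scale, planform * scale


def surface_area_triangles(
    z: np.ndarray, cell: float, valid: np.ndarray | None = None
) -> tuple[float, float]:
    """(3-D area, 2-D area) summing every quad's two triangles explicitly.

    Quads split along the diagonal from the lower-left (south-west) corner,
    matching the package's stated triangulation convention.
    """
    if valid is None:
        valid = np.ones(z.shape, dtype=bool)
    rows, cols = z.shape
    a3 = a2 = 0.0
    for r in range(rows - 1):
        for c in range(cols - 1):
            if not (valid[r, c] & valid[r, c + 1] & valid[r + 1, c] & valid[r + 1, c + 1]):
                continue
            # 3-D corner points; row r+1 lies south of row r
            ul = np.array([0.0, cell, z[r, c]])
            ur = np.array([cell, cell, z[r, c + 1]])
            ll = np.array([0.0, 0.0, z[r + 1, c]])
            lr = np.array([cell, 0.0, z[r + 1, c + 1]])
            for p1, p2, p3 in ((ll, lr, ur), (ll, ur, ul)):
                cross = np.cross(p2 - p1, p3 - p1)
                a3 += 0.5 * float(np.linalg.norm(cross))
            a2 += cell * cell
    return a3, a2


def block_mean_aggregate(
    z: np.ndarray, valid: np.ndarray, factor: int
) -> tuple[np.ndarray, np.ndarray]:
    """Block-mean coarsening by explicit loops, dropping partial blocks."""
    rows, cols = z.shape
    br, bc = rows // factor, cols // factor
    out = np.zeros((br, bc))
    mask = np.zeros((br, bc), dtype=bool)
    for i in range(br):
        for j in range(bc):
            vals = []
            for di in range(factor):
                for dj in range(factor):
                    r, c = i * factor + di, j * factor + dj
                    if valid[r, c]:
                        vals.append(z[r, c])
            if vals:
                out[i, j] = sum(vals) / len(vals)
            else:
                mask[i, j] = True
    return out, mask


def two_pass_mean_sd(values) -> tuple[float, float]:
    """Population mean and SD by an explicit two-pass accumulation."""
    values = list(values)
    n = len(values)
    mean = sum(values) / n
    var = sum((v - mean) ** 2 for v in values) / n
    return mean, math.sqrt(var)
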