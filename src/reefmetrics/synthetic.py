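"""Seeded synthetic reef DEM generator.

The study DEMs are not deposited, so testing the metric pipeline end-to-end
requires surfaces that emulate the *statistical* structure of the two survey
states:

* a **tabulate** scene — the pre-disturbance state: a rugose base (reef
  framework) densely covered by elevated, gently tilted elliptical plates
  (tabulate *Acropora*) whose rasterized edges are abrupt vertical drops,
  with fine correlated texture standing in for turf and corallite relief
  that a 1-cm DEM renders as nearly level;
* a **rubble** scene — the post-disturbance state: a flatter base strewn
  with small decimeter-scale spherical-cap clasts that create high-frequency
  slope/aspect variation, interspersed with smooth sand patches;

plus three control morphologies (**flat**, **incline**, **mound**) used for
analytic limits and the standard test battery.

Every scene couples a DEM to a per-cell benthic label map so the percent-
cover stage is testable against known ground truth. Generation is fully
deterministic for a given spec + seed. These are geometric caricatures:
plate/clast geometry is a stated assumption, not a claim about real reefs.
"""

from __future__ import annotations

import math
from dataclasses import asdict, dataclass

import numpy as np
from scipy.ndimage import gaussian_filter

from .errors import ValidationError
from .grid import DemGrid

SCENE_TYPES = ("flat", "incline", "tabulate", "rubble", "mound")

#: Controlled benthic vocabulary used by the generator's label maps.
LABEL_CORAL_TABULATE = "coral_tabulate_acropora"
LABEL_CORAL_MOUNDING = "coral_mounding"
LABEL_TURF_HARD = "turf_on_hard"
LABEL_TURF_RUBBLE = "turf_on_rubble"
LABEL_SAND = "sand"


@dataclass(frozen=True)
class SceneSpec:
    """Parameters of a synthetic reef surface.

    Geometry defaults mirror the study plot: a 10 x 5 m extent at 0.01-m
    cells. Type-specific parameters are order-of-magnitude choices for
    NW-Hawaiian tabulate *Acropora* stands and post-storm rubble fields;
    none are measured values (the source imagery reports cover fractions,
    not plate or clast geometry). Lengths are meters, fractions in [0, 1],
    angles in degrees.
    """

    scene_type: str
    extent: tuple[float, float] = (10.0, 5.0)
    cell_size: float = 0.01
    seed: int = 0
    base_elevation: float = 0.0

    # incline
    gradient: float = 0.5

    # tabulate: target plate cover mirrors the 69.7% tabulate Acropora
    # cover of the pre-disturbance survey
    plate_cover_fraction: float = 0.70
    plate_height: tuple[float, float] = (0.2, 0.4)
    plate_radius: tuple[float, float] = (0.3, 0.7)
    plate_tilt_max_deg: float = 30.0
    plate_texture_sd: float = 0.004
    plate_texture_corr: float = 0.03
    base_relief_sd: float = 0.06
    base_relief_corr: float = 0.20
    fine_roughness_sd: float = 0.001

    # rubble: sand fraction mirrors the 31.8% sand of the post-disturbance
    # survey; clasts are decimeter-scale spherical caps
    clast_density: float = 250.0
    clast_radius: tuple[float, float] = (0.02, 0.06)
    clast_height: tuple[float, float] = (0.015, 0.04)
    sand_fraction: float = 0.32
    rubble_base_sd: float = 0.012
    rubble_base_corr: float = 0.30
    rubble_fine_sd: float = 0.0015
    sand_patch_corr: float = 0.50

    # mound
    mound_count: int = 6
    mound_radius: tuple[float, float] = (0.6, 1.2)
    mound_height: tuple[float, float] = (0.3, 0.5)

    def __post_init__(self) -> None:
        def fail(name: str, why: str):
            raise ValidationError(f"SceneSpec.{name}: {why}")

        if self.scene_type not in SCENE_TYPES:
            fail("scene_type", f"{self.scene_type!r} not in {SCENE_TYPES}")
        if self.extent[0] <= 0 or self.extent[1] <= 0:
            fail("extent", f"must be positive, got {self.extent}")
        if self.cell_size <= 0:
            fail("cell_size", f"must be positive, got {self.cell_size}")
        if (
            self.extent[0] / self.cell_size < 3
            or self.extent[1] / self.cell_size < 3
        ):
            fail("extent", "extent/cell_size must yield at least 3x3 cells")
        for name in ("plate_cover_fraction", "sand_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                fail(name, f"fraction must be in [0, 1], got {v}")
        for name in (
            "plate_height", "plate_radius", "clast_radius",
            "clast_height", "mound_radius", "mound_height",
        ):
            lo, hi = getattr(self, name)
            if lo <= 0 or hi <= 0 or lo > hi:
                fail(name, f"must be a positive (lo, hi) range, got {(lo, hi)}")
        for name in (
            "plate_texture_sd", "plate_texture_corr", "base_relief_sd",
            "base_relief_corr", "fine_roughness_sd", "clast_density",
            "rubble_base_sd", "rubble_base_corr", "rubble_fine_sd",
            "sand_patch_corr",
        ):
            if getattr(self, name) <= 0:
                fail(name, f"must be positive, got {getattr(self, name)}")
        if self.plate_tilt_max_deg < 0 or self.plate_tilt_max_deg >= 90:
            fail("plate_tilt_max_deg", "must be in [0, 90)")
        if self.mound_count < 1:
            fail("mound_count", "must be >= 1")

    @property
    def shape(self) -> tuple[int, int]:
        return (
            int(round(self.extent[1] / self.cell_size)),
            int(round(self.extent[0] / self.cell_size)),
        )

    def to_dict(self) -> dict:
        d = asdict(self)
        d["extent"] = list(self.extent)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SceneSpec":
        d = dict(d)
        for key in (
            "extent", "plate_height", "plate_radius", "clast_radius",
            "clast_height", "mound_radius", "mound_height",
        ):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)


@dataclass
class Scene:
    """A synthetic DEM coupled to its per-cell benthic label map."""

    dem: DemGrid
    label_map: np.ndarray  # integer codes into `categories`, dem-aligned
    categories: tuple[str, ...]
    spec: SceneSpec

    def __post_init__(self) -> None:
        if self.label_map.shape != self.dem.shape:
            raise ValidationError("label_map must be aligned to the DEM grid")

    def label_at(self, x: float, y: float) -> str:
        """Benthic category of the cell containing (x, y), half-open cells."""
        r, c = self.dem.cell_of(x, y)
        return self.categories[self.label_map[r, c]]

    def label_fractions(self) -> dict[str, float]:
        """Fraction of cells per category (sums to 1)."""
        counts = np.bincount(self.label_map.ravel(), minlength=len(self.categories))
        total = self.label_map.size
        return {c: counts[i] / total for i, c in enumerate(self.categories)}


# ---------------------------------------------------------------------------
# random-field helpers
# ---------------------------------------------------------------------------

def _correlated_field(
    rng: np.random.Generator, shape: tuple[int, int], sd: float, corr_cells: float
) -> np.ndarray:
    """Zero-mean Gaussian random field with a Gaussian correlation kernel."""
    noise = rng.standard_normal(shape)
    f = gaussian_filter(noise, sigma=corr_cells, mode="reflect")
    s = f.std()
    if s > 0:
        f *= sd / s
    return f


def _cap_height(d2: np.ndarray, radius: float, height: float) -> np.ndarray:
    """Spherical-cap elevation above its base for squared distances d2."""
    rho = (radius * radius + height * height) / (2.0 * height)
    z = np.sqrt(np.maximum(rho * rho - d2, 0.0)) - (rho - height)
    return np.where(d2 <= radius * radius, np.maximum(z, 0.0), 0.0)


class _SceneCanvas:
    """Shared raster scaffolding: coordinates, bbox windows, feature blitting."""

    def __init__(self, spec: SceneSpec):
        self.spec = spec
        self.nrows, self.ncols = spec.shape
        self.cs = spec.cell_size
        self.x0, self.y0 = 0.0, 0.0
        # cell-center coordinates; row 0 is the northernmost row
        self.xs = self.x0 + (np.arange(self.ncols) + 0.5) * self.cs
        self.ys = self.y0 + (self.nrows - 1 - np.arange(self.nrows) + 0.5) * self.cs

    def bbox(self, cx: float, cy: float, rad: float):
        """Row/col slice generously covering a disc of radius rad."""
        c_lo = max(0, int(math.floor((cx - rad - self.x0) / self.cs)) - 1)
        c_hi = min(self.ncols, int(math.ceil((cx + rad - self.x0) / self.cs)) + 1)
        r_lo = max(0, self.nrows - int(math.ceil((cy + rad - self.y0) / self.cs)) - 1)
        r_hi = min(
            self.nrows, self.nrows - int(math.floor((cy - rad - self.y0) / self.cs)) + 1
        )
        return slice(r_lo, r_hi), slice(c_lo, c_hi)

    def local_coords(self, rs: slice, cs_: slice):
        dx = self.xs[cs_][np.newaxis, :]
        dy = self.ys[rs][:, np.newaxis]
        return dx, dy


# ---------------------------------------------------------------------------
# scene builders
# ---------------------------------------------------------------------------

def generate_scene(spec: SceneSpec) -> Scene:
    """Build the DEM + label map for a :class:`SceneSpec`.

    Deterministic for a given spec (including its seed): identical calls
    return bitwise-identical scenes.
    """
    rng = np.random.default_rng(spec.seed)
    builders = {
        "flat": _build_flat,
        "incline": _build_incline,
        "tabulate": _build_tabulate,
        "rubble": _build_rubble,
        "mound": _build_mound,
    }
    elevations, label_map, categories = builders[spec.scene_type](spec, rng)
    dem = DemGrid(
        elevations + spec.base_elevation, cell_size=spec.cell_size, origin=(0.0, 0.0)
    )
    return Scene(dem=dem, label_map=label_map, categories=categories, spec=spec)


def _build_flat(spec: SceneSpec, rng: np.random.Generator):
    shape = spec.shape
    return (
        np.zeros(shape),
        np.zeros(shape, dtype=np.uint8),
        (LABEL_SAND,),
    )


def _build_incline(spec: SceneSpec, rng: np.random.Generator):
    canvas = _SceneCanvas(spec)
    z = spec.gradient * np.broadcast_to(canvas.xs, spec.shape).copy()
    return z, np.zeros(spec.shape, dtype=np.uint8), (LABEL_TURF_HARD,)


def _build_tabulate(spec: SceneSpec, rng: np.random.Generator):
    canvas = _SceneCanvas(spec)
    shape = spec.shape
    cs = spec.cell_size
    base = _correlated_field(rng, shape, spec.base_relief_sd, spec.base_relief_corr / cs)

    plate_top = np.full(shape, -np.inf)
    covered = np.zeros(shape, dtype=bool)
    target_cells = spec.plate_cover_fraction * covered.size
    n_covered = 0
    # dart-throwing until the plate union reaches the target cover fraction
    max_tries = 200000
    tries = 0
    while n_covered < target_cells and tries < max_tries:
        tries += 1
        cx = rng.uniform(0.0, spec.extent[0])
        cy = rng.uniform(0.0, spec.extent[1])
        a = rng.uniform(*spec.plate_radius)
        b = a * rng.uniform(0.7, 1.0)
        phi = rng.uniform(0.0, np.pi)
        h = rng.uniform(*spec.plate_height)
        tilt = math.tan(math.radians(rng.uniform(0.0, spec.plate_tilt_max_deg)))
        az = rng.uniform(0.0, 2.0 * np.pi)
        rs, cs_ = canvas.bbox(cx, cy, a)
        if rs.start >= rs.stop or cs_.start >= cs_.stop:
            continue
        x, y = canvas.local_coords(rs, cs_)
        dx, dy = x - cx, y - cy
        u = dx * math.cos(phi) + dy * math.sin(phi)
        v = -dx * math.sin(phi) + dy * math.cos(phi)
        inside = (u / a) ** 2 + (v / b) ** 2 <= 1.0
        zp = h + tilt * (dx * math.cos(az) + dy * math.sin(az))
        plate_top[rs, cs_] = np.where(
            inside, np.maximum(plate_top[rs, cs_], zp), plate_top[rs, cs_]
        )
        newly = inside & ~covered[rs, cs_]
        n_covered += int(newly.sum())
        covered[rs, cs_] |= inside

    z = np.maximum(base, plate_top)
    on_plate = plate_top > base
    # fine correlated texture: turf/corallite relief as rendered at 1 cm
    texture = _correlated_field(
        rng, shape, spec.plate_texture_sd, spec.plate_texture_corr / cs
    )
    z = z + texture + rng.standard_normal(shape) * spec.fine_roughness_sd
    labels = np.where(on_plate, 0, 1).astype(np.uint8)
    return z, labels, (LABEL_CORAL_TABULATE, LABEL_TURF_HARD)


def _build_rubble(spec: SceneSpec, rng: np.random.Generator):
    canvas = _SceneCanvas(spec)
    shape = spec.shape
    cs = spec.cell_size
    # contiguous sand patches from the low quantile of a smooth field
    patch_field = _correlated_field(rng, shape, 1.0, spec.sand_patch_corr / cs)
    threshold = np.quantile(patch_field, spec.sand_fraction)
    sand = patch_field <= threshold

    base = _correlated_field(rng, shape, spec.rubble_base_sd, spec.rubble_base_corr / cs)
    clast_field = np.zeros(shape)
    area = spec.extent[0] * spec.extent[1]
    n_clasts = int(round(spec.clast_density * area))
    for _ in range(n_clasts):
        cx = rng.uniform(0.0, spec.extent[0])
        cy = rng.uniform(0.0, spec.extent[1])
        r = rng.uniform(*spec.clast_radius)
        h = rng.uniform(*spec.clast_height)
        rs, cs_ = canvas.bbox(cx, cy, r)
        if rs.start >= rs.stop or cs_.start >= cs_.stop:
            continue
        row_c = min(max(int((cy - canvas.y0) / cs), 0), shape[0] - 1)
        row_c = shape[0] - 1 - row_c
        col_c = min(max(int((cx - canvas.x0) / cs), 0), shape[1] - 1)
        if sand[row_c, col_c]:
            continue  # sand patches stay smooth
        x, y = canvas.local_coords(rs, cs_)
        d2 = (x - cx) ** 2 + (y - cy) ** 2
        clast_field[rs, cs_] = np.maximum(clast_field[rs, cs_], _cap_height(d2, r, h))

    roughness = rng.standard_normal(shape) * spec.rubble_fine_sd
    roughness[sand] *= 0.2  # sand is smooth relative to rubble
    z = base + clast_field + roughness
    labels = np.where(sand, 1, 0).astype(np.uint8)
    return z, labels, (LABEL_TURF_RUBBLE, LABEL_SAND)


def _build_mound(spec: SceneSpec, rng: np.random.Generator):
    canvas = _SceneCanvas(spec)
    shape = spec.shape
    mound_field = np.zeros(shape)
    on_mound = np.zeros(shape, dtype=bool)
    for _ in range(spec.mound_count):
        cx = rng.uniform(0.0, spec.extent[0])
        cy = rng.uniform(0.0, spec.extent[1])
        r = rng.uniform(*spec.mound_radius)
        h = rng.uniform(*spec.mound_height)
        rs, cs_ = canvas.bbox(cx, cy, r)
        if rs.start >= rs.stop or cs_.start >= cs_.stop:
            continue
        x, y = canvas.local_coords(rs, cs_)
        d2 = (x - cx) ** 2 + (y - cy) ** 2
        cap = _cap_height(d2, r, h)
        mound_field[rs, cs_] = np.maximum(mound_field[rs, cs_], cap)
        on_mound[rs, cs_] |= cap > 0.0
    z = mound_field + rng.standard_normal(shape) * spec.fine_roughness_sd
    labels = np.where(on_mound, 0, 1).astype(np.uint8)
    return z, labels, (LABEL_CORAL_MOUNDING, LABEL_TURF_HARD)


# ---------------------------------------------------------------------------
# standard battery
# ---------------------------------------------------------------------------

def scene_battery(seed: int, extent: tuple[float, float] = (10.0, 5.0),
                  cell_size: float = 0.01) -> list[Scene]:
    """One default scene per scene type, deterministically seeded.

    Scene k gets seed ``seed + k`` so the battery is reproducible
    bit-for-bit from a single integer while each scene draws an
    independent stream.
    """
    scenes = []
    for k, scene_type in enumerate(SCENE_TYPES):
        spec = SceneSpec(
            scene_type=scene_type, extent=extent, cell_size=cell_size, seed=seed + k
        )
        scenes.append(generate_scene(spec))
    return scenes
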