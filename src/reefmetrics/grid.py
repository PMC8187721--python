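"""Grid containers for elevation rasters and derived per-cell metrics.

A :class:`DemGrid` is a 2.5-D elevation raster: a rectangular array of
elevations (meters) on square cells, with row 0 the northernmost row (the
usual raster convention) and the origin recorded as the x/y of the
lower-left (south-west) corner in a local metric coordinate system.
Overhanging structure is absent by construction — a DEM is a single-valued
surface seen from directly overhead.

A :class:`MetricGrid` holds one per-cell metric aligned to its source DEM.
Cells without the full unmasked neighborhood a metric needs are invalid and
carry NaN; population statistics are always computed over valid cells only.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ValidationError

#: Metric identifiers used across the package.
METRIC_NAMES = ("slope_deg", "aspect_deg", "vrm", "profile_curv", "planform_curv")


@dataclass
class DemGrid:
    """Single-band elevation raster on square cells.

    Parameters
    ----------
    elevations:
        2-D float array of elevations in meters. Values under the nodata
        mask are ignored and need not be finite.
    cell_size:
        Edge length of a (square) cell in meters. The study exports DEMs at
        0.01 m cells.
    origin:
        ``(x, y)`` of the lower-left corner in meters, local coordinates.
    nodata_mask:
        Boolean array, same shape, True where a cell is invalid. Defaults to
        all-valid.
    """

    elevations: np.ndarray
    cell_size: float
    origin: tuple[float, float] = (0.0, 0.0)
    nodata_mask: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.elevations = np.asarray(self.elevations, dtype=float)
        if self.elevations.ndim != 2:
            raise ValidationError(
                f"elevations must be 2-D, got {self.elevations.ndim}-D"
            )
        if self.elevations.shape[0] < 1 or self.elevations.shape[1] < 1:
            raise ValidationError(
                f"grid must hold at least one cell, got {self.elevations.shape}"
            )
        if not np.isfinite(self.cell_size) or self.cell_size <= 0:
            raise ValidationError(f"cell_size must be positive, got {self.cell_size}")
        self.cell_size = float(self.cell_size)
        self.origin = (float(self.origin[0]), float(self.origin[1]))
        if self.nodata_mask is None:
            self.nodata_mask = np.zeros(self.elevations.shape, dtype=bool)
        else:
            self.nodata_mask = np.asarray(self.nodata_mask, dtype=bool)
            if self.nodata_mask.shape != self.elevations.shape:
                raise ValidationError(
                    "nodata_mask shape "
                    f"{self.nodata_mask.shape} != elevations shape "
                    f"{self.elevations.shape}"
                )
        if not np.all(np.isfinite(self.elevations[~self.nodata_mask])):
            raise ValidationError("non-masked elevations must all be finite")

    # -- geometry ---------------------------------------------------------
    @property
    def shape(self) -> tuple[int, int]:
        return self.elevations.shape

    @property
    def n_rows(self) -> int:
        return self.elevations.shape[0]

    @property
    def n_cols(self) -> int:
        return self.elevations.shape[1]

    @property
    def valid(self) -> np.ndarray:
        """Boolean array, True where the cell carries a usable elevation."""
        return ~self.nodata_mask

    @property
    def extent(self) -> tuple[float, float]:
        """(width, height) of the grid in meters."""
        return (self.n_cols * self.cell_size, self.n_rows * self.cell_size)

    def cell_of(self, x: float, y: float) -> tuple[int, int]:
        """Map a point to its (row, col) by the half-open convention.

        A point belongs to the cell whose footprint is ``[x0, x0+cs) x
        [y0, y0+cs)``. Raises :class:`ValidationError` for points outside
        the grid extent.
        """
        col = int(np.floor((x - self.origin[0]) / self.cell_size))
        row_from_south = int(np.floor((y - self.origin[1]) / self.cell_size))
        row = self.n_rows - 1 - row_from_south
        if not (0 <= col < self.n_cols and 0 <= row < self.n_rows):
            raise ValidationError(
                f"point ({x}, {y}) lies outside the grid extent"
            )
        return row, col

    def copy(self) -> "DemGrid":
        return DemGrid(
            self.elevations.copy(),
            self.cell_size,
            self.origin,
            self.nodata_mask.copy(),
        )


@dataclass
class MetricGrid:
    """One per-cell metric aligned to a source :class:`DemGrid`.

    ``values`` carries NaN at invalid cells; ``valid_mask`` is True where the
    metric is defined (the full neighborhood the metric needs was unmasked,
    plus any metric-specific condition such as nonzero slope for aspect).
    ``resolution`` is the cell size of the grid the metric was computed on.
    """

    values: np.ndarray
    metric_name: str
    resolution: float
    valid_mask: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.valid_mask = np.asarray(self.valid_mask, dtype=bool)
        if self.values.shape != self.valid_mask.shape:
            raise ValidationError("values and valid_mask shapes differ")
        if self.metric_name not in METRIC_NAMES:
            raise ValidationError(
                f"unknown metric_name {self.metric_name!r}; expected one of "
                f"{METRIC_NAMES}"
            )
        v = self.values[self.valid_mask]
        if v.size and not np.all(np.isfinite(v)):
            raise ValidationError("valid cells must hold finite metric values")
        if self.metric_name == "vrm" and v.size:
            if v.min() < 0.0 or v.max() > 1.0:
                raise ValidationError("VRM values must lie in [0, 1]")
        if self.metric_name == "slope_deg" and v.size:
            if v.min() < 0.0 or v.max() > 90.0:
                raise ValidationError("slope values must lie in [0, 90] degrees")
        if self.metric_name == "aspect_deg" and v.size:
            if v.min() < 0.0 or v.max() >= 360.0:
                raise ValidationError("aspect values must lie in [0, 360)")

    @property
    def valid_values(self) -> np.ndarray:
        """1-D array of the metric at valid cells."""
        return self.values[self.valid_mask]

    @property
    def n_valid(self) -> int:
        return int(self.valid_mask.sum())


def window_all_valid(valid: np.ndarray, window: int = 3) -> np.ndarray:
    """True where the full ``window x window`` neighborhood is valid.

    Edge cells (incomplete neighborhood) are False. Used by every 3x3-window
    metric to exclude nodata-adjacent and border cells rather than fabricate
    elevations by padding.
    """
    if window % 2 != 1 or window < 1:
        raise ValidationError(f"window must be a positive odd integer, got {window}")
    from scipy.ndimage import minimum_filter

    out = minimum_filter(valid.astype(np.uint8), size=window, mode="constant", cval=0)
    return out.astype(bool)
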