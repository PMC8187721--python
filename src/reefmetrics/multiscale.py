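"""Block-mean aggregation of DEMs and multi-resolution VRM.

A 1-cm DEM is coarsened to 2- and 4-cm cells by averaging non-overlapping
``factor x factor`` blocks, then VRM is recomputed on the coarse grid. The
resolution ladder matters scientifically: fine cells capture the high-
frequency orientation texture of rubble and coral branches, while coarse
cells capture the broad geometry of plate and mound morphologies — the two
can move in opposite directions after a disturbance.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ValidationError
from .grid import DemGrid, MetricGrid
from .metrics import vrm


@dataclass(frozen=True)
class AggregationSpec:
    """Block aggregation parameters.

    ``factor`` is the number of fine cells per coarse cell edge;
    ``statistic`` is fixed to the block mean; ``truncation_policy`` controls
    trailing blocks that do not fill a full ``factor x factor`` footprint:
    ``drop_partial_blocks`` (default) discards them, ``expand`` keeps them
    as the mean of the cells present.
    """

    factor: int
    statistic: str = "mean"
    truncation_policy: str = "drop_partial_blocks"

    def __post_init__(self) -> None:
        if int(self.factor) != self.factor or self.factor < 1:
            raise ValidationError(f"factor must be a positive integer, got {self.factor}")
        if self.statistic != "mean":
            raise ValidationError(f"unsupported statistic {self.statistic!r}")
        if self.truncation_policy not in ("drop_partial_blocks", "expand"):
            raise ValidationError(
                f"unknown truncation_policy {self.truncation_policy!r}"
            )


def aggregate(dem: DemGrid, spec: AggregationSpec | int) -> DemGrid:
    """Coarsen a DEM by block-averaging unmasked cells.

    Each output cell is the mean of the unmasked cells in its
    ``factor x factor`` block; blocks with no unmasked cell become masked.
    Output ``cell_size`` is the input's times the factor. With the default
    truncation policy, trailing rows/columns that do not complete a block
    are dropped (they lie on the south and east edges, so the stored origin
    shifts north by the dropped rows). Factor 1 returns a copy.
    """
    if isinstance(spec, (int, np.integer)):
        spec = AggregationSpec(int(spec))
    f = int(spec.factor)
    if f == 1:
        return dem.copy()
    rows, cols = dem.shape
    if f > rows or f > cols:
        raise ValidationError(
            f"aggregation factor {f} exceeds grid dimensions {dem.shape}"
        )
    z = np.where(dem.valid, dem.elevations, 0.0)
    w = dem.valid.astype(float)
    drop = spec.truncation_policy == "drop_partial_blocks"
    if drop:
        r2, c2 = (rows // f) * f, (cols // f) * f
        z, w = z[:r2, :c2], w[:r2, :c2]
        n_dropped_rows = rows - r2
    else:
        pr = (-rows) % f
        pc = (-cols) % f
        z = np.pad(z, ((0, pr), (0, pc)))
        w = np.pad(w, ((0, pr), (0, pc)))
        n_dropped_rows = 0
    br, bc = z.shape[0] // f, z.shape[1] // f
    zsum = z.reshape(br, f, bc, f).sum(axis=(1, 3))
    wsum = w.reshape(br, f, bc, f).sum(axis=(1, 3))
    mask = wsum == 0.0
    with np.errstate(invalid="ignore", divide="ignore"):
        mean = np.where(mask, 0.0, zsum / np.where(mask, 1.0, wsum))
    origin = (dem.origin[0], dem.origin[1] + n_dropped_rows * dem.cell_size)
    if not drop and (rows % f or cols % f):
        # padded blocks extend the footprint south/east of the original
        origin = (dem.origin[0], dem.origin[1] - ((-rows) % f) * dem.cell_size)
    return DemGrid(mean, cell_size=dem.cell_size * f, origin=origin, nodata_mask=mask)


def vrm_at_resolutions(
    dem: DemGrid,
    factors: list[int] = (1, 2, 4),
    window: int = 3,
    truncation_policy: str = "drop_partial_blocks",
) -> dict[float, MetricGrid]:
    """VRM computed at a ladder of resolutions derived from one fine DEM.

    For each factor, the DEM is block-aggregated (factor 1 = native
    resolution) and VRM is computed on the result. Returns a mapping from
    output cell size (meters) to the VRM grid, e.g. a 0.01-m DEM with
    factors (1, 2, 4) yields keys 0.01, 0.02, 0.04.
    """
    out: dict[float, MetricGrid] = {}
    for f in factors:
        coarse = aggregate(dem, AggregationSpec(f, truncation_policy=truncation_policy))
        out[coarse.cell_size] = vrm(coarse, window=window)
    return out
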