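"""Raster I/O: GeoTIFF and ESRI ASCII grid readers/writers for DEMs.

Two plain single-band formats are supported:

* **GeoTIFF** — float32 band; cell size from ``ModelPixelScaleTag``, origin
  from ``ModelTiepointTag``, nodata from the ``GDAL_NODATA`` ASCII tag.
  Backed by :mod:`tifffile`.
* **ESRI ASCII grid** — the classic ``ncols/nrows/xllcorner/yllcorner/
  cellsize/NODATA_value`` text header followed by rows of elevations,
  northernmost row first.

Both readers return a :class:`~reefmetrics.grid.DemGrid` with nodata cells
masked; both writers round-trip elevations, cell size, origin and mask.
Coordinate reference systems and reprojection are out of scope — the study
plots live in a local metric coordinate system.
"""

from __future__ import annotations

import os

import numpy as np
import tifffile

from .errors import RasterIOError, ValidationError
from .grid import DemGrid

#: ESRI convention sentinel written for masked cells.
DEFAULT_NODATA = -9999.0

_TAG_MODEL_PIXEL_SCALE = 33550
_TAG_MODEL_TIEPOINT = 33922
_TAG_GDAL_NODATA = 42113

_FORMATS = ("geotiff", "ascii_grid")


def _infer_format(path: str) -> str:
    ext = os.path.splitext(path)[1].lower()
    if ext in (".tif", ".tiff"):
        return "geotiff"
    if ext in (".asc", ".txt", ".grd"):
        return "ascii_grid"
    raise ValidationError(
        f"cannot infer raster format from extension {ext!r}; "
        "pass format='geotiff' or 'ascii_grid'"
    )


def read_dem(path: str, format: str | None = None) -> DemGrid:
    """Read a single-band elevation raster into a :class:`DemGrid`.

    Parameters
    ----------
    path:
        File to read.
    format:
        ``"geotiff"`` or ``"ascii_grid"``; inferred from the extension when
        omitted.

    Raises
    ------
    RasterIOError
        If the file is unreadable, multi-band, or has non-square cells.
    """
    fmt = format or _infer_format(path)
    if fmt not in _FORMATS:
        raise ValidationError(f"unknown format {fmt!r}; expected one of {_FORMATS}")
    if not os.path.exists(path):
        raise RasterIOError(f"raster file not found: {path}")
    if fmt == "geotiff":
        return _read_geotiff(path)
    return _read_ascii_grid(path)


def write_dem(dem: DemGrid, path: str, format: str | None = None) -> None:
    """Write a :class:`DemGrid` so that :func:`read_dem` reproduces it.

    GeoTIFF stores float32 (elevations round-trip to float32 precision);
    ASCII grids store decimal text. Masked cells are written as the nodata
    sentinel (−9999 for ASCII, the ``GDAL_NODATA`` tag value for GeoTIFF).
    """
    fmt = format or _infer_format(path)
    if fmt not in _FORMATS:
        raise ValidationError(f"unknown format {fmt!r}; expected one of {_FORMATS}")
    try:
        if fmt == "geotiff":
            _write_geotiff(dem, path)
        else:
            _write_ascii_grid(dem, path)
    except OSError as exc:
        raise RasterIOError(f"cannot write raster {path}: {exc}") from exc


def write_metric(grid, path: str, format: str | None = None,
                 origin: tuple[float, float] = (0.0, 0.0)) -> None:
    """Export a :class:`~reefmetrics.grid.MetricGrid` as a raster.

    Valid cells carry the metric value; invalid cells are written as
    nodata. The grid's resolution becomes the raster cell size.
    """
    data = np.where(grid.valid_mask, grid.values, 0.0)
    dem = DemGrid(
        data, cell_size=grid.resolution, origin=origin,
        nodata_mask=~grid.valid_mask,
    )
    write_dem(dem, path, format=format)


# ---------------------------------------------------------------------------
# GeoTIFF
# ---------------------------------------------------------------------------

def _read_geotiff(path: str) -> DemGrid:
    try:
        tif = tifffile.TiffFile(path)
    except Exception as exc:  # noqa: BLE001 - surface as I/O error
        raise RasterIOError(f"cannot read GeoTIFF {path}: {exc}") from exc
    with tif:
        page = tif.pages[0]
        data = page.asarray()
        if data.ndim != 2:
            raise RasterIOError(
                f"{path}: expected a single-band raster, got array of shape "
                f"{data.shape}"
            )
        tags = page.tags
        scale_tag = tags.get(_TAG_MODEL_PIXEL_SCALE)
        if scale_tag is None:
            raise RasterIOError(
                f"{path}: no ModelPixelScaleTag; cell size is unknown"
            )
        sx, sy = float(scale_tag.value[0]), float(scale_tag.value[1])
        if not np.isclose(sx, sy, rtol=1e-9, atol=0.0):
            raise RasterIOError(
                f"{path}: non-square cells (x edge {sx} m, y edge {sy} m)"
            )
        tie_tag = tags.get(_TAG_MODEL_TIEPOINT)
        if tie_tag is not None:
            # tiepoint maps raster (0, 0) = upper-left corner to model space
            x_ul, y_ul = float(tie_tag.value[3]), float(tie_tag.value[4])
            origin = (x_ul, y_ul - data.shape[0] * sx)
        else:
            origin = (0.0, 0.0)
        nodata_tag = tags.get(_TAG_GDAL_NODATA)
        elevations = np.asarray(data, dtype=float)
        if nodata_tag is not None:
            nodata = float(str(nodata_tag.value))
            mask = np.isclose(elevations, nodata, rtol=1e-6) | ~np.isfinite(
                elevations
            )
        else:
            mask = ~np.isfinite(elevations)
        elevations = np.where(mask, 0.0, elevations)
    return DemGrid(elevations, cell_size=sx, origin=origin, nodata_mask=mask)


def _write_geotiff(dem: DemGrid, path: str, nodata: float = DEFAULT_NODATA) -> None:
    data = np.where(dem.nodata_mask, nodata, dem.elevations).astype(np.float32)
    x_ul = dem.origin[0]
    y_ul = dem.origin[1] + dem.n_rows * dem.cell_size
    nodata_ascii = f"{nodata:g}\x00"
    extratags = [
        (_TAG_MODEL_PIXEL_SCALE, "d", 3, (dem.cell_size, dem.cell_size, 0.0), True),
        (_TAG_MODEL_TIEPOINT, "d", 6, (0.0, 0.0, 0.0, x_ul, y_ul, 0.0), True),
        (_TAG_GDAL_NODATA, "s", len(nodata_ascii), nodata_ascii, True),
    ]
    tifffile.imwrite(path, data, extratags=extratags)


# ---------------------------------------------------------------------------
# ESRI ASCII grid
# ---------------------------------------------------------------------------

def _read_ascii_grid(path: str) -> DemGrid:
    header: dict[str, float] = {}
    n_header = 0
    try:
        with open(path, "r", encoding="ascii") as fh:
            for line in fh:
                parts = line.split()
                if len(parts) == 2 and parts[0].lower() in (
                    "ncols", "nrows", "xllcorner", "yllcorner",
                    "cellsize", "dx", "dy", "nodata_value",
                ):
                    header[parts[0].lower()] = float(parts[1])
                    n_header += 1
                else:
                    break
        body = np.loadtxt(path, skiprows=n_header, ndmin=2)
    except (OSError, ValueError) as exc:
        raise RasterIOError(f"cannot parse ASCII grid {path}: {exc}") from exc
    for key in ("ncols", "nrows"):
        if key not in header:
            raise RasterIOError(f"{path}: ASCII grid header missing {key}")
    if "cellsize" in header:
        cell = header["cellsize"]
    elif "dx" in header and "dy" in header:
        if not np.isclose(header["dx"], header["dy"], rtol=1e-9, atol=0.0):
            raise RasterIOError(
                f"{path}: non-square cells (x edge {header['dx']} m, "
                f"y edge {header['dy']} m)"
            )
        cell = header["dx"]
    else:
        raise RasterIOError(f"{path}: ASCII grid header missing cellsize")
    nrows, ncols = int(header["nrows"]), int(header["ncols"])
    if body.shape != (nrows, ncols):
        raise RasterIOError(
            f"{path}: body shape {body.shape} does not match header "
            f"({nrows}, {ncols})"
        )
    nodata = header.get("nodata_value")
    if nodata is not None:
        mask = np.isclose(body, nodata, rtol=1e-9)
    else:
        mask = ~np.isfinite(body)
    origin = (header.get("xllcorner", 0.0), header.get("yllcorner", 0.0))
    return DemGrid(
        np.where(mask, 0.0, body), cell_size=cell, origin=origin, nodata_mask=mask
    )


def _write_ascii_grid(
    dem: DemGrid, path: str, nodata: float = DEFAULT_NODATA
) -> None:
    data = np.where(dem.nodata_mask, nodata, dem.elevations)
    with open(path, "w", encoding="ascii") as fh:
        fh.write(f"ncols {dem.n_cols}\n")
        fh.write(f"nrows {dem.n_rows}\n")
        fh.write(f"xllcorner {dem.origin[0]:.10g}\n")
        fh.write(f"yllcorner {dem.origin[1]:.10g}\n")
        fh.write(f"cellsize {dem.cell_size:.10g}\n")
        fh.write(f"NODATA_value {nodata:g}\n")
        np.savetxt(fh, data, fmt="%.10g")
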