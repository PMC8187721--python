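"""Percent benthic cover from random annotation points.

Replicates the point-count arithmetic of orthomosaic annotation: uniform
random points over the plot, each labeled with a benthic category, with
points landing on survey equipment or mobile fauna removed from both the
numerator and the denominator before percent cover is computed.

Annotation and cover tables are plain :class:`pandas.DataFrame` objects so
they serialize naturally to CSV and interoperate with the usual analysis
stack.
"""

from __future__ import annotations

from collections.abc import Iterable

import numpy as np
import pandas as pd

from .errors import ValidationError
from .synthetic import Scene

#: Categories removed from the denominator by convention: survey equipment
#: and animals that moved through the frame, not benthos.
DEFAULT_EXCLUSIONS = frozenset({"transect_tape", "scale_bar", "mobile_fauna"})

ANNOTATION_COLUMNS = ("point_id", "x", "y", "label")
COVER_COLUMNS = ("category", "point_count", "percent")


def sample_points(
    extent: tuple[float, float], n: int = 1000, seed: int = 0
) -> np.ndarray:
    """Uniform random annotation points over a rectangular plot.

    Returns an ``(n, 2)`` array of (x, y) in meters, seeded and
    reproducible. The default n = 1000 matches standard orthomosaic
    annotation effort for a 10 x 5 m plot.
    """
    if n < 1:
        raise ValidationError(f"n must be >= 1, got {n}")
    w, h = float(extent[0]), float(extent[1])
    if w <= 0 or h <= 0:
        raise ValidationError(f"extent must be positive, got {extent}")
    rng = np.random.default_rng(seed)
    pts = rng.uniform(0.0, 1.0, size=(n, 2))
    pts[:, 0] *= w
    pts[:, 1] *= h
    return pts


def annotate_from_labelmap(scene: Scene, points: np.ndarray) -> pd.DataFrame:
    """Label each point by the scene's label-map cell containing it.

    Stands in for manual annotation when working on synthetic scenes: the
    generator's ground-truth label map plays the role of the human
    annotator. Cells are half-open ``[x, x+cell) x [y, y+cell)``.

    Returns an annotation table with columns (point_id, x, y, label).
    """
    points = np.asarray(points, dtype=float)
    if points.ndim != 2 or points.shape[1] != 2:
        raise ValidationError("points must be an (n, 2) array of x, y")
    dem = scene.dem
    x0, y0 = dem.origin
    w, h = dem.extent
    cols = np.floor((points[:, 0] - x0) / dem.cell_size).astype(int)
    rows_south = np.floor((points[:, 1] - y0) / dem.cell_size).astype(int)
    rows = dem.n_rows - 1 - rows_south
    bad = (cols < 0) | (cols >= dem.n_cols) | (rows < 0) | (rows >= dem.n_rows)
    if bad.any():
        first = int(np.flatnonzero(bad)[0])
        raise ValidationError(
            f"point_id {first} at ({points[first, 0]}, {points[first, 1]}) "
            f"lies outside the plot extent ({w} x {h} m)"
        )
    codes = scene.label_map[rows, cols]
    labels = [scene.categories[c] for c in codes]
    return pd.DataFrame(
        {
            "point_id": np.arange(len(points)),
            "x": points[:, 0],
            "y": points[:, 1],
            "label": labels,
        }
    )


def percent_cover(
    annotations: pd.DataFrame,
    exclusions: Iterable[str] = DEFAULT_EXCLUSIONS,
) -> pd.DataFrame:
    """Percent cover per category after removing excluded points.

    Excluded labels are dropped from both numerator and denominator:
    ``percent = 100 * category count / total retained points``. The result
    is sorted by descending count (ties alphabetical) and carries
    ``total_points_used`` in ``DataFrame.attrs``; percents sum to 100.
    """
    if "label" not in annotations.columns:
        raise ValidationError("annotation table must have a 'label' column")
    if annotations["label"].isna().any() or (annotations["label"] == "").any():
        raise ValidationError("annotation labels must be non-empty")
    exclusions = set(exclusions)
    kept = annotations[~annotations["label"].isin(exclusions)]
    total = len(kept)
    if total == 0:
        raise ValidationError("no annotatable points: every point was excluded")
    counts = kept["label"].value_counts()
    table = pd.DataFrame(
        {
            "category": counts.index,
            "point_count": counts.to_numpy(),
            "percent": 100.0 * counts.to_numpy() / total,
        }
    )
    table = table.sort_values(
        ["point_count", "category"], ascending=[False, True], ignore_index=True
    )
    table.attrs["total_points_used"] = total
    return table
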