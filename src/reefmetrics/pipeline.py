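"""End-to-end runs: DEM → metric set → summaries → comparison artifacts.

These functions back the command-line interface but are importable on their
own. A "metric set" is the study's standard seven-row panel per survey:
rugosity at native resolution, mean slope, VRM at the native/2x/4x
resolution ladder, and profile/planform curvature.
"""

from __future__ import annotations

import json
import logging
import os
from dataclasses import dataclass

import yaml

from .dem_io import read_dem, write_dem
from .errors import ValidationError
from .grid import DemGrid
from .metrics import curvature, slope_aspect, surface_complexity
from .multiscale import vrm_at_resolutions
from .cover import annotate_from_labelmap, percent_cover, sample_points
from .report import ComparisonReport, compare, metric_key, summarize
from .synthetic import Scene, SceneSpec, generate_scene

log = logging.getLogger("reefmetrics")

DEFAULT_FACTORS = (1, 2, 4)


@dataclass
class RunConfig:
    """Resolved configuration of one pipeline run."""

    output_dir: str
    dem_path: str | None = None
    scene: SceneSpec | None = None
    factors: tuple[int, ...] = DEFAULT_FACTORS
    slope_algorithm: str = "horn"
    curvature_scale: float = 100.0
    n_points: int = 1000
    exclusions: tuple[str, ...] = ("transect_tape", "scale_bar", "mobile_fauna")
    seed: int = 1
    log_level: str = "INFO"

    def to_dict(self) -> dict:
        # the output directory is deliberately omitted: the copy lives in it,
        # and identical runs into different directories must stay comparable
        d = {
            "dem_path": self.dem_path,
            "scene": self.scene.to_dict() if self.scene else None,
            "factors": list(self.factors),
            "slope_algorithm": self.slope_algorithm,
            "curvature_scale": self.curvature_scale,
            "n_points": self.n_points,
            "exclusions": list(self.exclusions),
            "seed": self.seed,
            "log_level": self.log_level,
        }
        return d


def compute_metric_set(
    dem: DemGrid,
    factors: tuple[int, ...] = DEFAULT_FACTORS,
    slope_algorithm: str = "horn",
    curvature_scale: float = 100.0,
) -> dict:
    """The standard per-survey metric panel keyed by 'metric@resolution'.

    Keys for a 0.01-m DEM with the default ladder: ``rugosity@0.01``,
    ``slope_deg@0.01``, ``vrm@0.01``, ``vrm@0.02``, ``vrm@0.04``,
    ``profile_curv@0.01``, ``planform_curv@0.01``.
    """
    cs = dem.cell_size
    out: dict = {}
    out[metric_key("rugosity", cs)] = surface_complexity(dem)
    slope, _aspect = slope_aspect(dem, algorithm=slope_algorithm)
    out[metric_key("slope_deg", cs)] = slope
    for res, grid in vrm_at_resolutions(dem, factors=list(factors)).items():
        out[metric_key("vrm", res)] = grid
    prof, plan = curvature(dem, scale=curvature_scale)
    out[metric_key("profile_curv", cs)] = prof
    out[metric_key("planform_curv", cs)] = plan
    return out


def metric_set_summary_frame(metric_set: dict, survey: str):
    """Summarize a metric set into a long-format DataFrame."""
    import pandas as pd

    from .metrics import SurfaceComplexity
    from .report import summarize_scalar

    rows = []
    for key in sorted(metric_set):
        obj = metric_set[key]
        name, _, res = key.partition("@")
        if isinstance(obj, SurfaceComplexity):
            s = summarize_scalar(name, float(res), obj.ratio)
        else:
            s = summarize(obj)
        rows.append(
            {
                "metric": name,
                "resolution_m": s.resolution,
                "survey": survey,
                "mean": s.mean,
                "sd": s.sd,
                "min": s.min,
                "max": s.max,
                "n": s.n_valid_cells,
            }
        )
    return pd.DataFrame(rows)


def _setup_run_dir(config: RunConfig) -> None:
    os.makedirs(config.output_dir, exist_ok=True)
    with open(os.path.join(config.output_dir, "resolved_config.yaml"), "w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=True)
    handler = logging.FileHandler(
        os.path.join(config.output_dir, "run.log"), mode="w"
    )
    # fixed, timestamp-free format: identical runs must produce identical logs
    handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    log.addHandler(handler)
    log.setLevel(config.log_level)


def _teardown_run_dir() -> None:
    for h in list(log.handlers):
        if isinstance(h, logging.FileHandler):
            log.removeHandler(h)
            h.close()


def run_metrics(config: RunConfig) -> dict:
    """Compute the metric panel for one DEM (file or synthetic scene).

    Writes ``summary.csv``, the resolved config and a log file into the
    output directory; returns the metric set.
    """
    _setup_run_dir(config)
    try:
        if config.dem_path is not None:
            log.info("stage=read_dem path=%s", config.dem_path)
            dem = read_dem(config.dem_path)
        elif config.scene is not None:
            log.info("stage=generate_scene type=%s", config.scene.scene_type)
            dem = generate_scene(config.scene).dem
        else:
            raise ValidationError("RunConfig needs either dem_path or scene")
        log.info("stage=metrics shape=%s cell=%g", dem.shape, dem.cell_size)
        metric_set = compute_metric_set(
            dem,
            factors=config.factors,
            slope_algorithm=config.slope_algorithm,
            curvature_scale=config.curvature_scale,
        )
        frame = metric_set_summary_frame(metric_set, survey="survey")
        frame.to_csv(
            os.path.join(config.output_dir, "summary.csv"),
            index=False,
            float_format="%.10g",
        )
        log.info("stage=report rows=%d", len(frame))
        return metric_set
    finally:
        _teardown_run_dir()


def run_comparison(
    pre_dem: DemGrid,
    post_dem: DemGrid,
    config: RunConfig,
) -> ComparisonReport:
    """Metric panels for two surveys plus the paired comparison artifact."""
    pre_set = compute_metric_set(
        pre_dem, config.factors, config.slope_algorithm, config.curvature_scale
    )
    post_set = compute_metric_set(
        post_dem, config.factors, config.slope_algorithm, config.curvature_scale
    )
    report = compare(pre_set, post_set)
    report.save(config.output_dir)
    return report


def run_paper_emulation(
    seed: int,
    output_dir: str,
    extent: tuple[float, float] = (10.0, 5.0),
    cell_size: float = 0.01,
    n_points: int = 1000,
    write_rasters: bool = False,
) -> ComparisonReport:
    """One-command synthetic pre/post experiment.

    Generates the default tabulate (pre) and rubble (post) scenes on the
    study-plot footprint, computes the full metric panel for both (VRM at
    the native/2x/4x ladder), annotates each scene with uniform random
    points for percent cover, and writes the comparison artifacts
    (``summary.csv``, ``comparison.json``, density CSVs, cover CSVs) into
    the output directory. Fully deterministic for a given seed.
    """
    config = RunConfig(output_dir=output_dir, seed=seed)
    config.scene = SceneSpec(
        "tabulate", extent=extent, cell_size=cell_size, seed=seed
    )
    _setup_run_dir(config)
    try:
        pre_spec = SceneSpec("tabulate", extent=extent, cell_size=cell_size, seed=seed)
        post_spec = SceneSpec(
            "rubble", extent=extent, cell_size=cell_size, seed=seed + 1
        )
        log.info("stage=generate_scene type=tabulate seed=%d", seed)
        pre = generate_scene(pre_spec)
        log.info("stage=generate_scene type=rubble seed=%d", seed + 1)
        post = generate_scene(post_spec)

        if write_rasters:
            write_dem(pre.dem, os.path.join(output_dir, "dem_pre.tif"))
            write_dem(post.dem, os.path.join(output_dir, "dem_post.tif"))

        log.info("stage=metrics surveys=2")
        pre_set = compute_metric_set(pre.dem)
        post_set = compute_metric_set(post.dem)
        report = compare(pre_set, post_set)
        report.save(output_dir)

        log.info("stage=cover n_points=%d", n_points)
        for survey, scene, pt_seed in (("pre", pre, seed + 2), ("post", post, seed + 3)):
            pts = sample_points(extent, n=n_points, seed=pt_seed)
            annotations = annotate_from_labelmap(scene, pts)
            annotations.to_csv(
                os.path.join(output_dir, f"annotations_{survey}.csv"),
                index=False,
                float_format="%.10g",
            )
            table = percent_cover(annotations)
            table.to_csv(
                os.path.join(output_dir, f"cover_{survey}.csv"),
                index=False,
                float_format="%.10g",
            )
            with open(
                os.path.join(output_dir, f"cover_{survey}_meta.json"), "w"
            ) as fh:
                json.dump(
                    {"total_points_used": table.attrs["total_points_used"]},
                    fh,
                    indent=2,
                )
                fh.write("\n")
        log.info("stage=done")
        return report
    finally:
        _teardown_run_dir()
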