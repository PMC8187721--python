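import numpy as np
import pytest

from reefmetrics import (
    DemGrid,
    MetricGrid,
    ValidationError,
    compare,
    curvature_density,
    metric_key,
    summarize,
    summarize_scalar,
    vrm,
)

import oracles


def metric_grid(values, name="vrm", resolution=0.01):
    values = np.asarray(values, dtype=float)
    return MetricGrid(values, name, resolution, np.isfinite(values))


def test_hand_computed_population_statistics():
    """{1, 2, 3}: mean 2, population SD sqrt(2/3)."""
    grid = metric_grid([[1.0, 2.0, 3.0]], name="slope_deg")
    s = summarize(grid)
    assert s.mean == pytest.approx(2.0)
    assert s.sd == pytest.approx(np.sqrt(2.0 / 3.0))
    assert s.n_valid_cells == 3
    assert (s.min, s.max) == (1.0, 3.0)


def test_constant_grid_summary():
    s = summarize(metric_grid(np.full((4, 4), 0.2)))
    assert s.sd == 0.0
    assert s.min == s.max == s.mean == pytest.approx(0.2)


def test_summary_matches_two_pass_oracle():
    """A 50x50 VRM grid summarized to 1e-12 of an explicit two-pass
    mean/variance accumulation."""
    rng = np.random.default_rng(21)
    dem = DemGrid(rng.normal(0, 0.05, size=(52, 52)), 0.01)
    grid = vrm(dem)
    s = summarize(grid)
    mean, sd = oracles.two_pass_mean_sd(grid.valid_values)
    assert s.mean == pytest.approx(mean, rel=1e-12)
    assert s.sd == pytest.approx(sd, rel=1e-12)


def test_invalid_cells_excluded_from_summary():
    values = np.array([[1.0, np.nan], [3.0, np.nan]])
    mask = np.isfinite(values)
    s = summarize(MetricGrid(values, "slope_deg", 0.01, mask))
    assert s.n_valid_cells == 2
    assert s.mean == pytest.approx(2.0)


def test_zero_valid_cells_is_an_error():
    grid = MetricGrid(np.full((3, 3), np.nan), "vrm", 0.01, np.zeros((3, 3), bool))
    with pytest.raises(ValidationError):
        summarize(grid)


# ---------------------------------------------------------------------------
# curvature density
# ---------------------------------------------------------------------------

def test_degenerate_sample_concentrates_at_value():
    grid, density, _ = curvature_density(np.zeros(50))
    assert density[np.argmin(np.abs(grid))] == density.max()
    np.testing.assert_allclose(density, density[::-1], rtol=1e-9)


def test_windowed_density_integrates_to_one_when_window_covers_support():
    rng = np.random.default_rng(5)
    grid, density, bw = curvature_density(rng.standard_normal(20_000))
    integral = np.trapezoid(density, grid)
    assert integral == pytest.approx(1.0, abs=0.01)
    assert bw > 0


def test_tail_mass_outside_window_reduces_windowed_integral():
    """5% of mass at +-500 sits outside (-100, 100): the windowed density
    integrates to about 0.95 because normalization uses all the data."""
    rng = np.random.default_rng(6)
    n = 20_000
    values = rng.standard_normal(n)
    n_tail = n // 20
    values[:n_tail] = 500.0 * rng.choice([-1.0, 1.0], size=n_tail)
    grid, density, _ = curvature_density(values)
    integral = np.trapezoid(density, grid)
    assert integral == pytest.approx(0.95, abs=0.01)


def test_density_input_contracts():
    with pytest.raises(ValidationError):
        curvature_density(np.array([1.0]))
    with pytest.raises(ValidationError):
        curvature_density(np.array([1.0, 2.0]), window=(5.0, -5.0))


# ---------------------------------------------------------------------------
# comparison
# ---------------------------------------------------------------------------

def panel(seed, scale=1.0):
    rng = np.random.default_rng(seed)
    return {
        metric_key("vrm", 0.01): metric_grid(scale * rng.random((6, 6)) * 0.3),
        metric_key("slope_deg", 0.01): metric_grid(
            scale * rng.random((6, 6)) * 40, name="slope_deg"
        ),
        metric_key("rugosity", 0.01): summarize_scalar("rugosity", 0.01, 1.5 * scale),
    }


def test_identical_inputs_give_zero_deltas():
    report = compare(panel(1), panel(1))
    assert all(v == 0.0 for v in report.delta_mean.values())
    assert all(v == 0 for v in report.sign_of_change.values())


def test_swapping_surveys_negates_deltas():
    a, b = panel(1), panel(2, scale=0.5)
    fwd = compare(a, b)
    rev = compare(b, a)
    for key in fwd.delta_mean:
        assert fwd.delta_mean[key] == pytest.approx(-rev.delta_mean[key])
        assert fwd.sign_of_change[key] == -rev.sign_of_change[key]


def test_mismatched_metric_sets_name_the_difference():
    a, b = panel(1), panel(1)
    del b[metric_key("vrm", 0.01)]
    with pytest.raises(ValidationError, match="vrm@0.01"):
        compare(a, b)


def test_comparison_artifacts_round_trip(tmp_path):
    rng = np.random.default_rng(9)
    a = panel(3)
    b = panel(4, scale=0.8)
    curv = metric_grid(rng.standard_normal((20, 20)) * 50, name="profile_curv")
    curv2 = metric_grid(rng.standard_normal((20, 20)) * 20, name="profile_curv")
    a[metric_key("profile_curv", 0.01)] = curv
    b[metric_key("profile_curv", 0.01)] = curv2
    report = compare(a, b)
    assert metric_key("profile_curv", 0.01) in report.densities
    report.save(tmp_path)
    assert (tmp_path / "summary.csv").exists()
    assert (tmp_path / "comparison.json").exists()
    assert (tmp_path / "density_profile_curv_at_0.01.csv").exists()
    frame = report.to_frame()
    assert set(frame["survey"]) == {"pre", "post"}
    assert len(frame) == 2 * len(a)
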