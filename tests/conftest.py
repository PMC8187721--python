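import numpy as np
import pytest

from reefmetrics import SceneSpec, compute_metric_set, generate_scene


def random_dem(seed: int, shape=(5, 5), cell=0.01, scale=0.05):
    """Seeded random elevation grid used by the oracle-equivalence checks."""
    from reefmetrics import DemGrid

    rng = np.random.default_rng(seed)
    return DemGrid(rng.normal(0.0, scale, size=shape), cell)


@pytest.fixture(scope="session")
def tabulate_scene():
    """Default pre-disturbance scene: study-plot footprint, seed 1."""
    return generate_scene(SceneSpec("tabulate", seed=1))


@pytest.fixture(scope="session")
def rubble_scene():
    """Default post-disturbance scene: study-plot footprint, seed 1."""
    return generate_scene(SceneSpec("rubble", seed=1))


@pytest.fixture(scope="session")
def tabulate_metrics(tabulate_scene):
    return compute_metric_set(tabulate_scene.dem)


@pytest.fixture(scope="session")
def rubble_metrics(rubble_scene):
    return compute_metric_set(rubble_scene.dem)


@pytest.fixture()
def small_tabulate():
    """A fast 2 x 1 m tabulate scene for unit-level checks."""
    return generate_scene(
        SceneSpec("tabulate", extent=(2.0, 1.0), seed=3, plate_radius=(0.15, 0.3))
    )


@pytest.fixture()
def small_rubble():
    return generate_scene(SceneSpec("rubble", extent=(2.0, 1.0), seed=4))
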