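import numpy as np
import pytest

from tidalmarsh import SynthConfig, generate_scene
from tidalmarsh.pipeline import analyze_scene
from tidalmarsh.raster import block_resample, slope_deg


@pytest.fixture(scope="session")
def default_scene():
    """Seeded synthetic estuary at the default study conditions."""
    return generate_scene(SynthConfig(seed=20))


@pytest.fixture(scope="session")
def default_report(default_scene):
    """Full analysis of the default scene, including ground-truth fields."""
    scene = default_scene
    years = list(scene.config.years)
    last = years[-1]
    return analyze_scene(
        years, scene.dems_10m, scene.exposure_10m, scene.intensity_10m,
        scene.truth.veg_masks,
        slope2_by_year={last: slope_deg(block_resample(scene.dems[last], 2.0, "mean"))},
        true_p=scene.truth.true_p,
    )


@pytest.fixture(scope="session")
def small_config():
    """A fast, reduced-size estuary for unit tests."""
    return SynthConfig(
        grid_shape=(200, 300),
        years=tuple(range(2004, 2008)),
        station_positions_m=(0.0, 150.0, 300.0),
        tide_duration_days=31.0,
        shoulder_row=140.0,
        shoulder_width_m=15.0,
        seed=9,
    )


@pytest.fixture(scope="session")
def small_scene(small_config):
    return generate_scene(small_config)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
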