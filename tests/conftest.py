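import numpy as np
import pytest

import phenocube as pc


@pytest.fixture(scope="session")
def default_scene():
    """The seeded default 64x64 benchmark scene (~200 acquisitions, 9 years)."""
    return pc.build_scene(pc.default_benchmark_config(seed=42))


@pytest.fixture(scope="session")
def default_waypoints(default_scene):
    return pc.sample_waypoints(default_scene, 400, stratified=True, seed=43)


@pytest.fixture(scope="session")
def pipeline_result(default_scene, default_waypoints):
    """Full pipeline (indices -> SVD -> stepwise LR -> map) on the default scene."""
    return pc.full_pipeline(default_scene, default_waypoints)


@pytest.fixture(scope="session")
def rank6_scene():
    """Scene whose noise-free greenness spans six temporal patterns."""
    return pc.build_scene(pc.rank6_benchmark_config(seed=7))


@pytest.fixture()
def tiny_cube():
    """Hand-built 3-date 2x2 fully-valid cube with simple band values."""
    dates = ["2020-01-01", "2020-01-06", "2020-01-11"]
    shape = (3, 2, 2)
    bands = {
        "BLUE": np.full(shape, 0.05),
        "GREEN": np.full(shape, 0.10),
        "RED": np.full(shape, 0.10),
        "NIR": np.full(shape, 0.40),
        "SWIR1": np.full(shape, 0.20),
    }
    return pc.ReflectanceCube(dates=dates, bands=bands,
                              valid_mask=np.ones(shape, dtype=bool))
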