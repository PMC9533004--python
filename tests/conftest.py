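import numpy as np
import pytest

from whipkin.mocap_io import MarkerDataset, default_schema
from whipkin.pipeline import BlockRef, process_block
from whipkin.synthetic_scene import SceneParams, simulate_block, simulate_trial


@pytest.fixture(scope="session")
def schema():
    return default_schema()


@pytest.fixture
def static_dataset(schema):
    """A 100-frame dataset with all markers at distinct static positions."""
    rng = np.random.default_rng(0)
    base = rng.uniform(-1, 1, size=(1, len(schema.marker_names), 3))
    pos = np.repeat(base, 100, axis=0)
    return MarkerDataset(pos, 500.0, np.zeros((100, len(schema.marker_names)), bool), schema)


@pytest.fixture(scope="session")
def discrete_scene():
    """Noise-free single discrete throw with planted error/extension/azimuth."""
    params = SceneParams.for_style(
        "discrete", noise_sd=0.0, planted_error=0.05, seed=7
    )
    return simulate_trial(params)


@pytest.fixture(scope="session")
def discrete_block_scene():
    """Discrete block at realistic noise with several planted throws."""
    params = SceneParams.for_style("discrete", seed=42)
    return simulate_block(params, n_trials=8)


@pytest.fixture(scope="session")
def rhythmic_block_scene():
    """Rhythmic 40 s block at realistic noise."""
    params = SceneParams.for_style("rhythmic", seed=42)
    return simulate_block(params, duration=40.0)


@pytest.fixture(scope="session")
def discrete_block_processed(discrete_block_scene):
    dataset, gt = discrete_block_scene
    return process_block(BlockRef("P01", "discrete", 1, dataset=dataset)), gt


@pytest.fixture(scope="session")
def rhythmic_block_processed(rhythmic_block_scene):
    dataset, gt = rhythmic_block_scene
    return process_block(BlockRef("P01", "rhythmic", 1, dataset=dataset)), gt
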