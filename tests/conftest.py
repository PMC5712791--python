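import numpy as np
import pytest

from dropcount import PipelineConfig
from dropcount.simulate import SimulationParams, generate_fmi


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def default_config():
    return PipelineConfig()


@pytest.fixture(scope="session")
def small_params():
    """A small, quick-to-render scene used by several detection tests."""
    # frame kept small for speed, but large enough that the 8x8 CLAHE blocks
    # (67x120 px) stay well above the droplet diameter, as in full frames
    return SimulationParams(
        height=540, width=960, n_droplets=35, lambda_occupancy=0.14,
        n_speckles=8, seed=7,
    )


@pytest.fixture(scope="session")
def small_frame(small_params):
    return generate_fmi(small_params)
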