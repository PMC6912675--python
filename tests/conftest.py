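import numpy as np
import pytest

from spinesva.heatmaps import HeatmapSpec
from spinesva.model import ModelConfig
from spinesva.preprocess import PreprocessSpec
from spinesva.synthetic import SpinePhantomParams, generate_dataset

#: Heatmap widths used throughout the model-selection sweep.
SIGMAS = (0.79, 1.57, 3.14, 6.28)


@pytest.fixture(scope="session")
def desk_preprocess():
    return PreprocessSpec.for_canvas(192, 112)


@pytest.fixture(scope="session")
def tiny_model_config():
    """Smallest config that exercises every conv code path."""
    return ModelConfig(input_height=64, input_width=32, base_filters=4, norm_groups=2)


@pytest.fixture(scope="session")
def phantom_batch():
    """Ten deterministic desk-scale phantoms shared across tests."""
    return generate_dataset(10, SpinePhantomParams(), seed=42)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def exp_spec():
    return HeatmapSpec(family="exponential", sigma=1.57, amplitude=1000.0)


@pytest.fixture(scope="session")
def gauss_spec():
    return HeatmapSpec(family="gaussian", sigma=1.57, amplitude=1000.0)
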