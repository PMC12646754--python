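import numpy as np
import pytest

from canopyage import GeneratorConfig, build_truth, simulate_plot_table
from canopyage.chm_io import CHMRaster


@pytest.fixture(scope="session")
def truth():
    return build_truth()


@pytest.fixture(scope="session")
def default_table(truth):
    """One default 250-plot Tier A draw."""
    return simulate_plot_table(truth, GeneratorConfig(seed=1))


@pytest.fixture(scope="session")
def noiseless_table(truth):
    """500 plots exactly on the truth surfaces."""
    return simulate_plot_table(truth, GeneratorConfig(n_plots=500, seed=5).zero_noise())


@pytest.fixture()
def flat_raster():
    def make(height: float, shape=(10, 10), resolution=1.0):
        return CHMRaster(np.full(shape, float(height)), resolution=resolution,
                         origin=(0.0, shape[0] * resolution))
    return make


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240917)
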