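import numpy as np
import pytest

from clockloops import rhythms, surrogate, workbench


@pytest.fixture(scope="session")
def jetlag_reference():
    """Synthetic jet-lag shift curves at the documented truth parameters."""
    return workbench.make_jetlag_reference()


@pytest.fixture(scope="session")
def analysis_config():
    return rhythms.AnalysisConfig()


@pytest.fixture
def small_config():
    """A tiny surrogate configuration for fast structural tests."""
    return surrogate.SurrogateConfig(
        n_cells=4, grid_shape=(32, 32), duration_days=2.0, seed=7
    )


@pytest.fixture
def cosine_series():
    t = np.arange(0.0, 12 * 24 + 0.5, 1.0)
    return rhythms.TimeSeries(t, np.cos(2 * np.pi * t / 24.0))
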