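import warnings

import numpy as np
import pytest

from molscreen.io_config import PipelineConfig
from molscreen.synthetic_data import SyntheticSpec, generate


@pytest.fixture(autouse=True)
def _quiet_domain_warnings():
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)
        yield


@pytest.fixture(scope="session")
def small_dataset():
    """60-compound synthetic table shared by IO / pipeline tests."""
    return generate(SyntheticSpec(n_compounds=60, seed=11))


@pytest.fixture(scope="session")
def default_config():
    return PipelineConfig()


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
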