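import numpy as np
import pytest

from bfoptstop.models import ModelSpec


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20_260_927)


@pytest.fixture
def jzs_spec():
    return ModelSpec("jzs_ttest", mu0=1.0)
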