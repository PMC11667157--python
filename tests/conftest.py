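import numpy as np
import pytest

from mitopo.montage import default_layout
from mitopo.synthetic_data import SyntheticConfig, generate


@pytest.fixture(scope="session")
def layout():
    return default_layout()


@pytest.fixture(scope="session")
def erd_segments():
    """Small simulated session with a strong contralateral ERD."""
    return generate(SyntheticConfig(n_trials_per_class=30, erd_effect=0.6, seed=11))


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
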