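import numpy as np
import pytest

from cretam.synth import SynthConfig, generate_dataset


@pytest.fixture(scope="session")
def ds():
    """One shared default-regime dataset (3 types x 200 cells)."""
    return generate_dataset(SynthConfig(seed=11))


@pytest.fixture(scope="session")
def ds_strong_links():
    """High link-effect regime used for recovery checks."""
    return generate_dataset(SynthConfig(seed=11, link_effect=0.9))


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
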