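import numpy as np
import pytest

from acovit.synthetic import SyntheticSpec, generate_dataset


@pytest.fixture(scope="session")
def small_imbalanced_dataset():
    """280-image OCT-like set with the 12:4:3:9 class ratio, 64x64."""
    return generate_dataset(SyntheticSpec(counts=(120, 40, 30, 90), seed=0))


@pytest.fixture(scope="session")
def tiny_dataset():
    """60-image set for fast pipeline-level tests."""
    return generate_dataset(SyntheticSpec(counts=(24, 8, 6, 18), seed=1))


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
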