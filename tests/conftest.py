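import pytest
from hypothesis import settings

from mzdefect import PUBLISHED_LINE, alkane_series

settings.register_profile("deterministic", deadline=None, derandomize=True)
settings.load_profile("deterministic")
from mzdefect.synth import SyntheticSpec, generate


@pytest.fixture(scope="session")
def line():
    return PUBLISHED_LINE


@pytest.fixture(scope="session")
def alkanes():
    return alkane_series()


@pytest.fixture(scope="session")
def small_dataset():
    """85 metabolites + 10 clusters + 5 peptides with disjoint RT supports."""
    return generate(SyntheticSpec(85, 10, 5, seed=42))


@pytest.fixture(scope="session")
def plasma_positive():
    return generate(SyntheticSpec.plasma_positive(seed=7))
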