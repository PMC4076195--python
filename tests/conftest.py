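import numpy as np
import pytest

from cypevol.treeio import load_vertebrate_chronogram
from cypevol.catalog import load_human_catalog


@pytest.fixture(scope="session")
def chronogram():
    return load_vertebrate_chronogram()


@pytest.fixture(scope="session")
def catalog():
    return load_human_catalog()


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
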