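import numpy as np
import pytest

from rdnameth import make_reference, prepare_reference


@pytest.fixture(scope="session")
def ref_small():
    """Tiny 6-CpG amplicon for fast unit tests."""
    return make_reference(region="mini", n_cpgs=6, name="mini")


@pytest.fixture(scope="session")
def ann_small(ref_small):
    return prepare_reference(ref_small)


@pytest.fixture(scope="session")
def ref_region2():
    return make_reference("region2")


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
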