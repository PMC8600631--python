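import numpy as np
import pytest

from igrec.simulate import synthetic_germline_db


@pytest.fixture(scope="session")
def db():
    """Synthetic miniature germline database (4 V, 4 D, 4 J alleles)."""
    return synthetic_germline_db(seed=0)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
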