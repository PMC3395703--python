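import numpy as np
import pytest

from pyrotagger.synth_community import (ERROR_FREE, ROCHE_MIDS,
                                        build_mock_community)


@pytest.fixture(scope="session")
def small_pool():
    """Six-taxon aquifer-like community, fixed seed."""
    return build_mock_community(6, dominance=2.0, seed=1)


@pytest.fixture(scope="session")
def mid():
    return ROCHE_MIDS[0]


@pytest.fixture
def rng():
    return np.random.default_rng(0)
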