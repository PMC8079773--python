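import os
import sys

import numpy as np
import pytest

sys.path.insert(0, os.path.dirname(__file__))

from gliorad.synthetic import PhantomSpec, generate_phantom


@pytest.fixture(scope="session")
def default_phantom():
    """One noiseless-geometry phantom shared across tests (read-only)."""
    return generate_phantom(PhantomSpec(seed=7))


@pytest.fixture()
def rng():
    return np.random.default_rng(123)
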