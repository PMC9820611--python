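import logging

import numpy as np
import pytest
from hypothesis import settings

from hiergrn.grn import TripleTestResult

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")

logging.getLogger("hiergrn").setLevel(logging.ERROR)


@pytest.fixture
def rng():
    return np.random.default_rng(20240101)


def make_passing_triple(x: str, y: str, z: str) -> TripleTestResult:
    """Minimal passing triple for constructing networks in bookkeeping tests."""
    return TripleTestResult(
        x=x, y=y, z=z, r_xy=0.95, p_xy=1e-6, r_xz=0.9, r_yz=0.9,
        r_xy_given_z=0.1, passes=True,
    )


@pytest.fixture
def passing_triple_factory():
    return make_passing_triple
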