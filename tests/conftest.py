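import numpy as np
import pytest

from tdspect.fixtures import toy_library, toy_scheme


@pytest.fixture(scope="session")
def library8():
    """Eight-member toy spectrum library (coarse grid, all three families)."""
    return toy_library(n_members=8)


@pytest.fixture(scope="session")
def scheme3():
    """Three intervals: 0-25, 25-50, 50+ Hz."""
    return toy_scheme(n_primary=2, width_hz=25.0)


@pytest.fixture(scope="session")
def scheme6():
    from tdspect import IntervalScheme
    return IntervalScheme.uniform(10.0)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240917)
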