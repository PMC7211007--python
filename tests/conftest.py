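import numpy as np
import pytest

from scintiseg import PhantomSpec, generate_cohort, generate_scan


@pytest.fixture(scope="session")
def default_spec():
    return PhantomSpec()


@pytest.fixture(scope="session")
def small_spec():
    """A 64x64 phantom for fast unit tests."""
    return PhantomSpec(image_height=64, image_width=64,
                       remnant_axes=((6.0, 8.0), (4.0, 6.0)),
                       mln_axes=((3.0, 4.0), (2.0, 3.0)),
                       oral_axes=((4.0, 5.0), (3.0, 4.0)))


@pytest.fixture(scope="session")
def phantom_pair(default_spec):
    return generate_scan(default_spec, seed=11)


@pytest.fixture(scope="session")
def small_cohort(small_spec):
    return generate_cohort(small_spec, n=12, seed=5)
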