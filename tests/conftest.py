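import numpy as np
import pytest

from matsplice.synthetic import (
    FixtureSpec,
    make_gene_fixture,
    mat111_standin,
    mat121_standin,
)

try:
    from hypothesis import settings

    settings.register_profile("ci", derandomize=True, max_examples=50,
                              deadline=None)
    settings.load_profile("ci")
except ImportError:  # pragma: no cover
    pass


@pytest.fixture(scope="session")
def mat121():
    """Synthetic MAT1-2-1-architecture gene system (stand-in)."""
    fix, info = mat121_standin()
    return fix, info


@pytest.fixture(scope="session")
def mat111():
    """Synthetic MAT1-1-1-architecture gene system (stand-in)."""
    fix, info = mat111_standin()
    return fix, info


@pytest.fixture(scope="session")
def small_fixture():
    return make_gene_fixture(FixtureSpec(seed=11))


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
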