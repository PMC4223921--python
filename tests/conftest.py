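import numpy as np
import pytest

from gaitmanifold import BodyParameters, ContactParams, GainSet
from gaitmanifold.trajectory import fixture_reference
from gaitmanifold.floquet import monodromy

#: study gain sets: stiff/stable, weakly unstable saddle (used by the
#: intermittent-control experiments), and strongly unstable
STABLE_GAINS = GainSet(Pa=2000, Pk=2000, Ph=2000, Da=50, Dk=50, Dh=50)
SADDLE_GAINS = GainSet(Pa=500, Pk=500, Ph=500, Da=30, Dk=30, Dh=30)
UNSTABLE_GAINS = GainSet(Pa=700, Pk=700, Ph=700, Da=30, Dk=30, Dh=30)


@pytest.fixture(scope="session")
def body():
    return BodyParameters()


@pytest.fixture(scope="session")
def contact():
    return ContactParams()


@pytest.fixture(scope="session")
def ref():
    """Steady-state reference gait of the packaged fixture (shared)."""
    return fixture_reference()


@pytest.fixture(scope="session")
def mono_stable(ref):
    return monodromy(ref, STABLE_GAINS)


@pytest.fixture(scope="session")
def mono_saddle(ref):
    return monodromy(ref, SADDLE_GAINS)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260921)
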