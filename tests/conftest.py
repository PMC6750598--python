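import matplotlib

matplotlib.use("Agg")

import numpy as np
import pytest

from gaitmet.inverse_dynamics import CycleTrajectory
from gaitmet.muscle import default_muscles


@pytest.fixture(scope="session")
def muscles():
    return default_muscles()


@pytest.fixture(scope="session")
def muscle_map(muscles):
    return {m.name: m for m in muscles}


@pytest.fixture(scope="session")
def soleus(muscle_map):
    return muscle_map["soleus"]


def make_cycle(angles=None, moments=None, duration=1.1, n=100):
    """Toy 100-node cycle with given (n, 3) angle/moment arrays."""
    angles = np.zeros((n, 3)) if angles is None else angles
    moments = np.zeros((n, 3)) if moments is None else moments
    return CycleTrajectory(joint_angles=angles, joint_moments=moments,
                           grf=np.zeros((n, 2)), duration=duration)


@pytest.fixture
def toy_cycle_factory():
    return make_cycle
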