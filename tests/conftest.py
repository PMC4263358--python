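import numpy as np
import pytest

from bdslide import assemble_system, build_dna, build_protein
from bdslide.fixtures import make_fixture


@pytest.fixture(scope="session")
def dna20():
    return build_dna(20)


@pytest.fixture(scope="session")
def protein40():
    return build_protein(a_pbp=40.0, q_dbp=8.0)


@pytest.fixture(scope="session")
def mini_system():
    return assemble_system(build_dna(20), build_protein(40.0, 8.0))


@pytest.fixture(scope="session")
def dimer():
    return make_fixture("dimer")


@pytest.fixture
def rng():
    return np.random.default_rng(20140901)


def numerical_forces(system, x, params=None, h=1e-5, **kw):
    """Central-difference gradient oracle for the total potential."""
    from bdslide import total_energy_forces
    g = np.zeros_like(x)
    for i in range(x.shape[0]):
        for d in range(3):
            xp = x.copy()
            xp[i, d] += h
            xm = x.copy()
            xm[i, d] -= h
            ep = total_energy_forces(system, xp, params, **kw).total
            em = total_energy_forces(system, xm, params, **kw).total
            g[i, d] = -(ep - em) / (2 * h)
    return g
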