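import math

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from mmkit.fixtures import make_polyala, make_toy_paramset, make_toy_pocket
from mmkit.molsys import perceive_topology, read_xyz


@pytest.fixture(scope="session")
def toy_params():
    return make_toy_paramset()


@pytest.fixture(scope="session")
def polyala3():
    return make_polyala(3, "helix")


@pytest.fixture()
def water():
    return read_xyz("3\n\nO 0.0 0.0 0.0\nH 0.96 0.0 0.0\nH -0.24 0.93 0.0\n")


@pytest.fixture()
def butane():
    return read_xyz("4\n\nC 0 0 0\nC 1.5 0 0\nC 2.0 1.4 0\nC 1.5 2.0 1.3\n")


@pytest.fixture()
def pocket():
    system, receptor, ligand = make_toy_pocket(seed=0)
    return system, receptor, ligand


def superposed_rmsd(P: np.ndarray, Q: np.ndarray) -> float:
    """RMSD after optimal rigid superposition (Kabsch via scipy)."""
    Pc = P - P.mean(axis=0)
    Qc = Q - Q.mean(axis=0)
    rot, _ = Rotation.align_vectors(Pc, Qc)
    diff = Pc - rot.apply(Qc)
    return math.sqrt(float(np.mean(np.sum(diff * diff, axis=1))))


def finite_difference_gradient(system, topology, params, settings=None, h=1e-5):
    from mmkit.forcefield import energy_and_gradient
    x0 = system.coords()
    g = np.zeros_like(x0)
    for i in range(x0.shape[0]):
        for k in range(3):
            xp = x0.copy()
            xp[i, k] += h
            xm = x0.copy()
            xm[i, k] -= h
            fp, _ = energy_and_gradient(system, topology, params, settings, coords=xp)
            fm, _ = energy_and_gradient(system, topology, params, settings, coords=xm)
            g[i, k] = (fp.total - fm.total) / (2 * h)
    return g


@pytest.fixture()
def fd_gradient():
    return finite_difference_gradient


@pytest.fixture()
def kabsch_rmsd():
    return superposed_rmsd


@pytest.fixture(scope="session")
def topology_of():
    return perceive_topology
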