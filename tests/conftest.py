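import numpy as np
import pytest

from mtmd.forcefield import N2ForceField, ToyPolyForceField, ToyPolyParams
from mtmd.massmatrix import DiatomicMassModel
from mtmd.topology import build_topology

M_N = 14.007


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def n2_pair():
    """Two N2 molecules in a small periodic box."""
    h = 8.0 * np.eye(3)
    X = np.array([[1.0, 1.0, 1.0], [1.0, 1.0, 2.1],
                  [4.5, 4.0, 4.0], [4.5, 5.1, 4.0]])
    topo = build_topology(X, ["N"] * 4, h)
    ff = N2ForceField(topo, cutoff=3.9)
    s = X @ np.linalg.inv(h).T
    return dict(topo=topo, ff=ff, s=s, h=h, X=X)


@pytest.fixture
def diatomic_model():
    return DiatomicMassModel(M_N, 4 * M_N, 100 * M_N)


@pytest.fixture
def toy_molecule():
    """One isolated 4-atom chain (bonds, angles, one dihedral)."""
    h = 20.0 * np.eye(3)
    X = np.array([[0.0, 0.0, 0.0], [1.0, 0.1, 0.0],
                  [1.6, 1.0, 0.25], [1.4, 1.9, 0.9]])
    topo = build_topology(X, ["H", "O", "O", "H"])
    params = ToyPolyParams(k_b=[20.0, 25.0, 20.0], b0=[1.0, 1.17, 1.1],
                           k_a=[5.0, 5.0], a0=[1.8, 1.85], cutoff=8.0)
    ff = ToyPolyForceField(topo, params)
    return dict(topo=topo, ff=ff, X=X, h=h, s=X @ np.linalg.inv(h).T)


@pytest.fixture(scope="session")
def toy_crystal():
    from mtmd.fixtures import build_toy_crystal
    state, topo, ff, hess = build_toy_crystal()
    return dict(state=state, topo=topo, ff=ff, hess=hess,
                X0=state.s @ state.h.T)
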