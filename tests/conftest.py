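import numpy as np
import pytest

from bilff import load_bilff
from bilff.topology import SystemTopology


@pytest.fixture(scope="session")
def ff():
    return load_bilff()


def bare_topology(ff, positions, q=None, sigma=None, epsilon=None, mass=None,
                  box=50.0, mol_id=None):
    """Build a minimal topology of free atoms (no bonded terms)."""
    positions = np.asarray(positions, dtype=float)
    n = len(positions)
    zeros2 = np.zeros((0, 2), dtype=int)
    return SystemTopology(
        ff=ff,
        box_edge=box,
        positions=positions,
        q=np.zeros(n) if q is None else np.asarray(q, dtype=float),
        sigma=np.zeros(n) if sigma is None else np.asarray(sigma, dtype=float),
        epsilon=np.zeros(n) if epsilon is None else np.asarray(epsilon, dtype=float),
        mass=np.full(n, 40.0) if mass is None else np.asarray(mass, dtype=float),
        mol_id=np.arange(n) if mol_id is None else np.asarray(mol_id, dtype=int),
        species=["X"] * n,
        type_names=["X"] * n,
        elements=["X"] * n,
        bond_idx=zeros2, bond_l0=np.zeros(0), bond_kl=np.zeros(0),
        angle_idx=np.zeros((0, 3), dtype=int),
        angle_theta0=np.zeros(0), angle_ktheta=np.zeros(0),
        dih_idx=np.zeros((0, 4), dtype=int), dih_v=np.zeros((0, 4)),
        scaled_pairs=zeros2, scaled_f=np.zeros(0),
    )


def lj_lattice(ff, n, box, sigma=3.4, epsilon=1.0, mass=40.0):
    """n LJ particles on a cubic lattice inside a periodic box."""
    m = int(np.ceil(n ** (1.0 / 3.0)))
    pts = np.array([[i, j, k] for i in range(m) for j in range(m) for k in range(m)])[:n]
    pos = (pts + 0.5) * box / m
    return bare_topology(
        ff, pos, sigma=np.full(n, sigma), epsilon=np.full(n, epsilon),
        mass=np.full(n, mass), box=box,
    )


@pytest.fixture(scope="session")
def rocksalt(ff):
    """2×2×2 rock-salt point-charge crystal; Madelung oracle applies."""
    import itertools

    d = 2.0
    pos, q = [], []
    for i, j, k in itertools.product(range(2), repeat=3):
        pos.append([i * d, j * d, k * d])
        q.append(1.0 if (i + j + k) % 2 == 0 else -1.0)
    sys = bare_topology(ff, np.array(pos, dtype=float), q=np.array(q), box=2 * d)
    return sys, d
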