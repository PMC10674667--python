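"""Potential terms, forces, exclusions and Ewald electrostatics."""

import math

import numpy as np
import pytest

from bilff import (
    Composition,
    build_molecule,
    build_system,
    nonbonded_energy,
    total_energy_forces,
)
from bilff.energetics import (
    OverlapError,
    angle_energy,
    bond_energy,
    numerical_forces,
    torsion_energy,
)
from bilff.molecules import reference_geometry
from bilff.parameters import AngleParam, BondParam, TorsionParam
from bilff.units import COULOMB

from conftest import bare_topology

# closed-form Madelung constants (point-charge lattice oracles)
MADELUNG_NACL = 1.747564594633
MADELUNG_CSCL = 1.762674773


# ---------------------------------------------------------------------------
# Single-term closed forms
# ---------------------------------------------------------------------------

def test_bond_energy_closed_form(ff):
    p = ff.bond("NA", "NR")
    assert bond_energy(1.344, p) == pytest.approx(0.0)
    assert bond_energy(1.444, p) == pytest.approx(31.992, rel=1e-9)
    assert bond_energy(5.0, BondParam(("A", "B"), 1.0, 0.0)) == 0.0


def test_angle_energy_closed_form(ff):
    p = ff.angle("O2", "CO", "O2")
    assert angle_energy(math.radians(126.0), p) == pytest.approx(0.0)
    expected = 735.9 * math.radians(5.0) ** 2
    assert angle_energy(math.radians(131.0), p) == pytest.approx(expected)
    # even function about theta0
    assert angle_energy(math.radians(121.0), p) == pytest.approx(
        angle_energy(math.radians(131.0), p)
    )


def test_torsion_energy_closed_form(ff):
    p = ff.torsion("CA", "CA", "CO", "O2")
    assert torsion_energy(0.0, p) == pytest.approx(0.0)
    assert torsion_energy(math.pi / 2, p) == pytest.approx(8.0)
    p2 = ff.torsion("NA", "CW", "CW", "NA")
    assert torsion_energy(math.pi / 2, p2) == pytest.approx(65.0)
    # full OPLS series at a generic angle
    p3 = TorsionParam(("A", "B", "C", "D"), 1.0, 2.0, 3.0, 4.0)
    phi = 0.7
    expected = (
        0.5 * 1 * (1 + math.cos(phi))
        + 0.5 * 2 * (1 - math.cos(2 * phi))
        + 0.5 * 3 * (1 + math.cos(3 * phi))
        + 0.5 * 4 * (1 - math.cos(4 * phi))
    )
    assert torsion_energy(phi, p3) == pytest.approx(expected)


# ---------------------------------------------------------------------------
# Non-bonded pairs
# ---------------------------------------------------------------------------

def test_lj_pair_zero_and_minimum(ff):
    sig, eps = 3.0, 0.5
    for r, e_expected in [(sig, 0.0), (2 ** (1 / 6) * sig, -eps)]:
        sys = bare_topology(
            ff, [[10.0, 10, 10], [10.0 + r, 10, 10]],
            sigma=[sig, sig], epsilon=[eps, eps], box=60.0,
        )
        e_lj, e_c = nonbonded_energy(sys, method="cutoff", rc=None)
        assert e_lj == pytest.approx(e_expected, abs=1e-12)
        assert e_c == 0.0


def test_coulomb_pair_value(ff):
    sys = bare_topology(ff, [[10.0, 10, 10], [15.0, 10, 10]], q=[1.0, -1.0], box=60.0)
    _, e_c = nonbonded_energy(sys, method="cutoff", rc=None)
    assert e_c == pytest.approx(-COULOMB / 5.0)
    assert e_c == pytest.approx(-277.87, abs=0.05)


def test_overlapping_atoms_error(ff):
    sys = bare_topology(ff, [[10.0, 10, 10], [10.0, 10, 10 + 1e-5]],
                        q=[1.0, -1.0], box=60.0)
    with pytest.raises(OverlapError):
        nonbonded_energy(sys, method="cutoff", rc=None)


def test_cutoff_requires_wide_box(ff):
    sys = bare_topology(ff, [[1.0, 1, 1], [5.0, 1, 1]], q=[1.0, -1.0], box=10.0)
    with pytest.raises(ValueError, match="cutoff"):
        nonbonded_energy(sys, method="cutoff", rc=8.0)


# ---------------------------------------------------------------------------
# Exclusions
# ---------------------------------------------------------------------------

def _two_molecule_system(ff, species="OBz", shift=20.0):
    t = build_molecule(species)
    geo = reference_geometry(t)
    pos = np.vstack([geo + 15.0, geo + 15.0 + shift])
    comp = Composition([(t, 2)], 6000.0)
    return build_system(comp, ff, pos)


def test_12_and_13_nonbonded_excluded(ff):
    """1-2 and 1-3 partners contribute nothing; moving a bonded atom
    changes no non-bonded term beyond the 1-4-and-further set."""
    sys = _two_molecule_system(ff)
    f = dict(zip(map(tuple, sys.scaled_pairs), sys.scaled_f))
    # benzoate: O2-CO bonded (1-2), O2-CO-O2 (1-3)
    assert f[(0, 1)] == 0.0 and f[(0, 2)] == 0.0  # CO with both O2
    assert f[(1, 2)] == 0.0  # O2⋯O2 via CO
    # ipso-C with O2 is 1-3 via CO
    assert f[(1, 3)] == 0.0


def test_14_scaling_half_for_lj_and_coulomb(ff):
    sys = _two_molecule_system(ff)
    f = dict(zip(map(tuple, sys.scaled_pairs), sys.scaled_f))
    # O2 (idx 1) to ortho carbon (idx 4): path O2-CO-C1-C2 is 1-4
    assert f[(1, 4)] == 0.5


def test_14_scaling_linear_and_symmetric(ff):
    """LJ and Coulomb respond linearly (and identically) to the 1-4
    factor: E(f=0.5) sits exactly midway between E(0) and E(1)."""
    t = build_molecule("OBz")
    comp = Composition([(t, 1)], 6000.0)
    energies = {}
    for f14 in (0.0, 0.5, 1.0):
        sys = build_system(comp, ff, reference_geometry(t) + 20.0)
        sys.scaled_f = np.where(sys.scaled_f == 0.5, f14, sys.scaled_f)
        energies[f14] = total_energy_forces(sys, method="cutoff", rc=None)
    for term in ("lj", "coulomb"):
        e0 = getattr(energies[0.0], term)
        e5 = getattr(energies[0.5], term)
        e1 = getattr(energies[1.0], term)
        assert e5 == pytest.approx(0.5 * (e0 + e1), rel=1e-12)
        assert e1 != pytest.approx(e0)  # 1-4 pairs really contribute


# ---------------------------------------------------------------------------
# Force-gradient consistency and invariances
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("species", ["EMTr", "OBz"])
def test_forces_match_numerical_gradient(ff, species):
    """Central-difference oracle over every term class at once."""
    t = build_molecule(species)
    comp = Composition([(t, 1)], 5000.0)
    sys = build_system(comp, ff, reference_geometry(t) + 20.0)
    rep = total_energy_forces(sys, method="cutoff", rc=None)
    num = numerical_forces(sys, method="cutoff", rc=None)
    scale = np.abs(num).max()
    assert np.abs(rep.forces - num).max() / scale < 1e-5


def test_forces_match_gradient_under_ewald(ff):
    rng = np.random.default_rng(11)
    n = 10
    pos = rng.uniform(2.0, 8.0, size=(n, 3))
    q = rng.normal(size=n)
    q -= q.mean()
    sys = bare_topology(ff, pos, q=q, sigma=np.full(n, 2.5),
                        epsilon=np.full(n, 0.3), box=10.0)
    rep = total_energy_forces(sys, method="ewald", rc=4.9)
    num = numerical_forces(sys, method="ewald", rc=4.9)
    assert np.abs(rep.forces - num).max() / np.abs(num).max() < 1e-5


def test_forces_sum_to_zero(ff):
    t = build_molecule("EMTr")
    comp = Composition([(t, 2)], 5000.0)
    geo = reference_geometry(t)
    sys = build_system(comp, ff, np.vstack([geo + 15.0, geo + 25.0]))
    rep = total_energy_forces(sys, method="cutoff", rc=None)
    assert np.abs(rep.forces.sum(axis=0)).max() < 1e-8


def test_energy_invariant_under_rigid_motion(ff):
    from scipy.spatial.transform import Rotation

    t = build_molecule("OBz")
    comp = Composition([(t, 2)], 6000.0)
    geo = reference_geometry(t)
    pos = np.vstack([geo + 20.0, geo + 28.0])
    sys = build_system(comp, ff, pos)
    e0 = total_energy_forces(sys, method="cutoff", rc=None).total
    # translation (including across the periodic boundary)
    sys.positions = pos + np.array([37.0, -11.0, 5.0])
    e1 = total_energy_forces(sys, method="cutoff", rc=None).total
    # rotation about the box center
    rot = Rotation.from_euler("zyx", [0.3, -1.1, 0.7]).as_matrix()
    center = pos.mean(axis=0)
    sys.positions = (pos - center) @ rot.T + center
    e2 = total_energy_forces(sys, method="cutoff", rc=None).total
    assert e1 == pytest.approx(e0, rel=1e-10)
    assert e2 == pytest.approx(e0, rel=1e-9)


def test_single_rigid_water_has_no_bonded_energy(ff):
    w = build_molecule("TIP4PEW")
    comp = Composition([(w, 1)], 3000.0)
    sys = build_system(comp, ff, reference_geometry(w) + 10.0)
    rep = total_energy_forces(sys, method="cutoff", rc=None)
    assert rep.bond == 0.0 and rep.angle == 0.0 and rep.torsion == 0.0
    assert rep.lj == 0.0 and rep.coulomb == pytest.approx(0.0, abs=1e-12)


# ---------------------------------------------------------------------------
# Ewald vs closed-form lattice sums
# ---------------------------------------------------------------------------

def test_ewald_matches_madelung_rocksalt(rocksalt):
    sys, d = rocksalt
    _, e_c = nonbonded_energy(sys, method="ewald", rc=sys.box_edge / 2,
                              accuracy=1e-9)
    expected = -4.0 * COULOMB * MADELUNG_NACL / d  # 4 ion pairs in the cell
    assert e_c == pytest.approx(expected, abs=1e-3)


def test_ewald_matches_madelung_cscl(ff):
    a = 4.0
    pos = np.array([[0.0, 0, 0], [a / 2, a / 2, a / 2]])
    sys = bare_topology(ff, pos, q=[1.0, -1.0], box=a)
    _, e_c = nonbonded_energy(sys, method="ewald", rc=a / 2, accuracy=1e-9)
    d_nn = a * math.sqrt(3.0) / 2.0
    expected = -COULOMB * MADELUNG_CSCL / d_nn
    assert e_c == pytest.approx(expected, abs=1e-3)


def test_ewald_matches_evjen_direct_sum(rocksalt):
    """Brute-force direct lattice sum with Evjen boundary weights."""
    sys, d = rocksalt
    _, e_c = nonbonded_energy(sys, method="ewald", rc=sys.box_edge / 2,
                              accuracy=1e-9)
    # Evjen sum for the NaCl Madelung constant over a (2n+1)³ block
    n = 8
    m = 0.0
    for i in range(-n, n + 1):
        for j in range(-n, n + 1):
            for k in range(-n, n + 1):
                if i == j == k == 0:
                    continue
                w = 1.0
                for c in (i, j, k):
                    if abs(c) == n:
                        w *= 0.5
                m += w * (-1.0) ** (i + j + k) / math.sqrt(i * i + j * j + k * k)
    e_direct = 4.0 * COULOMB * m / d  # m is negative
    assert e_c == pytest.approx(e_direct, abs=5e-2)


def test_ewald_insensitive_to_cutoff_split(rocksalt):
    """The physical energy must not depend on the real/reciprocal split."""
    sys, _ = rocksalt
    vals = [
        nonbonded_energy(sys, method="ewald", rc=rc, accuracy=1e-8)[1]
        for rc in (1.4, 1.8, 2.0)
    ]
    assert max(vals) - min(vals) < 1e-3
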