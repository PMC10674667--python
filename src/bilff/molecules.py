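"""Molecule templates, bonded-term enumeration and composition bookkeeping.

Templates are hand-curated molecular graphs with per-atom type
assignments.  The fully parameterized species are the
1-ethyl-3-methyl-1,2,3-triazolium cation (``EMTr``), the benzoate anion
(``OBz``) and rigid TIP4P-Ew water (``TIP4PEW``).  The imidazolium
cation (``EMIm``) and acetate (``OAc``) graphs are included for
composition/density bookkeeping and can be simulated once a user
parameter file supplying their types is merged into the force field.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .parameters import ATOMIC_WEIGHTS, ForceField, ParameterError
from .units import N_AVOGADRO, pm_to_angstrom

__all__ = [
    "MoleculeTemplate",
    "VirtualSite",
    "Composition",
    "build_molecule",
    "enumerate_bonded_terms",
    "molar_mass",
    "system_density",
    "reference_geometry",
    "SPECIES",
]


@dataclass(frozen=True)
class VirtualSite:
    """Massless interaction site placed as a linear combination of parents.

    r_site = r_p0 + c · ((r_p1 − r_p0) + (r_p2 − r_p0)); forces on the
    site are redistributed with the same weights.  Valid for rigid
    parents (the combination coefficient is then a geometric constant).
    """

    index: int
    parents: tuple[int, int, int]
    coeff: float


@dataclass
class MoleculeTemplate:
    """Molecular graph of one species with atom-type assignment."""

    name: str
    atoms: list[tuple[str, str]]  # (type name, element)
    bonds: list[tuple[int, int]]
    net_charge_target: float = 0.0
    constraints: list[tuple[int, int, float]] = field(default_factory=list)
    virtual_sites: list[VirtualSite] = field(default_factory=list)
    rigid: bool = False

    def __post_init__(self):
        n = len(self.atoms)
        for i, j in self.bonds:
            if not (0 <= i < n and 0 <= j < n and i != j):
                raise ValueError(f"invalid bond indices ({i}, {j}) in {self.name}")
        if n > 1 and not self._connected():
            raise ValueError(f"molecular graph of {self.name} is not connected")

    def _connected(self) -> bool:
        adj = self.adjacency()
        seen = {0}
        stack = [0]
        while stack:
            for k in adj[stack.pop()]:
                if k not in seen:
                    seen.add(k)
                    stack.append(k)
        real = set(range(len(self.atoms))) - {v.index for v in self.virtual_sites}
        return real <= seen

    def adjacency(self) -> dict[int, list[int]]:
        adj: dict[int, list[int]] = {i: [] for i in range(len(self.atoms))}
        for i, j in self.bonds:
            adj[i].append(j)
            adj[j].append(i)
        return adj

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    def elements(self) -> list[str]:
        return [el for _, el in self.atoms]

    def type_counts(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for t, _ in self.atoms:
            counts[t] = counts.get(t, 0) + 1
        return counts

    def charges(self, ff: ForceField) -> np.ndarray:
        return np.array([ff.atom_type(t, self.name).q for t, _ in self.atoms])

    def net_charge(self, ff: ForceField) -> float:
        q = float(self.charges(ff).sum())
        if abs(q - self.net_charge_target) > 1e-6:
            raise ValueError(
                f"{self.name}: charge sum {q:+.6f} e differs from target "
                f"{self.net_charge_target:+.3f} e"
            )
        return q


# ---------------------------------------------------------------------------
# Species definitions
# ---------------------------------------------------------------------------

def _emtr() -> MoleculeTemplate:
    # Ring N1(ethyl)-N2-N3(methyl)-C4-C5; HCW on C4/C5.  The N-methyl
    # carbon and its hydrogens carry the C1/H1 parameters, the ethyl
    # CH2 is C1 with H1 hydrogens and the terminal CH3 is CE with HC.
    atoms = [
        ("NA", "N"),   # 0  N1 (ethyl)
        ("NR", "N"),   # 1  N2
        ("NA", "N"),   # 2  N3 (methyl)
        ("CW", "C"),   # 3  C4
        ("CW", "C"),   # 4  C5
        ("HCW", "H"),  # 5  on C4
        ("HCW", "H"),  # 6  on C5
        ("C1", "C"),   # 7  N-methyl carbon (CM alias)
        ("H1", "H"), ("H1", "H"), ("H1", "H"),  # 8-10 methyl H (HM alias)
        ("C1", "C"),   # 11 ethyl CH2
        ("H1", "H"), ("H1", "H"),               # 12-13
        ("CE", "C"),   # 14 ethyl CH3
        ("HC", "H"), ("HC", "H"), ("HC", "H"),  # 15-17 (HE alias)
    ]
    bonds = [
        (0, 1), (1, 2), (2, 3), (3, 4), (4, 0),
        (3, 5), (4, 6),
        (2, 7), (7, 8), (7, 9), (7, 10),
        (0, 11), (11, 12), (11, 13), (11, 14),
        (14, 15), (14, 16), (14, 17),
    ]
    return MoleculeTemplate("EMTr", atoms, bonds, net_charge_target=+0.820)


def _obz() -> MoleculeTemplate:
    # Carboxylate + aromatic ring; the symmetry-equivalent ortho (C2/H2)
    # and meta (C3/H3) positions each appear twice.
    atoms = [
        ("CO", "C"),   # 0 carboxylate carbon
        ("O2", "O"), ("O2", "O"),  # 1-2
        ("C1", "C"),   # 3 ipso
        ("C2", "C"), ("C2", "C"),  # 4-5 ortho
        ("C3", "C"), ("C3", "C"),  # 6-7 meta
        ("C4", "C"),   # 8 para
        ("H2", "H"), ("H2", "H"),  # 9-10
        ("H3", "H"), ("H3", "H"),  # 11-12
        ("H4", "H"),   # 13
    ]
    bonds = [
        (0, 1), (0, 2), (0, 3),
        (3, 4), (4, 6), (6, 8), (8, 7), (7, 5), (5, 3),
        (4, 9), (5, 10), (6, 11), (7, 12), (8, 13),
    ]
    return MoleculeTemplate("OBz", atoms, bonds, net_charge_target=-0.820)


_WATER_ROH = 0.9572
_WATER_HOH_DEG = 104.52
_WATER_ROM = 0.125
_WATER_RHH = 2.0 * _WATER_ROH * math.sin(math.radians(_WATER_HOH_DEG / 2.0))
# r_M = r_O + c ((r_H1-r_O)+(r_H2-r_O)) with |r_H1+r_H2-2 r_O| fixed by SHAKE
_WATER_MCOEFF = _WATER_ROM / (2.0 * _WATER_ROH * math.cos(math.radians(_WATER_HOH_DEG / 2.0)))


def _water() -> MoleculeTemplate:
    atoms = [("OW", "O"), ("HW", "H"), ("HW", "H"), ("MW", "M")]
    bonds = [(0, 1), (0, 2), (0, 3)]  # O-M edge only defines exclusions
    return MoleculeTemplate(
        "TIP4PEW",
        atoms,
        bonds,
        net_charge_target=0.0,
        constraints=[
            (0, 1, _WATER_ROH),
            (0, 2, _WATER_ROH),
            (1, 2, _WATER_RHH),
        ],
        virtual_sites=[VirtualSite(3, (0, 1, 2), _WATER_MCOEFF)],
        rigid=True,
    )


def _emim() -> MoleculeTemplate:
    # Imidazolium graph (ring N1-C2-N3-C4-C5); type names follow the
    # prior parameter set and must be supplied via a merged file.
    atoms = [
        ("NA", "N"),   # 0 N1 (ethyl)
        ("CR", "C"),   # 1 C2
        ("NA", "N"),   # 2 N3 (methyl)
        ("CW", "C"),   # 3 C4
        ("CW", "C"),   # 4 C5
        ("HCR", "H"),  # 5 on C2
        ("HCW", "H"), ("HCW", "H"),  # 6-7 on C4/C5
        ("C1", "C"),   # 8 N-methyl
        ("H1", "H"), ("H1", "H"), ("H1", "H"),  # 9-11
        ("C1", "C"),   # 12 ethyl CH2
        ("H1", "H"), ("H1", "H"),               # 13-14
        ("CE", "C"),   # 15 ethyl CH3
        ("HC", "H"), ("HC", "H"), ("HC", "H"),  # 16-18
    ]
    bonds = [
        (0, 1), (1, 2), (2, 3), (3, 4), (4, 0),
        (1, 5), (3, 6), (4, 7),
        (2, 8), (8, 9), (8, 10), (8, 11),
        (0, 12), (12, 13), (12, 14), (12, 15),
        (15, 16), (15, 17), (15, 18),
    ]
    return MoleculeTemplate("EMIm", atoms, bonds, net_charge_target=+0.820)


def _oac() -> MoleculeTemplate:
    atoms = [
        ("CO", "C"),   # 0 carboxylate carbon
        ("O2", "O"), ("O2", "O"),  # 1-2
        ("CT", "C"),   # 3 methyl
        ("HC", "H"), ("HC", "H"), ("HC", "H"),  # 4-6
    ]
    bonds = [(0, 1), (0, 2), (0, 3), (3, 4), (3, 5), (3, 6)]
    return MoleculeTemplate("OAc", atoms, bonds, net_charge_target=-0.820)


SPECIES = {
    "EMTr": _emtr,
    "OBz": _obz,
    "TIP4PEW": _water,
    "EMIm": _emim,
    "OAc": _oac,
}


def build_molecule(species: str) -> MoleculeTemplate:
    """Return the curated template for one of the supported species."""
    try:
        return SPECIES[species]()
    except KeyError:
        raise ValueError(
            f"unknown species {species!r}; available: {sorted(SPECIES)}"
        ) from None


# ---------------------------------------------------------------------------
# Bonded-term enumeration
# ---------------------------------------------------------------------------

def enumerate_bonded_terms(
    template: MoleculeTemplate, ff: ForceField | None = None
) -> tuple[list[tuple[int, int]], list[tuple[int, int, int]], list[tuple[int, int, int, int]]]:
    """Enumerate bonds, angles (connected triples) and proper dihedrals.

    Rigid templates (constrained water) contribute no bonded terms.
    With a force field given, every term is checked to resolve to a
    parameter row via its atom-class tuple; a missing row raises
    :class:`~bilff.parameters.ParameterError` naming the tuple.
    """
    if template.rigid:
        return [], [], []
    virtual = {v.index for v in template.virtual_sites}
    adj = template.adjacency()
    bonds = sorted(
        (min(i, j), max(i, j)) for i, j in template.bonds
        if i not in virtual and j not in virtual
    )
    angles = []
    for j in range(template.n_atoms):
        nbrs = sorted(adj[j])
        for a in range(len(nbrs)):
            for b in range(a + 1, len(nbrs)):
                i, k = nbrs[a], nbrs[b]
                if virtual & {i, j, k}:
                    continue
                angles.append((i, j, k) if i < k else (k, j, i))
    angles.sort()
    dihedrals = set()
    for j, k in bonds:
        for i in adj[j]:
            if i == k:
                continue
            for l in adj[k]:
                if l == j or l == i:
                    continue
                if virtual & {i, j, k, l}:
                    continue
                quad = (i, j, k, l)
                if quad[::-1] < quad:
                    quad = quad[::-1]
                dihedrals.add(quad)
    dihedrals = sorted(dihedrals)

    if ff is not None:
        cls = [ff.atom_type(t, template.name).atom_class for t, _ in template.atoms]
        missing = []
        for i, j in bonds:
            try:
                ff.bond(cls[i], cls[j])
            except ParameterError:
                missing.append(("bond", (cls[i], cls[j])))
        for i, j, k in angles:
            try:
                ff.angle(cls[i], cls[j], cls[k])
            except ParameterError:
                missing.append(("angle", (cls[i], cls[j], cls[k])))
        for i, j, k, l in dihedrals:
            try:
                ff.torsion(cls[i], cls[j], cls[k], cls[l])
            except ParameterError:
                missing.append(("dihedral", (cls[i], cls[j], cls[k], cls[l])))
        if missing:
            rows = ", ".join(f"{kind} {tup}" for kind, tup in missing)
            raise ParameterError(
                f"{template.name}: no parameter row for {rows}"
            )
    return bonds, angles, dihedrals


def molar_mass(template: MoleculeTemplate) -> float:
    """Molar mass in g/mol from standard atomic weights."""
    return float(sum(ATOMIC_WEIGHTS[el] for el in template.elements()))


# ---------------------------------------------------------------------------
# Compositions
# ---------------------------------------------------------------------------

@dataclass
class Composition:
    """A packed cubic box: list of (template, count) and box edge in pm."""

    items: list[tuple[MoleculeTemplate, int]]
    box_edge_pm: float

    def __post_init__(self):
        if self.box_edge_pm <= 0:
            raise ValueError("box edge must be positive")
        for _, n in self.items:
            if n <= 0:
                raise ValueError("molecule counts must be positive")

    @property
    def box_edge(self) -> float:
        """Box edge in Å."""
        return pm_to_angstrom(self.box_edge_pm)

    def total_atoms(self) -> int:
        return sum(t.n_atoms * n for t, n in self.items)


def system_density(comp: Composition) -> float:
    """Mass density ρ = Σ count·M / (N_A · V) in g/cm³."""
    mass_g = sum(n * molar_mass(t) for t, n in comp.items) / N_AVOGADRO
    edge_cm = comp.box_edge_pm * 1e-10
    return mass_g / edge_cm**3


# ---------------------------------------------------------------------------
# Rough reference geometries (for packing; refined by minimization)
# ---------------------------------------------------------------------------

def _ring(n: int, bond: float) -> np.ndarray:
    r = bond / (2.0 * math.sin(math.pi / n))
    ang = 2.0 * math.pi * np.arange(n) / n
    return np.column_stack([r * np.cos(ang), r * np.sin(ang), np.zeros(n)])


def _radial(pos: np.ndarray, center: np.ndarray, dist: float) -> np.ndarray:
    u = pos - center
    u /= np.linalg.norm(u)
    return pos + dist * u


def _methyl(c: np.ndarray, attach: np.ndarray, dist: float = 1.09) -> np.ndarray:
    """Three H atoms tetrahedrally around carbon ``c`` away from ``attach``."""
    axis = c - attach
    axis = axis / np.linalg.norm(axis)
    ref = np.array([0.0, 0.0, 1.0])
    if abs(axis @ ref) > 0.9:
        ref = np.array([1.0, 0.0, 0.0])
    e1 = np.cross(axis, ref)
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(axis, e1)
    out = []
    for k in range(3):
        phi = 2.0 * math.pi * k / 3.0
        d = math.cos(math.radians(180 - 109.5)) * axis + math.sin(
            math.radians(180 - 109.5)
        ) * (math.cos(phi) * e1 + math.sin(phi) * e2)
        out.append(c + dist * d / np.linalg.norm(d))
    return np.array(out)


def reference_geometry(template: MoleculeTemplate) -> np.ndarray:
    """Approximate 3D coordinates (Å) for a template, suitable as a
    packing/minimization starting point.  Ring systems are laid out as
    regular polygons with published bond lengths; substituents are
    placed with idealized valence geometry."""
    name = template.name
    n = template.n_atoms
    xyz = np.zeros((n, 3))
    if name == "EMTr":
        ring = _ring(5, 1.38)
        xyz[:5] = ring  # N1 N2 N3 C4 C5
        cen = ring.mean(axis=0)
        xyz[5] = _radial(ring[3], cen, 1.088)
        xyz[6] = _radial(ring[4], cen, 1.088)
        xyz[7] = _radial(ring[2], cen, 1.488)          # N-methyl C
        xyz[8:11] = _methyl(xyz[7], ring[2], 1.099)
        xyz[11] = _radial(ring[0], cen, 1.488)         # ethyl CH2
        ch2_dir = (xyz[11] - cen)
        ch2_dir /= np.linalg.norm(ch2_dir)
        zhat = np.array([0.0, 0.0, 1.0])
        d12 = 0.5 * zhat + 0.3 * ch2_dir
        xyz[12] = xyz[11] + 1.099 * d12 / np.linalg.norm(d12)
        d13 = -0.5 * zhat + 0.3 * ch2_dir
        xyz[13] = xyz[11] + 1.099 * d13 / np.linalg.norm(d13)
        # CE bends off the radial axis to keep the N-C-C angle near 111°
        inplane = np.array([-ch2_dir[1], ch2_dir[0], 0.0])
        bend = math.radians(180.0 - 110.9)
        dce = math.cos(bend) * ch2_dir + math.sin(bend) * inplane
        xyz[14] = xyz[11] + 1.533 * dce
        xyz[15:18] = _methyl(xyz[14], xyz[11], 1.099)
    elif name == "OBz":
        ring = _ring(6, 1.387)
        xyz[3:9] = ring[[0, 1, 5, 2, 4, 3]]  # ipso, ortho×2, meta×2, para
        cen = ring.mean(axis=0)
        xyz[0] = _radial(xyz[3], cen, 1.504)           # CO
        co_dir = (xyz[0] - xyz[3]) / np.linalg.norm(xyz[0] - xyz[3])
        perp = np.cross(co_dir, [0.0, 0.0, 1.0])
        half = math.radians(126.0 / 2.0)
        for k, s in ((1, 1.0), (2, -1.0)):
            d = math.cos(half) * co_dir + s * math.sin(half) * perp
            xyz[k] = xyz[0] + 1.282 * d
        for h, c in ((9, 4), (10, 5), (11, 6), (12, 7), (13, 8)):
            xyz[h] = _radial(xyz[c], cen, 1.088)
    elif name == "TIP4PEW":
        half = math.radians(_WATER_HOH_DEG / 2.0)
        xyz[0] = [0.0, 0.0, 0.0]
        xyz[1] = [_WATER_ROH * math.sin(half), _WATER_ROH * math.cos(half), 0.0]
        xyz[2] = [-_WATER_ROH * math.sin(half), _WATER_ROH * math.cos(half), 0.0]
        xyz[3] = [0.0, _WATER_ROM, 0.0]
    elif name == "EMIm":
        ring = _ring(5, 1.38)
        xyz[:5] = ring
        cen = ring.mean(axis=0)
        xyz[5] = _radial(ring[1], cen, 1.08)
        xyz[6] = _radial(ring[3], cen, 1.08)
        xyz[7] = _radial(ring[4], cen, 1.08)
        xyz[8] = _radial(ring[2], cen, 1.47)
        xyz[9:12] = _methyl(xyz[8], ring[2], 1.09)
        xyz[12] = _radial(ring[0], cen, 1.47)
        perp = np.array([0.0, 0.0, 1.0])
        d = (xyz[12] - cen) / np.linalg.norm(xyz[12] - cen)
        xyz[13] = xyz[12] + 1.09 * (0.6 * perp + 0.4 * d) / np.linalg.norm(0.6 * perp + 0.4 * d)
        xyz[14] = xyz[12] + 1.09 * (-0.6 * perp + 0.4 * d) / np.linalg.norm(0.6 * perp + 0.4 * d)
        inplane = np.array([-d[1], d[0], 0.0])
        bend = math.radians(180.0 - 111.0)
        xyz[15] = xyz[12] + 1.53 * (math.cos(bend) * d + math.sin(bend) * inplane)
        xyz[16:19] = _methyl(xyz[15], xyz[12], 1.09)
    elif name == "OAc":
        xyz[0] = [0.0, 0.0, 0.0]
        half = math.radians(126.0 / 2.0)
        xyz[1] = [1.28 * math.cos(half), 1.28 * math.sin(half), 0.0]
        xyz[2] = [1.28 * math.cos(half), -1.28 * math.sin(half), 0.0]
        xyz[3] = [-1.52, 0.0, 0.0]
        xyz[4:7] = _methyl(xyz[3], xyz[0], 1.09)
    else:  # generic: linear chain fallback
        for i in range(n):
            xyz[i] = [1.4 * i, 0.0, 0.0]
    return xyz
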