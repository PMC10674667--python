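"""Packed periodic systems: flattened atom arrays, bonded-term index
lists, exclusion bookkeeping and virtual-site handling."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .molecules import Composition, MoleculeTemplate, enumerate_bonded_terms
from .parameters import ForceField

__all__ = ["SystemTopology", "build_system"]


@dataclass
class SystemTopology:
    """Flattened periodic system ready for energy/force evaluation.

    All per-atom quantities are numpy arrays over the global atom index;
    bonded terms carry pre-resolved parameter columns so the evaluator
    never does dictionary lookups in the inner loop.
    """

    ff: ForceField
    box_edge: float  # Å
    positions: np.ndarray  # (N, 3) Å
    q: np.ndarray
    sigma: np.ndarray
    epsilon: np.ndarray
    mass: np.ndarray
    mol_id: np.ndarray
    species: list[str]
    type_names: list[str]
    elements: list[str]
    # bonded terms
    bond_idx: np.ndarray  # (nb, 2)
    bond_l0: np.ndarray
    bond_kl: np.ndarray
    angle_idx: np.ndarray  # (na, 3)
    angle_theta0: np.ndarray  # rad
    angle_ktheta: np.ndarray
    dih_idx: np.ndarray  # (nd, 4)
    dih_v: np.ndarray  # (nd, 4) V1..V4
    # exclusions: (i, j, f) with i < j, f the LJ/Coulomb scale factor
    scaled_pairs: np.ndarray  # (ns, 2) int
    scaled_f: np.ndarray  # (ns,)
    # constraints and virtual sites (global indices)
    constraints: list[tuple[int, int, float]] = field(default_factory=list)
    virtual_sites: list[tuple[int, tuple[int, int, int], float]] = field(
        default_factory=list
    )

    @property
    def n_atoms(self) -> int:
        return len(self.q)

    @property
    def volume(self) -> float:
        return self.box_edge**3

    def net_charge(self) -> float:
        return float(self.q.sum())

    def is_virtual(self) -> np.ndarray:
        mask = np.zeros(self.n_atoms, dtype=bool)
        for idx, _, _ in self.virtual_sites:
            mask[idx] = True
        return mask

    def _vsite_arrays(self):
        arr = getattr(self, "_vsite_cache", None)
        if arr is None:
            idx = np.array([v[0] for v in self.virtual_sites], dtype=int)
            par = np.array([v[1] for v in self.virtual_sites], dtype=int).reshape(-1, 3)
            c = np.array([v[2] for v in self.virtual_sites])
            arr = (idx, par, c)
            self._vsite_cache = arr
        return arr

    def place_virtual_sites(self, positions: np.ndarray | None = None) -> np.ndarray:
        """Reposition massless sites from their parent atoms (in place)."""
        r = self.positions if positions is None else positions
        if self.virtual_sites:
            idx, par, c = self._vsite_arrays()
            c = c[:, None]
            r[idx] = (1.0 - 2.0 * c) * r[par[:, 0]] + c * r[par[:, 1]] + c * r[par[:, 2]]
        return r

    def spread_virtual_forces(self, forces: np.ndarray) -> np.ndarray:
        """Redistribute forces from massless sites onto parents (in place)."""
        if self.virtual_sites:
            idx, par, c = self._vsite_arrays()
            f = forces[idx].copy()
            c = c[:, None]
            np.add.at(forces, par[:, 0], (1.0 - 2.0 * c) * f)
            np.add.at(forces, par[:, 1], c * f)
            np.add.at(forces, par[:, 2], c * f)
            forces[idx] = 0.0
        return forces

    def select(self, type_name: str, species: str | None = None) -> np.ndarray:
        """Global indices of atoms with the given type name."""
        out = [
            i
            for i, (t, s) in enumerate(zip(self.type_names, self.species))
            if t == type_name and (species is None or s == species)
        ]
        return np.array(out, dtype=int)


def _graph_distances(template: MoleculeTemplate, max_d: int = 3) -> dict[tuple[int, int], int]:
    """Shortest bond-path distance for all intramolecular pairs ≤ max_d."""
    adj = template.adjacency()
    dist: dict[tuple[int, int], int] = {}
    for src in range(template.n_atoms):
        level = {src}
        seen = {src}
        for d in range(1, max_d + 1):
            nxt = set()
            for u in level:
                for v in adj[u]:
                    if v not in seen:
                        nxt.add(v)
                        seen.add(v)
            for v in nxt:
                if src < v:
                    dist[(src, v)] = d
            level = nxt
    return dist


def build_system(
    comp: Composition,
    ff: ForceField,
    positions: np.ndarray | None = None,
) -> SystemTopology:
    """Flatten a composition into a :class:`SystemTopology`.

    ``positions`` (N, 3) Å may be supplied (e.g. from a packing run or a
    trajectory frame); otherwise they are zero-initialized and must be
    set before evaluating energies.
    """
    q, sig, eps, mass, mol_id = [], [], [], [], []
    species, type_names, elements = [], [], []
    bond_rows, angle_rows, dih_rows = [], [], []
    constraints: list[tuple[int, int, float]] = []
    vsites: list[tuple[int, tuple[int, int, int], float]] = []
    scaled: list[tuple[int, int, float]] = []
    exc = ff.exclusions
    fmap = {1: exc.f12, 2: exc.f13, 3: exc.f14}

    offset = 0
    mol = 0
    for template, count in comp.items:
        types = [ff.atom_type(t, template.name) for t, _ in template.atoms]
        cls = [t.atom_class for t in types]
        bonds, angles, dihedrals = enumerate_bonded_terms(template, ff)
        gdist = _graph_distances(template)
        for _ in range(count):
            for t, (tn, el) in zip(types, template.atoms):
                q.append(t.q)
                sig.append(t.sigma)
                eps.append(t.epsilon)
                mass.append(t.mass)
                mol_id.append(mol)
                species.append(template.name)
                type_names.append(tn)
                elements.append(el)
            for i, j in bonds:
                p = ff.bond(cls[i], cls[j])
                bond_rows.append((offset + i, offset + j, p.l0, p.kl))
            for i, j, k in angles:
                p = ff.angle(cls[i], cls[j], cls[k])
                angle_rows.append((offset + i, offset + j, offset + k, p.theta0_rad, p.ktheta))
            for i, j, k, l in dihedrals:
                p = ff.torsion(cls[i], cls[j], cls[k], cls[l])
                dih_rows.append(
                    (offset + i, offset + j, offset + k, offset + l, p.v1, p.v2, p.v3, p.v4)
                )
            for (i, j), d in gdist.items():
                scaled.append((offset + i, offset + j, fmap[d]))
            for i, j, d0 in template.constraints:
                constraints.append((offset + i, offset + j, d0))
            for v in template.virtual_sites:
                vsites.append(
                    (offset + v.index, tuple(offset + p for p in v.parents), v.coeff)
                )
            offset += template.n_atoms
            mol += 1

    n = offset
    if positions is None:
        positions = np.zeros((n, 3))
    else:
        positions = np.asarray(positions, dtype=float).copy()
        if positions.shape != (n, 3):
            raise ValueError(f"positions shape {positions.shape} != ({n}, 3)")

    def _arr(rows, ncol_idx, ncol_par):
        if not rows:
            return np.zeros((0, ncol_idx), dtype=int), np.zeros((0, ncol_par))
        a = np.array(rows, dtype=float)
        return a[:, :ncol_idx].astype(int), a[:, ncol_idx:]

    b_idx, b_par = _arr(bond_rows, 2, 2)
    a_idx, a_par = _arr(angle_rows, 3, 2)
    d_idx, d_par = _arr(dih_rows, 4, 4)
    if scaled:
        s = np.array(scaled, dtype=float)
        s_idx, s_f = s[:, :2].astype(int), s[:, 2]
    else:
        s_idx, s_f = np.zeros((0, 2), dtype=int), np.zeros(0)

    return SystemTopology(
        ff=ff,
        box_edge=comp.box_edge,
        positions=positions,
        q=np.array(q),
        sigma=np.array(sig),
        epsilon=np.array(eps),
        mass=np.array(mass),
        mol_id=np.array(mol_id, dtype=int),
        species=species,
        type_names=type_names,
        elements=elements,
        bond_idx=b_idx,
        bond_l0=b_par[:, 0] if len(b_par) else np.zeros(0),
        bond_kl=b_par[:, 1] if len(b_par) else np.zeros(0),
        angle_idx=a_idx,
        angle_theta0=a_par[:, 0] if len(a_par) else np.zeros(0),
        angle_ktheta=a_par[:, 1] if len(a_par) else np.zeros(0),
        dih_idx=d_idx,
        dih_v=d_par if len(d_par) else np.zeros((0, 4)),
        scaled_pairs=s_idx,
        scaled_f=s_f,
        constraints=constraints,
        virtual_sites=vsites,
    )
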