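"""File formats: extended XYZ, PDB, LAMMPS data ("full" style),
Gaussian cube for spatial distributions and TSV result tables.

Every writer has a matching reader and round trips are lossless at the
declared precision (10⁻³ Å for coordinates)."""

from __future__ import annotations

from pathlib import Path

import numpy as np

from .analysis import RDFResult, SDFResult
from .dynamics import Trajectory
from .molecules import enumerate_bonded_terms
from .topology import SystemTopology

__all__ = [
    "write_xyz",
    "read_xyz",
    "write_pdb",
    "read_pdb",
    "write_lammps_data",
    "read_lammps_data",
    "write_cube",
    "write_rdf_tsv",
    "ParseError",
]

_BOHR = 0.529177210903  # Å


class ParseError(ValueError):
    """Malformed record; message carries the line number."""


# ---------------------------------------------------------------------------
# Extended XYZ (box edge and time on the comment line)
# ---------------------------------------------------------------------------

def write_xyz(traj: Trajectory, path: str | Path, elements: list[str] | None = None) -> None:
    if elements is None:
        if traj.topology is None:
            raise ValueError("need element labels (no topology attached)")
        elements = traj.topology.elements
    with open(path, "w") as fh:
        for f in range(traj.n_frames):
            fh.write(f"{traj.n_atoms}\n")
            fh.write(f"time={traj.times[f]:.4f} fs box={traj.boxes[f]:.6f} A\n")
            for el, (x, y, z) in zip(elements, traj.positions[f]):
                fh.write(f"{el} {x:.4f} {y:.4f} {z:.4f}\n")


def read_xyz(path: str | Path) -> tuple[Trajectory, list[str]]:
    """Read an extended-XYZ trajectory; returns (trajectory, elements)."""
    times, frames, boxes = [], [], []
    elements: list[str] = []
    lines = Path(path).read_text().splitlines()
    i = 0
    while i < len(lines):
        if not lines[i].strip():
            i += 1
            continue
        try:
            n = int(lines[i].strip())
        except ValueError:
            raise ParseError(f"line {i + 1}: expected atom count") from None
        comment = lines[i + 1] if i + 1 < len(lines) else ""
        t, box = 0.0, 0.0
        for tok in comment.split():
            if tok.startswith("time="):
                t = float(tok[5:])
            elif tok.startswith("box="):
                box = float(tok[4:])
        frame = np.zeros((n, 3))
        els = []
        for k in range(n):
            ln = i + 2 + k
            tok = lines[ln].split()
            if len(tok) < 4:
                raise ParseError(f"line {ln + 1}: expected 'element x y z'")
            els.append(tok[0])
            try:
                frame[k] = [float(tok[1]), float(tok[2]), float(tok[3])]
            except ValueError:
                raise ParseError(f"line {ln + 1}: bad coordinate") from None
        if not elements:
            elements = els
        times.append(t)
        frames.append(frame)
        boxes.append(box if box > 0 else 1.0)
        i += 2 + n
    if not frames:
        return (
            Trajectory(np.zeros(0), np.zeros((0, 0, 3)), np.zeros(0)),
            [],
        )
    return (
        Trajectory(np.array(times), np.array(frames), np.array(boxes)),
        elements,
    )


# ---------------------------------------------------------------------------
# PDB (CRYST1 + MODEL records)
# ---------------------------------------------------------------------------

def write_pdb(traj: Trajectory, path: str | Path, elements: list[str] | None = None) -> None:
    if elements is None:
        if traj.topology is None:
            raise ValueError("need element labels (no topology attached)")
        elements = traj.topology.elements
    with open(path, "w") as fh:
        for f in range(traj.n_frames):
            b = traj.boxes[f]
            fh.write(
                f"CRYST1{b:9.3f}{b:9.3f}{b:9.3f}  90.00  90.00  90.00 P 1           1\n"
            )
            fh.write(f"MODEL     {f + 1:4d}\n")
            for a, (el, (x, y, z)) in enumerate(zip(elements, traj.positions[f]), 1):
                name = el[:2].rjust(2)
                fh.write(
                    f"HETATM{a % 100000:5d} {name:<4s}MOL A   1    "
                    f"{x:8.3f}{y:8.3f}{z:8.3f}  1.00  0.00          {el:>2s}\n"
                )
            fh.write("ENDMDL\n")
        fh.write("END\n")


def read_pdb(path: str | Path) -> tuple[Trajectory, list[str]]:
    times, frames, boxes = [], [], []
    elements: list[str] = []
    cur: list[list[float]] = []
    cur_els: list[str] = []
    box = 1.0
    for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
        rec = line[:6]
        if rec == "CRYST1":
            try:
                box = float(line[6:15])
            except ValueError:
                raise ParseError(f"line {lineno}: bad CRYST1 record") from None
        elif rec in ("HETATM", "ATOM  "):
            try:
                x = float(line[30:38])
                y = float(line[38:46])
                z = float(line[46:54])
            except ValueError:
                raise ParseError(f"line {lineno}: bad coordinates") from None
            cur.append([x, y, z])
            cur_els.append(line[76:78].strip() or line[12:14].strip())
        elif rec.startswith("ENDMDL"):
            frames.append(np.array(cur))
            boxes.append(box)
            times.append(float(len(times)))
            if not elements:
                elements = cur_els
            cur, cur_els = [], []
    if cur:
        frames.append(np.array(cur))
        boxes.append(box)
        times.append(float(len(times)))
        if not elements:
            elements = cur_els
    if not frames:
        return Trajectory(np.zeros(0), np.zeros((0, 0, 3)), np.zeros(0)), []
    return Trajectory(np.array(times), np.array(frames), np.array(boxes)), elements


# ---------------------------------------------------------------------------
# LAMMPS data file, atom style "full"
# ---------------------------------------------------------------------------

def write_lammps_data(sys: SystemTopology, path: str | Path) -> None:
    """Export a fully parameterized system for cross-validation with a
    production engine: masses, per-type pair coefficients (ε, σ),
    bond/angle/dihedral coefficients and term lists, scaled charges."""
    type_keys: list[str] = []
    type_of = []
    for i in range(sys.n_atoms):
        key = f"{sys.species[i]}.{sys.type_names[i]}"
        if key not in type_keys:
            type_keys.append(key)
        type_of.append(type_keys.index(key) + 1)

    def _unique(rows):
        seen: dict[tuple, int] = {}
        idx = []
        for row in rows:
            t = tuple(np.round(row, 10))
            if t not in seen:
                seen[t] = len(seen) + 1
            idx.append(seen[t])
        return seen, idx

    bond_rows = np.column_stack([sys.bond_l0, sys.bond_kl]) if len(sys.bond_idx) else np.zeros((0, 2))
    angle_rows = (
        np.column_stack([np.degrees(sys.angle_theta0), sys.angle_ktheta])
        if len(sys.angle_idx)
        else np.zeros((0, 2))
    )
    dih_rows = sys.dih_v if len(sys.dih_idx) else np.zeros((0, 4))
    btypes, bidx = _unique(bond_rows)
    atypes, aidx = _unique(angle_rows)
    dtypes, didx = _unique(dih_rows)

    eps_of = {}
    sig_of = {}
    mass_of = {}
    q_rep = {}
    for i in range(sys.n_atoms):
        k = type_of[i]
        eps_of[k] = sys.epsilon[i]
        sig_of[k] = sys.sigma[i]
        mass_of[k] = sys.mass[i]
        q_rep[k] = sys.q[i]

    L = sys.box_edge
    with open(path, "w") as fh:
        fh.write("LAMMPS data file (full style)\n\n")
        fh.write(f"{sys.n_atoms} atoms\n")
        fh.write(f"{len(sys.bond_idx)} bonds\n")
        fh.write(f"{len(sys.angle_idx)} angles\n")
        fh.write(f"{len(sys.dih_idx)} dihedrals\n\n")
        fh.write(f"{len(type_keys)} atom types\n")
        fh.write(f"{len(btypes)} bond types\n")
        fh.write(f"{len(atypes)} angle types\n")
        fh.write(f"{len(dtypes)} dihedral types\n\n")
        fh.write(f"0.0 {L:.6f} xlo xhi\n0.0 {L:.6f} ylo yhi\n0.0 {L:.6f} zlo zhi\n\n")
        fh.write("Masses\n\n")
        for k, key in enumerate(type_keys, 1):
            fh.write(f"{k} {max(mass_of[k], 1e-12):.4f}  # {key}\n")
        fh.write("\nPair Coeffs  # lj/cut/coul/long (kJ/mol, A)\n\n")
        for k in range(1, len(type_keys) + 1):
            fh.write(f"{k} {eps_of[k]:.6f} {sig_of[k]:.6f}\n")
        if btypes:
            fh.write("\nBond Coeffs  # harmonic, no 1/2 prefactor\n\n")
            for t, k in btypes.items():
                fh.write(f"{k} {t[1]:.4f} {t[0]:.4f}\n")  # K, r0
        if atypes:
            fh.write("\nAngle Coeffs\n\n")
            for t, k in atypes.items():
                fh.write(f"{k} {t[1]:.4f} {t[0]:.4f}\n")  # K, theta0 (deg)
        if dtypes:
            fh.write("\nDihedral Coeffs  # opls\n\n")
            for t, k in dtypes.items():
                fh.write(f"{k} {t[0]:.4f} {t[1]:.4f} {t[2]:.4f} {t[3]:.4f}\n")
        fh.write("\nAtoms  # full\n\n")
        for i in range(sys.n_atoms):
            x, y, z = sys.positions[i]
            fh.write(
                f"{i + 1} {sys.mol_id[i] + 1} {type_of[i]} {sys.q[i]:.6f} "
                f"{x:.6f} {y:.6f} {z:.6f}\n"
            )
        if len(sys.bond_idx):
            fh.write("\nBonds\n\n")
            for n, ((i, j), t) in enumerate(zip(sys.bond_idx, bidx), 1):
                fh.write(f"{n} {t} {i + 1} {j + 1}\n")
        if len(sys.angle_idx):
            fh.write("\nAngles\n\n")
            for n, ((i, j, k), t) in enumerate(zip(sys.angle_idx, aidx), 1):
                fh.write(f"{n} {t} {i + 1} {j + 1} {k + 1}\n")
        if len(sys.dih_idx):
            fh.write("\nDihedrals\n\n")
            for n, ((i, j, k, l), t) in enumerate(zip(sys.dih_idx, didx), 1):
                fh.write(f"{n} {t} {i + 1} {j + 1} {k + 1} {l + 1}\n")


def read_lammps_data(path: str | Path) -> dict:
    """Minimal reader for the bundled writer's output.

    Returns a dict with counts, per-atom charges/positions/molecule ids
    and the bond/angle/dihedral index lists (0-based)."""
    text = Path(path).read_text().splitlines()
    out = {
        "n_atoms": 0, "n_bonds": 0, "n_angles": 0, "n_dihedrals": 0,
        "charges": [], "positions": [], "mol_id": [],
        "bonds": [], "angles": [], "dihedrals": [], "box": 0.0,
    }
    section = None
    for lineno, raw in enumerate(text, 1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        low = line.lower()
        if low.endswith(" atoms"):
            out["n_atoms"] = int(line.split()[0])
            continue
        if low.endswith(" bonds"):
            out["n_bonds"] = int(line.split()[0])
            continue
        if low.endswith(" angles"):
            out["n_angles"] = int(line.split()[0])
            continue
        if low.endswith(" dihedrals"):
            out["n_dihedrals"] = int(line.split()[0])
            continue
        if low.endswith("xhi"):
            out["box"] = float(line.split()[1])
            continue
        if low.endswith("types") or low.endswith("yhi") or low.endswith("zhi"):
            continue
        if line in ("Masses", "Atoms", "Bonds", "Angles", "Dihedrals") or line.startswith(
            ("Pair Coeffs", "Bond Coeffs", "Angle Coeffs", "Dihedral Coeffs")
        ):
            section = line.split()[0] if "Coeffs" not in line else None
            continue
        tok = line.split()
        try:
            if section == "Atoms":
                out["mol_id"].append(int(tok[1]) - 1)
                out["charges"].append(float(tok[3]))
                out["positions"].append([float(tok[4]), float(tok[5]), float(tok[6])])
            elif section == "Bonds":
                out["bonds"].append((int(tok[2]) - 1, int(tok[3]) - 1))
            elif section == "Angles":
                out["angles"].append(tuple(int(t) - 1 for t in tok[2:5]))
            elif section == "Dihedrals":
                out["dihedrals"].append(tuple(int(t) - 1 for t in tok[2:6]))
        except (ValueError, IndexError):
            raise ParseError(f"line {lineno}: malformed {section} record") from None
    out["charges"] = np.array(out["charges"])
    out["positions"] = np.array(out["positions"])
    return out


# ---------------------------------------------------------------------------
# Gaussian cube (SDF grids) and TSV tables
# ---------------------------------------------------------------------------

def write_cube(result: SDFResult, path: str | Path, comment: str = "spatial distribution") -> None:
    ex, ey, ez = result.edges
    nx, ny, nz = result.density.shape
    dx = (ex[1] - ex[0]) / _BOHR
    origin = np.array([ex[0], ey[0], ez[0]]) / _BOHR
    with open(path, "w") as fh:
        fh.write(f"{comment}\ndensity in nm^-3\n")
        fh.write(f"{1:5d} {origin[0]:12.6f} {origin[1]:12.6f} {origin[2]:12.6f}\n")
        fh.write(f"{nx:5d} {dx:12.6f} {0.0:12.6f} {0.0:12.6f}\n")
        fh.write(f"{ny:5d} {0.0:12.6f} {dx:12.6f} {0.0:12.6f}\n")
        fh.write(f"{nz:5d} {0.0:12.6f} {0.0:12.6f} {dx:12.6f}\n")
        fh.write(f"{1:5d} {0.0:12.6f} {0.0:12.6f} {0.0:12.6f} {0.0:12.6f}\n")
        flat = result.density.reshape(nx * ny, nz)
        for row in flat:
            for k in range(0, nz, 6):
                fh.write(" ".join(f"{v:13.5e}" for v in row[k : k + 6]) + "\n")


def write_rdf_tsv(result: RDFResult, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("# r/pm\tg(r)\n")
        for r, g in zip(result.r_pm, result.g):
            fh.write(f"{r:.1f}\t{g:.6f}\n")
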