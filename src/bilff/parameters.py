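"""BILFF parameter library.

The force field uses the OPLS-AA functional form: harmonic bonds and
angles *without* the ½ prefactor, a four-term Fourier series for proper
dihedrals, 12-6 Lennard-Jones with geometric combining rules for both σ
and ε, and point-charge Coulomb interactions with scaled net ionic
charges of ±0.82 e (a mean-field stand-in for electronic polarization).

The published tables for the 1-ethyl-3-methyl-1,2,3-triazolium cation
([EMTr]+) and the benzoate anion ([OBz]−) are embedded verbatim as
:data:`BILFF_TABLE`.  Species whose full parameter sets live elsewhere
(imidazolium, acetate, the TIP4P-Ew water model) are merged in from text
parameter files in the documented ``.bff`` format; a water file ships
with the package.

Atom *types* (charges, LJ) are namespaced per species because the
published nomenclature reuses names (both ions have a "C1"); atom
*classes* (bonded parameters) are global.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping

__all__ = [
    "AtomType",
    "BondParam",
    "AngleParam",
    "TorsionParam",
    "ExclusionPolicy",
    "ForceField",
    "load_bilff",
    "combine_lj",
    "parse_parameter_text",
    "serialize_parameters",
    "ParameterError",
    "MergeConflictError",
]


class ParameterError(KeyError):
    """A requested parameter is missing or ambiguous."""


class MergeConflictError(ValueError):
    """Two parameter sources disagree on the same key."""


#: Standard atomic weights (amu) for the elements the force field covers.
ATOMIC_WEIGHTS: dict[str, float] = {
    "H": 1.008,
    "C": 12.011,
    "N": 14.007,
    "O": 15.999,
    # massless virtual site (water M site)
    "M": 0.0,
}


@dataclass(frozen=True)
class AtomType:
    """Non-bonded parameters of one atom type.

    ``q`` in e, ``sigma`` in Å, ``epsilon`` in kJ/mol, ``mass`` in amu.
    Every type maps to exactly one atom class used for bonded lookups.
    """

    name: str
    atom_class: str
    element: str
    mass: float
    q: float
    sigma: float
    epsilon: float
    species: str = ""

    def __post_init__(self):
        if self.sigma < 0:
            raise ValueError(f"sigma < 0 for type {self.name}")
        if self.epsilon < 0:
            raise ValueError(f"epsilon < 0 for type {self.name}")
        if abs(self.q) >= 2:
            raise ValueError(f"|q| >= 2 e for type {self.name}")

    @property
    def key(self) -> str:
        return f"{self.species}.{self.name}" if self.species else self.name


@dataclass(frozen=True)
class BondParam:
    """Harmonic bond, U = kl (l − l0)²; l0 in Å, kl in kJ mol⁻¹ Å⁻².

    ``classes`` is stored in canonical (reversal-normalized) order so
    lookups and serialization are orientation-independent.
    """

    classes: tuple[str, str]
    l0: float
    kl: float

    def __post_init__(self):
        object.__setattr__(self, "classes", _norm_pair(*self.classes))
        if self.l0 <= 0 or self.kl < 0:
            raise ValueError(f"invalid bond parameters for {self.classes}")


@dataclass(frozen=True)
class AngleParam:
    """Harmonic angle, U = kθ (θ − θ0)²; θ0 in degrees, kθ in kJ mol⁻¹ rad⁻²."""

    classes: tuple[str, str, str]
    theta0: float
    ktheta: float

    def __post_init__(self):
        object.__setattr__(self, "classes", _norm_triple(tuple(self.classes)))
        if not 0 < self.theta0 < 180:
            raise ValueError(f"theta0 outside (0, 180) for {self.classes}")
        if self.ktheta < 0:
            raise ValueError(f"ktheta < 0 for {self.classes}")

    @property
    def theta0_rad(self) -> float:
        return math.radians(self.theta0)


@dataclass(frozen=True)
class TorsionParam:
    """OPLS proper dihedral, four-term Fourier coefficients in kJ/mol.

    U(φ) = V1/2 (1+cos φ) + V2/2 (1−cos 2φ) + V3/2 (1+cos 3φ) + V4/2 (1−cos 4φ)
    """

    classes: tuple[str, str, str, str]
    v1: float = 0.0
    v2: float = 0.0
    v3: float = 0.0
    v4: float = 0.0

    def __post_init__(self):
        object.__setattr__(self, "classes", _norm_quad(tuple(self.classes)))


@dataclass(frozen=True)
class ExclusionPolicy:
    """Scale factors f applied to both LJ and Coulomb for bonded neighbours.

    1-2 and 1-3 interactions are removed and 1-4 interactions halved,
    the OPLS-AA convention.
    """

    f12: float = 0.0
    f13: float = 0.0
    f14: float = 0.5

    def __post_init__(self):
        for f in (self.f12, self.f13, self.f14):
            if not 0.0 <= f <= 1.0:
                raise ValueError("exclusion factors must lie in [0, 1]")


def _norm_pair(a: str, b: str) -> tuple[str, str]:
    return (a, b) if a <= b else (b, a)


def _norm_triple(t: tuple[str, str, str]) -> tuple[str, str, str]:
    return t if t <= t[::-1] else t[::-1]


def _norm_quad(t: tuple[str, ...]) -> tuple[str, ...]:
    return t if t <= t[::-1] else t[::-1]


@dataclass
class ForceField:
    """Complete parameter set plus exclusion policy and combining rule."""

    atom_types: dict[str, AtomType] = field(default_factory=dict)
    bonds: dict[tuple[str, str], BondParam] = field(default_factory=dict)
    angles: dict[tuple[str, str, str], AngleParam] = field(default_factory=dict)
    torsions: dict[tuple[str, ...], TorsionParam] = field(default_factory=dict)
    exclusions: ExclusionPolicy = field(default_factory=ExclusionPolicy)
    combining_rule: str = "geometric"

    # -- lookups ---------------------------------------------------------
    def atom_type(self, name: str, species: str | None = None) -> AtomType:
        """Resolve an atom type by qualified or bare name.

        Bare names ("O2") work when unique across species; ambiguous
        names ("C1") must be qualified as "OBz.C1" or via ``species``.
        """
        if species is not None:
            name = f"{species}.{name}"
        if name in self.atom_types:
            return self.atom_types[name]
        hits = [t for k, t in self.atom_types.items() if k.split(".")[-1] == name]
        if not hits:
            raise ParameterError(f"unknown atom type {name!r}")
        if len({(t.q, t.sigma, t.epsilon) for t in hits}) > 1:
            keys = sorted(t.key for t in hits)
            raise ParameterError(f"ambiguous atom type {name!r}: one of {keys}")
        return hits[0]

    def bond(self, a: str, b: str) -> BondParam:
        try:
            return self.bonds[_norm_pair(a, b)]
        except KeyError:
            raise ParameterError(f"no bond parameters for class pair {a}-{b}") from None

    def angle(self, a: str, b: str, c: str) -> AngleParam:
        try:
            return self.angles[_norm_triple((a, b, c))]
        except KeyError:
            raise ParameterError(f"no angle parameters for {a}-{b}-{c}") from None

    def torsion(self, a: str, b: str, c: str, d: str) -> TorsionParam:
        try:
            return self.torsions[_norm_quad((a, b, c, d))]
        except KeyError:
            raise ParameterError(f"no torsion parameters for {a}-{b}-{c}-{d}") from None

    # -- construction ----------------------------------------------------
    def add_atom_type(self, t: AtomType, *, strict: bool = True) -> None:
        if t.key in self.atom_types:
            old = self.atom_types[t.key]
            if old == t:
                return
            if strict:
                raise MergeConflictError(
                    f"atom type {t.key} redefined with different values: {old} vs {t}"
                )
        self.atom_types[t.key] = t

    def _add_keyed(self, table: dict, key, value, strict: bool) -> None:
        if key in table and table[key] != value:
            if strict:
                raise MergeConflictError(
                    f"parameter {key} redefined: {table[key]} vs {value}"
                )
        table[key] = value

    def add_bond(self, p: BondParam, *, strict: bool = True) -> None:
        self._add_keyed(self.bonds, _norm_pair(*p.classes), p, strict)

    def add_angle(self, p: AngleParam, *, strict: bool = True) -> None:
        self._add_keyed(self.angles, _norm_triple(p.classes), p, strict)

    def add_torsion(self, p: TorsionParam, *, strict: bool = True) -> None:
        self._add_keyed(self.torsions, _norm_quad(p.classes), p, strict)

    def merge(self, other: "ForceField", *, strict: bool = True) -> "ForceField":
        """Return a new field with ``other``'s parameters merged in.

        Identical duplicates are tolerated; conflicting redefinitions
        raise :class:`MergeConflictError` unless ``strict=False``.
        """
        out = ForceField(
            atom_types=dict(self.atom_types),
            bonds=dict(self.bonds),
            angles=dict(self.angles),
            torsions=dict(self.torsions),
            exclusions=self.exclusions,
            combining_rule=self.combining_rule,
        )
        for t in other.atom_types.values():
            out.add_atom_type(t, strict=strict)
        for p in other.bonds.values():
            out.add_bond(p, strict=strict)
        for p in other.angles.values():
            out.add_angle(p, strict=strict)
        for p in other.torsions.values():
            out.add_torsion(p, strict=strict)
        return out


def combine_lj(a: AtomType, b: AtomType) -> tuple[float, float]:
    """Geometric-mean combining rule for cross LJ parameters.

    σ_ij = sqrt(σ_i σ_j), ε_ij = sqrt(ε_i ε_j).
    """
    for t in (a, b):
        if t.sigma == 0.0:
            raise ParameterError(f"atom type {t.key} has no LJ parameters")
    return math.sqrt(a.sigma * b.sigma), math.sqrt(a.epsilon * b.epsilon)


# ---------------------------------------------------------------------------
# Published parameter tables (embedded verbatim).
#
# Atom-type rows: name, class, element, q/e, sigma/Å, epsilon/(kJ/mol).
# Type aliases: the nomenclature table lists CM (N-methyl carbon), HM
# (its hydrogens) and HE (ethyl-terminal hydrogens) without their own
# charge rows; CM carries the C1 parameters, HM the H1 parameters and HE
# the HC parameters.  With these aliases each ion's charge sum closes
# exactly at ±0.820 e.
# ---------------------------------------------------------------------------

_EMTR_TYPES = [
    ("C1", "CT", "C", -0.187, 3.34, 0.2760),
    ("CE", "CT", "C", -0.054, 3.34, 0.2760),
    ("CW", "CW", "C", -0.144, 3.38, 0.2930),
    ("HCW", "HA", "H", 0.191, 1.48, 0.1260),
    ("HC", "HC", "H", 0.070, 2.38, 0.1260),
    ("H1", "HC", "H", 0.148, 2.38, 0.1260),
    ("NR", "NR", "N", -0.204, 3.10, 0.7110),
    ("NA", "NA", "N", 0.204, 3.10, 0.7110),
]

_OBZ_TYPES = [
    ("C1", "CA", "C", 0.005, 3.70, 0.2929),
    ("C2", "CA", "C", -0.118, 3.70, 0.2929),
    ("C3", "CA", "C", -0.121, 3.70, 0.2929),
    ("C4", "CA", "C", -0.299, 3.70, 0.2929),
    ("CO", "CO", "C", 0.398, 3.90, 0.4393),
    ("H2", "HA", "H", 0.070, 2.42, 0.1255),
    ("H3", "HA", "H", 0.157, 2.42, 0.1255),
    ("H4", "HA", "H", 0.200, 2.42, 0.1255),
    ("O2", "O2", "O", -0.550, 2.80, 0.8786),
]

# Bond rows: classA, classB, l0/Å, kl/(kJ mol⁻¹ Å⁻²).
_BONDS = [
    ("NA", "NR", 1.344, 3199.2),
    ("CW", "HA", 1.088, 2633.8),
    ("CW", "NA", 1.375, 3108.7),
    ("CW", "CW", 1.386, 3773.2),
    ("NA", "CT", 1.488, 2046.3),
    ("HC", "CT", 1.099, 2679.4),
    ("CT", "CT", 1.533, 2125.5),
    ("CA", "CA", 1.387, 3274.1),
    ("CA", "HA", 1.088, 2707.4),
    ("CA", "CO", 1.504, 1906.9),
    ("CO", "O2", 1.282, 4273.1),
]

# Angle rows: classes, theta0/deg, ktheta/(kJ mol⁻¹ rad⁻²).
_ANGLES = [
    ("CW", "NA", "NR", 112.1, 568.7),
    ("NR", "NA", "CT", 118.6, 396.5),
    ("NA", "NR", "NA", 104.4, 610.1),
    ("NA", "CT", "CT", 110.9, 361.2),
    ("NA", "CW", "CW", 107.0, 579.7),
    ("NA", "CW", "HA", 120.8, 200.9),
    ("CW", "CW", "HA", 131.7, 190.5),
    ("NA", "CT", "HC", 107.2, 375.9),
    ("CT", "CT", "HC", 111.4, 296.2),
    ("HC", "CT", "HC", 109.2, 226.5),
    ("CW", "NA", "CT", 125.2, 242.9),
    ("CA", "CA", "CA", 120.0, 446.0),
    ("CA", "CA", "HA", 120.0, 258.1),
    ("CA", "CA", "CO", 120.0, 397.6),
    ("CA", "CO", "O2", 117.0, 550.2),
    ("O2", "CO", "O2", 126.0, 735.9),
]

# Torsion rows: classes, V1..V4 in kJ/mol.
_TORSIONS = [
    ("CW", "NA", "NR", "NA", 0.0, 19.4600, 0.0, 0.0),
    ("CT", "NA", "NR", "NA", 0.0, 19.4600, 0.0, 0.0),
    ("NR", "NA", "CW", "CW", 0.0, 12.5500, 0.0, 0.0),
    ("NR", "NA", "CW", "HA", 0.0, 12.5500, 0.0, 0.0),
    ("NR", "NA", "CT", "HC", 0.0, 0.0, 0.0, 0.0),
    ("NR", "NA", "CT", "CT", 0.1, 1.0, 0.1, -0.3),
    ("CT", "NA", "CW", "CW", 0.0, 12.5500, 0.0, 0.0),
    ("CT", "NA", "CW", "HA", 0.0, 12.5500, 0.0, 0.0),
    ("NA", "CW", "CW", "NA", 0.0, 65.0, 0.0, 0.0),
    ("NA", "CW", "CW", "HA", 0.0, 44.98, 0.0, 0.0),
    ("HA", "CW", "CW", "HA", 0.0, 30.0, 0.0, 0.0),
    ("CW", "NA", "CT", "HC", 0.1, 0.2, 0.0, 0.0),
    ("CW", "NA", "CT", "CT", 0.4, 1.0, 0.0, 0.2),
    ("NA", "CT", "CT", "HC", 0.0, 0.0, 0.3670, 0.0),
    ("HC", "CT", "CT", "HC", 0.0, 0.0, 1.2552, 0.0),
    ("CA", "CA", "CA", "CA", 0.0, 30.334, 0.0, 0.0),
    ("HA", "CA", "CA", "CA", 0.0, 30.334, 0.0, 0.0),
    ("HA", "CA", "CA", "CO", 0.0, 30.334, 0.0, 0.0),
    ("HA", "CA", "CA", "HA", 0.0, 30.334, 0.0, 0.0),
    ("CA", "CA", "CA", "CO", 0.0, 30.334, 0.0, 0.0),
    ("CA", "CA", "CO", "O2", 0.0, 8.0, 0.0, 0.0),
]

#: Net ionic charge of the scaled-charge model, in e.
ION_CHARGE = 0.82

#: Imidazolium ring-proton charge and σ of the prior parameter set, the
#: baseline against which the triazolium ring-proton values were tuned.
EMIM_RING_H_Q = 0.150
EMIM_RING_H_SIGMA = 1.62

#: Acetate carboxylate-oxygen charge of the prior parameter set.
OAC_O_Q = -0.66


def _builtin_forcefield() -> ForceField:
    ff = ForceField()
    for species, rows in (("EMTr", _EMTR_TYPES), ("OBz", _OBZ_TYPES)):
        for name, cls, el, q, sig, eps in rows:
            ff.add_atom_type(
                AtomType(name, cls, el, ATOMIC_WEIGHTS[el], q, sig, eps, species)
            )
    for a, b, l0, kl in _BONDS:
        ff.add_bond(BondParam((a, b), l0, kl))
    for a, b, c, t0, kt in _ANGLES:
        ff.add_angle(AngleParam((a, b, c), t0, kt))
    for row in _TORSIONS:
        ff.add_torsion(TorsionParam(tuple(row[:4]), *row[4:]))
    return ff


# ---------------------------------------------------------------------------
# Text parameter-file format (".bff")
# ---------------------------------------------------------------------------

_FORMAT_DOC = """\
Sections are introduced by bracketed headers; '#' starts a comment.

[types]
# name  class  element  mass  q  sigma  epsilon   (optionally: species=XX first)
[bonds]
# classA-classB  l0  kl
[angles]
# A-B-C  theta0  ktheta
[dihedrals]
# A-B-C-D  V1  V2  V3  V4
"""


def parse_parameter_text(text: str, *, default_species: str = "") -> ForceField:
    """Parse the ``.bff`` text format into a :class:`ForceField`.

    Format::

    """ + _FORMAT_DOC
    ff = ForceField()
    section = None
    species = default_species
    for lineno, raw in enumerate(text.splitlines(), 1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if line.startswith("[") and line.endswith("]"):
            section = line[1:-1].strip().lower()
            continue
        if "=" in line and line.split("=", 1)[0].strip() == "species":
            species = line.split("=", 1)[1].strip()
            continue
        tok = line.split()
        try:
            if section == "types":
                name, cls, el = tok[0], tok[1], tok[2]
                mass, q, sig, eps = map(float, tok[3:7])
                ff.add_atom_type(AtomType(name, cls, el, mass, q, sig, eps, species))
            elif section == "bonds":
                a, b = tok[0].split("-")
                ff.add_bond(BondParam((a, b), float(tok[1]), float(tok[2])))
            elif section == "angles":
                ff.add_angle(
                    AngleParam(tuple(tok[0].split("-")), float(tok[1]), float(tok[2]))
                )
            elif section == "dihedrals":
                ff.add_torsion(
                    TorsionParam(tuple(tok[0].split("-")), *map(float, tok[1:5]))
                )
            else:
                raise ValueError(f"data line outside a known section: {raw!r}")
        except (IndexError, ValueError) as exc:
            raise ValueError(f"parameter file line {lineno}: {exc}") from exc
    return ff


def serialize_parameters(ff: ForceField) -> str:
    """Emit a force field in the ``.bff`` text format (lossless round trip)."""
    lines = []
    by_species: dict[str, list[AtomType]] = {}
    for t in ff.atom_types.values():
        by_species.setdefault(t.species, []).append(t)
    lines.append("[types]")
    for sp in sorted(by_species):
        if sp:
            lines.append(f"species = {sp}")
        for t in sorted(by_species[sp], key=lambda t: t.name):
            lines.append(
                f"{t.name} {t.atom_class} {t.element} {t.mass:.6g} "
                f"{t.q:.6g} {t.sigma:.6g} {t.epsilon:.6g}"
            )
    lines.append("[bonds]")
    for key in sorted(ff.bonds):
        p = ff.bonds[key]
        lines.append(f"{key[0]}-{key[1]} {p.l0:.6g} {p.kl:.6g}")
    lines.append("[angles]")
    for key in sorted(ff.angles):
        p = ff.angles[key]
        lines.append(f"{'-'.join(key)} {p.theta0:.6g} {p.ktheta:.6g}")
    lines.append("[dihedrals]")
    for key in sorted(ff.torsions):
        p = ff.torsions[key]
        lines.append(f"{'-'.join(key)} {p.v1:.6g} {p.v2:.6g} {p.v3:.6g} {p.v4:.6g}")
    return "\n".join(lines) + "\n"


_DATA_DIR = Path(__file__).parent / "data"


def load_bilff(extra_files: Iterable[str | Path] = (), *, water: bool = True) -> ForceField:
    """Load the embedded parameter tables, optionally merging extra files.

    ``water=True`` (default) also merges the bundled TIP4P-Ew water
    model.  Extra files use the ``.bff`` format and may supply species
    not fully printed in the embedded tables (imidazolium, acetate);
    conflicting redefinitions of an embedded parameter raise
    :class:`MergeConflictError`.
    """
    ff = _builtin_forcefield()
    if water:
        ff = ff.merge(parse_parameter_text((_DATA_DIR / "tip4pew.bff").read_text()))
    for f in extra_files:
        ff = ff.merge(parse_parameter_text(Path(f).read_text()))
    return ff
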