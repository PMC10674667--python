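"""Physical constants and unit conventions.

Internal units throughout the package:

====================  =========================
quantity              unit
====================  =========================
length                Å (angstrom)
time                  fs
mass                  amu (g/mol)
charge                e
energy                kJ/mol
force                 kJ mol⁻¹ Å⁻¹
temperature           K
pressure              kJ mol⁻¹ Å⁻³
====================  =========================

Picometres appear only at I/O boundaries (several published tables are
pm-resolved); convert with :data:`PM_PER_ANGSTROM`.
"""

from __future__ import annotations

#: Boltzmann constant, kJ mol⁻¹ K⁻¹.
KB = 8.31446261815324e-3

#: Coulomb prefactor e²/(4π ε0), kJ mol⁻¹ Å e⁻².
COULOMB = 1389.35457644382

#: 1 amu Å² fs⁻² expressed in kJ/mol (kinetic-energy conversion).
KE_CONV = 1.0e4

#: Avogadro constant, mol⁻¹.
N_AVOGADRO = 6.02214076e23

#: 1 atm expressed in internal pressure units (kJ mol⁻¹ Å⁻³).
ATM = 101325.0 * 1e-30 * N_AVOGADRO / 1000.0

PM_PER_ANGSTROM = 100.0

#: Convert a diffusion coefficient from Å²/fs to the conventional
#: 10⁻¹¹ m² s⁻¹ scale used for ionic liquids.
D_TO_1E11_M2_S = 1.0e6


def pm_to_angstrom(x):
    return x / PM_PER_ANGSTROM


def angstrom_to_pm(x):
    return x * PM_PER_ANGSTROM
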