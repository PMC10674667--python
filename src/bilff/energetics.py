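"""Potential energy and analytic forces.

The total potential is the OPLS-AA functional form: harmonic bonds and
angles without the ½ prefactor, a four-term Fourier dihedral series,
12-6 Lennard-Jones with geometric combining rules and point-charge
electrostatics.  Intramolecular 1-2 and 1-3 non-bonded interactions are
removed and 1-4 interactions scaled by 0.5 (both LJ and Coulomb).

Electrostatics come in two flavours: a minimum-image (optionally
truncated) direct sum for desk-scale testing, and a classic Ewald
summation (real + reciprocal + self + excluded-pair corrections,
tinfoil boundary conditions) for production periodic systems.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.special import erfc

from .parameters import AngleParam, BondParam, TorsionParam
from .topology import SystemTopology
from .units import COULOMB

__all__ = [
    "EnergyReport",
    "bond_energy",
    "angle_energy",
    "torsion_energy",
    "nonbonded_energy",
    "total_energy_forces",
    "OverlapError",
]

_MIN_R = 0.01  # Å; closer approaches abort the evaluation


class OverlapError(RuntimeError):
    """Two interacting atoms closer than the hard overlap threshold."""


@dataclass
class EnergyReport:
    """Per-term potential energy (kJ/mol), forces and virial."""

    bond: float
    angle: float
    torsion: float
    lj: float
    coulomb: float
    forces: np.ndarray  # (N, 3) kJ mol⁻¹ Å⁻¹
    virial: float = 0.0  # Σ r·F pair virial, kJ/mol

    @property
    def total(self) -> float:
        return self.bond + self.angle + self.torsion + self.lj + self.coulomb


# ---------------------------------------------------------------------------
# Closed-form single-term energies (the building blocks of the total sum)
# ---------------------------------------------------------------------------

def bond_energy(l: float, p: BondParam) -> float:
    """U = kl (l − l0)²  — no ½ prefactor."""
    return p.kl * (l - p.l0) ** 2


def angle_energy(theta: float, p: AngleParam) -> float:
    """U = kθ (θ − θ0)², θ in radians."""
    return p.ktheta * (theta - p.theta0_rad) ** 2


def torsion_energy(phi: float, p: TorsionParam) -> float:
    """Four-term OPLS Fourier series, φ in radians."""
    return (
        0.5 * p.v1 * (1.0 + math.cos(phi))
        + 0.5 * p.v2 * (1.0 - math.cos(2.0 * phi))
        + 0.5 * p.v3 * (1.0 + math.cos(3.0 * phi))
        + 0.5 * p.v4 * (1.0 - math.cos(4.0 * phi))
    )


# ---------------------------------------------------------------------------
# Vectorized helpers
# ---------------------------------------------------------------------------

def minimum_image(d: np.ndarray, box: float) -> np.ndarray:
    return d - box * np.round(d / box)


def _bond_terms(sys: SystemTopology, r: np.ndarray):
    if len(sys.bond_idx) == 0:
        return 0.0, np.zeros_like(r), 0.0
    i, j = sys.bond_idx[:, 0], sys.bond_idx[:, 1]
    d = minimum_image(r[i] - r[j], sys.box_edge)
    l = np.linalg.norm(d, axis=1)
    dl = l - sys.bond_l0
    e = float(np.sum(sys.bond_kl * dl**2))
    # F_i = -2 kl (l - l0) d̂
    fmag = -2.0 * sys.bond_kl * dl / l
    fi = fmag[:, None] * d
    forces = np.zeros_like(r)
    np.add.at(forces, i, fi)
    np.add.at(forces, j, -fi)
    w = float(np.sum(np.einsum("ij,ij->i", fi, d)))
    return e, forces, w


def _angle_terms(sys: SystemTopology, r: np.ndarray):
    if len(sys.angle_idx) == 0:
        return 0.0, np.zeros_like(r), 0.0
    i, j, k = sys.angle_idx.T
    u = minimum_image(r[i] - r[j], sys.box_edge)
    v = minimum_image(r[k] - r[j], sys.box_edge)
    ru = np.linalg.norm(u, axis=1)
    rv = np.linalg.norm(v, axis=1)
    c = np.einsum("ij,ij->i", u, v) / (ru * rv)
    c = np.clip(c, -1.0, 1.0)
    s = np.sqrt(np.maximum(1.0 - c * c, 1e-12))
    theta = np.arccos(c)
    dth = theta - sys.angle_theta0
    e = float(np.sum(sys.angle_ktheta * dth**2))
    a = -2.0 * sys.angle_ktheta * dth / s
    a11 = a * c / ru**2
    a12 = -a / (ru * rv)
    a22 = a * c / rv**2
    fi = a11[:, None] * u + a12[:, None] * v
    fk = a22[:, None] * v + a12[:, None] * u
    forces = np.zeros_like(r)
    np.add.at(forces, i, fi)
    np.add.at(forces, k, fk)
    np.add.at(forces, j, -(fi + fk))
    w = float(np.sum(np.einsum("ij,ij->i", fi, u) + np.einsum("ij,ij->i", fk, v)))
    return e, forces, w


def _dihedral_terms(sys: SystemTopology, r: np.ndarray):
    if len(sys.dih_idx) == 0:
        return 0.0, np.zeros_like(r), 0.0
    i, j, k, l = sys.dih_idx.T
    b1 = minimum_image(r[j] - r[i], sys.box_edge)
    b2 = minimum_image(r[k] - r[j], sys.box_edge)
    b3 = minimum_image(r[l] - r[k], sys.box_edge)
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    b2n = np.linalg.norm(b2, axis=1)
    # signed dihedral angle
    x = np.einsum("ij,ij->i", n1, n2)
    y = np.einsum("ij,ij->i", np.cross(n1, n2), b2) / b2n
    phi = np.arctan2(y, x)
    v1, v2, v3, v4 = sys.dih_v.T
    e = float(
        np.sum(
            0.5 * v1 * (1 + np.cos(phi))
            + 0.5 * v2 * (1 - np.cos(2 * phi))
            + 0.5 * v3 * (1 + np.cos(3 * phi))
            + 0.5 * v4 * (1 - np.cos(4 * phi))
        )
    )
    dudphi = (
        -0.5 * v1 * np.sin(phi)
        + v2 * np.sin(2 * phi)
        - 1.5 * v3 * np.sin(3 * phi)
        + 2.0 * v4 * np.sin(4 * phi)
    )
    n1sq = np.einsum("ij,ij->i", n1, n1)
    n2sq = np.einsum("ij,ij->i", n2, n2)
    n1sq = np.maximum(n1sq, 1e-12)
    n2sq = np.maximum(n2sq, 1e-12)
    dphi_dri = (-b2n / n1sq)[:, None] * n1
    dphi_drl = (b2n / n2sq)[:, None] * n2
    c12 = np.einsum("ij,ij->i", b1, b2) / b2n**2
    c32 = np.einsum("ij,ij->i", b3, b2) / b2n**2
    dphi_drj = -(1.0 + c12)[:, None] * dphi_dri + c32[:, None] * dphi_drl
    dphi_drk = -(1.0 + c32)[:, None] * dphi_drl + c12[:, None] * dphi_dri
    g = -dudphi[:, None]
    forces = np.zeros_like(r)
    np.add.at(forces, i, g * dphi_dri)
    np.add.at(forces, j, g * dphi_drj)
    np.add.at(forces, k, g * dphi_drk)
    np.add.at(forces, l, g * dphi_drl)
    # dihedral virial from atomic decomposition (pairwise w.r.t. atom k
    # as reference); use Σ r·F over minimum-image relative vectors.
    w = float(
        np.sum(
            np.einsum("ij,ij->i", g * dphi_dri, -(b1 + b2))
            + np.einsum("ij,ij->i", g * dphi_drj, -b2)
            + np.einsum("ij,ij->i", g * dphi_drl, b3)
        )
    )
    return e, forces, w


# ---------------------------------------------------------------------------
# Non-bonded interactions
# ---------------------------------------------------------------------------

def _pair_scale(sys: SystemTopology, iu: np.ndarray, ju: np.ndarray) -> np.ndarray:
    n = sys.n_atoms
    key = iu.astype(np.int64) * n + ju
    f = np.ones(len(iu))
    if len(sys.scaled_pairs):
        si = np.minimum(sys.scaled_pairs[:, 0], sys.scaled_pairs[:, 1])
        sj = np.maximum(sys.scaled_pairs[:, 0], sys.scaled_pairs[:, 1])
        skey = si.astype(np.int64) * n + sj
        order = np.argsort(skey)
        skey = skey[order]
        sf = sys.scaled_f[order]
        pos = np.searchsorted(skey, key)
        pos = np.clip(pos, 0, len(skey) - 1)
        hit = skey[pos] == key
        f[hit] = sf[pos[hit]]
    return f


def _pair_geometry(sys: SystemTopology, r: np.ndarray):
    cache = getattr(sys, "_nb_cache", None)
    if cache is None or cache[0].shape[0] != sys.n_atoms * (sys.n_atoms - 1) // 2:
        iu, ju = np.triu_indices(sys.n_atoms, k=1)
        f = _pair_scale(sys, iu, ju)
        cache = (iu, ju, f)
        sys._nb_cache = cache
    iu, ju, f = cache
    d = minimum_image(r[iu] - r[ju], sys.box_edge)
    rij = np.linalg.norm(d, axis=1)
    live = f > 0.0
    if np.any(rij[live] < _MIN_R):
        k = int(np.argmin(np.where(live, rij, np.inf)))
        raise OverlapError(
            f"atoms {iu[k]} and {ju[k]} overlap (r = {rij[k]:.4f} Å)"
        )
    return iu, ju, d, rij, f


def _lj_tail(sys, rc):
    """Mean-field (g≈1) long-range LJ correction beyond the cutoff.

    Returns (energy, virial).  Uses the geometric-combination identity
    ε_ij σ_ij^n = (√ε_i σ_i^(n/2))(√ε_j σ_j^(n/2)) to avoid pair loops.
    """
    a6 = np.sqrt(sys.epsilon) * sys.sigma**3
    a12 = np.sqrt(sys.epsilon) * sys.sigma**6
    s6 = 0.5 * (a6.sum() ** 2 - (a6**2).sum())  # Σ_{i<j} ε_ij σ_ij⁶
    s12 = 0.5 * (a12.sum() ** 2 - (a12**2).sum())
    pref = 4.0 * math.pi / sys.volume
    e = pref * (4.0 * s12 / (9.0 * rc**9) - 4.0 * s6 / (3.0 * rc**3))
    w = pref * ((16.0 / 3.0) * s12 / rc**9 - 8.0 * s6 / rc**3)
    return e, w


def _lj(sys, iu, ju, d, rij, f, rc):
    sqs = np.sqrt(sys.sigma)
    sqe = np.sqrt(sys.epsilon)
    sig = sqs[iu] * sqs[ju]
    eps = sqe[iu] * sqe[ju] * f
    mask = eps > 0.0
    if rc is not None:
        mask &= rij <= rc
    sr6 = (sig[mask] / rij[mask]) ** 6
    e = float(np.sum(4.0 * eps[mask] * (sr6**2 - sr6)))
    # F = 24 ε (2 sr12 − sr6) / r along d̂
    fmag = 24.0 * eps[mask] * (2.0 * sr6**2 - sr6) / rij[mask] ** 2
    fv = fmag[:, None] * d[mask]
    forces = np.zeros((sys.n_atoms, 3))
    np.add.at(forces, iu[mask], fv)
    np.add.at(forces, ju[mask], -fv)
    w = float(np.sum(fmag * rij[mask] ** 2))
    return e, forces, w


def _coulomb_direct(sys, iu, ju, d, rij, f, rc):
    qq = COULOMB * sys.q[iu] * sys.q[ju] * f
    mask = qq != 0.0
    if rc is not None:
        mask &= rij <= rc
    e = float(np.sum(qq[mask] / rij[mask]))
    fmag = qq[mask] / rij[mask] ** 3
    fv = fmag[:, None] * d[mask]
    forces = np.zeros((sys.n_atoms, 3))
    np.add.at(forces, iu[mask], fv)
    np.add.at(forces, ju[mask], -fv)
    w = float(np.sum(fmag * rij[mask] ** 2))
    return e, forces, w


def nonbonded_energy(sys: SystemTopology, method: str = "cutoff", rc: float | None = 8.0,
                     coulomb_rc: float | None = None, accuracy: float = 1e-5,
                     tail: bool = False):
    """LJ and Coulomb energies (kJ/mol) of a periodic system.

    ``method`` selects ``"cutoff"`` (minimum-image truncated direct sum,
    for testing) or ``"ewald"`` electrostatics.  LJ is truncated at
    ``rc`` (pass ``None`` for no cutoff); ``tail=True`` adds the
    mean-field long-range LJ correction (off by default).
    """
    e_lj, e_c, _, _, _ = _nonbonded_full(sys, sys.positions, method, rc,
                                         coulomb_rc, accuracy, tail)
    return e_lj, e_c


def total_energy_forces(
    sys: SystemTopology,
    method: str = "cutoff",
    rc: float | None = 8.0,
    coulomb_rc: float | None = None,
    accuracy: float = 1e-5,
    tail: bool = False,
) -> EnergyReport:
    """Evaluate every energy term and the analytic forces."""
    r = sys.place_virtual_sites(sys.positions)
    eb, fb, wb = _bond_terms(sys, r)
    ea, fa, wa = _angle_terms(sys, r)
    ed, fd, wd = _dihedral_terms(sys, r)
    e_lj, e_c, fnb, wnb, _ = _nonbonded_full(sys, r, method, rc, coulomb_rc,
                                             accuracy, tail)
    forces = fb + fa + fd + fnb
    sys.spread_virtual_forces(forces)
    return EnergyReport(
        bond=eb, angle=ea, torsion=ed, lj=e_lj, coulomb=e_c,
        forces=forces, virial=wb + wa + wd + wnb,
    )


def _nonbonded_full(sys, r, method, rc, coulomb_rc, accuracy, tail=False):
    if sys.n_atoms < 2:
        return 0.0, 0.0, np.zeros((sys.n_atoms, 3)), 0.0, None
    if rc is not None and method == "cutoff" and sys.box_edge < 2.0 * rc:
        raise ValueError(
            f"box edge {sys.box_edge:.1f} Å < 2·cutoff {2 * rc:.1f} Å; "
            "shrink the cutoff or use Ewald"
        )
    iu, ju, d, rij, f = _pair_geometry(sys, r)
    e_lj, f_lj, w_lj = _lj(sys, iu, ju, d, rij, f, rc)
    if tail and rc is not None:
        e_t, w_t = _lj_tail(sys, rc)
        e_lj += e_t
        w_lj += w_t
    if method == "cutoff":
        crc = coulomb_rc if coulomb_rc is not None else rc
        e_c, f_c, w_c = _coulomb_direct(sys, iu, ju, d, rij, f, crc)
    elif method == "ewald":
        e_c, f_c, w_c = _ewald(sys, r, iu, ju, d, rij, f, rc, accuracy)
    else:
        raise ValueError(f"unknown electrostatics method {method!r}")
    return e_lj, e_c, f_lj + f_c, w_lj + w_c, None


_KVEC_CACHE: dict[tuple, tuple] = {}


def _half_lattice(nmax: int) -> np.ndarray:
    """Integer half-space lattice |n| ≤ nmax (box-independent, cached)."""
    hit = _KVEC_CACHE.get(nmax)
    if hit is not None:
        return hit
    ns = np.arange(-nmax, nmax + 1)
    nx, ny, nz = np.meshgrid(ns, ns, ns, indexing="ij")
    nvec = np.column_stack([nx.ravel(), ny.ravel(), nz.ravel()]).astype(float)
    nsq = np.einsum("ij,ij->i", nvec, nvec)
    half = (
        (nvec[:, 0] > 0)
        | ((nvec[:, 0] == 0) & (nvec[:, 1] > 0))
        | ((nvec[:, 0] == 0) & (nvec[:, 1] == 0) & (nvec[:, 2] > 0))
    )
    nvec = nvec[half & (nsq <= nmax**2 + 1e-9)]
    if len(_KVEC_CACHE) > 16:
        _KVEC_CACHE.clear()
    _KVEC_CACHE[nmax] = nvec
    return nvec


def _kvectors(box: float, nmax: int, alpha: float):
    """Half-space reciprocal vectors with symmetry factor folded into a_k."""
    nvec = _half_lattice(nmax)
    kvec = (2.0 * math.pi / box) * nvec
    ksq = np.einsum("ij,ij->i", kvec, kvec)
    ak2 = 2.0 * np.exp(-ksq / (4.0 * alpha**2)) / ksq
    return kvec, ksq, ak2


def _ewald(sys, r, iu, ju, d, rij, f, rc, accuracy):
    box = sys.box_edge
    if rc is None:
        rc = box / 2.0
    rc = min(rc, box / 2.0)
    s = math.sqrt(max(-math.log(accuracy), 1.0))
    alpha = s / rc
    nmax = max(1, int(math.ceil(alpha * s * box / math.pi)))
    q = sys.q
    n_at = sys.n_atoms
    forces = np.zeros((n_at, 3))

    # --- real space (scaled charge products: an excluded pair's erfc
    # part must not enter, its erf part is removed by the correction) ---
    qq = COULOMB * q[iu] * q[ju] * f
    mask = (qq != 0.0) & (rij <= rc)
    rr = rij[mask]
    ar = alpha * rr
    er = erfc(ar)
    gauss = (2.0 * alpha / math.sqrt(math.pi)) * np.exp(-(ar**2))
    e_real = float(np.sum(qq[mask] * er / rr))
    fmag = qq[mask] * (er / rr + gauss) / rr**2
    fv = fmag[:, None] * d[mask]
    np.add.at(forces, iu[mask], fv)
    np.add.at(forces, ju[mask], -fv)
    w = float(np.sum(fmag * rr**2))

    # --- excluded/scaled pair corrections (nearest image) ---
    e_corr = 0.0
    sub = (f < 1.0) & (q[iu] * q[ju] != 0.0)
    if np.any(sub):
        qs = COULOMB * q[iu[sub]] * q[ju[sub]] * (1.0 - f[sub])
        rs = rij[sub]
        ars = alpha * rs
        erf_s = 1.0 - erfc(ars)
        gauss_s = (2.0 * alpha / math.sqrt(math.pi)) * np.exp(-(ars**2))
        e_corr = -float(np.sum(qs * erf_s / rs))
        fmag_c = -qs * (erf_s / rs - gauss_s) / rs**2
        fvc = fmag_c[:, None] * d[sub]
        np.add.at(forces, iu[sub], fvc)
        np.add.at(forces, ju[sub], -fvc)
        w += float(np.sum(fmag_c * rs**2))

    # --- reciprocal space (half k-space + conjugate symmetry) ---
    kvec, ksq, ak2 = _kvectors(box, nmax, alpha)
    pref = COULOMB * 2.0 * math.pi / sys.volume
    phase = np.exp(1j * (r @ kvec.T))  # (N, nk)
    sk = q @ phase  # (nk,)
    sk2 = np.abs(sk) ** 2
    e_rec = float(pref * np.sum(ak2 * sk2))
    # forces: F_i = pref * 2 q_i Σ_k a_k k Im(e^{ik·r_i} S*)
    im = np.imag(phase * np.conj(sk)[None, :])  # (N, nk)
    fk = 2.0 * pref * (q[:, None] * im * ak2[None, :]) @ kvec
    forces += fk
    w += float(np.sum(pref * ak2 * sk2 * (1.0 - ksq / (2.0 * alpha**2))))

    # --- self energy and neutralizing background ---
    e_self = -COULOMB * alpha / math.sqrt(math.pi) * float(np.sum(q**2))
    qtot = float(np.sum(q))
    e_bg = -COULOMB * math.pi / (2.0 * alpha**2 * sys.volume) * qtot**2

    return e_real + e_corr + e_rec + e_self + e_bg, forces, w


def numerical_forces(sys: SystemTopology, h: float = 1e-5, **kwargs) -> np.ndarray:
    """Central-difference gradient of the total energy (test oracle)."""
    base = sys.positions.copy()
    n = sys.n_atoms
    out = np.zeros((n, 3))
    virtual = sys.is_virtual()
    for i in range(n):
        if virtual[i]:
            continue
        for k in range(3):
            sys.positions = base.copy()
            sys.positions[i, k] += h
            ep = total_energy_forces(sys, **kwargs).total
            sys.positions = base.copy()
            sys.positions[i, k] -= h
            em = total_energy_forces(sys, **kwargs).total
            out[i, k] = -(ep - em) / (2.0 * h)
    sys.positions = base
    return out
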