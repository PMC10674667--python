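"""Compact MD engine: velocity-Verlet integration with Berendsen,
Langevin and Nosé–Hoover thermostats, an isotropic Nosé–Hoover (MTK)
barostat, SHAKE-constrained rigid water and seeded deterministic runs.

The default protocol mirrors typical ionic-liquid equilibration: a hot
scramble at 500 K under an aggressive Berendsen thermostat, an NpT
stage to find the density, Langevin damping of acoustic shocks, then
NVT production with a Nosé–Hoover chain.  The default timestep is
0.5 fs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.optimize import minimize as _scipy_minimize

from .energetics import total_energy_forces
from .molecules import Composition, reference_geometry
from .parameters import ForceField
from .topology import SystemTopology, build_system
from .units import ATM, KB, KE_CONV

__all__ = [
    "IntegratorConfig",
    "Trajectory",
    "integrate_nvt",
    "integrate_npt",
    "shake_constrain",
    "run_protocol",
    "pack_box",
    "minimize_energy",
    "kinetic_energy",
    "instantaneous_temperature",
    "ConstraintError",
    "EnergyBlowupError",
]


class ConstraintError(RuntimeError):
    """SHAKE failed to converge; message carries the worst violation."""


class EnergyBlowupError(RuntimeError):
    """Total energy overflowed / went non-finite during integration."""


@dataclass
class IntegratorConfig:
    """Integration parameters (fs, K, internal pressure units).

    Defaults follow the published protocol: 0.5 fs timestep, 100 fs
    Nosé–Hoover coupling, 2000 fs barostat coupling, LJ cutoff 8 Å.
    """

    dt: float = 0.5
    temperature: float = 350.0
    thermostat: str = "nose-hoover"  # none | berendsen | langevin | nose-hoover
    tau_t: float = 100.0
    barostat: bool = False
    tau_p: float = 2000.0
    pressure: float = ATM
    seed: int = 0
    constraint_tol: float = 1e-6
    electrostatics: str = "cutoff"  # cutoff | ewald
    rc: float | None = 8.0
    ewald_accuracy: float = 1e-4
    lj_tail: bool = False
    stride: int = 10

    def __post_init__(self):
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.thermostat not in ("none", "berendsen", "langevin", "nose-hoover"):
            raise ValueError(f"unknown thermostat {self.thermostat!r}")
        if self.thermostat != "none" and self.tau_t < self.dt:
            raise ValueError("thermostat coupling must be >= dt")


@dataclass
class Trajectory:
    """Ordered frames of a run: times (fs), positions (Å), box edges (Å).

    Positions are stored unwrapped (molecules never jump across the
    boundary), which makes mean-squared displacements trivial;
    analyses apply the minimum-image convention themselves.
    """

    times: np.ndarray  # (F,)
    positions: np.ndarray  # (F, N, 3)
    boxes: np.ndarray  # (F,)
    topology: SystemTopology | None = None
    stride: int = 1
    stage_log: list[dict] = field(default_factory=list)
    final_velocities: np.ndarray | None = None
    temperatures: np.ndarray | None = None  # instantaneous T per stored frame

    def __post_init__(self):
        if len(self.times) > 1 and not np.all(np.diff(self.times) > 0):
            raise ValueError("frame times must be strictly increasing")
        if np.any(self.boxes <= 0):
            raise ValueError("box edges must be positive")

    @property
    def n_frames(self) -> int:
        return len(self.times)

    @property
    def n_atoms(self) -> int:
        return self.positions.shape[1]

    @property
    def timestep_fs(self) -> float:
        if self.n_frames < 2:
            return 0.0
        return float(self.times[1] - self.times[0])

    def concat(self, other: "Trajectory") -> "Trajectory":
        return Trajectory(
            times=np.concatenate([self.times, other.times]),
            positions=np.concatenate([self.positions, other.positions]),
            boxes=np.concatenate([self.boxes, other.boxes]),
            topology=self.topology or other.topology,
            stride=self.stride,
            stage_log=self.stage_log + other.stage_log,
            final_velocities=other.final_velocities,
        )


# ---------------------------------------------------------------------------
# Kinetics
# ---------------------------------------------------------------------------

def kinetic_energy(v: np.ndarray, mass: np.ndarray) -> float:
    """Kinetic energy in kJ/mol for velocities in Å/fs."""
    return 0.5 * KE_CONV * float(np.sum(mass * np.einsum("ij,ij->i", v, v)))


def degrees_of_freedom(sys: SystemTopology) -> int:
    n_real = int(np.sum(sys.mass > 0))
    return 3 * n_real - 3 * (n_real > 1) - len(sys.constraints)


def instantaneous_temperature(sys: SystemTopology, v: np.ndarray) -> float:
    nf = max(degrees_of_freedom(sys), 1)
    return 2.0 * kinetic_energy(v, sys.mass) / (nf * KB)


def maxwell_boltzmann_velocities(
    sys: SystemTopology, temperature: float, rng: np.random.Generator
) -> np.ndarray:
    """Seeded Maxwell–Boltzmann draw, COM motion removed, rescaled to T."""
    v = np.zeros((sys.n_atoms, 3))
    real = sys.mass > 0
    sd = np.sqrt(KB * temperature / (KE_CONV * sys.mass[real]))
    v[real] = rng.normal(size=(int(real.sum()), 3)) * sd[:, None]
    _remove_com(v, sys.mass)
    t = instantaneous_temperature(sys, v)
    if t > 0:
        v[real] *= math.sqrt(temperature / t)
    return v


def _remove_com(v: np.ndarray, mass: np.ndarray) -> None:
    m = mass.sum()
    if m > 0:
        v -= (mass @ v / m)[None, :]


# ---------------------------------------------------------------------------
# SHAKE
# ---------------------------------------------------------------------------

def shake_constrain(
    positions: np.ndarray,
    reference: np.ndarray,
    constraints: list[tuple[int, int, float]],
    mass: np.ndarray,
    tol: float = 1e-6,
    max_iter: int = 500,
    return_virial: bool = False,
):
    """Iteratively project ``positions`` onto the constraint manifold.

    Standard SHAKE: corrections act along the *reference* (pre-step)
    bond vectors with inverse-mass weighting.  ``tol`` is the relative
    squared-distance tolerance |d² − d0²|/d0².  Returns the corrected
    positions (and, with ``return_virial``, the accumulated multiplier
    sum Σ g (d_ref·d) from which the constraint-force virial follows as
    −Σ g (d_ref·d)/dt² in kinetic units).  Raises
    :class:`ConstraintError` with the worst violation on
    non-convergence (e.g. geometrically infeasible constraints).
    """
    if not constraints:
        return (positions, 0.0) if return_virial else positions
    r = positions.copy()
    inv = np.where(mass > 0, 1.0 / np.maximum(mass, 1e-300), 0.0)
    cons = np.asarray(constraints, dtype=float)
    ci = cons[:, 0].astype(int)
    cj = cons[:, 1].astype(int)
    d0sq = cons[:, 2] ** 2
    dref = reference[ci] - reference[cj]
    inv_sum = inv[ci] + inv[cj]
    g_dot = 0.0
    for _ in range(max_iter):
        d = r[ci] - r[cj]
        diff = np.einsum("ij,ij->i", d, d) - d0sq
        rel = np.abs(diff) / d0sq
        worst = float(rel.max())
        if worst <= tol:
            return (r, g_dot) if return_virial else r
        dot = np.einsum("ij,ij->i", dref, d)
        denom = 2.0 * inv_sum * dot
        if np.any(np.abs(denom) < 1e-300):
            raise ConstraintError(
                "degenerate constraint (displacement perpendicular to reference)"
            )
        g = np.where(rel > tol, diff / denom, 0.0)
        g_dot += float(np.sum(g * dot))
        corr = (g)[:, None] * dref
        np.add.at(r, ci, -inv[ci, None] * corr)
        np.add.at(r, cj, inv[cj, None] * corr)
    raise ConstraintError(
        f"SHAKE did not converge in {max_iter} iterations; "
        f"worst relative squared-distance violation {worst:.3e}"
    )


def _constrain_velocities(
    v: np.ndarray,
    r: np.ndarray,
    constraints: list[tuple[int, int, float]],
    mass: np.ndarray,
    iters: int = 50,
) -> None:
    """RATTLE velocity stage: remove relative velocity along constraints."""
    if not constraints:
        return
    inv = np.where(mass > 0, 1.0 / np.maximum(mass, 1e-300), 0.0)
    cons = np.asarray(constraints, dtype=float)
    ci = cons[:, 0].astype(int)
    cj = cons[:, 1].astype(int)
    d = r[ci] - r[cj]
    dsq = np.einsum("ij,ij->i", d, d)
    inv_sum = inv[ci] + inv[cj]
    for _ in range(iters):
        rv = np.einsum("ij,ij->i", d, v[ci] - v[cj])
        if np.abs(rv).max() < 1e-12:
            break
        k = rv / (inv_sum * dsq)
        corr = k[:, None] * d
        np.add.at(v, ci, -inv[ci, None] * corr)
        np.add.at(v, cj, inv[cj, None] * corr)


# ---------------------------------------------------------------------------
# Integrator core
# ---------------------------------------------------------------------------

class _NoseHooverChain:
    """Two-link Nosé–Hoover chain acting on the particle velocities."""

    def __init__(self, nf: int, temperature: float, tau: float):
        self.nf = nf
        self.kt = KB * temperature
        # chain masses in (kJ/mol)·fs²
        self.q = np.array([nf * self.kt * tau**2, self.kt * tau**2])
        self.vxi = np.zeros(2)

    def half_step(self, v: np.ndarray, mass: np.ndarray, dt: float) -> float:
        """Advance chain by dt/2; returns velocity scale factor."""
        k2 = 2.0 * kinetic_energy(v, mass)
        g2 = (self.q[0] * self.vxi[0] ** 2 - self.kt) / self.q[1]
        self.vxi[1] += 0.25 * dt * g2
        g1 = (k2 - self.nf * self.kt) / self.q[0]
        self.vxi[0] *= math.exp(-0.125 * dt * self.vxi[1])
        self.vxi[0] += 0.25 * dt * g1
        self.vxi[0] *= math.exp(-0.125 * dt * self.vxi[1])
        s = math.exp(-0.5 * dt * self.vxi[0])
        k2 *= s * s
        self.vxi[0] *= math.exp(-0.125 * dt * self.vxi[1])
        g1 = (k2 - self.nf * self.kt) / self.q[0]
        self.vxi[0] += 0.25 * dt * g1
        self.vxi[0] *= math.exp(-0.125 * dt * self.vxi[1])
        g2 = (self.q[0] * self.vxi[0] ** 2 - self.kt) / self.q[1]
        self.vxi[1] += 0.25 * dt * g2
        return s


class _MTKBarostat:
    """Isotropic cell mode with Nosé–Hoover-style inertia and its own
    single thermostat link (keeps the cell oscillation thermalized).

    Operates on the *molecular* degrees of freedom: the pressure it
    feels is the molecular (COM) pressure and its cell scaling acts on
    molecular centers, which keeps rigid molecules rigid.
    """

    def __init__(self, cfg: IntegratorConfig, n_mol: int):
        kt = KB * cfg.temperature
        self.nf = 3 * n_mol
        self.w = (self.nf + 3) * kt * cfg.tau_p**2
        self.p_eps = 0.0
        self.kt = kt
        self.p0 = cfg.pressure
        self.qb = kt * (10.0 * cfg.tau_p) ** 2
        self.vxib = 0.0

    def half_step(self, volume, pressure, k2_trans, dt):
        gb = (self.p_eps**2 / self.w - self.kt) / self.qb
        self.vxib += 0.5 * dt * gb
        self.p_eps *= math.exp(-0.5 * dt * self.vxib)
        g = 3.0 * volume * (pressure - self.p0) + (3.0 / self.nf) * k2_trans
        self.p_eps += 0.5 * dt * g
        self.p_eps *= math.exp(-0.5 * dt * self.vxib)
        gb = (self.p_eps**2 / self.w - self.kt) / self.qb
        self.vxib += 0.5 * dt * gb

    def scale(self, dt: float) -> float:
        return math.exp(dt * self.p_eps / self.w)

    def vel_scale(self, dt: float) -> float:
        return math.exp(-dt * (1.0 + 3.0 / self.nf) * self.p_eps / self.w)


def _mol_arrays(sys: SystemTopology):
    cache = getattr(sys, "_mol_cache", None)
    if cache is None:
        mol = sys.mol_id
        n_mol = int(mol.max()) + 1
        mmol = np.zeros(n_mol)
        np.add.at(mmol, mol, sys.mass)
        cache = (mol, n_mol, mmol)
        sys._mol_cache = cache
    return cache


def _com_positions(sys: SystemTopology):
    mol, n_mol, mmol = _mol_arrays(sys)
    com = np.zeros((n_mol, 3))
    np.add.at(com, mol, sys.mass[:, None] * sys.positions)
    return com / mmol[:, None]


def _com_velocities(sys: SystemTopology, v: np.ndarray):
    mol, n_mol, mmol = _mol_arrays(sys)
    p = np.zeros((n_mol, 3))
    np.add.at(p, mol, sys.mass[:, None] * v)
    return p / mmol[:, None]


def molecular_pressure(sys: SystemTopology, v: np.ndarray, rep) -> tuple[float, float]:
    """Molecular (COM-based) pressure and twice the COM kinetic energy.

    P = (2K_trans + W_atomic − Σ_i F_i·(r_i − R_com)) / 3V.  The lever-arm
    correction removes intramolecular contributions, so rigid-molecule
    constraint forces never enter.
    """
    mol, n_mol, mmol = _mol_arrays(sys)
    com = _com_positions(sys)
    wcorr = -float(np.einsum("ij,ij->", rep.forces, sys.positions - com[mol]))
    vcom = _com_velocities(sys, v)
    k2 = KE_CONV * float(np.einsum("i,ij,ij->", mmol, vcom, vcom))
    return (k2 + rep.virial + wcorr) / (3.0 * sys.volume), k2


def _forces(sys: SystemTopology, cfg: IntegratorConfig):
    rep = total_energy_forces(
        sys, method=cfg.electrostatics, rc=cfg.rc, accuracy=cfg.ewald_accuracy,
        tail=cfg.lj_tail,
    )
    if not np.isfinite(rep.total):
        raise EnergyBlowupError(
            f"non-finite potential energy ({rep.total}); "
            "reduce the timestep or re-equilibrate"
        )
    return rep


def _integrate(
    sys: SystemTopology,
    cfg: IntegratorConfig,
    steps: int,
    velocities: np.ndarray | None,
    barostat: bool,
) -> Trajectory:
    rng = np.random.default_rng(cfg.seed)
    if velocities is None:
        v = maxwell_boltzmann_velocities(sys, cfg.temperature, rng)
    else:
        v = velocities.copy()
    nf = max(degrees_of_freedom(sys), 1)
    nhc = _NoseHooverChain(nf, cfg.temperature, cfg.tau_t)
    baro = _MTKBarostat(cfg, _mol_arrays(sys)[1]) if barostat else None
    mol = sys.mol_id

    sys.place_virtual_sites()
    rep = _forces(sys, cfg)
    inv_m = np.where(sys.mass > 0, 1.0 / np.maximum(sys.mass, 1e-300), 0.0)

    frames_t, frames_r, frames_b = [0.0], [sys.positions.copy()], [sys.box_edge]
    frames_temp = [instantaneous_temperature(sys, v)]
    if cfg.thermostat == "langevin":
        c1 = math.exp(-cfg.dt / cfg.tau_t)
        c2 = math.sqrt(1.0 - c1 * c1)

    dt = cfg.dt

    def _baro_couple(half):
        """Half-step barostat update + COM velocity scaling."""
        nonlocal v
        p_mol, k2t = molecular_pressure(sys, v, rep)
        if half == "pre":
            baro.half_step(sys.volume, p_mol, k2t, dt)
        vs = baro.vel_scale(0.5 * dt)
        vcom = _com_velocities(sys, v)
        v += (vs - 1.0) * vcom[mol]
        if half == "post":
            p_mol, k2t = molecular_pressure(sys, v, rep)
            baro.half_step(sys.volume, p_mol, k2t, dt)

    for step in range(1, steps + 1):
        if cfg.thermostat == "nose-hoover":
            s = nhc.half_step(v, sys.mass, dt)
            v *= s
        if baro is not None:
            _baro_couple("pre")

        # kick
        v += 0.5 * dt * 1e-4 * rep.forces * inv_m[:, None]
        # drift (+ cell scaling of molecular centers)
        ref = sys.positions.copy()
        if baro is not None:
            sc = baro.scale(dt)
            sys.box_edge *= sc
            com = _com_positions(sys)
            sys.positions += (sc - 1.0) * com[mol]
        sys.positions += dt * v
        if sys.constraints:
            unconstrained = sys.positions
            sys.positions = shake_constrain(
                sys.positions, ref, sys.constraints, sys.mass, cfg.constraint_tol
            )
            v += (sys.positions - unconstrained) / dt
        sys.place_virtual_sites()
        rep = _forces(sys, cfg)
        # kick
        v += 0.5 * dt * 1e-4 * rep.forces * inv_m[:, None]
        if sys.constraints:
            _constrain_velocities(v, sys.positions, sys.constraints, sys.mass)

        if baro is not None:
            _baro_couple("post")
        if cfg.thermostat == "nose-hoover":
            s = nhc.half_step(v, sys.mass, dt)
            v *= s
        elif cfg.thermostat == "berendsen":
            t = instantaneous_temperature(sys, v)
            if t > 0:
                lam = math.sqrt(
                    max(1.0 + (dt / cfg.tau_t) * (cfg.temperature / t - 1.0), 0.0)
                )
                v *= lam
        elif cfg.thermostat == "langevin":
            real = sys.mass > 0
            sd = np.sqrt(KB * cfg.temperature / (KE_CONV * sys.mass[real]))
            v[real] = c1 * v[real] + c2 * sd[:, None] * rng.normal(
                size=(int(real.sum()), 3)
            )
            _remove_com(v, sys.mass)
            if sys.constraints:
                _constrain_velocities(v, sys.positions, sys.constraints, sys.mass)

        if step % cfg.stride == 0 or step == steps:
            frames_t.append(step * dt)
            frames_r.append(sys.positions.copy())
            frames_b.append(sys.box_edge)
            frames_temp.append(instantaneous_temperature(sys, v))

    return Trajectory(
        times=np.array(frames_t),
        positions=np.array(frames_r),
        boxes=np.array(frames_b),
        topology=sys,
        stride=cfg.stride,
        final_velocities=v,
        temperatures=np.array(frames_temp),
    )


def integrate_nvt(
    sys: SystemTopology,
    cfg: IntegratorConfig,
    steps: int,
    velocities: np.ndarray | None = None,
) -> Trajectory:
    """Constant-volume run; ``thermostat='none'`` gives the NVE limit."""
    return _integrate(sys, cfg, steps, velocities, barostat=False)


def integrate_npt(
    sys: SystemTopology,
    cfg: IntegratorConfig,
    steps: int,
    velocities: np.ndarray | None = None,
) -> Trajectory:
    """Isotropic NpT run; the cubic box edge fluctuates."""
    if not cfg.barostat:
        return _integrate(sys, cfg, steps, velocities, barostat=False)
    return _integrate(sys, cfg, steps, velocities, barostat=True)


# ---------------------------------------------------------------------------
# Packing and minimization
# ---------------------------------------------------------------------------

def pack_box(
    comp: Composition,
    ff: ForceField,
    seed: int = 0,
    min_dist: float = 2.0,
    max_tries: int = 20000,
) -> np.ndarray:
    """Seeded random insertion with overlap rejection (Packmol stand-in).

    Each molecule is placed with a random rotation and translation; a
    candidate is rejected if any atom comes within ``min_dist`` Å
    (minimum image) of already placed atoms.
    """
    rng = np.random.default_rng(seed)
    box = comp.box_edge
    placed: list[np.ndarray] = []
    coords: list[np.ndarray] = []
    for template, count in comp.items:
        geo = reference_geometry(template)
        geo = geo - geo.mean(axis=0)
        for _ in range(count):
            for attempt in range(max_tries):
                m = _random_rotation(rng)
                shift = rng.uniform(0.0, box, size=3)
                cand = geo @ m.T + shift
                if _no_overlap(cand, placed, box, min_dist):
                    coords.append(cand)
                    placed.append(cand)
                    break
            else:
                raise RuntimeError(
                    f"could not place molecule {template.name} after {max_tries} tries; "
                    "box too dense for random insertion"
                )
    return np.vstack(coords)


def _random_rotation(rng: np.random.Generator) -> np.ndarray:
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array(
        [
            [1 - 2 * (y * y + z * z), 2 * (x * y - z * w), 2 * (x * z + y * w)],
            [2 * (x * y + z * w), 1 - 2 * (x * x + z * z), 2 * (y * z - x * w)],
            [2 * (x * z - y * w), 2 * (y * z + x * w), 1 - 2 * (x * x + y * y)],
        ]
    )


def _no_overlap(cand, placed, box, min_dist):
    for other in placed:
        d = cand[:, None, :] - other[None, :, :]
        d -= box * np.round(d / box)
        if np.min(np.einsum("ijk,ijk->ij", d, d)) < min_dist**2:
            return False
    return True


def minimize_energy(
    sys: SystemTopology,
    cfg: IntegratorConfig | None = None,
    maxiter: int = 200,
) -> float:
    """L-BFGS energy minimization in place; returns the final energy.

    Constrained (rigid) molecules are kept out of the optimization and
    re-projected by SHAKE afterwards.
    """
    cfg = cfg or IntegratorConfig()
    shape = sys.positions.shape
    frozen = sys.is_virtual()
    ref = sys.positions.copy()
    k_pen = 5.0e4  # kJ mol⁻¹ Å⁻²; keeps rigid geometries intact during descent

    def fun(x):
        sys.positions = x.reshape(shape).copy()
        sys.place_virtual_sites()
        rep = total_energy_forces(sys, method=cfg.electrostatics, rc=cfg.rc)
        g = -rep.forces
        e = rep.total
        for i, j, d0 in sys.constraints:
            dv = sys.positions[i] - sys.positions[j]
            dist = float(np.linalg.norm(dv))
            e += k_pen * (dist - d0) ** 2
            gv = 2.0 * k_pen * (dist - d0) * dv / max(dist, 1e-12)
            g[i] += gv
            g[j] -= gv
        g[frozen] = 0.0
        return e, g.ravel()

    res = _scipy_minimize(
        fun, sys.positions.ravel(), jac=True, method="L-BFGS-B",
        options={"maxiter": maxiter},
    )
    sys.positions = res.x.reshape(shape)
    if sys.constraints:
        # project onto the constraint manifold along the current bond
        # directions (the pre-descent reference is no longer relevant)
        sys.positions = shake_constrain(
            sys.positions, sys.positions.copy(), sys.constraints, sys.mass,
            cfg.constraint_tol,
        )
    sys.place_virtual_sites()
    return float(res.fun)


# ---------------------------------------------------------------------------
# Published four-stage protocol
# ---------------------------------------------------------------------------

def run_protocol(
    comp: Composition,
    ff: ForceField,
    seed: int = 0,
    *,
    scramble_ps: float = 25.0,
    npt_ps: float = 100.0,
    damp_ps: float = 5.0,
    production_ps: float = 100.0,
    temperature: float = 350.0,
    scramble_temperature: float = 500.0,
    cfg: IntegratorConfig | None = None,
) -> Trajectory:
    """Pack → 500 K Berendsen NVT → NpT → Langevin damping → NVT production.

    Durations are configurable; defaults follow the published protocol
    (25 ps scramble, 100 ps NpT, Nosé–Hoover production).  Returns the
    production trajectory; its ``stage_log`` records all four phases.
    """
    base = cfg or IntegratorConfig()
    log: list[dict] = []

    positions = pack_box(comp, ff, seed=seed)
    sys = build_system(comp, ff, positions)
    sys.place_virtual_sites()
    minimize_energy(sys, replace(base, electrostatics="cutoff",
                                 rc=min(base.rc or 8.0, sys.box_edge / 2 * 0.99)),
                    maxiter=150)
    log.append({"stage": "pack+minimize", "n_atoms": sys.n_atoms})

    def ps_steps(ps):
        return max(int(round(ps * 1000.0 / base.dt)), 1)

    c1 = replace(base, thermostat="berendsen", tau_t=max(1.0, base.dt),
                 temperature=scramble_temperature, seed=seed)
    traj = integrate_nvt(sys, c1, ps_steps(scramble_ps))
    log.append({"stage": "nvt-berendsen", "T": scramble_temperature,
                "ps": scramble_ps})

    c2 = replace(base, thermostat="nose-hoover", temperature=temperature,
                 barostat=True, seed=seed + 1)
    traj = integrate_npt(sys, c2, ps_steps(npt_ps), velocities=traj.final_velocities)
    log.append({"stage": "npt-nose-hoover", "T": temperature, "ps": npt_ps,
                "final_box": sys.box_edge})

    c3 = replace(base, thermostat="langevin", tau_t=100.0,
                 temperature=temperature, seed=seed + 2)
    traj = integrate_nvt(sys, c3, ps_steps(damp_ps), velocities=traj.final_velocities)
    log.append({"stage": "nvt-langevin-damp", "T": temperature, "ps": damp_ps})

    c4 = replace(base, thermostat="nose-hoover", temperature=temperature,
                 seed=seed + 3)
    prod = integrate_nvt(sys, c4, ps_steps(production_ps),
                         velocities=traj.final_velocities)
    log.append({"stage": "nvt-production", "T": temperature, "ps": production_ps})
    prod.stage_log = log
    return prod
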