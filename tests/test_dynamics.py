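"""MD engine: energy conservation, thermostats, barostat, SHAKE,
packing and protocol bookkeeping."""

import numpy as np
import pytest

from bilff import (
    Composition,
    IntegratorConfig,
    build_molecule,
    build_system,
    integrate_npt,
    integrate_nvt,
    pack_box,
    shake_constrain,
)
from bilff.dynamics import (
    ConstraintError,
    kinetic_energy,
    maxwell_boltzmann_velocities,
    run_protocol,
)
from bilff.energetics import total_energy_forces
from bilff.molecules import reference_geometry
from bilff.units import ATM, KB

from conftest import bare_topology, lj_lattice


def _dimer(ff):
    sys = bare_topology(
        ff, [[25.0, 25, 25], [25.0 + 3.4 * 1.2, 25, 25]],
        sigma=[3.4, 3.4], epsilon=[1.0, 1.0], box=50.0,
    )
    return sys


def test_nve_energy_conservation(ff):
    """Symplectic velocity Verlet: relative drift < 1e-4 over 10⁴ steps."""
    sys = _dimer(ff)
    e0 = total_energy_forces(sys, method="cutoff", rc=None).total
    cfg = IntegratorConfig(dt=0.5, thermostat="none", rc=None, stride=2000, seed=1)
    traj = integrate_nvt(sys, cfg, 10000, velocities=np.zeros((2, 3)))
    e_end = total_energy_forces(sys, method="cutoff", rc=None).total
    e_end += kinetic_energy(traj.final_velocities, sys.mass)
    assert abs(e_end - e0) / abs(e0) < 1e-4


def test_zero_steps_returns_initial_configuration(ff):
    sys = _dimer(ff)
    start = sys.positions.copy()
    cfg = IntegratorConfig(dt=0.5, thermostat="none", rc=None, seed=1)
    traj = integrate_nvt(sys, cfg, 0, velocities=np.zeros((2, 3)))
    assert traj.n_frames == 1
    np.testing.assert_array_equal(traj.positions[0], start)


def test_langevin_temperature_control(ff):
    """Equipartition: ⟨T⟩ within 5 % of target on a 100-particle LJ fluid."""
    sys = lj_lattice(ff, 100, 22.0)
    cfg = IntegratorConfig(dt=5.0, thermostat="langevin", tau_t=200.0,
                           temperature=350.0, rc=8.0, stride=20, seed=2)
    traj = integrate_nvt(sys, cfg, 4000)
    t = traj.temperatures
    mean_t = t[len(t) // 2 :].mean()
    assert mean_t == pytest.approx(350.0, rel=0.05)


def test_nose_hoover_temperature_control(ff):
    """Nosé–Hoover chain holds ⟨T⟩ within 2 % on the LJ fluid."""
    sys = lj_lattice(ff, 100, 22.0)
    cfg = IntegratorConfig(dt=5.0, thermostat="nose-hoover", tau_t=200.0,
                           temperature=350.0, rc=8.0, stride=20, seed=3)
    traj = integrate_nvt(sys, cfg, 6000)
    t = traj.temperatures
    mean_t = t[len(t) // 3 :].mean()
    assert mean_t == pytest.approx(350.0, rel=0.02)


def test_fixed_seed_reproduces_trajectory_exactly(ff):
    cfg = IntegratorConfig(dt=2.0, thermostat="langevin", tau_t=100.0,
                           temperature=350.0, rc=7.0, stride=10, seed=7)
    t1 = integrate_nvt(lj_lattice(ff, 20, 15.0), cfg, 300)
    t2 = integrate_nvt(lj_lattice(ff, 20, 15.0), cfg, 300)
    assert np.array_equal(t1.positions, t2.positions)
    assert np.array_equal(t1.final_velocities, t2.final_velocities)


def test_momentum_conserved_in_nve(ff):
    sys = lj_lattice(ff, 27, 15.0)
    rng = np.random.default_rng(5)
    v0 = maxwell_boltzmann_velocities(sys, 100.0, rng)
    cfg = IntegratorConfig(dt=2.0, thermostat="none", rc=7.0, stride=50, seed=5)
    traj = integrate_nvt(sys, cfg, 500, velocities=v0)
    p = (sys.mass[:, None] * traj.final_velocities).sum(axis=0)
    assert np.abs(p).max() < 1e-10


def test_barostat_disabled_keeps_box_constant(ff):
    sys = lj_lattice(ff, 27, 15.0)
    cfg = IntegratorConfig(dt=2.0, thermostat="nose-hoover", temperature=200.0,
                           rc=7.0, barostat=False, stride=20, seed=6)
    traj = integrate_npt(sys, cfg, 200)
    assert np.all(traj.boxes == traj.boxes[0])


def test_npt_ideal_gas_density(ff):
    """Interaction-free gas: mean volume matches pV = NkT within 10 %."""
    n, t0 = 64, 350.0
    v_pred = n * KB * t0 / ATM
    sys = lj_lattice(ff, n, v_pred ** (1 / 3) * 0.8, epsilon=0.0)
    cfg = IntegratorConfig(dt=10.0, thermostat="nose-hoover", tau_t=500.0,
                           temperature=t0, rc=None, barostat=True,
                           tau_p=5000.0, stride=50, seed=4)
    traj = integrate_npt(sys, cfg, 6000)
    v_mean = np.mean(traj.boxes[len(traj.boxes) // 2 :] ** 3)
    assert v_mean == pytest.approx(v_pred, rel=0.10)


# ---------------------------------------------------------------------------
# SHAKE
# ---------------------------------------------------------------------------

def _water_constraints():
    w = build_molecule("TIP4PEW")
    return w, w.constraints


def test_shake_leaves_satisfied_geometry_unchanged():
    w, cons = _water_constraints()
    pos = reference_geometry(w)
    mass = np.array([15.999, 1.008, 1.008, 0.0])
    out = shake_constrain(pos.copy(), pos, cons, mass, tol=1e-10)
    np.testing.assert_allclose(out, pos, atol=1e-12)


def test_shake_restores_perturbed_water():
    w, cons = _water_constraints()
    ref = reference_geometry(w)
    pos = ref.copy()
    pos[1] += [0.01, 0.0, 0.0]  # +1 pm on one OH
    mass = np.array([15.999, 1.008, 1.008, 0.0])
    out = shake_constrain(pos, ref, cons, mass, tol=1e-14)
    for i, j, d0 in cons:
        assert abs(np.linalg.norm(out[i] - out[j]) - d0) < 1e-6


def test_shake_infeasible_constraints_error():
    # triangle inequality violated: three collinear targets 1-1-5
    pos = np.array([[0.0, 0, 0], [1.0, 0, 0], [2.0, 0, 0]])
    cons = [(0, 1, 1.0), (1, 2, 1.0), (0, 2, 5.0)]
    mass = np.ones(3)
    with pytest.raises(ConstraintError):
        shake_constrain(pos.copy(), pos, cons, mass, tol=1e-10, max_iter=50)


def test_rigid_water_stays_rigid_during_md(ff):
    w = build_molecule("TIP4PEW")
    geo = reference_geometry(w)
    pos = np.vstack([geo + [10, 10, 10], geo + [13.2, 10, 10]])
    comp = Composition([(w, 2)], 3000.0)
    sys = build_system(comp, ff, pos)
    cfg = IntegratorConfig(dt=1.0, thermostat="langevin", tau_t=100.0,
                           temperature=300.0, rc=None, stride=100, seed=5)
    integrate_nvt(sys, cfg, 1000)
    for i, j, d0 in sys.constraints:
        assert abs(np.linalg.norm(sys.positions[i] - sys.positions[j]) - d0) < 1e-5


# ---------------------------------------------------------------------------
# Packing and protocol
# ---------------------------------------------------------------------------

def test_pack_box_respects_minimum_distance(ff):
    comp = Composition([(build_molecule("OBz"), 6)], 2500.0)
    pos = pack_box(comp, ff, seed=3, min_dist=2.0)
    box = comp.box_edge
    n_mol = 6
    n_at = build_molecule("OBz").n_atoms
    for a in range(n_mol):
        for b in range(a + 1, n_mol):
            d = pos[a * n_at : (a + 1) * n_at, None, :] - pos[None, b * n_at : (b + 1) * n_at, :]
            d -= box * np.round(d / box)
            assert np.sqrt((d ** 2).sum(axis=-1)).min() >= 2.0 - 1e-9


def test_pack_box_deterministic(ff):
    comp = Composition([(build_molecule("EMTr"), 4)], 2500.0)
    p1 = pack_box(comp, ff, seed=9)
    p2 = pack_box(comp, ff, seed=9)
    np.testing.assert_array_equal(p1, p2)


def test_protocol_logs_four_stages_in_order(ff):
    comp = Composition([(build_molecule("OBz"), 2)], 2400.0)
    traj = run_protocol(
        comp, ff, seed=1,
        scramble_ps=0.05, npt_ps=0.05, damp_ps=0.02, production_ps=0.05,
        cfg=IntegratorConfig(dt=1.0, electrostatics="cutoff", rc=8.0, stride=10),
    )
    names = [s["stage"] for s in traj.stage_log]
    assert names == [
        "pack+minimize", "nvt-berendsen", "npt-nose-hoover",
        "nvt-langevin-damp", "nvt-production",
    ]


def test_protocol_deterministic(ff):
    comp = Composition([(build_molecule("OBz"), 2)], 2400.0)
    kw = dict(scramble_ps=0.03, npt_ps=0.03, damp_ps=0.01, production_ps=0.03,
              cfg=IntegratorConfig(dt=1.0, electrostatics="cutoff", rc=8.0, stride=5))
    t1 = run_protocol(comp, ff, seed=2, **kw)
    t2 = run_protocol(comp, ff, seed=2, **kw)
    assert np.array_equal(t1.positions, t2.positions)
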