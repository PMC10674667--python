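"""Trajectory analyses against synthetic fixtures with known structure."""

import math

import numpy as np
import pytest

from bilff.analysis import (
    HBondCriterion,
    NoBondsError,
    NoPeakError,
    cdf_distance_angle,
    coordination_number,
    diffusion,
    first_peak,
    hbond_lifetimes,
    rdf,
    sdf,
)
from bilff.fixtures import FixtureSpec, make_fixture


@pytest.fixture(scope="module")
def ideal_gas():
    return make_fixture(
        FixtureSpec("ideal_gas", n_frames=60, box=30.0, seed=1, params={"n": 300})
    )


def test_ideal_gas_rdf_is_flat(ideal_gas):
    """Homogeneous Poisson field: g(r) = 1 within 5 % beyond the first bins."""
    res = rdf(ideal_gas, np.arange(300), np.arange(300),
              bin_width_pm=20.0, r_max_pm=1400.0)
    tail = res.g[10:]
    assert np.all(np.abs(tail - 1.0) < 0.05 + 3.0 / np.sqrt(res.n_frames))
    assert abs(tail.mean() - 1.0) < 0.02


def test_frozen_pair_single_occupied_bin():
    traj = make_fixture(
        FixtureSpec("frozen_pair", n_frames=5, box=50.0, params={"r_pm": 300.0})
    )
    res = rdf(traj, np.array([0]), np.array([1]), bin_width_pm=1.0, r_max_pm=2000.0)
    occupied = np.flatnonzero(res.g > 0)
    assert len(occupied) == 1
    assert res.r_pm[occupied[0]] == pytest.approx(300.0, abs=1.0)


def test_rdf_rejects_rmax_beyond_half_box(ideal_gas):
    with pytest.raises(ValueError, match="half the box"):
        rdf(ideal_gas, np.arange(10), np.arange(10), r_max_pm=2000.0)


def test_rdf_counting_identity():
    """∫ 4π r² ρ g dr over the full histogram equals the mean number of
    counted partners per observer (exact, by construction)."""
    traj = make_fixture(
        FixtureSpec("ideal_gas", n_frames=10, box=20.0, seed=3, params={"n": 64})
    )
    res = rdf(traj, np.arange(64), np.arange(64), bin_width_pm=10.0,
              r_max_pm=1000.0)
    n_integral = coordination_number(res, 1000.0)
    # count directly
    total = 0
    for f in range(traj.n_frames):
        d = traj.positions[f][:, None, :] - traj.positions[f][None, :, :]
        d -= 20.0 * np.round(d / 20.0)
        dist = np.sqrt((d ** 2).sum(-1))
        np.fill_diagonal(dist, np.inf)
        total += (dist <= 10.0).sum()
    expected = total / (traj.n_frames * 64)
    assert n_integral == pytest.approx(expected, rel=1e-9)


def test_rdf_invariant_under_rigid_translation(ideal_gas):
    shifted = make_fixture(
        FixtureSpec("ideal_gas", n_frames=60, box=30.0, seed=1, params={"n": 300})
    )
    shifted.positions = shifted.positions + np.array([13.0, -7.0, 41.0])
    a = rdf(ideal_gas, np.arange(50), np.arange(50), bin_width_pm=20.0,
            r_max_pm=1200.0)
    b = rdf(shifted, np.arange(50), np.arange(50), bin_width_pm=20.0,
            r_max_pm=1200.0)
    np.testing.assert_allclose(a.g, b.g)


def test_first_peak_on_gaussian_shell():
    """Constructed fixture: targets at N(200 pm, 10 pm) around a center."""
    traj = make_fixture(
        FixtureSpec("gaussian_shell", n_frames=150, box=50.0, seed=2,
                    params={"n_targets": 100, "r0_pm": 200.0, "sigma_pm": 10.0})
    )
    res = rdf(traj, np.array([0]), np.arange(1, 101), bin_width_pm=2.0,
              r_max_pm=1000.0)
    r_peak, g_peak, r_min = first_peak(res)
    assert r_peak == pytest.approx(200.0, abs=6.0)
    # analytic height: g(r0) = V φ(r0) / (4π r0²), φ the radial Gaussian
    g_pred = 50.0**3 / (4 * math.pi * 2.0**2) / (0.1 * math.sqrt(2 * math.pi))
    assert g_peak == pytest.approx(g_pred, rel=0.15)
    assert r_min > r_peak


def test_first_peak_monotone_curve_raises(ideal_gas):
    res = rdf(ideal_gas, np.arange(20), np.arange(20), bin_width_pm=50.0,
              r_max_pm=1000.0)
    res.g = np.linspace(0.0, 2.0, len(res.g))
    with pytest.raises(NoPeakError):
        first_peak(res)


def test_coordination_number_ideal_gas_closed_form(ideal_gas):
    """n(R) = (4/3)π R³ ρ for g ≡ 1, to better than 1 %."""
    res = rdf(ideal_gas, np.arange(300), np.arange(300), bin_width_pm=10.0,
              r_max_pm=1400.0)
    rho = 300 / 30.0**3
    for r_pm in (800.0, 1000.0, 1200.0):
        expected = 4.0 / 3.0 * math.pi * (r_pm / 100.0) ** 3 * rho
        assert coordination_number(res, r_pm) == pytest.approx(expected, rel=0.01)


def test_coordination_number_zero_for_empty_g(ideal_gas):
    res = rdf(ideal_gas, np.arange(10), np.arange(10), bin_width_pm=10.0,
              r_max_pm=1000.0)
    res.g = np.zeros_like(res.g)
    assert coordination_number(res, 900.0) == 0.0


# ---------------------------------------------------------------------------
# CDF
# ---------------------------------------------------------------------------

def _static_triplet(angle_deg, r_ha=2.0, frames=3):
    """One donor-H-acceptor triplet with a fixed H⋯A geometry."""
    from bilff.dynamics import Trajectory

    a = math.radians(angle_deg)
    pos = np.array([
        [0.0, 0.0, 0.0],      # donor
        [1.0, 0.0, 0.0],      # hydrogen
        [1.0 + r_ha * math.cos(a), r_ha * math.sin(a), 0.0],  # acceptor
    ]) + 25.0
    return Trajectory(
        times=np.arange(frames, dtype=float) * 10.0,
        positions=np.repeat(pos[None], frames, axis=0),
        boxes=np.full(frames, 50.0),
    )


@pytest.mark.parametrize("angle", [0.0, 90.0])
def test_cdf_mass_at_constructed_angle(angle):
    traj = _static_triplet(angle)
    res = cdf_distance_angle(traj, np.array([0]), np.array([1]), np.array([2]),
                             r_max_pm=600.0, r_bin_pm=5.0, angle_bin_deg=2.0)
    i, j = np.unravel_index(np.argmax(res.counts), res.counts.shape)
    assert res.r_edges_pm[i] == pytest.approx(200.0, abs=5.0)
    assert res.angle_edges_deg[j] == pytest.approx(angle, abs=2.0)
    assert res.counts.sum() == traj.n_frames  # every triplet counted once


def test_cdf_empty_selection_raises(ideal_gas):
    with pytest.raises(ValueError, match="empty"):
        cdf_distance_angle(ideal_gas, np.array([], dtype=int),
                           np.array([], dtype=int), np.array([0]))


# ---------------------------------------------------------------------------
# SDF
# ---------------------------------------------------------------------------

def test_sdf_uniform_targets_give_bulk_density():
    traj = make_fixture(
        FixtureSpec("ideal_gas", n_frames=100, box=20.0, seed=7, params={"n": 400})
    )
    res = sdf(traj, np.array([[0, 1, 2]]), np.arange(3, 400),
              extent=5.0, grid_res=2.5)
    bulk_nm3 = 397 / 20.0**3 * 1000.0  # targets per nm³
    assert res.density.mean() == pytest.approx(bulk_nm3, rel=0.05)


def test_sdf_integral_equals_mean_target_count():
    """Conservation: Σ density·voxel = mean targets inside the grid."""
    traj = make_fixture(
        FixtureSpec("ideal_gas", n_frames=30, box=20.0, seed=8, params={"n": 100})
    )
    res = sdf(traj, np.array([[0, 1, 2]]), np.arange(3, 100),
              extent=6.0, grid_res=1.0)
    voxel_nm3 = 1.0**3 / 1000.0
    assert res.density.sum() * voxel_nm3 == pytest.approx(
        res.mean_targets_in_grid, rel=1e-9
    )


def test_sdf_comoving_target_single_voxel():
    from bilff.dynamics import Trajectory

    frames = 20
    rng = np.random.default_rng(4)
    # target coordinates chosen off voxel boundaries
    base = np.array([[0.0, 0, 0], [2.0, 0, 0], [0.0, 2, 0], [1.2, 0.7, 1.3]])
    pos = np.zeros((frames, 4, 3))
    for f in range(frames):
        shift = rng.uniform(0, 30, size=3)
        pos[f] = base + shift  # rigid co-motion, no rotation
    traj = Trajectory(np.arange(frames, dtype=float), pos, np.full(frames, 30.0))
    res = sdf(traj, np.array([[0, 1, 2]]), np.array([3]), extent=4.0, grid_res=0.5)
    assert (res.density > 0).sum() == 1


def test_sdf_collinear_anchors_error():
    from bilff.dynamics import Trajectory

    pos = np.array([[[0.0, 0, 0], [1.0, 0, 0], [2.0, 0, 0], [5.0, 5, 5]]])
    traj = Trajectory(np.array([0.0]), pos, np.array([30.0]))
    with pytest.raises(ValueError, match="collinear"):
        sdf(traj, np.array([[0, 1, 2]]), np.array([3]))


# ---------------------------------------------------------------------------
# Hydrogen-bond lifetimes
# ---------------------------------------------------------------------------

def _telegraph(k_break, k_form=0.5, n_pairs=27, frames=8000, dt_fs=50.0, seed=3):
    traj = make_fixture(
        FixtureSpec("telegraph_hbond", n_frames=frames, dt_fs=dt_fs, box=200.0,
                    seed=seed,
                    params={"n_pairs": n_pairs, "k_break_per_ps": k_break,
                            "k_form_per_ps": k_form})
    )
    d = np.arange(n_pairs) * 3
    return traj, d, d + 1, d + 2


def test_telegraph_continuous_lifetime_recovery():
    """First-passage oracle: continuous τ = 1/k_break within 10 %."""
    traj, d, h, a = _telegraph(0.5)
    res = hbond_lifetimes(traj, HBondCriterion(300.0, 30.0), d, h, a, matched=True)
    assert res.tau_continuous_ps == pytest.approx(2.0, rel=0.10)


@pytest.mark.parametrize("rate", [0.1, 0.5, 2.0])
def test_telegraph_rate_sweep(rate):
    traj, d, h, a = _telegraph(rate, seed=int(rate * 10) + 1)
    res = hbond_lifetimes(traj, HBondCriterion(300.0, 30.0), d, h, a, matched=True)
    assert res.tau_continuous_ps == pytest.approx(1.0 / rate, rel=0.10)


def test_lifetime_ordering_continuous_below_intermittent():
    """Re-formation can only lengthen the correlation: τ_cont ≤ τ_int."""
    for seed in (1, 2, 3):
        traj, d, h, a = _telegraph(1.0, k_form=0.3, frames=4000, seed=seed)
        res = hbond_lifetimes(traj, HBondCriterion(300.0, 30.0), d, h, a,
                              matched=True)
        assert res.tau_continuous_ps <= res.tau_intermittent_ps


def test_permanent_bond_censoring_flagged():
    traj, d, h, a = _telegraph(1e-9, k_form=100.0, frames=200)
    res = hbond_lifetimes(traj, HBondCriterion(300.0, 30.0), d, h, a, matched=True)
    assert res.censored
    # the sampled window is 10 ps; the survival estimate cannot shrink
    # below a large fraction of it for a never-breaking bond
    assert res.tau_continuous_ps > 2.0


def test_no_bonds_raises():
    traj, d, h, a = _telegraph(100.0, k_form=1e-9, frames=300, seed=9)
    with pytest.raises(NoBondsError):
        hbond_lifetimes(traj, HBondCriterion(10.0, 1.0), d, h, a, matched=True)


# ---------------------------------------------------------------------------
# Diffusion
# ---------------------------------------------------------------------------

def test_brownian_diffusion_recovery():
    """Generator-parameter recovery: D within 10 % of the input."""
    traj = make_fixture(
        FixtureSpec("brownian", n_frames=2000, dt_fs=50.0, box=100.0, seed=4,
                    params={"n": 60, "d_1e11_m2_s": 20.0})
    )
    res = diffusion(traj, np.arange(60))
    assert res.d_1e11_m2_s == pytest.approx(20.0, rel=0.10)
    assert res.r_squared > 0.99


def test_frozen_particles_do_not_diffuse():
    traj = make_fixture(
        FixtureSpec("frozen_pair", n_frames=200, dt_fs=50.0, box=50.0,
                    params={"r_pm": 300.0})
    )
    res = diffusion(traj, np.array([0, 1]))
    assert res.d_1e11_m2_s == pytest.approx(0.0, abs=1e-9)


def test_diffusion_fit_window_validation():
    traj = make_fixture(
        FixtureSpec("brownian", n_frames=100, dt_fs=50.0, seed=5,
                    params={"n": 5, "d_1e11_m2_s": 10.0})
    )
    with pytest.raises(ValueError, match="window"):
        diffusion(traj, np.arange(5), fit_window_ps=(0.1, 1e9))
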