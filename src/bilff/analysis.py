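"""Trajectory analyses for hydrogen-bonded ionic liquids.

All public APIs speak the units the ionic-liquid literature plots:
distances in pm, angles in degrees, times in ps, diffusion coefficients
in 10⁻¹¹ m² s⁻¹, spatial densities in nm⁻³.  Internally everything is
Å/fs as elsewhere in the package.

The hydrogen-bond population operator h(t) is 1 when the H⋯acceptor
distance and the deviation from linearity both satisfy the geometric
criterion.  The intermittent lifetime integrates the normalized
autocorrelation ⟨h(0)h(t)⟩/⟨h⟩ (bond may break and re-form); the
continuous lifetime integrates the survival function of the unbroken
bond (time to the very first breakage).  Both integrals carry a
single-exponential tail extension, since lifetimes can exceed any
finite trajectory.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .dynamics import Trajectory
from .units import angstrom_to_pm, pm_to_angstrom

__all__ = [
    "RDFResult",
    "CDF2DResult",
    "SDFResult",
    "HBondCriterion",
    "LifetimeResult",
    "DiffusionResult",
    "rdf",
    "first_peak",
    "coordination_number",
    "cdf_distance_angle",
    "sdf",
    "hbond_lifetimes",
    "diffusion",
    "NoPeakError",
    "NoBondsError",
]


class NoPeakError(RuntimeError):
    """The RDF has no interior local maximum."""


class NoBondsError(RuntimeError):
    """No hydrogen bond ever satisfied the criterion; lifetimes undefined."""


def _min_image(d: np.ndarray, box: float) -> np.ndarray:
    return d - box * np.round(d / box)


def _frame_iter(traj: Trajectory):
    for f in range(traj.n_frames):
        yield traj.positions[f], float(traj.boxes[f])


# ---------------------------------------------------------------------------
# Radial distribution functions
# ---------------------------------------------------------------------------

@dataclass
class RDFResult:
    """g(r) with bin centers in pm and normalization metadata."""

    r_pm: np.ndarray
    g: np.ndarray
    n_frames: int
    n_observers: int
    rho_target: float  # targets per Å³
    bin_width_pm: float

    def __post_init__(self):
        if np.any(self.g < 0):
            raise ValueError("g(r) must be non-negative")


def rdf(
    traj: Trajectory,
    sel_a: np.ndarray,
    sel_b: np.ndarray,
    bin_width_pm: float = 1.0,
    r_max_pm: float | None = None,
    exclude_same_molecule: bool = True,
) -> RDFResult:
    """Radial distribution function between two atom selections.

    Histogram of minimum-image A⋯B distances, normalized by the ideal
    shell population 4π r² Δr ρ_B per observer and frame.  Pairs within
    the same molecule (by the topology's molecule ids) are excluded by
    default, as is self-pairing when the selections overlap.
    """
    sel_a = np.asarray(sel_a, dtype=int)
    sel_b = np.asarray(sel_b, dtype=int)
    if len(sel_a) == 0 or len(sel_b) == 0:
        raise ValueError("empty selection")
    box0 = float(traj.boxes[0])
    if r_max_pm is None:
        r_max_pm = angstrom_to_pm(box0 / 2.0)
    r_max = pm_to_angstrom(r_max_pm)
    if r_max > box0 / 2.0 + 1e-9:
        raise ValueError(
            f"r_max {r_max_pm:.0f} pm exceeds half the box edge "
            f"({angstrom_to_pm(box0 / 2):.0f} pm)"
        )
    dr = pm_to_angstrom(bin_width_pm)
    nbins = int(math.floor(r_max / dr))
    edges = np.arange(nbins + 1) * dr

    pair_mask = np.ones((len(sel_a), len(sel_b)), dtype=bool)
    pair_mask &= sel_a[:, None] != sel_b[None, :]
    if exclude_same_molecule and traj.topology is not None:
        mol = traj.topology.mol_id
        pair_mask &= mol[sel_a][:, None] != mol[sel_b][None, :]

    counts = np.zeros(nbins)
    vol_sum = 0.0
    for r, box in _frame_iter(traj):
        d = _min_image(r[sel_a][:, None, :] - r[sel_b][None, :, :], box)
        dist = np.sqrt(np.einsum("ijk,ijk->ij", d, d))[pair_mask]
        h, _ = np.histogram(dist, bins=edges)
        counts += h
        vol_sum += box**3

    vol_mean = vol_sum / traj.n_frames
    rho = len(sel_b) / vol_mean
    centers = 0.5 * (edges[:-1] + edges[1:])
    shell = 4.0 * math.pi * centers**2 * dr
    norm = traj.n_frames * len(sel_a) * rho * shell
    g = counts / norm
    return RDFResult(
        r_pm=angstrom_to_pm(centers),
        g=g,
        n_frames=traj.n_frames,
        n_observers=len(sel_a),
        rho_target=rho,
        bin_width_pm=bin_width_pm,
    )


def first_peak(
    result: RDFResult, smooth_bins: int = 3, prominence: float | None = None
) -> tuple[float, float, float]:
    """Locate the first RDF maximum and the following minimum.

    Returns ``(r_peak_pm, g_peak, r_min_pm)``.  A centered moving
    average over ``smooth_bins`` bins suppresses bin noise during the
    search and peaks need a minimum prominence (default: 10 % of the
    curve's range) so that shot noise in sparsely populated small-r
    shells is not mistaken for a hydrogen-bond contact.  The reported
    height is read from the unsmoothed curve.  Curves without an
    interior maximum raise :class:`NoPeakError`.
    """
    from scipy.signal import find_peaks

    g = result.g
    if smooth_bins > 1:
        k = np.ones(smooth_bins) / smooth_bins
        pad = smooth_bins // 2
        gpad = np.pad(g, pad, mode="edge")
        gs = np.convolve(gpad, k, mode="same")[pad : pad + len(g)]
    else:
        gs = g
    if prominence is None:
        prominence = 0.1 * (float(gs.max()) - float(gs.min()))
    peaks, _ = find_peaks(gs, prominence=max(prominence, 1e-12))
    if len(peaks) == 0:
        raise NoPeakError("RDF has no interior local maximum")
    i_peak = int(peaks[0])
    # first minimum: lowest point between this peak and the next (or end)
    i_next = int(peaks[1]) if len(peaks) > 1 else len(gs) - 1
    i_min = i_peak + int(np.argmin(gs[i_peak : i_next + 1]))
    # refine peak location on the raw curve within the smoothed window
    lo = max(i_peak - smooth_bins, 0)
    hi = min(i_peak + smooth_bins + 1, len(g))
    i_raw = lo + int(np.argmax(g[lo:hi]))
    return float(result.r_pm[i_raw]), float(g[i_raw]), float(result.r_pm[i_min])


def coordination_number(result: RDFResult, r_upper_pm: float) -> float:
    """n = 4π ρ ∫₀^r g(r) r² dr up to ``r_upper_pm`` (first RDF minimum).

    The integral is taken bin-wise (rectangle rule on the histogram
    bins, with a linear fraction of the bin containing ``r_upper``),
    which reproduces the underlying pair counts exactly.
    """
    if r_upper_pm > result.r_pm[-1] + 0.5 * result.bin_width_pm + 1e-9:
        raise ValueError("integration limit outside the RDF range")
    r = pm_to_angstrom(result.r_pm)
    dr = pm_to_angstrom(result.bin_width_pm)
    hi_edge_pm = result.r_pm + 0.5 * result.bin_width_pm
    lo_edge_pm = result.r_pm - 0.5 * result.bin_width_pm
    frac = np.clip((r_upper_pm - lo_edge_pm) / result.bin_width_pm, 0.0, 1.0)
    contrib = result.g * 4.0 * math.pi * r**2 * dr * frac
    return float(result.rho_target * contrib.sum())


# ---------------------------------------------------------------------------
# Combined distance–angle distribution
# ---------------------------------------------------------------------------

@dataclass
class CDF2DResult:
    """2D occurrence histogram over (H⋯acceptor distance, linearity angle)."""

    r_edges_pm: np.ndarray
    angle_edges_deg: np.ndarray
    counts: np.ndarray  # (n_r, n_angle)
    n_frames: int

    def __post_init__(self):
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")


def _hb_geometry(r, box, donors, hydrogens, acceptors):
    """Distances H⋯A (Å) and deviations from linearity (deg), flattened
    over (hydrogen, acceptor) pairs.  Angle 0° means donor→H→acceptor
    collinear."""
    dh = _min_image(r[hydrogens] - r[donors], box)  # donor → H
    ha = _min_image(r[acceptors][None, :, :] - r[hydrogens][:, None, :], box)
    dist = np.sqrt(np.einsum("ijk,ijk->ij", ha, ha))
    dh_n = dh / np.linalg.norm(dh, axis=1)[:, None]
    cosang = np.einsum("ik,ijk->ij", dh_n, ha) / np.maximum(dist, 1e-12)
    ang = np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0)))
    return dist, ang


def cdf_distance_angle(
    traj: Trajectory,
    donors: np.ndarray,
    hydrogens: np.ndarray,
    acceptors: np.ndarray,
    r_max_pm: float = 800.0,
    r_bin_pm: float = 5.0,
    angle_bin_deg: float = 2.0,
) -> CDF2DResult:
    """Combined distance–angle distribution of donor–H⋯acceptor triplets."""
    donors = np.asarray(donors, dtype=int)
    hydrogens = np.asarray(hydrogens, dtype=int)
    acceptors = np.asarray(acceptors, dtype=int)
    if len(donors) != len(hydrogens):
        raise ValueError("donors and hydrogens must pair up one-to-one")
    if min(len(donors), len(acceptors)) == 0:
        raise ValueError("empty selection")
    r_edges = np.arange(0.0, r_max_pm + r_bin_pm, r_bin_pm)
    a_edges = np.arange(0.0, 180.0 + angle_bin_deg, angle_bin_deg)
    counts = np.zeros((len(r_edges) - 1, len(a_edges) - 1))
    for r, box in _frame_iter(traj):
        dist, ang = _hb_geometry(r, box, donors, hydrogens, acceptors)
        h, _, _ = np.histogram2d(
            angstrom_to_pm(dist.ravel()), ang.ravel(), bins=(r_edges, a_edges)
        )
        counts += h
    return CDF2DResult(r_edges, a_edges, counts, traj.n_frames)


# ---------------------------------------------------------------------------
# Spatial distribution functions
# ---------------------------------------------------------------------------

@dataclass
class SDFResult:
    """3D particle density (nm⁻³) in a molecule-fixed orthonormal frame."""

    edges: tuple[np.ndarray, np.ndarray, np.ndarray]  # Å, frame coordinates
    density: np.ndarray  # (nx, ny, nz) nm⁻³
    n_frames: int
    n_references: int
    mean_targets_in_grid: float

    def __post_init__(self):
        if np.any(self.density < 0):
            raise ValueError("densities must be non-negative")


def sdf(
    traj: Trajectory,
    anchor_triples: np.ndarray,
    targets: np.ndarray,
    extent: float = 8.0,
    grid_res: float = 0.5,
) -> SDFResult:
    """Spatial distribution of targets around reference molecules.

    ``anchor_triples`` is (n_ref, 3): three non-collinear atoms per
    reference molecule defining the local frame (origin at the first
    anchor, x toward the second, the third fixing the xz half-plane).
    ``extent`` is the half-width of the cubic grid in Å, ``grid_res``
    the voxel edge in Å.
    """
    anchor_triples = np.asarray(anchor_triples, dtype=int)
    targets = np.asarray(targets, dtype=int)
    if anchor_triples.ndim != 2 or anchor_triples.shape[1] != 3:
        raise ValueError("anchor_triples must have shape (n_ref, 3)")
    if len(targets) == 0:
        raise ValueError("empty target selection")
    nb = int(round(2 * extent / grid_res))
    edges = [np.linspace(-extent, extent, nb + 1)] * 3
    counts = np.zeros((nb, nb, nb))
    for r, box in _frame_iter(traj):
        for a0, a1, a2 in anchor_triples:
            ex = _min_image(r[a1] - r[a0], box)
            v2 = _min_image(r[a2] - r[a0], box)
            nz = np.cross(ex, v2)
            if np.linalg.norm(nz) < 1e-8 * np.linalg.norm(ex) * np.linalg.norm(v2):
                raise ValueError(f"collinear anchors ({a0}, {a1}, {a2})")
            ex = ex / np.linalg.norm(ex)
            ez = nz / np.linalg.norm(nz)
            ey = np.cross(ez, ex)
            rel = _min_image(r[targets] - r[a0], box)
            local = rel @ np.column_stack([ex, ey, ez])
            h, _ = np.histogramdd(local, bins=edges)
            counts += h
    denom = traj.n_frames * len(anchor_triples)
    voxel_nm3 = (grid_res**3) / 1000.0  # Å³ → nm³
    density = counts / (denom * voxel_nm3)
    return SDFResult(
        edges=tuple(edges),
        density=density,
        n_frames=traj.n_frames,
        n_references=len(anchor_triples),
        mean_targets_in_grid=float(counts.sum() / denom),
    )


# ---------------------------------------------------------------------------
# Hydrogen-bond lifetimes
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class HBondCriterion:
    """Geometric hydrogen-bond criterion.

    ``r_max_pm``: maximum H⋯acceptor distance; ``alpha_max_deg``:
    maximum deviation from donor–H⋯acceptor linearity.  The defaults
    bracket the main contact peak of carboxylate⋯ring-proton bonds.
    """

    r_max_pm: float = 300.0
    alpha_max_deg: float = 30.0

    def __post_init__(self):
        if self.r_max_pm <= 0:
            raise ValueError("r_max must be positive")
        if not 0 < self.alpha_max_deg <= 90:
            raise ValueError("alpha_max must lie in (0, 90] degrees")


@dataclass
class LifetimeResult:
    """Intermittent and continuous hydrogen-bond lifetimes (ps)."""

    tau_intermittent_ps: float
    tau_continuous_ps: float
    times_ps: np.ndarray
    c_intermittent: np.ndarray
    s_continuous: np.ndarray
    n_pairs: int
    mean_population: float
    censored: bool  # bonds persisted to the end of the trajectory

    def __post_init__(self):
        if self.tau_intermittent_ps <= 0 or self.tau_continuous_ps <= 0:
            raise ValueError("lifetimes must be positive")


def indicator_series(
    traj: Trajectory,
    criterion: HBondCriterion,
    donors: np.ndarray,
    hydrogens: np.ndarray,
    acceptors: np.ndarray,
    matched: bool = False,
) -> np.ndarray:
    """Boolean (n_pairs, n_frames) hydrogen-bond population operator.

    By default every hydrogen is paired with every acceptor; with
    ``matched=True`` hydrogen i pairs only with acceptor i (useful for
    pre-assigned bonds and synthetic fixtures).
    """
    donors = np.asarray(donors, dtype=int)
    hydrogens = np.asarray(hydrogens, dtype=int)
    acceptors = np.asarray(acceptors, dtype=int)
    rmax = pm_to_angstrom(criterion.r_max_pm)
    if matched and len(hydrogens) != len(acceptors):
        raise ValueError("matched mode needs equal-length hydrogen/acceptor lists")
    n_pairs = len(hydrogens) if matched else len(hydrogens) * len(acceptors)
    out = np.zeros((n_pairs, traj.n_frames), dtype=bool)
    for f, (r, box) in enumerate(_frame_iter(traj)):
        if matched:
            dh = _min_image(r[hydrogens] - r[donors], box)
            ha = _min_image(r[acceptors] - r[hydrogens], box)
            dist = np.linalg.norm(ha, axis=1)
            cosang = np.einsum("ij,ij->i", dh, ha) / np.maximum(
                np.linalg.norm(dh, axis=1) * dist, 1e-12
            )
            ang = np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0)))
            out[:, f] = (dist <= rmax) & (ang <= criterion.alpha_max_deg)
        else:
            dist, ang = _hb_geometry(r, box, donors, hydrogens, acceptors)
            out[:, f] = ((dist <= rmax) & (ang <= criterion.alpha_max_deg)).ravel()
    return out


def _acf_binary(h: np.ndarray, batch: int = 128) -> np.ndarray:
    """⟨h(0)h(t)⟩ summed over pairs and time origins, via FFT."""
    npairs, nf = h.shape
    nfft = 1 << (2 * nf - 1).bit_length()
    acf = np.zeros(nf)
    for lo in range(0, npairs, batch):
        x = h[lo : lo + batch].astype(float)
        fx = np.fft.rfft(x, n=nfft, axis=1)
        acf += np.fft.irfft(fx * np.conj(fx), n=nfft, axis=1)[:, :nf].sum(axis=0)
    norm = np.arange(nf, 0, -1)  # origins per lag
    return acf / (npairs * norm)


def _survival(h: np.ndarray) -> np.ndarray:
    """⟨h(0)·(bond unbroken through t)⟩ over pairs and origins."""
    npairs, nf = h.shape
    num = np.zeros(nf)
    for p in range(npairs):
        row = h[p]
        # run-length encode
        idx = np.flatnonzero(np.diff(np.r_[0, row.view(np.int8), 0]))
        starts, ends = idx[::2], idx[1::2]
        for s, e in zip(starts, ends):
            L = e - s
            # a run of length L contributes (L - t) origins at lag t
            num[:L] += np.arange(L, 0, -1)
    norm = np.arange(nf, 0, -1)
    return num / (npairs * norm)


def _tail_integral(t: np.ndarray, c: np.ndarray) -> float:
    """∫c dt over the sampled window plus a single-exponential tail."""
    area = float(np.trapezoid(c, t))
    # fit ln c over the last decaying third with positive values
    n = len(t)
    lo = max(2 * n // 3, 1)
    mask = c[lo:] > 1e-6
    if mask.sum() >= 3:
        tt, cc = t[lo:][mask], np.log(c[lo:][mask])
        slope, intercept = np.polyfit(tt, cc, 1)
        if slope < 0:
            tau = -1.0 / slope
            area += math.exp(intercept + slope * t[-1]) * tau
    return area


def hbond_lifetimes(
    traj: Trajectory,
    criterion: HBondCriterion,
    donors: np.ndarray,
    hydrogens: np.ndarray,
    acceptors: np.ndarray,
    matched: bool = False,
) -> LifetimeResult:
    """Intermittent and continuous hydrogen-bond lifetimes.

    Frames must be evenly spaced.  Raises :class:`NoBondsError` if the
    criterion is never satisfied.
    """
    dt_ps = traj.timestep_fs / 1000.0
    if traj.n_frames < 3 or dt_ps <= 0:
        raise ValueError("need at least three evenly spaced frames")
    steps = np.diff(traj.times)
    if not np.allclose(steps, steps[0], rtol=1e-6):
        raise ValueError("frames must be evenly spaced")
    h = indicator_series(traj, criterion, donors, hydrogens, acceptors, matched=matched)
    mean_pop = float(h.mean())
    if not h.any():
        raise NoBondsError("criterion never satisfied; lifetimes undefined")
    c = _acf_binary(h)
    s = _survival(h)
    c = c / c[0]
    s = s / s[0]
    t = np.arange(len(c)) * dt_ps
    tau_i = _tail_integral(t, c)
    tau_c = _tail_integral(t, s)
    censored = bool(h[:, 0].any() or h[:, -1].any())
    return LifetimeResult(
        tau_intermittent_ps=tau_i,
        tau_continuous_ps=tau_c,
        times_ps=t,
        c_intermittent=c,
        s_continuous=s,
        n_pairs=h.shape[0],
        mean_population=mean_pop,
        censored=censored,
    )


# ---------------------------------------------------------------------------
# Self-diffusion
# ---------------------------------------------------------------------------

@dataclass
class DiffusionResult:
    """Einstein-relation self-diffusion from the mean-squared displacement."""

    lag_ps: np.ndarray
    msd_pm2: np.ndarray
    d_1e11_m2_s: float
    fit_window_ps: tuple[float, float]
    r_squared: float

    def __post_init__(self):
        if self.d_1e11_m2_s < -1e-9:
            raise ValueError("negative diffusion coefficient")


def _msd_fft(x: np.ndarray) -> np.ndarray:
    """MSD of one walker over all time origins (FFT algorithm)."""
    nf = len(x)
    nfft = 1 << (2 * nf - 1).bit_length()
    sq = np.einsum("ij,ij->i", x, x)
    s1 = np.zeros(nf)
    cum = 2.0 * sq.sum()
    s1[0] = cum / nf
    for m in range(1, nf):
        cum -= sq[m - 1] + sq[nf - m]
        s1[m] = cum / (nf - m)
    fx = np.fft.rfft(x, n=nfft, axis=0)
    acf = np.fft.irfft(fx * np.conj(fx), n=nfft, axis=0)[:nf].sum(axis=1)
    s2 = acf / np.arange(nf, 0, -1)
    return s1 - 2.0 * s2


def diffusion(
    traj: Trajectory,
    sel: np.ndarray,
    fit_window_ps: tuple[float, float] | None = None,
) -> DiffusionResult:
    """Self-diffusion coefficient D = slope(MSD)/6 (Einstein relation).

    Uses unwrapped coordinates, averages the MSD over all atoms in
    ``sel`` and all time origins with lag ≤ 50 % of the trajectory, and
    fits the default window 10–50 % of the maximum lag.
    """
    sel = np.asarray(sel, dtype=int)
    if len(sel) == 0:
        raise ValueError("empty selection")
    dt_ps = traj.timestep_fs / 1000.0
    msd = np.zeros(traj.n_frames)
    for a in sel:
        msd += _msd_fft(traj.positions[:, a, :])
    msd /= len(sel)
    max_lag = traj.n_frames // 2
    lag_ps = np.arange(max_lag) * dt_ps
    msd = msd[:max_lag]
    if fit_window_ps is None:
        fit_window_ps = (0.1 * lag_ps[-1], 0.5 * lag_ps[-1])
    lo, hi = fit_window_ps
    if hi > lag_ps[-1] + 1e-9 or lo < 0 or hi <= lo:
        raise ValueError("fit window outside the sampled lag range")
    mask = (lag_ps >= lo) & (lag_ps <= hi)
    if mask.sum() < 2:
        raise ValueError("fit window contains fewer than two lags")
    slope, intercept = np.polyfit(lag_ps[mask], msd[mask], 1)  # Å²/ps
    pred = slope * lag_ps[mask] + intercept
    ss_res = float(np.sum((msd[mask] - pred) ** 2))
    ss_tot = float(np.sum((msd[mask] - msd[mask].mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    d_a2_fs = slope / 6.0 / 1000.0  # Å²/ps → Å²/fs
    return DiffusionResult(
        lag_ps=lag_ps,
        msd_pm2=msd * 1e4,  # Å² → pm²
        d_1e11_m2_s=max(d_a2_fs * 1.0e6, 0.0),
        fit_window_ps=(lo, hi),
        r_squared=r2,
    )
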