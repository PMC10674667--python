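"""Deterministic synthetic trajectories with known statistical structure.

These fixtures make every analysis operation testable without running a
single MD step: an ideal gas (flat g(r)), a frozen pair (δ-peak RDF), a
telegraph-process hydrogen bond (exponential lifetimes with stated
rates), Brownian walkers (known diffusion coefficient) and a Gaussian
radial shell (known RDF peak position and height).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .dynamics import Trajectory
from .units import pm_to_angstrom

__all__ = ["FixtureSpec", "make_fixture"]

_KINDS = ("ideal_gas", "frozen_pair", "telegraph_hbond", "brownian", "gaussian_shell")


@dataclass(frozen=True)
class FixtureSpec:
    """Recipe for a synthetic trajectory.

    ``kind``-specific parameters go in ``params``:

    ideal_gas       n (particles), frames independent uniform draws
    frozen_pair     r_pm (separation)
    telegraph_hbond n_pairs, k_break_per_ps, k_form_per_ps, r_on_pm, r_off_pm
    brownian        n, d_1e11_m2_s
    gaussian_shell  n_targets, r0_pm, sigma_pm
    """

    kind: str
    n_frames: int = 100
    dt_fs: float = 50.0
    box: float = 50.0  # Å
    seed: int = 0
    params: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.kind not in _KINDS:
            raise ValueError(f"unknown fixture kind {self.kind!r}; one of {_KINDS}")
        if self.n_frames < 1 or self.dt_fs <= 0 or self.box <= 0:
            raise ValueError("invalid fixture dimensions")


def make_fixture(spec: FixtureSpec) -> Trajectory:
    """Generate the synthetic trajectory described by ``spec``.

    Identical specs (including seed) produce identical trajectories.
    """
    rng = np.random.default_rng(spec.seed)
    gen = {
        "ideal_gas": _ideal_gas,
        "frozen_pair": _frozen_pair,
        "telegraph_hbond": _telegraph,
        "brownian": _brownian,
        "gaussian_shell": _gaussian_shell,
    }[spec.kind]
    positions = gen(spec, rng)
    times = np.arange(spec.n_frames) * spec.dt_fs
    boxes = np.full(spec.n_frames, spec.box)
    return Trajectory(times=times, positions=positions, boxes=boxes)


def _ideal_gas(spec: FixtureSpec, rng) -> np.ndarray:
    n = int(spec.params.get("n", 200))
    return rng.uniform(0.0, spec.box, size=(spec.n_frames, n, 3))


def _frozen_pair(spec: FixtureSpec, rng) -> np.ndarray:
    r = pm_to_angstrom(spec.params.get("r_pm", 300.0))
    frame = np.array([[0.0, 0.0, 0.0], [r, 0.0, 0.0]]) + spec.box / 2.0
    return np.repeat(frame[None, :, :], spec.n_frames, axis=0)


def _telegraph(spec: FixtureSpec, rng) -> np.ndarray:
    """Donor–H–acceptor triplets whose acceptor hops between a bonded
    and an unbonded site following a two-state Markov (telegraph)
    process with the stated rates."""
    n_pairs = int(spec.params.get("n_pairs", 20))
    kb = float(spec.params.get("k_break_per_ps", 0.5))
    kf = float(spec.params.get("k_form_per_ps", 0.5))
    r_on = pm_to_angstrom(spec.params.get("r_on_pm", 200.0))
    r_off = pm_to_angstrom(spec.params.get("r_off_pm", 600.0))
    dt_ps = spec.dt_fs / 1000.0
    p_break = 1.0 - np.exp(-kb * dt_ps)
    p_form = 1.0 - np.exp(-kf * dt_ps)

    # each triplet lives on its own lattice site, far from the others
    spacing = spec.box / max(int(np.ceil(n_pairs ** (1.0 / 3.0))), 1)
    origins = np.array(
        [
            [
                (i % 4) * spacing,
                ((i // 4) % 4) * spacing,
                (i // 16) * spacing,
            ]
            for i in range(n_pairs)
        ]
    ) if n_pairs <= 64 else rng.uniform(0, spec.box, size=(n_pairs, 3))

    state = rng.random(n_pairs) < kf / (kf + kb)  # stationary start
    pos = np.zeros((spec.n_frames, 3 * n_pairs, 3))
    ex = np.array([1.0, 0.0, 0.0])
    for f in range(spec.n_frames):
        u = rng.random(n_pairs)
        flip_on = state & (u < p_break)
        flip_off = (~state) & (u < p_form)
        if f > 0:  # first frame keeps the stationary draw
            state = np.where(flip_on, False, np.where(flip_off, True, state))
        for p in range(n_pairs):
            d = origins[p]
            h = d + 1.0 * ex
            a = h + (r_on if state[p] else r_off) * ex
            pos[f, 3 * p] = d
            pos[f, 3 * p + 1] = h
            pos[f, 3 * p + 2] = a
    return pos


def _brownian(spec: FixtureSpec, rng) -> np.ndarray:
    n = int(spec.params.get("n", 50))
    d11 = float(spec.params.get("d_1e11_m2_s", 20.0))
    d_a2_fs = d11 / 1.0e6  # Å²/fs
    sigma = np.sqrt(2.0 * d_a2_fs * spec.dt_fs)
    steps = rng.normal(scale=sigma, size=(spec.n_frames, n, 3))
    steps[0] = 0.0
    start = rng.uniform(0.0, spec.box, size=(1, n, 3))
    return start + np.cumsum(steps, axis=0)


def _gaussian_shell(spec: FixtureSpec, rng) -> np.ndarray:
    n_t = int(spec.params.get("n_targets", 100))
    r0 = pm_to_angstrom(spec.params.get("r0_pm", 200.0))
    sg = pm_to_angstrom(spec.params.get("sigma_pm", 10.0))
    center = np.full(3, spec.box / 2.0)
    pos = np.zeros((spec.n_frames, n_t + 1, 3))
    pos[:, 0] = center
    for f in range(spec.n_frames):
        u = rng.normal(size=(n_t, 3))
        u /= np.linalg.norm(u, axis=1)[:, None]
        rr = rng.normal(loc=r0, scale=sg, size=n_t)
        pos[f, 1:] = center + u * rr[:, None]
    return pos
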