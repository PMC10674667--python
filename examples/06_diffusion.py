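"""Einstein-relation self-diffusion from the mean-squared displacement.

Brownian walkers are generated with a known diffusion coefficient;
D = slope(MSD)/6 over the 10–50 % lag window must recover it.
"""

import numpy as np

from bilff import FixtureSpec, diffusion, make_fixture

d_in = 20.0  # 1e-11 m^2/s
traj = make_fixture(
    FixtureSpec("brownian", n_frames=2000, dt_fs=50.0, box=100.0, seed=4,
                params={"n": 60, "d_1e11_m2_s": d_in})
)
res = diffusion(traj, np.arange(60))
print(f"input  D = {d_in:.1f} x 1e-11 m^2/s")
print(f"output D = {res.d_1e11_m2_s:.1f} x 1e-11 m^2/s "
      f"(fit window {res.fit_window_ps[0]:.1f}-{res.fit_window_ps[1]:.1f} ps, "
      f"R^2 = {res.r_squared:.4f})")
# Recovery within a few percent; R^2 ~ 1 confirms the MSD is linear in
# lag time, as it must be for free Brownian motion.
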