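"""Intermittent vs continuous hydrogen-bond lifetimes.

A telegraph-process fixture switches each donor-H⋯acceptor triplet
between bonded and broken states at known rates, so the continuous
lifetime (time to first breakage) has the exact answer 1/k_break.
"""

import numpy as np

from bilff import FixtureSpec, HBondCriterion, hbond_lifetimes, make_fixture

k_break = 0.5  # ps^-1  ->  continuous lifetime 2.0 ps
n_pairs = 27
traj = make_fixture(
    FixtureSpec("telegraph_hbond", n_frames=8000, dt_fs=50.0, box=200.0, seed=3,
                params={"n_pairs": n_pairs, "k_break_per_ps": k_break,
                        "k_form_per_ps": 0.5})
)
d = np.arange(n_pairs) * 3
res = hbond_lifetimes(traj, HBondCriterion(r_max_pm=300.0, alpha_max_deg=30.0),
                      d, d + 1, d + 2, matched=True)
print(f"continuous lifetime: {res.tau_continuous_ps:.2f} ps "
      f"(exact {1 / k_break:.1f} ps)")
print(f"intermittent lifetime: {res.tau_intermittent_ps:.1f} ps "
      f"(allows re-formation, so always >= continuous)")
print(f"mean bonded population: {res.mean_population:.2f}")
# The continuous estimate recovers 1/k_break within sampling error; the
# intermittent curve plateaus at the stationary population of this
# two-state fixture, so its integral is much larger — the ordering
# continuous <= intermittent holds on every input.
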