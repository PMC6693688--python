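"""Simulate a flashing fish school and watch polarization emerge.

100 fish start at rest in a 20-unit cube with default force weights
(cohesion 7, alignment 6, separation 9) and Bernoulli flashing at P = 0.5.
mSync (|mean velocity| / mean speed) rises from near 0 to ~0.9 as the school
organises.
"""

import numpy as np

import flashschool as fs

cfg = fs.SimConfig(n_fish=100, seed=1)
traj = fs.run_simulation(cfg, n_frames=900)
ks = fs.kinematics_series(traj)

for lo, hi in [(1, 50), (100, 200), (400, 500), (800, 900)]:
    seg = ks.iloc[lo:hi]
    print(
        f"frames {lo:3d}-{hi:3d}: mean speed {seg.mean_speed.mean():.2f} BL/s, "
        f"mSync {np.nanmean(seg.msync):.3f}"
    )

print()
print("mSync near 0 is an unpolarised shoal; near 1 a polarised school.")
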