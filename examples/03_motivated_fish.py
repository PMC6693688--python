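"""Two motivated leaders redirect a school of 100.

At frame 300 two fish become 'motivated': they swim straight along +x at
elevated speed, ignoring social forces. The direction correlation of the
other 98 fish against the leaders' velocity rises after the onset — the
school follows its leaders, conveyed purely by flashing.
"""

import numpy as np

import flashschool as fs
from flashschool.metrics import direction_correlation_series

sim = fs.init_school(fs.SimConfig(n_fish=100, seed=3))
onset = 300
traj = sim.run(
    800, interventions=[(onset, lambda s: s.set_motivated([0, 1], (1, 0, 0), 1.5))]
)
dc = direction_correlation_series(traj, leader_ids=[0, 1])["direction_correlation"]

pre = np.nanmean(dc[50:onset])
post = np.nanmean(dc[onset + 100 :])
print(f"direction correlation before onset: {pre:.3f}")
print(f"direction correlation after onset:  {post:.3f}")
print()
print("Values near 1 mean the school swims with the leaders; the rise after")
print("frame 300 shows the school aligning with just 2 motivated fish.")
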