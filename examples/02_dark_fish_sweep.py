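"""How many fish must flash for the school to hold together?

Dark fish (parameter D) never flash, so flash-gated social forces cannot
see them — yet they still see the flashers. Steady-state polarization stays
near the all-flashing baseline until only ~5% of fish flash, then collapses.
(Reduced scale here: 100 fish, 1200 steps, one seed per fraction.)
"""

import numpy as np

import flashschool as fs

for D in (0.0, 0.5, 0.9, 0.95, 0.99):
    sim = fs.init_school(fs.SimConfig(n_fish=100, D=D, seed=2))
    vals = []
    for t in range(1200):
        sim.step()
        if t >= 900 and np.linalg.norm(sim.velocities, axis=1).max() > 0:
            vals.append(fs.msync(sim.velocities))
    print(f"dark fraction {D:4.2f}  ->  steady-state mSync {np.mean(vals):.3f}")

print()
print("Schooling survives 95% dark fish; at 99% too few flashes remain.")
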