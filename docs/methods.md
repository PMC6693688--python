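# Methods

This note documents the models and procedures implemented in `flashschool`,
the choices made where the design was genuinely open, and what the synthetic
data can and cannot show.

## The school model

Each of `n_fish` agents carries position **r**, velocity **v** and
acceleration **a** in unbounded 3-D space, in body-length units. Agents are
updated synchronously from the previous frame's state with explicit Euler
integration at `dt = 1/30 s` (mirroring 30 fps video):

    a = f_tot          (unit mass)
    v ← clamp(v + a·dt, v_max)
    r ← r + v·dt

`f_tot` is the weighted sum of three social forces and two internal forces.
Each social force has the same structure — steer at full speed toward a
target direction, braking the current velocity:

    f_c = unit(s_c)·v_max − v      s_c = centroid(visible) − r      (cohesion)
    f_a = unit(s_a)·v_max − v      s_a = mean of visible velocities (alignment)
    f_s = unit(s_s)·v_max − v      s_s = mean of (r − r_k)/|r − r_k|² (separation)

with weights `w_c = 7`, `w_a = 6`, `w_s = 9`. The cohesion target is the
centroid of visible fish *relative to the focal fish*, which makes the force
translation-invariant (an absolute-position sum would depend on the world
origin while meaning the same thing for a school near it). When a force's
neighbour set is empty or its s-vector vanishes by symmetry, that force
contributes the zero vector rather than a spurious −v brake.

The internal forces are linear drag and a speed regulator,

    f_f = −v                         weight w_f = 1.05
    f_v = unit(v)·(v_cruise − |v|)   weight w_v = 5,   zero at rest

These functional forms are a design choice (only the weights were given):
linear drag is the simplest resistive force, and the regulator is the
simplest restoring force toward a preferred speed. `v_max = 2` body
lengths/s and `v_cruise = 0.8·v_max` are likewise package defaults chosen
once to give visibly moving, stable schools; both are configurable.

### Vision regions and flash gating

Each social force has its own spherical region of vision with blind cones:
cohesion reaches furthest (radius 10) and excludes a 90° full-apex cone
behind the fish; separation is short-range (radius 1) excluding 60° behind;
alignment, mediated by the lateral line, covers the flanks at intermediate
range (radius 3), excluding 60° cones both fore and aft. The numeric radii
preserve the stated ordering (furthest / much shorter / intermediate) but
are themselves package defaults — the source gives no numbers. A fish at
rest has no heading, so no blind cone applies to it that frame.

Crucially, a neighbour only enters a force's visible set while it is
flashing. By default this gating applies to all three forces; a flag exempts
the lateral-line forces (alignment, separation) for sensitivity analysis.

### Flashing, dark fish, leaders

In Bernoulli mode each non-dark fish flashes on a frame with probability
`P` (0.5 in nature, matching the ~50% duty cycle). In square-wave mode each
fish follows a deterministic on/off schedule (defaults 0.166 s / 0.168 s)
with a per-fish random integer phase assigned at initialisation — the phase
convention is ours; distinct phases match the asynchronous flashing seen in
recordings. Each fish draws one uniform number R at initialisation and is
dark while `R < D`; dark fish never flash and are invisible to flash-gated
forces, but still see and react to flashing fish. Because R is kept, a
mid-run change of D re-evaluates darkness monotonically (fish "light up" as
D decreases), and under constant D the flag is fixed for the agent's
lifetime.

Motivated leaders are flagged fish that thereafter move in a fixed
direction at `min(speed_factor·v_cruise, v_max)`, ignoring social forces.
They must not be dark — they lead by being seen.

### Initialisation, determinism, degenerate inputs

Fish start at rest, uniformly placed in a cube of side 20 centred on the
origin. One seeded generator drives all randomness with per-agent draws in
fixed order, so a (config, seed, interventions) triple reproduces a
trajectory bitwise. Coincident fish make the separation force undefined and
raise a degenerate-geometry error; non-finite states raise a numeric
failure rather than propagating NaNs.

## Synchrony metrics

`mSync` of a frame is |mean velocity| / mean speed — the polarization order
parameter: 0 for an unpolarised shoal, 1 for a perfectly aligned school. It
is undefined when every fish is at rest (raised as an error at the function
level; marked missing in per-frame series). It is dimension-agnostic: 2-D
for image-plane tracks, 3-D for the model, same formula. Track velocities
are forward differences of centroids between consecutive frames (px/s);
only fish tracked in both frames contribute.

The direction correlation against a leader velocity v_L is
Σ⟨v_L, v_i⟩ / (|v_L| Σ|v_i|), the leaders' average velocity standing in for
v_L when there are several. The formula admits negative values (fish
anti-aligned with the leader), so the implementation reports it unclamped
on [−1, 1] even though it is sometimes described as a [0, 1] quantity.

The random-motion null assigns every fish-frame an independent uniformly
random direction and a speed resampled from observed speeds; frame-wise
mSync then scales like n^(−1/2).

The Wilcoxon rank-sum test reports the midrank sum of the smaller sample.
With both samples of size ≤ 8 the two-sided p-value is computed by exact
enumeration of all rank splits (ties handled by midranks); otherwise a
normal approximation with tie-corrected variance and a 0.5 continuity
correction is used. The two branches agree within 0.02 at n = 8 vs 8.

### A model property that does not match expectations

One qualitative claim — that frames with higher mean speed are more
polarised — does **not** hold in this model as specified. Because every
printed social force carries a −v braking term, a dense polarised school is
braked by all three forces and cruises slowly (~0.74 units/s at defaults),
while incoherent episodes are fast centripetal pursuit of the centroid
(~1.3–1.7 units/s). The measured speed–mSync correlation is negative
(−0.5 to −0.98) in every run family we tried: defaults from rest,
time-varying D ramps, motivated-fish onsets, and v_cruise ∈ {0, 0.4, 1.6}.
The corresponding acceptance check is left failing by design; the remaining
dynamics (dark-fish robustness, leader following) do reproduce.

## Video pipeline

**FPN estimation.** At light levels where a flash uses ≤1% of the 16-bit
range, fixed-pattern noise (the per-pixel additive sensor offset) dominates.
Because flashing fish are sparse, each pixel sees a dark scene most of the
time, so the per-pixel temporal mean of the whole recording estimates the
FPN; it is subtracted from every frame and clipped at zero. On synthetic
stacks the spatial-mean bias from the flashes is below one count.

**Detection.** Corrected frames are thresholded at median + 5·(robust sd),
where the robust sd is the upper-quantile spread q84.13 − median — equal to
one sigma for Gaussian noise and, unlike the MAD, still valid when
zero-clipping puts half the pixels exactly at 0. An absolute threshold can
be supplied instead. The binary image is opened with a 3×3 cross to remove
isolated noisy pixels (note the cross clips square corners: a solid 5×5
block keeps 21 of 25 pixels — irrelevant for round blobs far above the area
cut). Connected components (8-connectivity) with area strictly greater than
20 px yield unweighted centroids, areas and peak corrected intensities.

**Linking.** Globally greedy nearest-distance matching: at each frame the
closest (open track, detection) pair within the allowed radius links first,
each used once; unmatched detections open tracks; tracks unseen longer than
`max_gap` frames close. A track last seen g+1 frames ago may move up to
`max_radius·(g+1)`. `max_gap = 0` is the strict reading (non-flashing fish
are not trackable); bridging the ~5-frame off-phase (`max_gap ≈ 7` at
30 fps) is used for flash-kinetics work. `max_radius` must be supplied —
there is no defensible universal constant; on the synthetic scenes 2 px
covers the default 0.3 px/frame motion across bridged gaps.

**Flash kinetics.** A track's per-frame peak intensity (missing frames in
bridged gaps count as off) is binarised at half the track's 95th-percentile
intensity — robust to single hot frames; an absolute level is accepted.
Runs are length-encoded; the leading and trailing runs are discarded as
truncated. A flash is an interior on-run and its following off-run; duty
cycle is on/(on+off) and the blink rate is flashes per second of
complete-cycle time (equal to 1/mean cycle length). The spectrum is the
boxcar periodogram of the mean-removed binary state, averaged across fish
(shorter records zero-padded to the longest — this rescales per-train power
but not peak position), with the peak sought above 0.5 Hz; constant trains
have no power there and are rejected.

## Synthetic scenes

The generator emulates the character of the described recordings: 16-bit
frames at 30 fps; per-pixel FPN ~ Normal(100, 5²) counts truncated at 0;
isotropic Gaussian blobs (σ = 2 px) of peak 600 counts (≤1% of 65535);
Gaussian read noise (sd 2 counts); square-wave flashing at 0.166 s on /
0.168 s off with per-fish phases; and either constant-velocity,
random-walk, or simulator-projected motion. Ground truth (positions, on/off
states, the FPN map) is returned with every render.

What it does not emulate: optics (point-spread, vignetting, rolling
shutter), Poisson photon statistics (Gaussian read noise is adequate at 1%
of range; blob brightness varies only through an optional per-fish factor
standing in for depth), occlusions, fish shape or wake. Passing recovery
tests therefore demonstrates the correctness of the algorithms under the
stated noise model, not performance on ocean footage; the real recordings'
background level, noise and blob sizes were never published, so the
defaults are declared fixtures, not estimates.

## Starlight attenuation

Beer–Lambert transmittance T = exp(−k·z) with defaults k = 0.0562 m⁻¹
(clear ocean water, 550 nm) and surface starlight 1.46×10⁻¹⁰ W/cm²
(0.0002 lux). `irradiance_at_depth(surface, T)` takes T as an explicit
argument so tabulated transmittance fractions from other sources can be
combined with a surface value directly; note that the commonly tabulated
fractions at 20/30/100 m (7.5%, 2.1%, 0.15%) are not mutually consistent
with a single exponential at k = 0.0562 m⁻¹, which gives 32.5%, 18.5% and
0.36% — the function computes the strict exponential, and products with
tabulated fractions reproduce the tabulated irradiances.

## Problem sizes used in checks

The headline recomputation (`scripts/acceptance.py`) uses: a dark-fraction
sweep of 200 fish × 2000 steps at 21 fractions × 5 seeds with mSync
averaged over the final 500 steps; 13 flash trains of 10 s at 30 fps;
a 300-frame 256×256 stack for FPN recovery; and a 600-frame (20 s) 5-fish
scene for end-to-end on-duration recovery. The test suite runs the same
checks at reduced seed counts and durations. A 200-fish run of 2000 steps
takes a few seconds on one core; the full sweep a few minutes.
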