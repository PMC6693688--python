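"""Full low-light video pipeline on a ground-truthed synthetic recording.

Renders 20 s of 16-bit video: 5 moving fish whose Gaussian flashes use <1%
of the dynamic range over fixed-pattern noise ~ Normal(100, 5²), flashing
0.166 s on / 0.168 s off. Then: FPN estimation by temporal averaging,
subtraction, robust thresholding, blob detection, greedy linking, and flash
segmentation — recovering the flash kinetics that were rendered in.
"""

import flashschool as fs
from flashschool.kinetics import flash_spectrum, flash_stats
from flashschool.linking import LinkConfig, build_tracks

stack, truth = fs.make_flash_scene(fs.SceneConfig(seed=7), n_frames=600)
print(f"rendered {stack.n_frames} frames of {stack.shape} at {stack.fps} fps")

fpn = fs.estimate_fpn(stack)
print(f"estimated FPN: spatial mean {fpn.mean():.2f} counts (true map {truth.fpn.mean():.2f})")

detections = fs.detect_stack(stack)
tracks = build_tracks(detections, LinkConfig(max_radius=2.0, max_gap=7))
print(f"{len(detections)} detections linked into {len(tracks)} tracks (5 fish rendered)")

trains = [fs.segment_flashes(fs.intensity_series(t), stack.fps) for t in tracks]
stats = flash_stats(trains)
spectrum = flash_spectrum(trains, stack.fps)
print(f"mean on  {stats.mean_on_s:.4f} s   (rendered 0.166 s)")
print(f"mean off {stats.mean_off_s:.4f} s   (rendered 0.168 s)")
print(f"duty cycle {100 * stats.duty_cycles.mean():.1f}%  over {stats.n_flashes} flashes")
print(f"blink rate {stats.blink_rate_hz:.2f} Hz, spectrum peak {spectrum.peak_frequency_hz:.2f} Hz")
print()
print("On/off durations come back within one frame period (1/30 s) of truth.")
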