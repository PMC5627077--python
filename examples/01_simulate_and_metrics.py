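"""Simulate one shoal trial and compute the three response variables.

Four fish swim for one minute in the annular channel (inner radius
135 mm, outer 330 mm) at 25 fps; we then measure mean group polarization,
each fish's median speed and its mean nearest-neighbour distance.
"""

import numpy as np

from shoalkit import (
    SimConfig,
    compute_kinematics,
    metric_records,
    simulate_trial,
)

trial = simulate_trial(SimConfig(duration=60.0, seed=1), trial_id="demo", treatment="familiar")
kin = compute_kinematics(trial)
group, individuals = metric_records(trial, kin, period="period1")

print(f"frames: {trial.n_frames}, tracking gaps: {trial.gap_mask.sum()}")
print(f"mean polarization: {group.mean_polarization:.3f}  (1 = perfectly aligned, ~0.45 = random for n=4)")
for rec in individuals:
    print(
        f"fish {rec.fish_id}: median speed {rec.median_speed:6.1f} mm/s, "
        f"mean NND {rec.mean_nnd:5.1f} mm"
    )
print("Speeds near 60 mm/s and NNDs well inside the 195 mm channel indicate a cohesive, moving shoal.")
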