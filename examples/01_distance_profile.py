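"""Profile a Venus-fly-trap-domain lobe distance on a synthetic trajectory.

Generates the packaged variant-inactive VFTD profile (two Cα lobes held at
a 37.5 Å mean separation with 0.5 Å rigid-body jitter over 250 frames),
measures the Gaussian-filtered centre-of-mass distance between the lobes,
and converts it to a closure index: 0 = open/inactive-like reference
(41.5 Å), 1 = closed/active-like reference (34.5 Å).
"""

import numpy as np

import gpcrvar as g

traj = g.generate_trajectory(g.trajectory_profile("R212Q-inactive-VFTD"))
series = g.com_distance_series(
    traj.frames, traj.library["GB1_LBupper"], traj.library["GB1_LBlower"]
)
closure = g.vftd_closure_index(series)

print(f"frames analysed:        {series.n_frames}")
print(f"raw mean distance:      {np.mean(series.raw):.2f} Å")
print(f"filtered mean distance: {series.mean_filtered:.2f} ± {series.sd_filtered:.2f} Å")
print(f"closure index:          {closure:.2f}")
print()
print("A closure index near 0.57 says the lobes sit noticeably closer to the")
print("active (closed) reference than the wild-type inactive state does —")
print("the geometric signature of increased constitutive activity.")
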