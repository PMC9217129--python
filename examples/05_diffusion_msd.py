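"""Recover a diffusion coefficient from single-particle tracks by MSD.

Simulates Brownian tracks at a known D, applies the segment-averaged MSD
procedure (5-frame segments, >=15-frame filter, through-origin 4Dt fit),
and compares the recovered ensemble mean with the ground truth.
"""

import numpy as np

from cotrack import SimulationParams, fit_ensemble, simulate_trajectories, \
    truth_to_tracks
from cotrack.tracks import REFERENCE

d_true = 0.18  # um^2/s
params = SimulationParams(
    diffusion_coefficient=d_true, n_particles=500, n_frames=100,
    bleach_probability=0.0, p1=1.0, p2=0.0,
    oligomer_size_distribution={1: 1.0},
    field_size=(2000.0, 2000.0), seed=3)
tracks = truth_to_tracks(simulate_trajectories(params), REFERENCE,
                         localization_sigma=0.0)

table = fit_ensemble(tracks, frame_interval=0.06)
fitted = table[~table.excluded]
print(f"{len(fitted)} tracks fitted; mean D = {fitted.d_fit.mean():.4f} "
      f"um^2/s (truth {d_true}), sd = {fitted.d_fit.std():.4f}")

# localization noise biases the through-origin fit upward
noisy = truth_to_tracks(simulate_trajectories(params), REFERENCE,
                        localization_sigma=0.03)
tn = fit_ensemble(noisy, frame_interval=0.06)
print(f"with 30 nm localization error: mean D = "
      f"{tn[~tn.excluded].d_fit.mean():.4f} um^2/s")
print("-> the offset that static error adds to the MSD is absorbed into "
      "the slope by the through-origin fit, inflating D; per-track spread "
      "is large because each track contributes only ~19 segments")
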