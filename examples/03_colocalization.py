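"""Classify co-diffusing two-color trajectory pairs with the sliding window.

Compares a dimer population (some particles carry both dyes and co-diffuse)
with a monomer population (independent tracks): the "% correlated
trajectories" statistic separates them by an order of magnitude.
"""

import numpy as np

from cotrack import (ColocParams, SimulationParams, find_colocalizers,
                     simulate_trajectories, truth_to_tracks)
from cotrack.tracks import REFERENCE, PARTNER

coloc = ColocParams(window_length=12, pcc_threshold=0.8)

for name, dist, n in [("dimers", {2: 1.0}, 1500),
                      ("monomers", {1: 1.0}, 3000)]:
    params = SimulationParams(
        oligomer_size_distribution=dist, n_particles=n, n_frames=100,
        seed=11, bleach_probability=0.0, field_size=(500.0, 500.0))
    truth = simulate_trajectories(params)
    ref = truth_to_tracks(truth, REFERENCE)
    par = truth_to_tracks(truth, PARTNER)
    res, _ = find_colocalizers(ref, par, coloc,
                               rng=np.random.default_rng(0))
    lo, hi = res.ci95
    print(f"{name:9s}: {res.n_ref_correlated:4d}/{res.n_ref_total:4d} "
          f"correlated = {res.percent_correlated:5.2f}% "
          f"(95% CI {lo:.2f}-{hi:.2f}), F_obs = {res.f_obs:.4f}")

print("-> at P_L = 0.14 ideal dimers give F_obs near "
      "P_L/(2(1-P_L)) = 0.0814, while independent monomers sit at the "
      "false-positive floor (< 2%)")
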