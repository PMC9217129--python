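"""Folder-per-condition batch run with permutation tests.

Simulates two experimental conditions (monomeric control vs dimer),
writes per-cell track files the way a tracking step would, and runs the
configuration-driven batch analysis end to end.
"""

import tempfile
from pathlib import Path

from cotrack import (AnalysisConfig, SimulationParams, run_batch,
                     simulate_trajectories, truth_to_tracks,
                     write_tracks_csv)
from cotrack.tracks import REFERENCE, PARTNER

root = Path(tempfile.mkdtemp(prefix="cotrack_batch_"))
for cond, dist, n, seed0 in [("1x_control", {1: 1.0}, 150, 100),
                             ("2x_dimer", {2: 1.0}, 80, 200)]:
    folder = root / cond
    folder.mkdir()
    for cell in range(5):
        p = SimulationParams(oligomer_size_distribution=dist, n_particles=n,
                             n_frames=100, seed=seed0 + cell,
                             field_size=(25.0, 25.0))
        truth = simulate_trajectories(p)
        write_tracks_csv(folder / f"cell{cell}_reference.csv",
                         truth_to_tracks(truth, REFERENCE))
        write_tracks_csv(folder / f"cell{cell}_partner.csv",
                         truth_to_tracks(truth, PARTNER))

config = AnalysisConfig(conditions={c: str(root / c)
                                    for c in ("1x_control", "2x_dimer")},
                        seed=1, n_bootstrap=2000, n_permutation=9999)
report = run_batch(config)
report.write(root / "report")

print(report.cells[["condition", "cell_id", "n_total", "n_corr",
                    "percent"]].to_string(index=False))
print()
print(report.condition_summaries.to_string(index=False))
print()
cmp_ = report.comparisons.iloc[0]
print(f"permutation p = {cmp_.p_permutation:.4g}, "
      f"t-test p = {cmp_.p_ttest:.4g}")
print(f"-> the dimer condition shows a higher percent of correlated "
      f"trajectories per cell; full report written to {root/'report'}")
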