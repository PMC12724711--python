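"""Compare synchrony trajectories between two treatment groups.

Two groups of camera-imaged explant stacks differ only in how fast their
per-pixel phase dispersion collapses (emulating treatment-accelerated vs
control synchronization).  Each stack runs through minimization, 2-frame
averaging, background subtraction, pixel extraction and wavelet phase; the
groups are summarized as mean +/- SEM Kuramoto trajectories.
"""

import numpy as np

from lucisync.synth import coupling_compare_study
from lucisync.pipeline import AnalysisConfig, run_treatment_compare

study = coupling_compare_study(seed=0, n_per_group=3)
groups = {g: {s: sim.stack for s, sim in members.items()}
          for g, members in study.items()}
config = AnalysisConfig(gaussian_sigma=0.0, average_n=2, seed=0)
report = run_treatment_compare(groups, config)

grid = np.asarray(report.group_sync["fast"]["grid"])
for name in ("fast", "slow"):
    rec = report.group_sync[name]
    for hour in (36.0, 60.0, 80.0):
        i = int(np.argmin(np.abs(grid - hour)))
        print(f"{name} group: r({hour:.0f} h) = {rec['mean'][i]:.2f} "
              f"+/- {rec['sem'][i]:.2f} (n={rec['n']})")
print("-> the fast-coupling group reaches high synchrony a day or more "
      "before the slow group, the signature of accelerated entrainment.")
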