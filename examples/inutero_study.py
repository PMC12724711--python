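"""A small end-to-end in utero imaging study.

Simulates dams imaged on the mixed gestational schedule (every 12 h, then
every 4 h) with ~100-fold luminescence growth and circadian modulation
emerging late in gestation; one dam is arrhythmic by construction.  The
study runner classifies each dam (18-30 h period, p < 0.05), excludes
non-circadian ones, and summarizes daily peak-time agreement across dams
as the Rayleigh statistic R.
"""

import numpy as np

from lucisync.synth import gestation_study
from lucisync.pipeline import AnalysisConfig, run_inutero

sims = gestation_study(seed=0, n_circadian=3, n_arrhythmic=1)
stacks = {dam: s.stack for dam, s in sims.items()}
report = run_inutero(stacks, AnalysisConfig(gaussian_sigma=0.0, seed=0))

for dam, rec in report.rhythm.items():
    print(f"{dam}: period {rec['period']:.2f} h, p={rec['p_value']:.3g}, "
          f"circadian={rec['is_circadian']}")
print("excluded:", [f"{d} ({r.split(':')[0]})" for d, r in report.exclusions])
for day in sorted(report.daily_rayleigh):
    c = report.daily_rayleigh[day]
    print(f"{day}: inter-pregnancy R = {c.R:.3f}, mean peak ZT {c.mean_direction:.1f}")
print("-> R near 1 on the last days means the dams' fetoplacental signals "
      "peak at the same time of day; the arrhythmic dam is excluded by the "
      "stated classification rule, not by hand.")
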