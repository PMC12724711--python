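"""Detect a developing circadian rhythm in a dual-PMT luminometry trace.

Simulates a 6-day counts-per-minute recording (two photomultiplier sensors,
dark counts collected 1 min every 15 min, exponential baseline growth,
circadian modulation switching on around hour 24 with peaks near dusk),
then runs the full trace pipeline: dark subtraction -> 24 h running-mean
detrend -> meta rhythm test -> daily peak extraction.
"""

import numpy as np

import lucisync as ls

truth = ls.OscillatorTruth("dam1", period=24.0, peak_time=13.0,
                           amplitude_rel=0.3, onset_time=24.0)
scenario = ls.SimScenario(seed=1, duration=144.0, sampling_interval=1.0,
                          baseline0=500.0, growth_rate=np.log(20) / 144.0,
                          noise_model="poisson", units=[truth],
                          dark_schedule=(15.0, 1.0))
sim = ls.simulate_pmt_trace(scenario)

clean = ls.subtract_dark_and_sum(sim.sensor_a, sim.sensor_b)
detrended = ls.running_mean_detrend(clean)
meta = ls.meta_rhythm_test(detrended)
peaks = ls.daily_peak_times(detrended)

print(f"integrated period: {meta.period:.2f} h  (truth 24.0)")
print(f"combined p-value:  {meta.p_value:.3g}")
print(f"circadian (18-30 h, p<0.05): {ls.classify_circadian(meta)}")
print("daily peak times (ZT):", np.round(peaks.times, 2))
print("-> peaks should sit near ZT 13 (programmed dusk peak) once the "
      "rhythm has ramped up; early days are noise-dominated.")
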