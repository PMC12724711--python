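"""Fit a damped cosine to a tissue-explant luminometry trace.

Simulates a 5-day explant recording in 10-min bins (damped cosine over a
slowly decaying baseline, Gaussian noise), fits
mesor + A*exp(-d*t)*cos(2*pi*(t-t0)/T) on days 2-5, and reports the
classification used for explants: circadian iff 18 <= T <= 30 h and the
fit-data correlation exceeds 0.70.
"""

import lucisync as ls

truth = ls.OscillatorTruth("uterus", period=24.5, peak_time=11.0,
                           amplitude_rel=0.3, damping_rate=0.005)
scenario = ls.SimScenario(seed=2, duration=120.0, sampling_interval=10.0,
                          baseline0=1000.0, growth_rate=-0.002,
                          noise_model="gaussian", gaussian_sigma=30.0)
trace = ls.simulate_explant_trace(truth, scenario)

fit = ls.fit_damped_cosine(trace)
amp = ls.peak_trough_amplitude(trace)

print(f"period:        {fit.period:.2f} h   (truth 24.50)")
print(f"peak phase:    ZT {fit.peak_phase_zt:.2f}")
print(f"amplitude:     {fit.amplitude:.0f} counts (truth 300 at t=0)")
print(f"damping rate:  {fit.damping_rate:.4f} /h (truth 0.0050)")
print(f"goodness r:    {fit.goodness:.3f}")
print(f"circadian:     {fit.is_circadian}")
print(f"peak-trough amplitude, 36-60 h window: {amp:.0f} counts")
print("-> the r>0.70 correlation rule accepts this clean rhythm; the "
      "36-60 h peak-trough value quantifies its early-recording swing.")
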