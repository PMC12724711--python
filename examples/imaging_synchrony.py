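"""Pixel-level synchronization in a bioluminescence image stack.

Simulates a 6-day hourly image stack in which one tissue region oscillates
with per-pixel peak-time scatter (SD 6 h) that collapses mid-record — the
synchronization scenario — plus cosmic-ray spikes and camera background.
The image pipeline (adjacent-frame minimization, background subtraction,
pixel extraction, sinc detrend/smooth, wavelet phase) feeds the Kuramoto
order parameter across pixels.
"""

import numpy as np

import lucisync as ls

truth = ls.OscillatorTruth("tissue", period=24.0, peak_time=13.0,
                           amplitude_rel=0.4)
scenario = ls.SimScenario(seed=3, duration=144.0, sampling_interval=60.0,
                          baseline0=200.0, noise_model="poisson",
                          units=[truth], spike_rate=0.3,
                          phase_dispersion_start=6.0, phase_dispersion_end=0.0,
                          dispersion_profile="logistic",
                          dispersion_midpoint=0.6, dispersion_width=8.0)
geometry = ls.StackGeometry(shape=(20, 20), unit_centers=[(10.0, 10.0)],
                            unit_radius=6.0, background_level=10.0)
sim = ls.simulate_image_stack(scenario, geometry)

stack = ls.adjacent_frame_minimize(sim.stack)
pixels = ls.extract_pixel_series(ls.subtract_background(stack),
                                 gaussian_sigma=0.0)
pm = ls.phases_from_pixels(pixels, seed=0)
sync = ls.sync_timecourse(pm)
smooth = ls.smooth_series(sync.r, sync.grid, window=2.0)

valid = np.isfinite(smooth)
t, r = sync.grid[valid], smooth[valid]
print(f"pixels analyzed: {pm.n_units} (of {pixels.n_pixels} in the ROI)")
print(f"cosmic-ray spikes injected and filtered: {len(sim.spikes)}")
print(f"sync index at t={t[0]:.0f} h: {r[0]:.2f}")
print(f"sync index at t={t[len(t)//2]:.0f} h: {r[len(t)//2]:.2f}")
print(f"sync index at t={t[-1]:.0f} h: {r[-1]:.2f}")
print("-> the Kuramoto order parameter climbs from dispersed (~0.3) to "
      "near-total synchrony (>0.95) as the programmed per-pixel phase "
      "scatter collapses.")
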