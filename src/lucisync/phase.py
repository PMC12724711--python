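"""Instantaneous phase via the continuous wavelet transform, and the
Kuramoto synchrony index.

Phase is read along the maximal-power ridge of a complex Morlet transform
over the circadian period band; phase 0 coincides with the waveform
maximum, so wavelet phases are directly comparable with peak times.  The
intra-pregnancy synchrony index is the first-order Kuramoto order
parameter r = |mean(exp(i*theta))| across pixels at each time point.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pywt

from .images import PixelSeriesMatrix
from .prep import InsufficientDataError, sinc_detrend_smooth

__all__ = ["PhaseMatrix", "SyncSeries", "wavelet_phase", "kuramoto_order",
           "sync_timecourse", "phases_from_pixels", "smooth_series"]

#: complex Morlet bandwidth (time-frequency resolution trade-off)
MORLET_BANDWIDTH = 2.0
#: edge margin of validity, in multiples of the local ridge period
#: (~ the sqrt(2)*scale e-folding distance of a Morlet wavelet)
COI_PERIODS = 1.37


@dataclass
class PhaseMatrix:
    """Per-unit instantaneous phase on one shared uniform grid."""

    grid: np.ndarray                 # hours
    phases: np.ndarray               # (n_units, n_times), radians in (-pi, pi]
    ridge_period: np.ndarray         # (n_units, n_times), hours
    coi_mask: np.ndarray             # (n_units, n_times) bool; True = valid
    ridge_power: np.ndarray | None = None
    unit_ids: list | None = None

    @property
    def n_units(self) -> int:
        return self.phases.shape[0]


@dataclass
class SyncSeries:
    """Time course of the Kuramoto order parameter across units."""

    grid: np.ndarray
    r: np.ndarray          # order parameter in [0, 1]; NaN where n_units < 2
    n_units: np.ndarray    # contributing units per time point
    meta: dict = field(default_factory=dict)


def _wrap(ph: np.ndarray) -> np.ndarray:
    return -(np.mod(-ph + np.pi, 2 * np.pi) - np.pi)   # (-pi, pi]


def wavelet_phase(series: np.ndarray, dt: float,
                  period_band: tuple[float, float] = (18.0, 30.0),
                  n_scales: int = 60,
                  bandwidth: float = MORLET_BANDWIDTH,
                  ) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Instantaneous phase of one uniformly sampled series.

    A complex Morlet transform is evaluated on ``n_scales`` periods
    spanning ``period_band``; per time point the ridge is the scale of
    maximal power and the phase is the transform's angle there.  Returns
    ``(phase, ridge_period, coi_mask, ridge_power)``; ``coi_mask`` is
    False within one local period of either record edge, where the
    wavelet support extends beyond the data.
    """
    series = np.asarray(series, dtype=float)
    n = len(series)
    if (n - 1) * dt < 2 * period_band[1]:
        raise InsufficientDataError(
            f"span {(n - 1) * dt:.1f} h < twice the max period {period_band[1]} h")
    periods = np.linspace(period_band[0], period_band[1], n_scales)
    wavelet = pywt.ContinuousWavelet(f"cmor{bandwidth}-1.0")
    scales = periods / dt       # center frequency 1.0 => scale = period / dt
    coef, _ = pywt.cwt(series - series.mean(), scales, wavelet, sampling_period=dt)
    power = np.abs(coef) ** 2
    ridge = np.argmax(power, axis=0)
    cols = np.arange(n)
    phase = _wrap(np.angle(coef[ridge, cols]))
    ridge_period = periods[ridge]
    ridge_power = power[ridge, cols]
    t = cols * dt
    margin = COI_PERIODS * ridge_period
    coi = (t >= margin) & ((n - 1) * dt - t >= margin)
    return phase, ridge_period, coi, ridge_power


def kuramoto_order(phases_at_t) -> float:
    """First-order Kuramoto order parameter: |mean of unit phasors|.

    1 for identical phases, 0 for balanced (e.g. antipodal or uniformly
    spread) phase sets.  Undefined for fewer than two phases.
    """
    ph = np.asarray(phases_at_t, dtype=float)
    if ph.size < 2:
        raise ValueError("Kuramoto order parameter needs >= 2 phases")
    return float(np.abs(np.exp(1j * ph).mean()))


def phases_from_pixels(pixels: PixelSeriesMatrix,
                       period_band: tuple[float, float] = (18.0, 30.0),
                       detrend_cutoff: float = 48.0,
                       smooth_cutoff: float = 4.0,
                       resample_dt: float = 1.0,
                       power_gate: bool = True,
                       gate_percentile: float = 95.0,
                       gate_null_reps: int = 50,
                       seed: int = 0) -> PhaseMatrix:
    """Sinc-detrend/smooth every pixel series, resample to a uniform grid
    when needed, and extract wavelet phases.

    Pixels whose median ridge power does not exceed the given percentile
    of a variance-matched white-noise null are excluded from the matrix
    (quality gate against pure-noise pixels diluting the sync index);
    excluded pixel ids are reported in the matrix's ``unit_ids`` gaps.
    """
    grid_in = pixels.grid
    dts = np.diff(grid_in)
    uniform = np.allclose(dts, dts[0], rtol=1e-3, atol=1e-6)
    if uniform and dts[0] <= resample_dt * 1.001:
        grid = grid_in.astype(float)
        series = pixels.series
    else:
        # linear interpolation to a uniform grid (logged processing step)
        grid = np.arange(grid_in[0], grid_in[-1] + resample_dt / 2, resample_dt)
        series = np.stack([np.interp(grid, grid_in, s) for s in pixels.series])
    dt = float(grid[1] - grid[0])
    proc = np.stack([sinc_detrend_smooth(s, detrend_cutoff, smooth_cutoff, dt)
                     for s in series])

    phases, ridge_p, coi, power, kept = [], [], [], [], []
    null_q = None
    if power_gate:
        rng = np.random.default_rng(seed)
        null_meds = []
        for _ in range(gate_null_reps):
            wn = rng.normal(0.0, 1.0, series.shape[1])
            wn = sinc_detrend_smooth(wn, detrend_cutoff, smooth_cutoff, dt)
            wn = wn / max(np.std(wn), 1e-12)
            _, _, c, pw = wavelet_phase(wn, dt, period_band)
            null_meds.append(np.median(pw[c]) if c.any() else np.median(pw))
        null_q = float(np.percentile(null_meds, gate_percentile))
    for i, s in enumerate(proc):
        ph, rp, c, pw = wavelet_phase(s, dt, period_band)
        if power_gate:
            var = float(np.var(s))
            med = np.median(pw[c]) if c.any() else np.median(pw)
            if var == 0 or med < null_q * var:
                continue
        kept.append(tuple(pixels.pixel_ids[i]))
        phases.append(ph)
        ridge_p.append(rp)
        coi.append(c)
        power.append(pw)
    if not phases:
        raise InsufficientDataError("no pixel passed the wavelet power gate")
    return PhaseMatrix(grid, np.stack(phases), np.stack(ridge_p),
                       np.stack(coi), np.stack(power), kept)


def sync_timecourse(pm: PhaseMatrix, min_units: int = 2,
                    min_fraction: float = 0.9) -> SyncSeries:
    """Kuramoto order parameter per time point over valid (inside-COI)
    unit phases.

    Time points where fewer than ``min_units`` units — or less than
    ``min_fraction`` of all units — are inside the cone of influence are
    reported as NaN: near the record edges the COI admits only the units
    with the shortest ridge periods, and an order parameter over that
    biased sliver is not comparable with the rest of the series.
    """
    n_t = len(pm.grid)
    r = np.full(n_t, np.nan)
    n_units = pm.coi_mask.sum(axis=0)
    threshold = max(min_units, int(np.ceil(min_fraction * pm.n_units)))
    for j in range(n_t):
        if n_units[j] >= threshold:
            r[j] = kuramoto_order(pm.phases[pm.coi_mask[:, j], j])
    return SyncSeries(pm.grid.copy(), r, n_units.astype(int))


def smooth_series(values: np.ndarray, grid: np.ndarray, window: float = 2.0
                  ) -> np.ndarray:
    """Centred moving average over a time window, NaN-aware (for sync
    trajectories; NaN samples are ignored inside the window)."""
    values = np.asarray(values, dtype=float)
    out = np.full_like(values, np.nan)
    for j, t in enumerate(grid):
        sel = np.abs(grid - t) <= window / 2.0
        v = values[sel]
        v = v[np.isfinite(v)]
        if v.size:
            out[j] = v.mean()
    return out
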