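"""Preprocessing applied to traces and image stacks before rhythm statistics.

The image pipeline order is: adjacent-frame minimization -> frame averaging
-> background subtraction (ROI flux or per-pixel) -> spatial Gaussian ->
per-pixel detrend/smooth.  Trace preprocessing is dark-count subtraction
(dual-sensor PMT) and running-mean or windowed-sinc detrending.
"""

from __future__ import annotations

import numpy as np

from .traces import BioluminescenceTrace
from .images import ImageStack, PixelSeriesMatrix

__all__ = [
    "subtract_dark_and_sum", "running_mean_detrend", "sinc_lowpass",
    "sinc_detrend_smooth", "adjacent_frame_minimize", "frame_average",
    "subtract_background", "roi_flux", "extract_pixel_series",
    "InsufficientDataError",
]


class InsufficientDataError(ValueError):
    pass


def subtract_dark_and_sum(sensor_a: BioluminescenceTrace,
                          sensor_b: BioluminescenceTrace,
                          dark_window: float = 1.0) -> BioluminescenceTrace:
    """Sum two PMT sensors after subtracting each sensor's dark counts.

    The dark level of each sensor is estimated locally: dark-interval
    samples (shutter closed) within a centred ``dark_window``-hour window
    are averaged and interpolated across the record, tracking drift.
    Dark-interval samples are dropped from the output; the gap stays in
    the timestamps.

    Parameters
    ----------
    sensor_a, sensor_b : BioluminescenceTrace
        Raw per-sensor counts sharing timestamps and ``dark_mask``.
    dark_window : float
        Width (hours) of the local window used per dark estimate.
    """
    if (len(sensor_a) != len(sensor_b)
            or not np.allclose(sensor_a.timestamps, sensor_b.timestamps)):
        raise ValueError("sensors must share one time grid")
    if sensor_a.dark_mask is None or sensor_b.dark_mask is None:
        raise ValueError("both sensors need a dark_mask")
    if not np.array_equal(sensor_a.dark_mask, sensor_b.dark_mask):
        raise ValueError("sensors must share the dark-interval schedule")

    t = sensor_a.timestamps
    dark = sensor_a.dark_mask
    if not dark.any():
        raise ValueError("no dark-interval samples to estimate dark counts from")
    td = t[dark]
    out = np.zeros(len(t))
    for sensor in (sensor_a, sensor_b):
        vd = sensor.values[dark]
        # local mean of dark samples in a centred window, then interpolate
        half = dark_window / 2.0
        lo = np.searchsorted(td, td - half, side="left")
        hi = np.searchsorted(td, td + half, side="right")
        csum = np.concatenate([[0.0], np.cumsum(vd)])
        local = (csum[hi] - csum[lo]) / (hi - lo)
        dark_level = np.interp(t, td, local)
        out += sensor.values - dark_level
    keep = ~dark
    return BioluminescenceTrace(t[keep], out[keep], sensor_a.zt0_offset,
                                meta={**sensor_a.meta, "dark_subtracted": "true"})


def _cum_trapz_interp(t: np.ndarray, y: np.ndarray, x: np.ndarray) -> np.ndarray:
    """Exact integral of the linear interpolant of (t, y) from t[0] to each x.

    x must lie within [t[0], t[-1]].
    """
    F = np.concatenate([[0.0], np.cumsum(np.diff(t) * (y[:-1] + y[1:]) / 2.0)])
    j = np.clip(np.searchsorted(t, x, side="right") - 1, 0, len(t) - 2)
    yl = y[j] + (y[j + 1] - y[j]) * (x - t[j]) / (t[j + 1] - t[j])
    return F[j] + (x - t[j]) * (y[j] + yl) / 2.0


def running_mean_detrend(trace: BioluminescenceTrace, window: float = 24.0
                         ) -> BioluminescenceTrace:
    """Subtract a centred time-based running mean (default 24 h).

    The mean is the exact time average of the trace's linear interpolant
    over ``[t - window/2, t + window/2]``, so uneven sampling is handled
    and a pure ``window``-periodic component is annihilated.  Samples whose
    full window does not fit inside the record are marked invalid in the
    output's ``valid_mask`` (no padding: padding would fabricate data at
    the recording edges, exactly where rhythm emergence is scored).
    """
    t, y = trace.timestamps, trace.values
    if trace.span < window:
        raise InsufficientDataError(
            f"trace span {trace.span:.1f} h shorter than window {window} h")
    half = window / 2.0
    valid = (t - t[0] >= half - 1e-9) & (t[-1] - t >= half - 1e-9)
    lo = np.clip(t - half, t[0], t[-1])
    hi = np.clip(t + half, t[0], t[-1])
    mean = (_cum_trapz_interp(t, y, hi) - _cum_trapz_interp(t, y, lo)) / window
    out = np.where(valid, y - mean, 0.0)
    if trace.valid_mask is not None:
        valid &= trace.valid_mask
    return trace.with_values(out, valid_mask=valid)


def sinc_lowpass(series: np.ndarray, cutoff: float, dt: float) -> np.ndarray:
    """Zero-phase windowed-sinc low-pass (cutoff in hours, dt in hours)."""
    from scipy.signal import firwin
    series = np.asarray(series, dtype=float)
    if cutoff <= 2 * dt:
        raise ValueError(f"cutoff {cutoff} h must exceed twice the sampling step")
    numtaps = int(round(4 * cutoff / dt)) | 1   # odd, ~4 cutoff periods wide
    numtaps = min(numtaps, 2 * len(series) - 1)
    taps = firwin(numtaps, 1.0 / cutoff, window="blackman", fs=1.0 / dt)
    pad = numtaps // 2
    padded = np.concatenate([series[pad:0:-1], series, series[-2:-pad - 2:-1]])
    return np.convolve(padded, taps, mode="valid")


def sinc_detrend_smooth(series: np.ndarray, detrend_cutoff: float,
                        smooth_cutoff: float, dt: float) -> np.ndarray:
    """Detrend then smooth a uniformly sampled series with sinc filters.

    The trend is the low-pass at ``detrend_cutoff`` (subtracted); the
    result is then low-passed at ``smooth_cutoff``.  Both filters are
    linear phase, so peak times are not shifted.
    """
    if not detrend_cutoff > smooth_cutoff > 2 * dt:
        raise ValueError("require detrend_cutoff > smooth_cutoff > 2*dt")
    detrended = series - sinc_lowpass(series, detrend_cutoff, dt)
    return sinc_lowpass(detrended, smooth_cutoff, dt)


def adjacent_frame_minimize(stack: ImageStack) -> ImageStack:
    """Remove single-frame bright events by pixelwise minimum with the
    next frame (the last frame pairs backward).

    A cosmic-ray hit present in exactly one frame cannot survive: at its
    frame the minimum picks the clean neighbour.
    """
    if stack.n_frames < 2:
        raise ValueError("adjacent-frame minimization needs >= 2 frames")
    f = stack.frames
    out = np.empty_like(f)
    out[:-1] = np.minimum(f[:-1], f[1:])
    out[-1] = np.minimum(f[-1], f[-2])
    return stack.with_frames(out)


def frame_average(stack: ImageStack, n: int = 2) -> ImageStack:
    """Average non-overlapping blocks of ``n`` frames (trailing partial
    block dropped); block timestamps are the mean of the members."""
    if n < 1:
        raise ValueError("n must be >= 1")
    if stack.n_frames < n:
        raise ValueError(f"stack has {stack.n_frames} frames; need >= {n}")
    k = stack.n_frames // n
    f = stack.frames[:k * n].reshape(k, n, *stack.frames.shape[1:]).mean(axis=1)
    t = stack.timestamps[:k * n].reshape(k, n).mean(axis=1)
    return stack.with_frames(f, t)


def subtract_background(stack: ImageStack) -> ImageStack:
    """Subtract each frame's mean background-region intensity from the frame."""
    if stack.background_region is None or not stack.background_region.any():
        raise ValueError("stack has no (non-empty) background_region")
    bg = stack.frames[:, stack.background_region].mean(axis=1)
    return stack.with_frames(stack.frames - bg[:, None, None])


def roi_flux(stack: ImageStack) -> BioluminescenceTrace:
    """Background-subtracted total flux inside the fixed ROI, per frame.

    flux(t) = sum(ROI pixels) - |ROI| * mean(background pixels).
    """
    if stack.roi_mask is None or not stack.roi_mask.any():
        raise ValueError("stack has no (non-empty) roi_mask")
    if stack.background_region is None or not stack.background_region.any():
        raise ValueError("stack has no (non-empty) background_region")
    roi_sum = stack.frames[:, stack.roi_mask].sum(axis=1)
    bg_mean = stack.frames[:, stack.background_region].mean(axis=1)
    flux = roi_sum - stack.roi_mask.sum() * bg_mean
    return BioluminescenceTrace(stack.timestamps, flux, stack.zt0_offset,
                                meta=dict(stack.meta))


def extract_pixel_series(stack: ImageStack, gaussian_sigma: float = 1.0
                         ) -> PixelSeriesMatrix:
    """Per-ROI-pixel time series after spatial Gaussian smoothing.

    Each frame is smoothed with an isotropic Gaussian (sigma in pixels;
    0 is the identity), then one series per ROI pixel is read off on the
    frame time grid.
    """
    from scipy.ndimage import gaussian_filter
    if gaussian_sigma < 0:
        raise ValueError("gaussian_sigma must be >= 0")
    if stack.roi_mask is None or not stack.roi_mask.any():
        raise ValueError("stack has no (non-empty) roi_mask")
    frames = stack.frames
    if gaussian_sigma > 0:
        frames = np.stack([gaussian_filter(fr, gaussian_sigma) for fr in frames])
    rows, cols = np.nonzero(stack.roi_mask)
    series = frames[:, rows, cols].T.copy()
    return PixelSeriesMatrix(np.column_stack([rows, cols]), series,
                             stack.timestamps.copy(), stack.zt0_offset)
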