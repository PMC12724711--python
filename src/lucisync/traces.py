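"""Timestamped bioluminescence traces and their delimited-text round trip.

A trace is the common currency of the package: photomultiplier counts per
minute, luminometer counts in 10-min bins, or per-frame photon flux from an
imaging region of interest.  Timestamps are hours from recording start and
may be uneven (e.g. a 12 h acquisition cadence switching to 4 h late in
gestation).  ``zt0_offset`` anchors the trace to Zeitgeber Time: the hours
from recording start to the reference lights-on, so ZT(t) = (t - zt0_offset)
mod 24.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["BioluminescenceTrace", "PeakTimeSet", "TraceFormatError",
           "read_trace", "write_trace"]


class TraceFormatError(ValueError):
    """Raised when a trace file is malformed (missing column, bad times)."""


@dataclass
class BioluminescenceTrace:
    """A luminescence time series with sampling metadata.

    Parameters
    ----------
    timestamps : array of float
        Hours from recording start; strictly increasing, possibly uneven.
    values : array of float
        Counts (or photons/s); finite.
    zt0_offset : float
        Hours from recording start to the reference lights-on.
    dark_mask : array of bool, optional
        True where the sample was acquired with the shutter closed
        (detector dark counts, no signal).
    valid_mask : array of bool, optional
        False where a processing step (e.g. running-mean detrending near
        the record edges) invalidated the sample.
    meta : dict
        Free-form subject / tissue / treatment labels.
    """

    timestamps: np.ndarray
    values: np.ndarray
    zt0_offset: float = 0.0
    dark_mask: np.ndarray | None = None
    valid_mask: np.ndarray | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.timestamps = np.asarray(self.timestamps, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.timestamps.ndim != 1 or self.timestamps.shape != self.values.shape:
            raise TraceFormatError("timestamps and values must be 1-D and equal length")
        d = np.diff(self.timestamps)
        if len(d) and not np.all(d > 0):
            # 1-based data row of the first offending (non-increasing) sample
            row = int(np.argmin(d > 0)) + 2
            raise TraceFormatError(f"timestamps not strictly increasing at row {row}")
        if not np.all(np.isfinite(self.values)):
            raise TraceFormatError("non-finite values in trace")
        for name in ("dark_mask", "valid_mask"):
            m = getattr(self, name)
            if m is not None:
                m = np.asarray(m, dtype=bool)
                if m.shape != self.values.shape:
                    raise TraceFormatError(f"{name} length mismatch")
                setattr(self, name, m)

    def __len__(self) -> int:
        return len(self.timestamps)

    @property
    def span(self) -> float:
        """Record span in hours."""
        return float(self.timestamps[-1] - self.timestamps[0])

    def zt(self, t: np.ndarray | float) -> np.ndarray | float:
        """Zeitgeber Time of recording-time ``t`` (hours), wrapped to [0, 24)."""
        return np.mod(np.asarray(t, dtype=float) - self.zt0_offset, 24.0)

    def with_values(self, values: np.ndarray, **kw) -> "BioluminescenceTrace":
        return replace(self, values=np.asarray(values, dtype=float), **kw)

    def select(self, mask: np.ndarray) -> "BioluminescenceTrace":
        """Subset of samples where ``mask`` is True (order preserved)."""
        mask = np.asarray(mask, dtype=bool)
        return BioluminescenceTrace(
            self.timestamps[mask], self.values[mask], self.zt0_offset,
            None if self.dark_mask is None else self.dark_mask[mask],
            None if self.valid_mask is None else self.valid_mask[mask],
            dict(self.meta))


@dataclass
class PeakTimeSet:
    """Peak times on the 24 h Zeitgeber circle, one per subject(-day)."""

    times: np.ndarray
    weights: np.ndarray | None = None
    labels: list[str] | None = None

    def __post_init__(self) -> None:
        self.times = np.mod(np.asarray(self.times, dtype=float), 24.0)
        if self.weights is not None:
            self.weights = np.asarray(self.weights, dtype=float)
            if self.weights.shape != self.times.shape:
                raise ValueError("weights length mismatch")

    def __len__(self) -> int:
        return len(self.times)

    @property
    def angles(self) -> np.ndarray:
        """Times mapped to radians on the 24 h circle."""
        return self.times * (2.0 * np.pi / 24.0)


_META_PREFIX = "#"


def write_trace(trace: BioluminescenceTrace, path: str | Path) -> None:
    """Write a trace as delimited text (full float precision round trip)."""
    path = Path(path)
    cols = {"time_hours": trace.timestamps, "counts": trace.values}
    if trace.dark_mask is not None:
        cols["is_dark_interval"] = trace.dark_mask.astype(int)
    if trace.valid_mask is not None:
        cols["is_valid"] = trace.valid_mask.astype(int)
    df = pd.DataFrame(cols)
    with open(path, "w") as fh:
        fh.write(f"{_META_PREFIX} zt0_offset: {trace.zt0_offset!r}\n")
        for k, v in trace.meta.items():
            fh.write(f"{_META_PREFIX} meta.{k}: {v}\n")
        df.to_csv(fh, index=False, float_format="%.17e")


def read_trace(path: str | Path) -> BioluminescenceTrace:
    """Read a trace written by :func:`write_trace` (or hand-made CSV).

    Required columns: ``time_hours``, ``counts``.  Optional:
    ``is_dark_interval``, ``is_valid``.  Header comment lines of the form
    ``# zt0_offset: <float>`` / ``# meta.<key>: <value>`` carry metadata.
    """
    path = Path(path)
    zt0 = 0.0
    meta: dict = {}
    with open(path) as fh:
        lines = fh.readlines()
    body_start = 0
    for line in lines:
        if not line.startswith(_META_PREFIX):
            break
        body_start += 1
        key, _, val = line[len(_META_PREFIX):].strip().partition(":")
        key, val = key.strip(), val.strip()
        if key == "zt0_offset":
            zt0 = float(val)
        elif key.startswith("meta."):
            meta[key[5:]] = val
    from io import StringIO
    df = pd.read_csv(StringIO("".join(lines[body_start:])),
                     float_precision="round_trip")
    for col in ("time_hours", "counts"):
        if col not in df.columns:
            raise TraceFormatError(f"{path}: missing required column {col!r}")
    dark = df["is_dark_interval"].to_numpy(dtype=bool) if "is_dark_interval" in df else None
    valid = df["is_valid"].to_numpy(dtype=bool) if "is_valid" in df else None
    try:
        return BioluminescenceTrace(df["time_hours"].to_numpy(dtype=float),
                                    df["counts"].to_numpy(dtype=float),
                                    zt0, dark, valid, meta)
    except TraceFormatError as exc:
        raise TraceFormatError(f"{path}: {exc}") from exc
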