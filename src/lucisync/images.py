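"""Image stacks (multi-frame TIFF + JSON sidecar) and per-pixel series.

An :class:`ImageStack` is a sequence of 2-D bioluminescence frames sharing a
shape, with per-frame timestamps (hours, possibly uneven — e.g. twice daily
early in gestation, every 4 h later), a fixed region-of-interest mask and a
background region used for background subtraction.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import tifffile

__all__ = ["ImageStack", "PixelSeriesMatrix", "read_stack", "write_stack"]


@dataclass
class ImageStack:
    frames: np.ndarray                      # (n_frames, rows, cols)
    timestamps: np.ndarray                  # hours from recording start
    roi_mask: np.ndarray | None = None      # bool image
    background_region: np.ndarray | None = None
    zt0_offset: float = 0.0
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        self.timestamps = np.asarray(self.timestamps, dtype=float)
        if self.frames.ndim != 3:
            raise ValueError("frames must be (n_frames, rows, cols)")
        if len(self.timestamps) != self.frames.shape[0]:
            raise ValueError("one timestamp per frame required")
        if len(self.timestamps) > 1 and not np.all(np.diff(self.timestamps) > 0):
            raise ValueError("timestamps not strictly increasing")
        shape = self.frames.shape[1:]
        for name in ("roi_mask", "background_region"):
            m = getattr(self, name)
            if m is not None:
                m = np.asarray(m, dtype=bool)
                if m.shape != shape:
                    raise ValueError(f"{name} shape mismatch")
                setattr(self, name, m)
        if (self.roi_mask is not None and self.background_region is not None
                and np.any(self.roi_mask & self.background_region)):
            raise ValueError("ROI and background regions must be disjoint")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    def with_frames(self, frames: np.ndarray, timestamps: np.ndarray | None = None
                    ) -> "ImageStack":
        kw = {"frames": np.asarray(frames, dtype=float)}
        if timestamps is not None:
            kw["timestamps"] = np.asarray(timestamps, dtype=float)
        return replace(self, **kw)


@dataclass
class PixelSeriesMatrix:
    """Per-pixel time series on one shared grid (rows of ``series``)."""

    pixel_ids: np.ndarray   # (n_pixels, 2) int (row, col), 0-based
    series: np.ndarray      # (n_pixels, n_times)
    grid: np.ndarray        # hours
    zt0_offset: float = 0.0

    def __post_init__(self) -> None:
        self.pixel_ids = np.asarray(self.pixel_ids, dtype=int)
        self.series = np.asarray(self.series, dtype=float)
        self.grid = np.asarray(self.grid, dtype=float)
        if self.series.ndim != 2 or self.series.shape[0] == 0:
            raise ValueError("series must be (n_pixels>0, n_times)")
        if self.series.shape[1] != len(self.grid):
            raise ValueError("every series must have the grid's length")
        if self.pixel_ids.shape != (self.series.shape[0], 2):
            raise ValueError("pixel_ids must be (n_pixels, 2)")

    @property
    def n_pixels(self) -> int:
        return self.series.shape[0]


def _mask_to_runs(mask: np.ndarray) -> list[list[int]]:
    """Row-wise run-length encoding [[row, col_start, col_stop], ...]."""
    runs = []
    for r, row in enumerate(np.asarray(mask, dtype=bool)):
        idx = np.flatnonzero(row)
        if idx.size == 0:
            continue
        breaks = np.flatnonzero(np.diff(idx) > 1)
        starts = np.concatenate([[0], breaks + 1])
        stops = np.concatenate([breaks, [idx.size - 1]])
        for a, b in zip(starts, stops):
            runs.append([r, int(idx[a]), int(idx[b]) + 1])
    return runs


def _runs_to_mask(runs: list, shape: tuple[int, int]) -> np.ndarray:
    mask = np.zeros(shape, dtype=bool)
    for r, a, b in runs:
        mask[r, a:b] = True
    return mask


def write_stack(stack: ImageStack, tiff_path: str | Path) -> Path:
    """Write frames as multi-frame float TIFF plus a ``.json`` sidecar."""
    tiff_path = Path(tiff_path)
    tifffile.imwrite(tiff_path, stack.frames.astype(np.float32))
    sidecar = {
        "timestamps_hours": stack.timestamps.tolist(),
        "zt0_offset": stack.zt0_offset,
        "shape": list(stack.frames.shape[1:]),
        "meta": stack.meta,
    }
    if stack.roi_mask is not None:
        sidecar["roi_runs"] = _mask_to_runs(stack.roi_mask)
    if stack.background_region is not None:
        sidecar["background_runs"] = _mask_to_runs(stack.background_region)
    side_path = tiff_path.with_suffix(".json")
    side_path.write_text(json.dumps(sidecar))
    return side_path


def read_stack(tiff_path: str | Path) -> ImageStack:
    tiff_path = Path(tiff_path)
    frames = tifffile.imread(tiff_path)
    if frames.ndim == 2:
        frames = frames[None]
    side = json.loads(tiff_path.with_suffix(".json").read_text())
    shape = tuple(side["shape"])
    roi = _runs_to_mask(side["roi_runs"], shape) if "roi_runs" in side else None
    bg = _runs_to_mask(side["background_runs"], shape) if "background_runs" in side else None
    return ImageStack(frames, np.array(side["timestamps_hours"], dtype=float),
                      roi, bg, side.get("zt0_offset", 0.0), side.get("meta", {}))
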