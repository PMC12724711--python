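"""End-to-end study runners: in utero imaging, explant luminometry, and
treatment-group synchrony comparison.

Each runner consumes in-memory containers (or paths via the config
wrapper), applies the preprocessing chain in the fixed order
minimize -> average -> background subtract -> ROI flux / pixel extraction
-> detrend -> rhythm statistics, and returns a :class:`StudyReport` that
serializes deterministically (config hash and seed embedded).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from . import __version__
from .traces import BioluminescenceTrace, PeakTimeSet, read_trace
from .images import ImageStack, read_stack
from .prep import (adjacent_frame_minimize, frame_average, subtract_background,
                   roi_flux, extract_pixel_series, running_mean_detrend,
                   InsufficientDataError)
from .rhythm import (meta_rhythm_test, classify_circadian, fit_damped_cosine,
                     daily_peak_times, peak_trough_amplitude, RhythmFit)
from .circular import rayleigh_R, phase_difference, CircularSummary
from .phase import phases_from_pixels, sync_timecourse, smooth_series, SyncSeries

__all__ = ["AnalysisConfig", "StudyReport", "run_inutero", "run_explant",
           "run_treatment_compare"]


@dataclass
class AnalysisConfig:
    """Parameters for one study run (YAML-serializable)."""

    inputs: dict = field(default_factory=dict)      # label -> path
    zt0_offset: float = 0.0
    minimize: bool = True
    average_n: int = 1
    gaussian_sigma: float = 1.0
    detrend_window: float = 24.0
    period_range: tuple[float, float] = (18.0, 30.0)
    alpha: float = 0.05
    goodness_cutoff: float = 0.70
    fit_window: tuple[float, float] = (48.0, 120.0)
    amplitude_window: tuple[float, float] = (36.0, 60.0)
    sync_band: tuple[float, float] = (18.0, 30.0)
    sinc_detrend_cutoff: float = 48.0
    sinc_smooth_cutoff: float = 4.0
    power_gate: bool = True
    seed: int = 0
    out_dir: str | None = None

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        lo, hi = self.period_range
        if not 0 < lo < hi:
            raise ValueError("require 0 < period_min < period_max")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AnalysisConfig":
        import yaml
        raw = yaml.safe_load(Path(path).read_text()) or {}
        for k in ("period_range", "fit_window", "amplitude_window", "sync_band"):
            if k in raw:
                raw[k] = tuple(raw[k])
        return cls(**raw)

    def hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return [_jsonable(v) for v in obj.tolist()]
    if isinstance(obj, (np.floating, float)):
        f = float(obj)
        return None if not np.isfinite(f) else f
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    if hasattr(obj, "__dataclass_fields__"):
        return _jsonable({k: getattr(obj, k) for k in obj.__dataclass_fields__})
    return obj


@dataclass
class StudyReport:
    """Aggregated per-subject fits, peaks and synchrony summaries."""

    rhythm: dict = field(default_factory=dict)        # subject -> fit/meta dict
    peaks: dict = field(default_factory=dict)         # subject -> PeakTimeSet
    daily_rayleigh: dict = field(default_factory=dict)  # day -> CircularSummary
    pixel_sync: dict = field(default_factory=dict)    # subject -> SyncSeries
    group_sync: dict = field(default_factory=dict)    # group -> summary dict
    phase_differences: dict = field(default_factory=dict)
    exclusions: list = field(default_factory=list)    # (subject, reason)
    warnings: list = field(default_factory=list)
    run_meta: dict = field(default_factory=dict)

    def to_json(self, path: str | Path | None = None) -> str:
        text = json.dumps(_jsonable(asdict(self)), sort_keys=True, indent=1)
        if path is not None:
            Path(path).write_text(text)
        return text

    def to_markdown(self, path: str | Path | None = None) -> str:
        lines = [f"# Study report (config {self.run_meta.get('config_hash', '?')}, "
                 f"seed {self.run_meta.get('seed', '?')})", ""]
        if self.rhythm:
            lines += ["## Rhythm classification", "",
                      "| subject | period (h) | p / r | circadian |",
                      "|---|---|---|---|"]
            for s, rec in self.rhythm.items():
                score = rec.get("p_value")
                score = rec.get("goodness") if score is None else score
                score_s = "-" if score is None or not np.isfinite(score) else f"{score:.3g}"
                per = rec.get("period")
                per_s = "-" if per is None or not np.isfinite(per) else f"{per:.2f}"
                lines.append(f"| {s} | {per_s} | {score_s} | {rec.get('is_circadian')} |")
            lines.append("")
        if self.daily_rayleigh:
            lines += ["## Inter-subject daily synchrony (Rayleigh R)", "",
                      "| day | R | mean ZT | n |", "|---|---|---|---|"]
            for d, c in self.daily_rayleigh.items():
                lines.append(f"| {d} | {c.R:.3f} | {c.mean_direction:.2f} | {c.n} |")
            lines.append("")
        if self.exclusions:
            lines += ["## Exclusions", ""]
            lines += [f"- {s}: {r}" for s, r in self.exclusions]
            lines.append("")
        text = "\n".join(lines)
        if path is not None:
            Path(path).write_text(text)
        return text


def _run_meta(config: AnalysisConfig) -> dict:
    return {"config_hash": config.hash(), "seed": config.seed,
            "version": __version__}


def _fine_sampled_tail(stack: ImageStack, max_spacing: float = 4.0) -> ImageStack:
    """Trailing segment of a stack where frame spacing is <= max_spacing h
    (the fine late-gestation acquisition); the sparse early segment cannot
    support instantaneous-phase estimation."""
    d = np.diff(stack.timestamps)
    start = 0
    for i in range(len(d) - 1, -1, -1):
        if d[i] > max_spacing + 1e-9:
            start = i + 1
            break
    if start == 0:
        return stack
    return ImageStack(stack.frames[start:], stack.timestamps[start:],
                      stack.roi_mask, stack.background_region,
                      stack.zt0_offset, dict(stack.meta))


def _prep_stack(stack: ImageStack, config: AnalysisConfig) -> ImageStack:
    if config.minimize and stack.n_frames >= 2:
        stack = adjacent_frame_minimize(stack)
    if config.average_n > 1:
        stack = frame_average(stack, config.average_n)
    return stack


def run_inutero(stacks: dict[str, ImageStack] | AnalysisConfig,
                config: AnalysisConfig | None = None) -> StudyReport:
    """In utero imaging analysis across pregnancies.

    Per dam: preprocess the stack, take background-subtracted ROI flux,
    detrend with the 24 h running mean, run the meta rhythm test and
    classify.  Dams that do not score circadian (period outside 18–30 h
    or p >= alpha) are excluded from the peak and synchrony summaries but
    listed with the reason.  For circadian dams, daily peak times feed a
    per-day across-dam Rayleigh R, and per-pixel wavelet phases feed a
    per-dam Kuramoto synchrony time course.
    """
    if isinstance(stacks, AnalysisConfig):
        config = stacks
        stacks = {label: read_stack(p) for label, p in config.inputs.items()}
    assert config is not None
    report = StudyReport(run_meta=_run_meta(config))
    circadian: dict[str, ImageStack] = {}
    for dam, stack in stacks.items():
        try:
            prepped = _prep_stack(stack, config)
            flux = roi_flux(prepped)
            det = running_mean_detrend(flux, config.detrend_window)
            meta = meta_rhythm_test(det, config.period_range)
            ok = classify_circadian(meta, config.period_range, config.alpha)
            report.rhythm[dam] = {"period": meta.period, "p_value": meta.p_value,
                                  "is_circadian": ok,
                                  "methods": {m.method: {"period": m.period,
                                                         "p": m.p_value}
                                              for m in meta.methods}}
            if not ok:
                report.exclusions.append(
                    (dam, f"not circadian: period={meta.period:.2f} h, "
                          f"p={meta.p_value:.3g}"))
                continue
            circadian[dam] = prepped
            report.peaks[dam] = daily_peak_times(det)
        except InsufficientDataError as exc:
            report.rhythm[dam] = {"period": None, "p_value": None,
                                  "is_circadian": False, "methods": {}}
            report.exclusions.append((dam, f"insufficient data: {exc}"))

    # per-day Rayleigh across circadian dams
    day_pool: dict[str, list[float]] = {}
    for dam, peaks in report.peaks.items():
        for label, t in zip(peaks.labels or [], peaks.times):
            day_pool.setdefault(label, []).append(float(t))
    for day in sorted(day_pool):
        times = day_pool[day]
        if len(times) >= 2:
            report.daily_rayleigh[day] = rayleigh_R(PeakTimeSet(np.array(times)))

    if len(circadian) < 1:
        report.warnings.append("no circadian dam: synchrony sections empty")
    for dam, prepped in circadian.items():
        try:
            tail = _fine_sampled_tail(prepped)
            pixels = extract_pixel_series(subtract_background(tail),
                                          config.gaussian_sigma)
            pm = phases_from_pixels(pixels, config.sync_band,
                                    config.sinc_detrend_cutoff,
                                    config.sinc_smooth_cutoff,
                                    power_gate=config.power_gate,
                                    seed=config.seed)
            report.pixel_sync[dam] = sync_timecourse(pm)
        except InsufficientDataError as exc:
            report.warnings.append(f"{dam}: pixel sync skipped ({exc})")
    return report


def run_explant(traces: dict[str, BioluminescenceTrace] | AnalysisConfig,
                config: AnalysisConfig | None = None,
                pairs: list[tuple[str, str]] | None = None) -> StudyReport:
    """Explant luminometry analysis.

    Per trace: damped-cosine fit on days 2–5 (classification at 18–30 h
    and r > 0.70), peak-to-trough amplitude on 36–60 h, ZT peak phase.
    Circadian explants' phases feed a Rayleigh uniformity summary;
    ``pairs`` of trace labels (e.g. uterus/cervix from the same dam)
    yield paired circular phase differences.
    """
    if isinstance(traces, AnalysisConfig):
        config = traces
        traces = {label: read_trace(p) for label, p in config.inputs.items()}
    assert config is not None
    report = StudyReport(run_meta=_run_meta(config))
    fits: dict[str, RhythmFit] = {}
    for name, trace in traces.items():
        try:
            fit = fit_damped_cosine(trace, config.fit_window,
                                    goodness_cutoff=config.goodness_cutoff,
                                    period_range=config.period_range)
            amp = peak_trough_amplitude(trace, config.amplitude_window)
            rec = fit.to_dict()
            rec["peak_trough_amplitude"] = amp
            report.rhythm[name] = rec
            fits[name] = fit
            if not fit.is_circadian:
                report.exclusions.append(
                    (name, "not circadian: "
                           + (f"r={fit.goodness:.2f}, T={fit.period:.2f} h"
                              if np.isfinite(fit.period) else "fit failed")))
        except (InsufficientDataError, ValueError) as exc:
            report.rhythm[name] = {"is_circadian": False, "error": str(exc)}
            report.exclusions.append((name, f"failed: {exc}"))

    circ = {n: f for n, f in fits.items() if f.is_circadian}
    if len(circ) >= 2:
        peaks = PeakTimeSet(np.array([f.peak_phase_zt for f in circ.values()]),
                            labels=list(circ))
        report.daily_rayleigh["all"] = rayleigh_R(peaks)
    for a, b in pairs or []:
        if a in fits and b in fits:
            pd = phase_difference(
                PeakTimeSet(np.array([fits[a].peak_phase_zt]), labels=[a]),
                PeakTimeSet(np.array([fits[b].peak_phase_zt]), labels=[b]),
                paired=False)
            report.phase_differences[f"{a}-{b}"] = pd.mean_difference
    return report


def run_treatment_compare(groups: dict[str, dict[str, ImageStack | SyncSeries]],
                          config: AnalysisConfig,
                          smooth_window: float = 2.0) -> StudyReport:
    """Compare per-group Kuramoto synchrony trajectories (descriptive).

    Each group maps subjects to image stacks (processed to sync series
    via the in utero pixel path) or precomputed sync series; trajectories
    are aligned on a common grid, and each group is summarized as mean ±
    SEM per time point together with the per-time group difference.
    """
    if not groups or any(len(g) == 0 for g in groups.values()):
        raise ValueError("every group needs at least one subject")
    report = StudyReport(run_meta=_run_meta(config))
    per_group: dict[str, dict[str, SyncSeries]] = {}
    for gname, members in groups.items():
        per_group[gname] = {}
        for subject, obj in members.items():
            if isinstance(obj, SyncSeries):
                ss = obj
            else:
                prepped = _prep_stack(obj, config)
                pixels = extract_pixel_series(subtract_background(prepped),
                                              config.gaussian_sigma)
                pm = phases_from_pixels(pixels, config.sync_band,
                                        config.sinc_detrend_cutoff,
                                        config.sinc_smooth_cutoff,
                                        power_gate=config.power_gate,
                                        seed=config.seed)
                ss = sync_timecourse(pm)
            per_group[gname][f"{gname}/{subject}"] = ss
            report.pixel_sync[f"{gname}/{subject}"] = ss

    grids = [ss.grid for g in per_group.values() for ss in g.values()]
    lo = max(g[0] for g in grids)
    hi = min(g[-1] for g in grids)
    if hi <= lo:
        raise ValueError("sync series have no overlapping time support")
    common = np.arange(lo, hi + 1e-9, 1.0)
    means = {}
    for gname, members in per_group.items():
        rows = []
        for ss in members.values():
            r = smooth_series(ss.r, ss.grid, smooth_window)
            rows.append(np.interp(common, ss.grid[np.isfinite(r)],
                                  r[np.isfinite(r)]))
        arr = np.vstack(rows)
        mean = arr.mean(axis=0)
        sem = arr.std(axis=0, ddof=1) / np.sqrt(arr.shape[0]) if arr.shape[0] > 1 \
            else np.zeros_like(mean)
        means[gname] = mean
        report.group_sync[gname] = {"grid": common, "mean": mean, "sem": sem,
                                    "n": arr.shape[0]}
    if len(means) == 2:
        (g1, m1), (g2, m2) = means.items()
        report.group_sync["difference"] = {"grid": common, "pair": [g1, g2],
                                           "mean": m1 - m2}
    return report
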