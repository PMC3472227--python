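"""End-to-end analysis pipeline and its serialisable report.

Order of operations follows the acquisition-to-intensity chain: load the
segment-derived U/A curves, interpolate to a uniform 1 ms grid, smooth the
area curve, locate the systolic foot, build the U-lnA loop and select its
early-systolic linear portion, estimate the wave speed, separate the
increments, and compute net/forward/backward wave intensity with classified
peaks.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Any

from . import __version__ as _version
from .intensity import (
    WaveIntensityResult,
    WavePeaks,
    find_peaks,
    separated_intensity,
    time_corrected_intensity,
)
from .separation import SeparatedWaves, differentials, separate
from .waveforms import (
    FootIndex,
    WaveformSeries,
    detect_systolic_foot,
    load_waveforms,
    resample_uniform,
    smooth_area,
)
from .wavespeed import WaveSpeedFit, build_loop, estimate_wave_speed, select_linear_window

logger = logging.getLogger("awia")

__all__ = ["AnalysisReport", "analyze_series", "analyze"]


@dataclass(frozen=True)
class AnalysisReport:
    """Everything the pipeline computed, with the settings that produced it."""

    source: str
    settings: dict
    wave_speed: WaveSpeedFit
    peaks: WavePeaks
    foot: FootIndex
    series: WaveformSeries
    separated: SeparatedWaves
    intensity: WaveIntensityResult
    version: str = _version

    def to_dict(self) -> dict[str, Any]:
        """JSON-safe summary (scalar results + settings, not the raw arrays)."""
        ws = self.wave_speed
        pk = self.peaks
        return {
            "source": self.source,
            "version": self.version,
            "settings": self.settings,
            "wave_speed": {
                "c_mps": ws.c,
                "window_start_ms": float(self.series.t[ws.window[0]]),
                "window_end_ms": float(self.series.t[ws.window[1]]),
                "r2": ws.r2,
                "distensibility_per_Pa": ws.distensibility,
            },
            "foot": {"index": self.foot.index, "time_ms": float(self.series.t[self.foot.index]),
                     "method": self.foot.method},
            "peaks": {
                "fcw_peak_mps": pk.fcw_peak,
                "fcw_time_ms": pk.fcw_time_ms,
                "few_peak_mps": pk.few_peak,
                "few_time_ms": pk.few_time_ms,
                "bcw_peak_mps": pk.bcw_peak,
                "bcw_time_ms": pk.bcw_time_ms,
                "absent": pk.absent,
            },
            "gated_complete_cycle": self.series.gated_complete_cycle,
        }

    def to_json(self, path: str | Path | None = None) -> str:
        text = json.dumps(self.to_dict(), indent=2, sort_keys=True)
        if path is not None:
            Path(path).write_text(text + "\n")
        return text


def analyze_series(
    series: WaveformSeries,
    dt_ms: float = 1.0,
    interpolation: str = "monotone-cubic",
    sg_poly_order: int = 3,
    sg_window: int | None = 101,
    smooth_velocity: bool = False,
    foot_threshold: float = 0.05,
    min_window_ms: float = 20.0,
    rho: float | None = None,
    noise_floor_fraction: float = 0.02,
    source: str = "in-memory",
) -> AnalysisReport:
    """Run the full pipeline on an already-loaded series.

    ``sg_window=None`` skips area smoothing entirely (appropriate for data
    that are noise-free or already smoothed).  Note that filtering only one
    of two signals whose gradient is the estimand distorts that gradient
    wherever the filter attenuates the signal; smoothing both curves with
    the same filter (``smooth_velocity=True``) makes the distortion cancel
    to first order in the loop slope.
    """
    settings = {
        "dt_ms": dt_ms,
        "interpolation": interpolation,
        "sg_poly_order": sg_poly_order,
        "sg_window": sg_window,
        "smooth_velocity": smooth_velocity,
        "foot_threshold": foot_threshold,
        "min_window_ms": min_window_ms,
        "rho": rho,
        "noise_floor_fraction": noise_floor_fraction,
    }
    uniform = resample_uniform(series, dt=dt_ms, method=interpolation)
    if sg_window is None:
        smoothed = uniform
    else:
        smoothed = smooth_area(
            uniform,
            poly_order=sg_poly_order,
            window_samples=sg_window,
            smooth_velocity=smooth_velocity,
        )
    foot = detect_systolic_foot(smoothed, threshold_fraction=foot_threshold)
    loop = build_loop(smoothed, foot)
    window, r2 = select_linear_window(loop, min_len_ms=min_window_ms, dt_ms=dt_ms)
    fit = estimate_wave_speed(loop, window, rho=rho)
    logger.info(
        "wave speed %.3f m/s from loop window [%.0f, %.0f] ms (r2=%.4f)",
        fit.c,
        smoothed.t[window[0]],
        smoothed.t[window[1]],
        r2,
    )
    inc = differentials(smoothed)
    sep = separate(inc, fit.c)
    wi = separated_intensity(sep)
    peaks = find_peaks(wi, sep, foot, noise_floor_fraction=noise_floor_fraction)
    logger.info(
        "peaks: FCW %.3g m/s @ %.0f ms; BCW %s; FEW %s",
        peaks.fcw_peak,
        peaks.fcw_time_ms,
        f"{peaks.bcw_peak:.3g} @ {peaks.bcw_time_ms:.0f} ms" if peaks.bcw_peak is not None else "absent",
        f"{peaks.few_peak:.3g} @ {peaks.few_time_ms:.0f} ms" if peaks.few_peak is not None else "absent",
    )
    return AnalysisReport(
        source=source,
        settings=settings,
        wave_speed=fit,
        peaks=peaks,
        foot=foot,
        series=smoothed,
        separated=sep,
        intensity=wi,
    )


def analyze(
    input_path: str | Path,
    column_map: dict[str, str] | None = None,
    velocity_sign: int = 1,
    units: dict[str, str] | None = None,
    **kwargs,
) -> AnalysisReport:
    """Load a waveform table from disk and run the full pipeline."""
    series = load_waveforms(
        input_path, column_map=column_map, velocity_sign=velocity_sign, units=units
    )
    return analyze_series(series, source=str(input_path), **kwargs)
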