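"""Velocity/area waveform container, I/O, resampling, smoothing and foot detection.

The entry point of the analysis is a pair of time series measured at one
vessel location over a single cardiac cycle: mean blood velocity ``U`` [m/s]
(signed, positive away from the heart) and lumen cross-sectional area ``A``
[mm^2], as produced by PC-CMR segmentation.  This module reads and validates
such series, interpolates them to a uniform (default 1 ms) grid, smooths the
area curve with a Savitzky-Golay filter, and locates the systolic foot that
anchors the early-systolic analysis windows downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Literal

import numpy as np
import pandas as pd
from scipy.interpolate import PchipInterpolator
from scipy.signal import savgol_filter

from .errors import DetectionError, FormatError, ValidationError

__all__ = [
    "WaveformSeries",
    "FootIndex",
    "load_waveforms",
    "resample_uniform",
    "smooth_area",
    "detect_systolic_foot",
]

#: minimum number of samples for a usable series
MIN_SAMPLES = 8


@dataclass(frozen=True)
class WaveformSeries:
    """Time-aligned velocity and area samples for one cardiac cycle.

    Attributes
    ----------
    t : ndarray
        Time since the R-wave trigger [ms], strictly increasing.
    U : ndarray
        Mean velocity [m/s]; positive = away from the heart.
    A : ndarray
        Cross-sectional area [mm^2]; strictly positive so ln A is defined.
    dt_native : float
        Original sampling interval [ms] (minimum spacing of the source grid).
    gated_complete_cycle : bool
        False when prospective gating truncated end diastole.
    meta : dict
        Processing provenance (resampling method, smoothing window, ...).
    """

    t: np.ndarray
    U: np.ndarray
    A: np.ndarray
    dt_native: float
    gated_complete_cycle: bool = False
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        t = np.asarray(self.t, dtype=float)
        U = np.asarray(self.U, dtype=float)
        A = np.asarray(self.A, dtype=float)
        object.__setattr__(self, "t", t)
        object.__setattr__(self, "U", U)
        object.__setattr__(self, "A", A)
        if not (len(t) == len(U) == len(A)):
            raise ValidationError(
                f"t, U, A lengths differ: {len(t)}, {len(U)}, {len(A)}"
            )
        if len(t) < MIN_SAMPLES:
            raise ValidationError(
                f"series has {len(t)} samples; at least {MIN_SAMPLES} required"
            )
        if not np.all(np.isfinite(t)) or not np.all(np.isfinite(U)) or not np.all(
            np.isfinite(A)
        ):
            raise ValidationError("non-finite sample encountered")
        if np.any(np.diff(t) <= 0):
            i = int(np.argmax(np.diff(t) <= 0))
            raise ValidationError(f"time not strictly increasing at row {i + 1}")
        bad = np.flatnonzero(A <= 0)
        if bad.size:
            raise ValidationError(
                f"non-positive area at row {bad[0]} (A={A[bad[0]]:g} mm^2); "
                "ln A is undefined"
            )

    def __len__(self) -> int:
        return len(self.t)

    @property
    def dt(self) -> float:
        """Current sampling interval [ms] (uniform grids only)."""
        return float(self.t[1] - self.t[0])

    @property
    def is_uniform(self) -> bool:
        d = np.diff(self.t)
        return bool(np.allclose(d, d[0], rtol=0.0, atol=1e-9))

    def lnA(self) -> np.ndarray:
        """Natural log of area; the additive constant from the unit is irrelevant."""
        return np.log(self.A)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"time_ms": self.t, "U_mps": self.U, "A_mm2": self.A})

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)


@dataclass(frozen=True)
class FootIndex:
    """Sample position of the systolic upstroke onset."""

    index: int
    method: str = "upstroke-threshold"

    def __int__(self) -> int:
        return self.index


# ---------------------------------------------------------------------------
# loading

_DEFAULT_COLUMNS = {"time": "time_ms", "velocity": "U_mps", "area": "A_mm2"}

#: multiplicative factors to the canonical units (ms, m/s, mm^2)
_TIME_FACTORS = {"ms": 1.0, "s": 1000.0}
_VEL_FACTORS = {"m/s": 1.0, "mps": 1.0, "cm/s": 0.01}
_AREA_FACTORS = {"mm2": 1.0, "mm^2": 1.0, "cm2": 100.0, "cm^2": 100.0, "m2": 1e6, "m^2": 1e6}


def load_waveforms(
    source: str | Path | pd.DataFrame,
    column_map: dict[str, str] | None = None,
    velocity_sign: int = 1,
    units: dict[str, str] | None = None,
    gated_complete_cycle: bool = False,
) -> WaveformSeries:
    """Read a velocity/area table (CSV or JSON records) into a validated series.

    Parameters
    ----------
    source
        Path to a CSV file (header row) or JSON records file, or a DataFrame.
    column_map
        Mapping of the logical names ``time``, ``velocity``, ``area`` to the
        column names in the file.  Defaults to ``time_ms``, ``U_mps``, ``A_mm2``.
    velocity_sign
        +1 or -1; multiplied into U to correct the velocity-encoding direction.
    units
        Declared units per logical name, e.g. ``{"area": "cm2"}``; values are
        converted to the canonical ms / m/s / mm^2.
    """
    if velocity_sign not in (+1, -1):
        raise FormatError(f"velocity_sign must be +1 or -1, got {velocity_sign!r}")
    if isinstance(source, pd.DataFrame):
        df = source
    else:
        path = Path(source)
        if path.suffix.lower() == ".json":
            df = pd.read_json(path)
        else:
            df = pd.read_csv(path)

    cols = dict(_DEFAULT_COLUMNS)
    if column_map:
        cols.update(column_map)
    for logical, name in cols.items():
        if name not in df.columns:
            raise FormatError(
                f"missing {logical} column {name!r}; available: {list(df.columns)}"
            )

    units = units or {}
    try:
        t_fac = _TIME_FACTORS[units.get("time", "ms")]
        u_fac = _VEL_FACTORS[units.get("velocity", "m/s")]
        a_fac = _AREA_FACTORS[units.get("area", "mm2")]
    except KeyError as exc:
        raise FormatError(f"unknown unit {exc.args[0]!r}") from None

    t = df[cols["time"]].to_numpy(dtype=float) * t_fac
    U = df[cols["velocity"]].to_numpy(dtype=float) * u_fac * velocity_sign
    A = df[cols["area"]].to_numpy(dtype=float) * a_fac
    dt_native = float(np.min(np.diff(t))) if len(t) > 1 else float("nan")
    return WaveformSeries(
        t=t,
        U=U,
        A=A,
        dt_native=dt_native,
        gated_complete_cycle=gated_complete_cycle,
        meta={"source": str(source) if not isinstance(source, pd.DataFrame) else "dataframe"},
    )


# ---------------------------------------------------------------------------
# resampling

def resample_uniform(
    series: WaveformSeries,
    dt: float = 1.0,
    method: Literal["monotone-cubic", "linear"] = "monotone-cubic",
) -> WaveformSeries:
    """Interpolate U and A onto a uniform grid of spacing ``dt`` ms.

    The default shape-preserving monotone cubic (PCHIP) avoids overshoot of
    the area curve between samples; linear interpolation is available and, on
    smooth physiological waveforms, yields indistinguishable downstream
    results.  Only upsampling is supported: the native temporal resolution is
    the information limit and decimating it is never part of this analysis.
    """
    if dt <= 0:
        raise ValidationError(f"dt must be positive, got {dt}")
    native = float(np.min(np.diff(series.t)))
    if dt > native + 1e-12:
        raise ValidationError(
            f"requested dt={dt} ms coarser than native spacing {native:g} ms; "
            "downsampling is not supported"
        )
    t0, t1 = float(series.t[0]), float(series.t[-1])
    n = int(np.floor((t1 - t0) / dt + 1e-9)) + 1
    t_new = t0 + dt * np.arange(n)

    if method == "monotone-cubic":
        U_new = PchipInterpolator(series.t, series.U)(t_new)
        A_new = PchipInterpolator(series.t, series.A)(t_new)
    elif method == "linear":
        U_new = np.interp(t_new, series.t, series.U)
        A_new = np.interp(t_new, series.t, series.A)
    else:
        raise ValidationError(f"unknown interpolation method {method!r}")

    meta = dict(series.meta)
    meta.update({"resampled_dt_ms": dt, "interpolation": method})
    return WaveformSeries(
        t=t_new,
        U=U_new,
        A=A_new,
        dt_native=series.dt_native,
        gated_complete_cycle=series.gated_complete_cycle,
        meta=meta,
    )


# ---------------------------------------------------------------------------
# smoothing

def smooth_area(
    series: WaveformSeries,
    poly_order: int = 3,
    window_samples: int = 101,
    smooth_velocity: bool = False,
) -> WaveformSeries:
    """Savitzky-Golay smooth the area curve (and optionally the velocity curve).

    Each sample is replaced by the value at its own time of the degree
    ``poly_order`` least-squares polynomial fitted over the centred window of
    ``window_samples`` points; edges use the polynomial fitted to the first /
    last full window evaluated at the edge times.  The window must be odd (a
    centred window has no even realisation); at 1 ms sampling the default 101
    samples spans 100 ms.  If the series is shorter than the window, the
    window shrinks to the largest valid odd size and the value used is
    recorded in ``meta['sg_window_used']``.
    """
    if window_samples % 2 == 0:
        raise ValidationError(
            f"window_samples must be odd (centred window); got {window_samples}"
        )
    if window_samples <= poly_order:
        raise ValidationError(
            f"window_samples ({window_samples}) must exceed poly_order ({poly_order})"
        )
    if not series.is_uniform:
        raise ValidationError("smoothing requires a uniformly sampled series")

    n = len(series)
    window = window_samples
    if n < window:
        window = n if n % 2 == 1 else n - 1
        if window <= poly_order:
            raise ValidationError(
                f"series too short ({n} samples) for poly_order {poly_order}"
            )

    A_s = savgol_filter(series.A, window, poly_order, mode="interp")
    U_s = (
        savgol_filter(series.U, window, poly_order, mode="interp")
        if smooth_velocity
        else series.U
    )
    if np.any(A_s <= 0):
        raise ValidationError("smoothing produced a non-positive area sample")

    meta = dict(series.meta)
    meta.update(
        {
            "sg_poly_order": poly_order,
            "sg_window_requested": window_samples,
            "sg_window_used": window,
            "sg_velocity_smoothed": smooth_velocity,
        }
    )
    return replace(series, U=U_s, A=A_s, meta=meta)


# ---------------------------------------------------------------------------
# systolic foot

def detect_systolic_foot(
    series: WaveformSeries, threshold_fraction: float = 0.05
) -> FootIndex:
    """Locate the onset of the systolic velocity upstroke.

    The baseline is the median of the first 5% of samples (end-diastolic
    rest); the foot is the last sample before U first exceeds
    ``baseline + threshold_fraction * (peak - baseline)`` on the way up to the
    global velocity maximum.  The rule is baseline-relative, hence invariant
    to constant velocity offsets.
    """
    U = series.U
    n = len(U)
    n_base = max(1, int(np.ceil(0.05 * n)))
    baseline = float(np.median(U[:n_base]))
    i_peak = int(np.argmax(U))
    peak = float(U[i_peak])
    excursion = peak - baseline
    noise_floor = 10 * np.finfo(float).eps * max(1.0, abs(peak), abs(baseline))
    if excursion <= noise_floor:
        raise DetectionError(
            f"no systolic upstroke: peak-baseline excursion {excursion:g} m/s"
        )
    threshold = baseline + threshold_fraction * excursion
    above = np.flatnonzero(U[: i_peak + 1] > threshold)
    if above.size == 0:
        raise DetectionError("velocity never exceeds the upstroke threshold")
    first_cross = int(above[0])
    index = max(0, first_cross - 1)
    return FootIndex(index=index, method=f"upstroke-threshold-{threshold_fraction:g}")
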