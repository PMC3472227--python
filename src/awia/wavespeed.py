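"""Wave speed from the early-systolic U-lnA loop.

In the absence of reflected waves the waterhammer relation for an
area-formulated wavefront reduces to ``dU = c * dlnA``, so velocity plotted
against log-area traces a straight line of slope ``c`` while only the forward
wave is present.  Early systole - between the systolic foot and peak
velocity - is the portion of the cycle where that assumption is credible, and
the wave speed is estimated as the ordinary-least-squares gradient of the
best-fitting linear stretch of the loop inside that span.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .errors import EstimationError
from .waveforms import FootIndex, WaveformSeries

__all__ = ["ULnALoop", "WaveSpeedFit", "build_loop", "select_linear_window",
           "estimate_wave_speed", "fit_wave_speed"]

#: r-squared values within this distance of the maximum are treated as tied
#: (ties go to the longest window, then the earliest start); this keeps the
#: selection deterministic on exactly-linear loops where floating-point noise
#: otherwise ranks equivalent windows arbitrarily.
R2_TIE_TOL = 1e-12


@dataclass(frozen=True)
class ULnALoop:
    """Velocity paired samplewise with log-area on the uniform grid."""

    lnA: np.ndarray
    U: np.ndarray
    foot: FootIndex
    peak_u_index: int

    def __post_init__(self) -> None:
        if len(self.lnA) != len(self.U):
            raise EstimationError("lnA and U lengths differ")
        if not self.foot.index < self.peak_u_index:
            raise EstimationError(
                f"foot index {self.foot.index} not before peak-U index "
                f"{self.peak_u_index}"
            )

    def __len__(self) -> int:
        return len(self.U)


@dataclass(frozen=True)
class WaveSpeedFit:
    """Estimated wave speed and the loop window it came from.

    ``c`` is in m/s; ``window`` holds the inclusive (start, end) sample
    indices of the selected linear portion; ``r2`` is the coefficient of
    determination of the within-window fit of U on lnA.  ``distensibility``
    (1/Pa) is populated when a blood density was supplied, via the
    Bramwell-Hill relation D = 1/(rho * c^2).
    """

    c: float
    window: tuple[int, int]
    r2: float
    distensibility: Optional[float] = None


def build_loop(series: WaveformSeries, foot: FootIndex) -> ULnALoop:
    """Pair U with lnA elementwise, preserving sample order.

    Area unit rescaling A -> kA only shifts lnA by ln k, so the loop shape -
    and every gradient taken from it - is unit invariant.
    """
    peak_u_index = int(np.argmax(series.U))
    return ULnALoop(
        lnA=series.lnA(), U=series.U.copy(), foot=foot, peak_u_index=peak_u_index
    )


def _window_samples(min_len_ms: float, dt_ms: float) -> int:
    # a window of duration min_len_ms spans min_len_ms/dt intervals + 1 sample
    return max(3, int(round(min_len_ms / dt_ms)) + 1)


def select_linear_window(
    loop: ULnALoop,
    min_len_ms: float = 20.0,
    dt_ms: float = 1.0,
    search_end: int | None = None,
) -> tuple[tuple[int, int], float]:
    """Pick the early-systolic window where the loop is most nearly linear.

    All contiguous windows starting at or after the foot, ending at or before
    ``search_end`` (default: the peak-velocity sample, after which reflections
    are expected), and at least ``min_len_ms`` long are scored by the
    r-squared of the U-on-lnA least-squares line; the highest r-squared wins,
    with ties (within :data:`R2_TIE_TOL`) resolved to the longest window and
    then the earliest start.  The minimum length rule prevents degenerate
    near-two-point windows from scoring a perfect fit.

    Returns ``((start, end), r2)`` with inclusive sample indices.
    """
    end_cap = loop.peak_u_index if search_end is None else min(search_end, len(loop) - 1)
    s0 = loop.foot.index
    span = end_cap - s0 + 1
    min_len = _window_samples(min_len_ms, dt_ms)
    if span < min_len:
        raise EstimationError(
            f"search span has {span} samples; at least {min_len} required "
            f"for a {min_len_ms:g} ms window at {dt_ms:g} ms sampling"
        )

    # centre both coordinates over the span: window variances and covariances
    # are shift invariant, and centring avoids the catastrophic cancellation
    # that raw prefix sums suffer when |lnA| >> its excursion
    x = loop.lnA[s0 : end_cap + 1]
    y = loop.U[s0 : end_cap + 1]
    x = x - x.mean()
    y = y - y.mean()
    m = len(x)

    # prefix sums -> moments of every contiguous window in O(m^2) memory
    cx = np.concatenate(([0.0], np.cumsum(x)))
    cy = np.concatenate(([0.0], np.cumsum(y)))
    cxx = np.concatenate(([0.0], np.cumsum(x * x)))
    cyy = np.concatenate(([0.0], np.cumsum(y * y)))
    cxy = np.concatenate(([0.0], np.cumsum(x * y)))

    starts, ends = np.triu_indices(m, k=min_len - 1)
    n = (ends - starts + 1).astype(float)
    sx = cx[ends + 1] - cx[starts]
    sy = cy[ends + 1] - cy[starts]
    sxx = cxx[ends + 1] - cxx[starts]
    syy = cyy[ends + 1] - cyy[starts]
    sxy = cxy[ends + 1] - cxy[starts]
    varx = sxx - sx * sx / n
    vary = syy - sy * sy / n
    cov = sxy - sx * sy / n

    with np.errstate(divide="ignore", invalid="ignore"):
        r2 = np.where(vary > 0, cov * cov / (varx * vary), 1.0)
    valid = varx > 0  # a vertical (constant-lnA) stretch has no gradient
    if not np.any(valid):
        raise EstimationError("lnA constant over the whole search span")
    r2 = np.where(valid, r2, -np.inf)
    r2 = np.minimum(r2, 1.0)  # guard rounding above 1

    best = float(np.max(r2))
    tied = np.flatnonzero(r2 >= best - R2_TIE_TOL)
    # longest window first, then earliest start
    order = np.lexsort((starts[tied], -n[tied]))
    pick = tied[order[0]]
    window = (int(starts[pick] + s0), int(ends[pick] + s0))
    return window, float(r2[pick])


def estimate_wave_speed(
    loop: ULnALoop,
    window: tuple[int, int],
    rho: float | None = None,
) -> WaveSpeedFit:
    """Wave speed as the OLS gradient dU/dlnA within the selected window.

    OLS of U on lnA (not orthogonal regression) follows the loop-gradient
    convention of the P-U loop literature.  The slope is invariant to area
    unit rescaling (additive lnA shift) and to constant velocity offsets.
    When ``rho`` (blood density, kg/m^3) is given, the Bramwell-Hill
    distensibility D = 1/(rho c^2) [1/Pa] is reported as well.
    """
    s, e = window
    x = loop.lnA[s : e + 1]
    y = loop.U[s : e + 1]
    if len(x) < 3:
        raise EstimationError(f"window [{s}, {e}] too short to fit")
    xm = x - x.mean()
    ym = y - y.mean()
    sxx = float(xm @ xm)
    if sxx <= 0:
        raise EstimationError("zero lnA variance in window (vertical loop)")
    syy = float(ym @ ym)
    sxy = float(xm @ ym)
    c = sxy / sxx
    r2 = 1.0 if syy == 0 else min(1.0, sxy * sxy / (sxx * syy))
    dist = None
    if rho is not None:
        if c <= 0:
            raise EstimationError(f"non-physiologic wave speed {c:g} m/s")
        dist = 1.0 / (rho * c * c)
    return WaveSpeedFit(c=float(c), window=(s, e), r2=float(r2), distensibility=dist)


def fit_wave_speed(
    series: WaveformSeries,
    foot: FootIndex,
    min_len_ms: float = 20.0,
    rho: float | None = None,
) -> WaveSpeedFit:
    """Convenience wrapper: loop construction, window selection, estimation."""
    loop = build_loop(series, foot)
    window, _ = select_linear_window(loop, min_len_ms=min_len_ms, dt_ms=series.dt)
    return estimate_wave_speed(loop, window, rho=rho)
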