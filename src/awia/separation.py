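"""Forward/backward wavefront separation of velocity and log-area increments.

Waves are treated as summations of incremental wavefronts.  Each observed
increment is the sum of a forward (+, away from the heart) and a backward
(-, toward the heart) component::

    dU    = dU+ + dU-
    dlnA  = dlnA+ + dlnA-

and unidirectional wavefronts obey the area form of the waterhammer
equation ``dU+- = +-c * dlnA+-``.  Substituting one into the other gives the
separation in closed form::

    dU+-   = (dU +- c * dlnA) / 2
    dlnA+- = (dlnA +- dU / c) / 2

A single scalar wave speed is used for the whole cycle.  Separated curves are
recovered by cumulative summation of the separated increments.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ValidationError
from .waveforms import WaveformSeries

__all__ = ["IncrementSeries", "SeparatedWaves", "differentials", "separate"]


@dataclass(frozen=True)
class IncrementSeries:
    """First differences of U and lnA over each sampling interval.

    ``dU`` [m/s] and ``dlnA`` (dimensionless) have length ``len(series) - 1``
    and align with interval midpoints; cumulative sums reproduce the original
    curves minus their initial values exactly (telescoping).
    """

    dU: np.ndarray
    dlnA: np.ndarray
    dt_ms: float
    t_mid: np.ndarray
    U0: float = 0.0
    lnA0: float = 0.0

    def __post_init__(self) -> None:
        if len(self.dU) != len(self.dlnA):
            raise ValidationError("dU and dlnA lengths differ")
        if len(self.dU) < 1:
            raise ValidationError("need at least 2 samples to form increments")

    def __len__(self) -> int:
        return len(self.dU)


@dataclass(frozen=True)
class SeparatedWaves:
    """Separated increment series and their integrated curves.

    The integration constants are assigned wholly to the forward curves
    (``U_plus`` starts at the measured U0, ``lnA_plus`` at lnA0) so that the
    backward curves start at zero - one admissible convention, recorded here
    rather than hidden.
    """

    dU_plus: np.ndarray
    dU_minus: np.ndarray
    dlnA_plus: np.ndarray
    dlnA_minus: np.ndarray
    U_plus: np.ndarray
    U_minus: np.ndarray
    lnA_plus: np.ndarray
    lnA_minus: np.ndarray
    c_used: float
    dt_ms: float
    t_mid: np.ndarray


def differentials(series: WaveformSeries) -> IncrementSeries:
    """Backward (first) differences of U and lnA at the series' sampling step.

    Increments, not derivatives: the wavefront formalism works with the change
    per sampling interval, so no centred differencing or scaling by dt is
    applied here.
    """
    if len(series) < 2:
        raise ValidationError("need at least 2 samples to form increments")
    if not series.is_uniform:
        raise ValidationError("increments require a uniformly sampled series")
    lnA = series.lnA()
    return IncrementSeries(
        dU=np.diff(series.U),
        dlnA=np.diff(lnA),
        dt_ms=series.dt,
        t_mid=0.5 * (series.t[:-1] + series.t[1:]),
        U0=float(series.U[0]),
        lnA0=float(lnA[0]),
    )


def separate(inc: IncrementSeries, c: float) -> SeparatedWaves:
    """Split increments into forward/backward components at wave speed ``c``.

    Conservation (dU+ + dU- == dU, dlnA+ + dlnA- == dlnA) holds by
    construction to machine precision for any c; the waterhammer identities
    dU+ == c*dlnA+ and dU- == -c*dlnA- follow algebraically.
    """
    if not np.isfinite(c) or c <= 0:
        raise ValidationError(f"wave speed must be finite and positive, got {c!r}")
    dU_plus = 0.5 * (inc.dU + c * inc.dlnA)
    dU_minus = 0.5 * (inc.dU - c * inc.dlnA)
    dlnA_plus = 0.5 * (inc.dlnA + inc.dU / c)
    dlnA_minus = 0.5 * (inc.dlnA - inc.dU / c)

    def integrate(d: np.ndarray, start: float) -> np.ndarray:
        out = np.empty(len(d) + 1)
        out[0] = start
        np.cumsum(d, out=out[1:])
        out[1:] += start
        return out

    return SeparatedWaves(
        dU_plus=dU_plus,
        dU_minus=dU_minus,
        dlnA_plus=dlnA_plus,
        dlnA_minus=dlnA_minus,
        U_plus=integrate(dU_plus, inc.U0),
        U_minus=integrate(dU_minus, 0.0),
        lnA_plus=integrate(dlnA_plus, inc.lnA0),
        lnA_minus=integrate(dlnA_minus, 0.0),
        c_used=float(c),
        dt_ms=inc.dt_ms,
        t_mid=inc.t_mid,
    )
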