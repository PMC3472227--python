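"""Observer-agreement statistics: two-way random-effects ICC, Bland-Altman
limits of agreement, and the unpaired t test.

These are the tools used to establish that a measurement pipeline is
reproducible across repeated readings and between observers, and that group
differences exceed measurement noise.  The ICC here is the single-measure,
absolute-agreement coefficient from a two-way random-effects ANOVA -
ICC(2,1) in the Shrout-Fleiss taxonomy - the standard choice when the
reproducibility of a single reading is in question; the average-measure
variant ICC(2,k) is available behind a flag.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Literal

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ValidationError

logger = logging.getLogger("awia")

__all__ = [
    "RatingsMatrix",
    "ICCResult",
    "BlandAltmanResult",
    "icc_two_way_random",
    "bland_altman",
    "unpaired_t",
    "ratings_from_tidy",
]


@dataclass(frozen=True)
class RatingsMatrix:
    """Subjects x raters matrix of one scalar measurement (common units)."""

    values: np.ndarray
    subjects: tuple[str, ...] = ()
    raters: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", v)
        if v.ndim != 2:
            raise ValidationError("ratings must be a 2-D subjects x raters matrix")
        n, k = v.shape
        if n < 2 or k < 2:
            raise ValidationError(
                f"need >= 2 subjects and >= 2 raters, got {n} x {k}"
            )
        if not np.all(np.isfinite(v)):
            raise ValidationError("missing or non-finite cells; complete the matrix first")


@dataclass(frozen=True)
class ICCResult:
    """ICC estimate with its 95% confidence interval and ANOVA audit trail."""

    icc: float
    ci95: tuple[float, float]
    variant: str
    ms_rows: float
    ms_cols: float
    ms_error: float
    n_subjects: int
    n_raters: int
    defined: bool = True
    note: str = ""


@dataclass(frozen=True)
class BlandAltmanResult:
    """Bias and 95% limits of agreement for paired measurements (x - y)."""

    bias: float
    loa_lower: float
    loa_upper: float
    sd_diff: float
    n: int


def ratings_from_tidy(
    df: pd.DataFrame,
    subject: str = "subject",
    rater: str = "rater",
    value: str = "value",
) -> RatingsMatrix:
    """Pivot a tidy (subject, rater, value) table into a ratings matrix.

    Subjects with any missing cell are dropped listwise and the count logged.
    """
    wide = df.pivot_table(index=subject, columns=rater, values=value, aggfunc="mean")
    complete = wide.dropna()
    dropped = len(wide) - len(complete)
    if dropped:
        logger.warning("dropped %d subject(s) with missing ratings", dropped)
    return RatingsMatrix(
        values=complete.to_numpy(),
        subjects=tuple(str(s) for s in complete.index),
        raters=tuple(str(r) for r in complete.columns),
    )


def icc_two_way_random(
    m: RatingsMatrix,
    variant: Literal["single", "average"] = "single",
    alpha: float = 0.05,
) -> ICCResult:
    """Two-way random-effects intraclass correlation with an F-based CI.

    Both subjects and raters are modelled as random samples from larger
    populations, and agreement is absolute (rater offsets count against
    agreement).  The point estimate comes from the two-way ANOVA mean
    squares; the confidence interval follows the Shrout-Fleiss / McGraw-Wong
    F-distribution construction.  An estimate at or below zero is reported as
    computed, not clipped: it indicates rater variance dominating subject
    variance.
    """
    v = m.values
    n, k = v.shape
    grand = v.mean()
    row_means = v.mean(axis=1)
    col_means = v.mean(axis=0)

    ss_rows = k * float(((row_means - grand) ** 2).sum())
    ss_cols = n * float(((col_means - grand) ** 2).sum())
    ss_total = float(((v - grand) ** 2).sum())
    # the residual SS is nonnegative by construction; guard float cancellation
    ss_err = max(ss_total - ss_rows - ss_cols, 0.0)

    ms_rows = ss_rows / (n - 1)
    ms_cols = ss_cols / (k - 1)
    ms_err = ss_err / ((n - 1) * (k - 1))

    if ss_total <= 0:
        return ICCResult(
            icc=float("nan"),
            ci95=(float("nan"), float("nan")),
            variant=variant,
            ms_rows=ms_rows,
            ms_cols=ms_cols,
            ms_error=ms_err,
            n_subjects=n,
            n_raters=k,
            defined=False,
            note="zero total variance: ICC undefined",
        )

    if variant == "single":
        denom = ms_rows + (k - 1) * ms_err + k * (ms_cols - ms_err) / n
        icc = (ms_rows - ms_err) / denom if denom != 0 else float("nan")
    elif variant == "average":
        denom = ms_rows + (ms_cols - ms_err) / n
        icc = (ms_rows - ms_err) / denom if denom != 0 else float("nan")
    else:
        raise ValidationError(f"unknown ICC variant {variant!r}")

    # Shrout-Fleiss confidence interval for the single-measure coefficient;
    # the average-measure interval is the Spearman-Brown transform of it.
    note = ""
    if not np.isfinite(icc):
        ci = (float("nan"), float("nan"))
        note = "degenerate variance structure"
    else:
        icc1 = icc if variant == "single" else icc / (k - (k - 1) * icc)
        if ms_err == 0:
            ci = (icc, icc)  # perfect within-cell agreement
        else:
            a = k * icc1 / (n * (1.0 - icc1)) if icc1 < 1 else np.inf
            b = 1.0 + k * icc1 * (n - 1) / (n * (1.0 - icc1)) if icc1 < 1 else np.inf
            if np.isinf(a) or np.isinf(b):
                ci = (icc, icc)
            else:
                num = (a * ms_cols + b * ms_err) ** 2
                den = (a * ms_cols) ** 2 / (k - 1) + (b * ms_err) ** 2 / (
                    (n - 1) * (k - 1)
                )
                vdf = num / den
                f_low = stats.f.ppf(1 - alpha / 2, n - 1, vdf)
                f_up = stats.f.ppf(1 - alpha / 2, vdf, n - 1)
                lower = (
                    n * (ms_rows - f_low * ms_err)
                    / (f_low * (k * ms_cols + (k * n - k - n) * ms_err) + n * ms_rows)
                )
                upper = (
                    n * (f_up * ms_rows - ms_err)
                    / (k * ms_cols + (k * n - k - n) * ms_err + n * f_up * ms_rows)
                )
                if variant == "average":
                    sb = lambda r: k * r / (1.0 + (k - 1) * r)  # noqa: E731
                    lower, upper = sb(lower), sb(upper)
                ci = (float(lower), float(upper))
        if icc <= 0:
            note = "non-positive ICC: rater variance exceeds subject variance"

    return ICCResult(
        icc=float(icc),
        ci95=ci,
        variant=variant,
        ms_rows=ms_rows,
        ms_cols=ms_cols,
        ms_error=ms_err,
        n_subjects=n,
        n_raters=k,
        note=note,
    )


def bland_altman(x, y, loa_factor: float = 1.96) -> BlandAltmanResult:
    """Bias and limits of agreement for paired series, oriented as x - y.

    bias = mean(x - y); limits = bias +- 1.96 * SD(x - y) (sample SD).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValidationError(f"paired series shapes differ: {x.shape} vs {y.shape}")
    if len(x) < 2:
        raise ValidationError("need at least 2 pairs")
    d = x - y
    bias = float(d.mean())
    sd = float(d.std(ddof=1))
    return BlandAltmanResult(
        bias=bias,
        loa_lower=bias - loa_factor * sd,
        loa_upper=bias + loa_factor * sd,
        sd_diff=sd,
        n=len(x),
    )


def unpaired_t(x, y, equal_var: bool = True) -> tuple[float, float]:
    """Two-sided unpaired t test; Welch's correction via ``equal_var=False``."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise ValidationError("each sample needs at least 2 values")
    if np.allclose(x.std(ddof=1), 0) and np.allclose(y.std(ddof=1), 0) and np.isclose(
        x.mean(), y.mean()
    ):
        raise ValidationError("both samples are constant and equal: t undefined")
    res = stats.ttest_ind(x, y, equal_var=equal_var)
    return float(res.statistic), float(res.pvalue)
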