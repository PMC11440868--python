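"""Through-origin calibration fits and the dose-per-cumulated-activity factor.

Two regressions anchor the method: absorbed dose (Gy) against administered
activity (MBq), and time-integrated activity (MBq.h) against administered
activity (MBq).  Both are fitted with the intercept forced through the origin
(zero activity deposits zero dose and integrates to zero), and their slope
ratio is the conversion factor C in Gy per MBq.h.

For a forced-origin fit the conventional centered R-squared is not meaningful;
the UNCENTERED convention ``1 - SS_res / sum(y^2)`` is used throughout.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = ["CalibrationFit", "ConversionFactor", "fit_through_origin", "derive_conversion_factor"]


@dataclass(frozen=True)
class CalibrationFit:
    """Result of a zero-intercept least-squares fit y = slope * x."""

    slope: float
    r2_uncentered: float
    n: int
    stderr: float
    residuals: np.ndarray

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ValueError("a calibration fit needs at least two points")
        if not math.isfinite(self.slope):
            raise ValueError("slope must be finite")


@dataclass(frozen=True)
class ConversionFactor:
    """Dose per unit cumulated activity, Gy/MBq.h, with its provenance."""

    value: float
    dose_per_activity: float  # Gy/MBq slope it came from
    tia_per_activity: float   # MBq.h/MBq slope it came from

    def __post_init__(self) -> None:
        if self.value <= 0:
            raise ValueError("conversion factor must be positive")


def fit_through_origin(x, y, weights=None) -> CalibrationFit:
    """Least-squares line through the origin.

    slope = sum(x*y) / sum(x^2) (optionally weighted); the reported
    R-squared is the uncentered form ``1 - SS_res / sum(y^2)`` appropriate
    for a forced origin.  The slope standard error is the usual residual-based
    estimate with n-1 degrees of freedom.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be matched 1-D sequences")
    n = x.size
    if n < 2:
        raise ValueError("at least two points are required")
    if np.allclose(x, 0.0):
        raise ValueError("degenerate input: all predictor values are zero")
    w = np.ones_like(x) if weights is None else np.asarray(weights, dtype=float)
    sxx = float(np.sum(w * x * x))
    slope = float(np.sum(w * x * y)) / sxx
    resid = y - slope * x
    ss_res = float(np.sum(w * resid * resid))
    ss_tot = float(np.sum(w * y * y))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    stderr = math.sqrt(ss_res / ((n - 1) * sxx)) if n > 1 else float("nan")
    return CalibrationFit(slope=slope, r2_uncentered=r2, n=n, stderr=stderr, residuals=resid)


def derive_conversion_factor(
    dose_per_activity: float, tia_per_activity: float
) -> ConversionFactor:
    """C = (Gy/MBq slope) / (MBq.h/MBq slope), in Gy per MBq.h."""
    if dose_per_activity <= 0 or tia_per_activity <= 0:
        raise ValueError("both calibration slopes must be positive")
    return ConversionFactor(
        value=dose_per_activity / tia_per_activity,
        dose_per_activity=dose_per_activity,
        tia_per_activity=tia_per_activity,
    )
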