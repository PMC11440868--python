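"""Radionuclide physical decay, activity time courses and cumulated activity.

Internal time unit is minutes (the unit of the laboratory protocols); cumulated
(time-integrated) activity is reported in MBq.h, the conventional unit of the
MIRD formalism.  Conversion between the two happens only at the reporting
boundary of each function.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "Radionuclide",
    "F18",
    "ActivityTimeCourse",
    "activity_at",
    "cumulated_activity_analytic",
    "cumulated_activity_trapezoid",
    "read_tac_csv",
    "write_tac_csv",
]

LN2 = math.log(2.0)


@dataclass(frozen=True)
class Radionuclide:
    """Physical decay data for a positron emitter.

    Parameters
    ----------
    name : str
        Nuclide label, e.g. ``"F-18"``.
    half_life_min : float
        Physical half-life in minutes. Must be positive.
    positron_branching : float
        Fraction of decays emitting a positron, in [0, 1].
    mean_positron_energy_kev : float
        Mean (not endpoint) kinetic energy of the emitted positron, keV.

    The decay constant ``lambda = ln 2 / T_half`` is always derived from the
    half-life, never stored separately.
    """

    name: str
    half_life_min: float
    positron_branching: float = 1.0
    mean_positron_energy_kev: float = 0.0

    def __post_init__(self) -> None:
        if self.half_life_min <= 0:
            raise ValueError(f"half-life must be positive, got {self.half_life_min}")
        if not 0.0 <= self.positron_branching <= 1.0:
            raise ValueError(
                f"positron branching must lie in [0, 1], got {self.positron_branching}"
            )

    @property
    def decay_constant_per_min(self) -> float:
        return LN2 / self.half_life_min

    @property
    def decay_constant_per_h(self) -> float:
        return 60.0 * LN2 / self.half_life_min

    @property
    def decay_constant_per_s(self) -> float:
        return LN2 / (60.0 * self.half_life_min)

    @property
    def half_life_h(self) -> float:
        return self.half_life_min / 60.0


#: Fluorine-18.  T1/2 = 109.77 min, beta+ branching 96.86 %, mean positron
#: energy 249.8 keV (standard physical data; drop-in replacements for other
#: emitters such as C-11 or Ga-68 are constructed the same way).
F18 = Radionuclide(
    name="F-18",
    half_life_min=109.77,
    positron_branching=0.9686,
    mean_positron_energy_kev=249.8,
)


def activity_at(a0: float, t_min: float, nuclide: Radionuclide = F18) -> float:
    """Activity (MBq) after ``t_min`` minutes of pure physical decay.

    A(t) = a0 * 2**(-t / T_half).
    """
    if a0 < 0:
        raise ValueError(f"initial activity must be non-negative, got {a0}")
    if t_min < 0:
        raise ValueError(f"time must be non-negative, got {t_min}")
    return a0 * 2.0 ** (-t_min / nuclide.half_life_min)


def cumulated_activity_analytic(
    a0: float, nuclide: Radionuclide = F18, t_end_h: float = math.inf
) -> float:
    """Cumulated activity (MBq.h) of a purely decaying source.

    Integrates ``a0 * exp(-lambda t)`` from 0 to ``t_end_h`` hours:
    ``(a0 / lambda_h) * (1 - exp(-lambda_h * t_end_h))``; with the default
    ``t_end_h = inf`` this is ``a0 * T_half / ln 2``.
    """
    if a0 < 0:
        raise ValueError(f"initial activity must be non-negative, got {a0}")
    if t_end_h < 0:
        raise ValueError(f"integration horizon must be non-negative, got {t_end_h}")
    lam = nuclide.decay_constant_per_h
    if math.isinf(t_end_h):
        return a0 / lam
    return (a0 / lam) * (1.0 - math.exp(-lam * t_end_h))


@dataclass
class ActivityTimeCourse:
    """A sampled activity time course.

    times_min are minutes post-administration (strictly increasing, first
    point >= 0); activities are MBq (non-negative); ``a0`` is the
    administered/initial activity in MBq.
    """

    times_min: np.ndarray
    activities_mbq: np.ndarray
    a0: float = field(default=float("nan"))

    def __post_init__(self) -> None:
        self.times_min = np.asarray(self.times_min, dtype=float)
        self.activities_mbq = np.asarray(self.activities_mbq, dtype=float)
        if self.times_min.ndim != 1 or self.times_min.shape != self.activities_mbq.shape:
            raise ValueError("times and activities must be matched 1-D sequences")
        if self.times_min.size and self.times_min[0] < 0:
            raise ValueError("times must start at or after administration (t >= 0)")
        if np.any(np.diff(self.times_min) <= 0):
            raise ValueError("times must be strictly increasing")
        if np.any(self.activities_mbq < 0):
            raise ValueError("activities must be non-negative")
        if math.isnan(self.a0) and self.activities_mbq.size:
            self.a0 = float(self.activities_mbq[0])

    def __len__(self) -> int:
        return int(self.times_min.size)


def cumulated_activity_trapezoid(
    tac: ActivityTimeCourse,
    nuclide: Radionuclide = F18,
    extrapolate_tail: bool = False,
) -> float:
    """Trapezoid-rule cumulated activity (MBq.h) of a sampled time course.

    With ``extrapolate_tail`` the analytic tail ``A(t_last)/lambda`` is added,
    assuming the source undergoes only physical decay beyond the last sample
    (no biological elimination).
    """
    if len(tac) < 2:
        raise ValueError("at least two time points are required for integration")
    times_h = tac.times_min / 60.0
    area = float(np.trapezoid(tac.activities_mbq, times_h))
    if extrapolate_tail:
        area += float(tac.activities_mbq[-1]) / nuclide.decay_constant_per_h
    return area


def read_tac_csv(path) -> ActivityTimeCourse:
    """Read a ``time_min,activity_MBq`` CSV into an :class:`ActivityTimeCourse`."""
    df = pd.read_csv(path)
    missing = {"time_min", "activity_MBq"} - set(df.columns)
    if missing:
        raise ValueError(f"TAC file {path} lacks required columns: {sorted(missing)}")
    return ActivityTimeCourse(
        times_min=df["time_min"].to_numpy(),
        activities_mbq=df["activity_MBq"].to_numpy(),
    )


def write_tac_csv(tac: ActivityTimeCourse, path) -> None:
    pd.DataFrame(
        {"time_min": tac.times_min, "activity_MBq": tac.activities_mbq}
    ).to_csv(path, index=False)
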