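"""PET ROI quantification: phantom calibration, %IA/g and cumulated activity.

ROI series from the scanner are assumed already reconstruction-corrected
(physical decay, dead time, crystal efficiency) as the acquisition software
does; the ``decay_corrected`` flag records whether the series was
decay-corrected so the physical (uncorrected) integral can be recovered when
needed.  Tissue density defaults to 1.0 g/mL unless supplied.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .decay import ActivityTimeCourse, F18, Radionuclide, cumulated_activity_trapezoid

__all__ = [
    "PetCalibration",
    "RoiSeries",
    "phantom_calibration_factor",
    "apply_calibration",
    "to_percent_injected_activity",
    "undo_decay_correction",
    "time_integrated_activity",
    "read_roi_csv",
    "read_calibration_json",
]

ROI_UNITS = ("cps_per_mL", "MBq_per_mL", "MBq_per_g")


@dataclass(frozen=True)
class PetCalibration:
    """Scanner calibration from a uniform phantom of known activity.

    The reference phantom is a 25.7 mL cylinder containing 2.02 MBq, giving a
    true concentration of ~0.0786 MBq/mL against which the measured cps/mL is
    ratioed.
    """

    calibration_factor: float  # (MBq/mL) per (cps/mL)
    phantom_volume_ml: float = 25.7
    phantom_activity_mbq: float = 2.02

    def __post_init__(self) -> None:
        if min(self.calibration_factor, self.phantom_volume_ml, self.phantom_activity_mbq) <= 0:
            raise ValueError("calibration factor, volume and activity must be positive")


@dataclass(frozen=True)
class RoiSeries:
    """A region-of-interest time series from reconstructed PET images."""

    roi_id: str
    times_min: np.ndarray
    values: np.ndarray
    unit: str = "cps_per_mL"
    decay_corrected: bool = True

    def __post_init__(self) -> None:
        object.__setattr__(self, "times_min", np.asarray(self.times_min, dtype=float))
        object.__setattr__(self, "values", np.asarray(self.values, dtype=float))
        if self.times_min.shape != self.values.shape or self.times_min.ndim != 1:
            raise ValueError("times and values must be matched 1-D sequences")
        if np.any(np.diff(self.times_min) <= 0):
            raise ValueError("times must be strictly increasing")
        if np.any(self.values < 0):
            raise ValueError("ROI values must be non-negative")
        if self.unit not in ROI_UNITS:
            raise ValueError(f"unit must be one of {ROI_UNITS}, got {self.unit!r}")


def phantom_calibration_factor(
    cps_per_ml_measured: float,
    phantom_volume_ml: float = 25.7,
    phantom_activity_mbq: float = 2.02,
) -> PetCalibration:
    """Calibration factor (MBq/mL per cps/mL) from a phantom acquisition."""
    if cps_per_ml_measured <= 0:
        raise ValueError("measured count rate must be positive")
    if phantom_volume_ml <= 0 or phantom_activity_mbq <= 0:
        raise ValueError("phantom volume and activity must be positive")
    true_conc = phantom_activity_mbq / phantom_volume_ml
    return PetCalibration(
        calibration_factor=true_conc / cps_per_ml_measured,
        phantom_volume_ml=phantom_volume_ml,
        phantom_activity_mbq=phantom_activity_mbq,
    )


def apply_calibration(
    series: RoiSeries, calibration: PetCalibration, density_g_per_ml: float = 1.0
) -> RoiSeries:
    """Convert a raw cps/mL series to MBq/g using the phantom factor.

    Linear and invertible; density converts per-mL to per-gram (1.0 g/mL
    unless a tissue-specific value is supplied).
    """
    if series.unit != "cps_per_mL":
        raise ValueError(f"series already calibrated (unit {series.unit!r})")
    if density_g_per_ml <= 0:
        raise ValueError("density must be positive")
    values = series.values * calibration.calibration_factor / density_g_per_ml
    return replace(series, values=values, unit="MBq_per_g")


def to_percent_injected_activity(conc, injected_mbq: float):
    """Percent injected activity per gram (or per mL): 100 * conc / injected."""
    if injected_mbq <= 0:
        raise ValueError("injected activity must be positive")
    conc = np.asarray(conc, dtype=float)
    out = 100.0 * conc / injected_mbq
    return out if out.ndim else float(out)


def undo_decay_correction(series: RoiSeries, nuclide: Radionuclide = F18) -> RoiSeries:
    """Recover the physical (uncorrected) series from a decay-corrected one.

    Decay correction refers activities back to the administration time;
    multiplying by ``2**(-t/T_half)`` restores what was physically present.
    """
    if not series.decay_corrected:
        return series
    factors = 2.0 ** (-series.times_min / nuclide.half_life_min)
    return replace(series, values=series.values * factors, decay_corrected=False)


def time_integrated_activity(
    series: RoiSeries,
    nuclide: Radionuclide = F18,
    extrapolate_tail: bool = False,
) -> float:
    """Time-integrated activity in MBq.h (MBq.h/g for a per-gram series).

    Trapezoidal integration of the physical time course, with an optional
    analytic physical-decay tail beyond the last sample.  A decay-corrected
    series is first converted back to the physical one.
    """
    if series.unit == "cps_per_mL":
        raise ValueError("series must be calibrated to activity units first")
    physical = undo_decay_correction(series, nuclide)
    tac = ActivityTimeCourse(times_min=physical.times_min, activities_mbq=physical.values)
    return cumulated_activity_trapezoid(tac, nuclide, extrapolate_tail=extrapolate_tail)


def read_roi_csv(path) -> list[RoiSeries]:
    """Read ``roi_id,time_min,value,unit,decay_corrected`` rows, one series per ROI."""
    df = pd.read_csv(path)
    missing = {"roi_id", "time_min", "value", "unit", "decay_corrected"} - set(df.columns)
    if missing:
        raise ValueError(f"ROI file {path} lacks required columns: {sorted(missing)}")
    out = []
    for roi_id, grp in df.groupby("roi_id", sort=False):
        units = grp["unit"].unique()
        flags = grp["decay_corrected"].astype(bool).unique()
        if len(units) != 1 or len(flags) != 1:
            raise ValueError(f"ROI {roi_id!r} mixes units or decay-correction flags")
        grp = grp.sort_values("time_min")
        out.append(
            RoiSeries(
                roi_id=str(roi_id),
                times_min=grp["time_min"].to_numpy(),
                values=grp["value"].to_numpy(),
                unit=str(units[0]),
                decay_corrected=bool(flags[0]),
            )
        )
    return out


def read_calibration_json(path) -> PetCalibration:
    """Read ``{phantom_volume_mL, phantom_activity_MBq, measured_cps_per_mL}``."""
    with open(path) as fh:
        raw = json.load(fh)
    return phantom_calibration_factor(
        cps_per_ml_measured=float(raw["measured_cps_per_mL"]),
        phantom_volume_ml=float(raw["phantom_volume_mL"]),
        phantom_activity_mbq=float(raw["phantom_activity_MBq"]),
    )
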