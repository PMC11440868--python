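"""Fricke (ferrous sulfate) dosimeter: optical density to absorbed dose.

The absorbed dose in water is obtained from the radiation-induced change in
absorbance at 304 nm of an air-saturated 1 mM Fe2+ / 0.4 M H2SO4 solution:

    D = dOA * R_F * K_vial * K_dd * K_E / (epsG * rho * l)

with dOA the background-corrected absorbance difference, R_F the water/Fricke
dose ratio, K_* perturbation correction factors, epsG the product of the Fe3+
molar extinction coefficient and its radiation chemical yield (cm^2 J^-1),
rho the solution density (kg cm^-3) and l the optical path length (cm).  The
quotient has units J/kg = Gy.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

__all__ = [
    "FrickeConstants",
    "ODRecord",
    "CONDITIONS",
    "delta_od",
    "dose_from_delta_od",
    "delta_od_for_dose",
    "fdg_background_correct",
    "read_od_csv",
    "write_od_csv",
]

log = logging.getLogger(__name__)

#: Experimental conditions an OD record can belong to.
CONDITIONS = ("radioactive", "fdg_control", "blank")

#: epsG(Fe3+) for Co-60 gamma rays, cm^2 J^-1 (calorimetry-referenced).
EPS_G_CO60 = 3.5060
#: epsG(Fe3+) for F-18 positron irradiation, cm^2 J^-1.
EPS_G_F18 = 3.498


@dataclass(frozen=True)
class FrickeConstants:
    """The constants of the dose equation; defaults for a 1 cm quartz cuvette.

    ``eps_g`` is radiation-quality dependent (low-LET G-values are nearly
    energy independent, but the Co-60 and F-18 reference values differ
    slightly); use :meth:`for_co60` / :meth:`for_f18`, or supply an explicit
    value for another quality.
    """

    r_f: float = 1.0032          # dose(water)/dose(Fricke), dimensionless
    k_vial: float = 1.00         # vial-wall perturbation
    k_dd: float = 1.00           # field non-uniformity across the vial
    k_e: float = 1.00            # energy/temperature dependence of G(Fe3+)
    eps_g: float = EPS_G_F18     # cm^2 J^-1
    rho: float = 1.0227e-3       # kg cm^-3, Fricke solution at 25 C
    path_length_cm: float = 1.0  # cuvette optical path

    def __post_init__(self) -> None:
        for name in ("r_f", "k_vial", "k_dd", "k_e", "eps_g", "rho", "path_length_cm"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")

    @classmethod
    def for_f18(cls, **overrides) -> "FrickeConstants":
        return replace(cls(eps_g=EPS_G_F18), **overrides)

    @classmethod
    def for_co60(cls, **overrides) -> "FrickeConstants":
        return replace(cls(eps_g=EPS_G_CO60), **overrides)


@dataclass(frozen=True)
class ODRecord:
    """A single 304 nm absorbance reading.

    ``time_min`` counts from F-18-FDG addition (or from the end of an external
    irradiation); ``condition`` distinguishes the radioactive sample from the
    matched non-radioactive-FDG control and the unirradiated blank.
    """

    sample_id: str
    time_min: float
    od_304: float
    condition: str = "radioactive"

    def __post_init__(self) -> None:
        if self.time_min < 0:
            raise ValueError(f"time must be non-negative, got {self.time_min}")
        if self.od_304 < 0:
            raise ValueError(f"optical density must be non-negative, got {self.od_304}")
        if self.condition not in CONDITIONS:
            raise ValueError(
                f"condition must be one of {CONDITIONS}, got {self.condition!r}"
            )


def delta_od(sample: ODRecord, control: ODRecord, clip_negative: bool = False) -> float:
    """Background-corrected absorbance difference sample - control.

    The control must be a blank or a non-radioactive-FDG control; by default
    the signed value is returned so that measurement noise remains visible,
    with optional clipping at zero.
    """
    if sample.condition != "radioactive":
        raise ValueError(f"sample must be 'radioactive', got {sample.condition!r}")
    if control.condition not in ("blank", "fdg_control"):
        raise ValueError(
            f"control must be 'blank' or 'fdg_control', got {control.condition!r}"
        )
    d = sample.od_304 - control.od_304
    if clip_negative and d < 0:
        return 0.0
    return d


def dose_from_delta_od(doa, constants: FrickeConstants = FrickeConstants()) -> float:
    """Absorbed dose in water (Gy) from an absorbance difference.

    Strictly linear in ``doa``; a negative difference (noise at low dose)
    yields a negative dose, which is logged rather than clipped.
    """
    doa = np.asarray(doa, dtype=float)
    factor = (constants.r_f * constants.k_vial * constants.k_dd * constants.k_e) / (
        constants.eps_g * constants.rho * constants.path_length_cm
    )
    dose = doa * factor
    if np.any(np.asarray(dose) < 0):
        log.info("negative absorbance difference converted to negative dose (noise)")
    return dose if dose.ndim else float(dose)


def delta_od_for_dose(dose_gy, constants: FrickeConstants = FrickeConstants()) -> float:
    """Exact inverse of :func:`dose_from_delta_od` (absorbance per dose)."""
    dose_gy = np.asarray(dose_gy, dtype=float)
    factor = (constants.eps_g * constants.rho * constants.path_length_cm) / (
        constants.r_f * constants.k_vial * constants.k_dd * constants.k_e
    )
    doa = dose_gy * factor
    return doa if doa.ndim else float(doa)


def fdg_background_correct(dose_radio_gy: float, dose_fdg_control_gy: float) -> float:
    """Subtract the non-radioactive-FDG control dose from the radioactive one.

    Both doses must have been computed with the same constants.  Inputs are
    recorded in the log as provenance; negative results are kept (the control
    correction is small and clipping would bias low-dose noise).
    """
    corrected = dose_radio_gy - dose_fdg_control_gy
    log.info(
        "FDG background correction: %.6g Gy - %.6g Gy = %.6g Gy",
        dose_radio_gy,
        dose_fdg_control_gy,
        corrected,
    )
    return corrected


def read_od_csv(path) -> list[ODRecord]:
    """Read ``sample_id,time_min,od_304,condition`` rows into ODRecords."""
    df = pd.read_csv(path)
    missing = {"sample_id", "time_min", "od_304", "condition"} - set(df.columns)
    if missing:
        raise ValueError(f"OD file {path} lacks required columns: {sorted(missing)}")
    return [
        ODRecord(
            sample_id=str(r.sample_id),
            time_min=float(r.time_min),
            od_304=float(r.od_304),
            condition=str(r.condition),
        )
        for r in df.itertuples(index=False)
    ]


def write_od_csv(records, path) -> None:
    pd.DataFrame(
        {
            "sample_id": [r.sample_id for r in records],
            "time_min": [r.time_min for r in records],
            "od_304": [r.od_304 for r in records],
            "condition": [r.condition for r in records],
        }
    ).to_csv(path, index=False)
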