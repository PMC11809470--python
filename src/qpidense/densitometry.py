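"""Optical conversions: OPD → refractive index → dry-mass density, chamber
height calibration and deformation → growth-induced pressure.

Two referencing modes exist. Plate mode references cells to the culture
medium: n_cell = n_background + OPD/d_cell. Chamber mode references the packed
chamber to the surrounding PDMS: n_cell(P) = n_PDMS + OPD(P)/d_chamber(P),
where the signed OPD is negative whenever the interior is optically rarer
than PDMS. OPD inputs are nm, lengths μm, pressures MPa, densities mg/ml.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .config import DeformationCalibration, OpticalConstants

__all__ = [
    "HeightCalibration",
    "ChamberObservation",
    "ri_plate",
    "chamber_height_from_opd",
    "fit_height_calibration",
    "ri_chamber",
    "density_from_ri",
    "gip_from_deformation",
]

_NM_PER_UM = 1000.0
_MG_PER_G = 1000.0


@dataclass(frozen=True)
class HeightCalibration:
    """Linear chamber-height model d_chamber(P) = height0 + slope·P (μm, MPa).

    Fitted from hydraulically pressurised, medium-filled chambers; ``cov`` is
    the OLS covariance of (height0, slope) and ``pressure_range`` the fitted
    pressure span — predictions outside it warn and extrapolate.
    """

    height0_um: float
    slope_um_per_mpa: float
    cov: np.ndarray
    pressure_range: tuple[float, float]
    n_points: int
    resid_sd_um: float

    def predict(self, pressure_mpa: float, warn_extrapolation: bool = True) -> float:
        lo, hi = self.pressure_range
        if warn_extrapolation and not (lo <= pressure_mpa <= hi):
            warnings.warn(
                f"pressure {pressure_mpa:.3g} MPa outside calibrated range "
                f"[{lo:.3g}, {hi:.3g}]; extrapolating chamber height",
                stacklevel=2,
            )
        d = self.height0_um + self.slope_um_per_mpa * pressure_mpa
        if d <= 0:
            raise ValueError(f"calibration predicts non-positive height at {pressure_mpa} MPa")
        return d


@dataclass
class ChamberObservation:
    """One pressurised chamber: GIP, signed mean OPD vs PDMS, derived RI/density.

    ``underestimated`` flags unpressurised (GIP = 0) chambers where loose cell
    packing dilutes the interior RI with culture medium; such points are
    excluded from inference by default.
    """

    gip_mpa: float
    mean_opd_vs_pdms_nm: float
    chamber_height_um: float | None = None
    ri: float | None = None
    density_mg_ml: float | None = None
    underestimated: bool = False


def ri_plate(opd_stat_nm: float, d_cell_um: float, n_background: float) -> float:
    """Plate-mode RI: n_cell = n_background + OPD/d_cell (OPD nm, d_cell μm)."""
    if d_cell_um <= 0:
        raise ValueError(f"cell height must be > 0, got {d_cell_um}")
    return n_background + (opd_stat_nm / _NM_PER_UM) / d_cell_um


def chamber_height_from_opd(opd_nm: float, constants: OpticalConstants) -> float:
    """Chamber height (μm) from the OPD of a medium-filled chamber vs PDMS.

    d_chamber = |OPD|/(n_PDMS − n_media); the magnitude is used since the
    medium-filled chamber reads negative against the optically denser PDMS.
    """
    denom = constants.n_pdms - constants.n_media
    if denom <= 0:
        raise ValueError("n_pdms must exceed n_media for height calibration")
    return abs(opd_nm) / _NM_PER_UM / denom


def fit_height_calibration(
    table: pd.DataFrame,
    constants: OpticalConstants,
    pressure_col: str = "pressure_mpa",
    opd_col: str = "opd_nm",
) -> HeightCalibration:
    """OLS line through (hydraulic pressure, chamber height from OPD).

    ``table`` holds one row per hydraulic calibration point. Requires at least
    3 distinct pressures; heights are obtained via ``chamber_height_from_opd``.
    """
    for col in (pressure_col, opd_col):
        if col not in table.columns:
            raise ValueError(f"calibration table is missing column {col!r}")
    p = table[pressure_col].to_numpy(dtype=float)
    heights = np.array([chamber_height_from_opd(o, constants)
                        for o in table[opd_col].to_numpy(dtype=float)])
    if np.unique(p).size < 3:
        raise ValueError("height calibration needs >= 3 distinct pressures")
    X = sm.add_constant(p)
    fit = sm.OLS(heights, X).fit()
    return HeightCalibration(
        height0_um=float(fit.params[0]),
        slope_um_per_mpa=float(fit.params[1]),
        cov=np.asarray(fit.cov_params()),
        pressure_range=(float(p.min()), float(p.max())),
        n_points=int(p.size),
        resid_sd_um=float(np.sqrt(fit.mse_resid)) if p.size > 2 else 0.0,
    )


def ri_chamber(
    mean_opd_vs_pdms_nm: float,
    gip_mpa: float,
    calib: HeightCalibration,
    constants: OpticalConstants,
) -> float:
    """Chamber-mode RI: n_cell(P) = n_PDMS + OPD(P)/d_chamber(P).

    The OPD is signed (negative while the interior is rarer than PDMS); the
    chamber height at this pressure comes from the hydraulic calibration.
    """
    d_um = calib.predict(gip_mpa)
    return constants.n_pdms + (mean_opd_vs_pdms_nm / _NM_PER_UM) / d_um


def density_from_ri(ri: float, baseline: float, alpha_ml_per_g: float = 0.190) -> float:
    """Dry-mass density ρ = (n_cell − baseline)/α, in mg/ml.

    ``baseline`` is the reference RI of the linear mixing relation
    n_cell = baseline + α·ρ (culture medium by default; water optionally).
    Negative densities are returned as-is — they flag RI below baseline.
    """
    if alpha_ml_per_g <= 0:
        raise ValueError(f"refractive increment must be > 0, got {alpha_ml_per_g}")
    return (ri - baseline) / alpha_ml_per_g * _MG_PER_G


def gip_from_deformation(delta_w_um: float, calib: DeformationCalibration | None = None) -> float:
    """Growth-induced pressure (MPa) from lateral chamber-wall deformation (μm)."""
    if calib is None:
        calib = DeformationCalibration()
    if delta_w_um < 0:
        raise ValueError(f"wall deformation must be >= 0, got {delta_w_um}")
    return delta_w_um / calib.k
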