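"""Linear inference: RI (or density) versus growth-induced pressure, and the
nominal intracellular osmotic pressure by inverse extrapolation.

The model is an ordinary-least-squares line response = a + b·P. Extrapolating
the fitted line down to the refractive index of water (the point where the
cell would be "empty" of macromolecules and its osmotic pressure null) gives
the pressure P_nwater = (n_water − a)/b; the nominal intracellular osmotic
pressure at zero growth-induced pressure is Π_c0 = −P_nwater = (a − n_water)/b.
Its 95% interval comes from a first-order delta method or from case-resampling
bootstrap (the default for headline numbers).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import statsmodels.api as sm
from scipy import stats

from .config import OpticalConstants
from .densitometry import ChamberObservation, density_from_ri

__all__ = [
    "LinearFit",
    "NominalPressureEstimate",
    "ProportionalityResult",
    "fit_ri_vs_gip",
    "nominal_pressure",
    "proportionality_check",
]


@dataclass(frozen=True)
class LinearFit:
    """OLS line response = intercept + slope·pressure, with its covariance
    and the fitted points (kept for bootstrap resampling)."""

    intercept: float
    slope: float
    cov: np.ndarray  # 2x2, order (intercept, slope)
    n_points: int
    resid_sd: float
    x: np.ndarray
    y: np.ndarray

    def __post_init__(self) -> None:
        c = np.asarray(self.cov)
        if c.shape != (2, 2) or not np.allclose(c, c.T, atol=1e-12):
            raise ValueError("covariance must be a symmetric 2x2 matrix")


@dataclass(frozen=True)
class NominalPressureEstimate:
    """Π_c0 (MPa) with a 95% interval; p_nwater = −Π_c0 is the signed
    pressure at which the fitted response reaches the water level."""

    pi_c0_mpa: float
    ci95_mpa: tuple[float, float]
    method: str  # "delta" or "bootstrap"
    seed: int | None = None

    @property
    def p_nwater_mpa(self) -> float:
        return -self.pi_c0_mpa


def _ols_line(x: np.ndarray, y: np.ndarray) -> LinearFit:
    X = sm.add_constant(x)
    fit = sm.OLS(y, X).fit()
    return LinearFit(
        intercept=float(fit.params[0]),
        slope=float(fit.params[1]),
        cov=np.asarray(fit.cov_params()),
        n_points=int(x.size),
        resid_sd=float(np.sqrt(fit.mse_resid)) if x.size > 2 else 0.0,
        x=np.asarray(x, dtype=float),
        y=np.asarray(y, dtype=float),
    )


def fit_ri_vs_gip(
    observations: list[ChamberObservation],
    anchor_point: tuple[float, float] | None = None,
    exclude_flagged: bool = True,
    response: str = "ri",
) -> LinearFit:
    """OLS fit of the chamber response (RI or density) against GIP.

    Flagged (underestimated, loosely packed GIP = 0) observations are dropped
    when ``exclude_flagged``; ``anchor_point`` — typically the plate-mode
    measurement at P = 0 — enters as an ordinary unweighted point. Requires
    at least 3 usable points spanning more than one pressure.
    """
    attr = {"ri": "ri", "density": "density_mg_ml"}.get(response)
    if attr is None:
        raise ValueError(f"response must be 'ri' or 'density', got {response!r}")
    xs, ys = [], []
    for obs in observations:
        if exclude_flagged and obs.underestimated:
            continue
        value = getattr(obs, attr)
        if value is None:
            raise ValueError(f"observation at {obs.gip_mpa} MPa has no {response} value")
        xs.append(obs.gip_mpa)
        ys.append(value)
    if anchor_point is not None:
        xs.append(anchor_point[0])
        ys.append(anchor_point[1])
    x = np.asarray(xs, dtype=float)
    y = np.asarray(ys, dtype=float)
    if x.size < 3:
        raise ValueError(f"need >= 3 usable points, have {x.size}")
    if np.unique(x).size < 2:
        raise ValueError("all pressures identical; slope is unidentifiable")
    return _ols_line(x, y)


def _water_level(response: str, constants: OpticalConstants, baseline: float | None) -> float:
    """The response value at which the cell would be 'empty': RI of water, or
    the dry-mass density corresponding to it under the chosen baseline."""
    if response == "ri":
        return constants.n_water
    if response == "density":
        base = constants.n_media if baseline is None else baseline
        return density_from_ri(constants.n_water, base, constants.alpha)
    raise ValueError(f"response must be 'ri' or 'density', got {response!r}")


def nominal_pressure(
    fit: LinearFit,
    constants: OpticalConstants,
    method: str = "bootstrap",
    n_boot: int = 2000,
    seed: int | None = None,
    response: str = "ri",
    baseline: float | None = None,
) -> NominalPressureEstimate:
    """Estimate Π_c0 = (a − water_level)/b from a fitted response-vs-GIP line.

    delta: first-order propagation of the OLS covariance through the ratio,
    normal 95% interval. bootstrap: case-resampling of the fitted points
    (seeded; n_boot ≥ 2000 recommended), percentile 95% interval. Since
    density is an affine function of RI, Π_c0 is identical for both responses.
    """
    if fit.slope <= 0:
        raise ValueError(
            f"fitted slope {fit.slope:.4g} is not positive; extrapolation to the "
            "water level is undefined in the model's direction"
        )
    level = _water_level(response, constants, baseline)
    a, b = fit.intercept, fit.slope
    pi_c0 = (a - level) / b

    if method == "delta":
        grad = np.array([1.0 / b, -(a - level) / b**2])
        var = float(grad @ fit.cov @ grad)
        half = stats.norm.ppf(0.975) * np.sqrt(max(var, 0.0))
        ci = (pi_c0 - half, pi_c0 + half)
        return NominalPressureEstimate(pi_c0_mpa=pi_c0, ci95_mpa=ci, method="delta")

    if method == "bootstrap":
        if seed is None:
            raise ValueError("bootstrap requires an explicit seed")
        if n_boot < 2:
            raise ValueError("n_boot must be >= 2")
        rng = np.random.default_rng(seed)
        n = fit.n_points
        idx = rng.integers(0, n, size=(n_boot, n))
        xb = fit.x[idx]
        yb = fit.y[idx]
        # closed-form per-resample OLS, vectorised over resamples
        xm = xb.mean(axis=1, keepdims=True)
        ym = yb.mean(axis=1, keepdims=True)
        sxx = ((xb - xm) ** 2).sum(axis=1)
        sxy = ((xb - xm) * (yb - ym)).sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            slope_b = sxy / sxx
            intercept_b = ym.ravel() - slope_b * xm.ravel()
            pi_b = (intercept_b - level) / slope_b
        # degenerate resamples (single pressure, or slope crossing zero under
        # resampling) carry no information about the extrapolation
        pi_b = pi_b[np.isfinite(pi_b) & (slope_b > 0)]
        if pi_b.size < max(10, n_boot // 10):
            raise ValueError("too few valid bootstrap resamples; data too degenerate")
        lo, hi = np.percentile(pi_b, [2.5, 97.5])
        ci = (min(float(lo), pi_c0), max(float(hi), pi_c0))
        return NominalPressureEstimate(pi_c0_mpa=pi_c0, ci95_mpa=ci, method="bootstrap", seed=seed)

    raise ValueError(f"method must be 'delta' or 'bootstrap', got {method!r}")


@dataclass(frozen=True)
class ProportionalityResult:
    """OLS of fluorescence on density with an intercept-zero test: the two
    quantities are 'proportional' when the intercept's 95% CI contains 0."""

    slope: float
    intercept: float
    intercept_ci95: tuple[float, float]
    proportional: bool
    n_points: int
    r_squared: float


def proportionality_check(x: np.ndarray, y: np.ndarray) -> ProportionalityResult:
    """Test whether y (fluorescence) is proportional to x (dry-mass density).

    Fits y = intercept + slope·x by OLS and reports the intercept's 95%
    confidence interval; proportionality holds when that interval contains 0.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("x and y must be paired")
    if x.size < 3:
        raise ValueError(f"need >= 3 pairs, have {x.size}")
    fit = sm.OLS(y, sm.add_constant(x)).fit()
    lo, hi = fit.conf_int(alpha=0.05)[0]
    return ProportionalityResult(
        slope=float(fit.params[1]),
        intercept=float(fit.params[0]),
        intercept_ci95=(float(lo), float(hi)),
        proportional=bool(lo <= 0.0 <= hi),
        n_points=int(x.size),
        r_squared=float(fit.rsquared),
    )
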