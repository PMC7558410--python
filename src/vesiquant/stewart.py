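"""Stewart colorimetric phospholipid assay: weighted calibration and
inverse prediction.

Phospholipids form a colored complex with ammonium ferrothiocyanate that
partitions into chloroform; its absorbance at 485 nm is linear in lipid
concentration over the working range (about 0.005-0.050 mg/mL total
lipid).  A matrix-matched calibration line (absorbance vs concentration,
weighted by the per-standard absorbance SEs) is fitted, and unknown
samples are read back through the inverted line with first-order error
propagation.  Different lipid matrices react differently (cholesterol
not at all), so each matrix gets its own curve.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import statsmodels.api as sm

__all__ = ["CalibrationCurve", "StewartPrediction", "fit_calibration", "predict_concentration"]


@dataclass(frozen=True)
class CalibrationCurve:
    """Weighted linear calibration: absorbance = slope * C + intercept."""

    concentrations: np.ndarray
    absorbances: np.ndarray
    absorbance_se: np.ndarray
    slope: float
    intercept: float
    slope_se: float
    intercept_se: float
    covariance: np.ndarray  # 2x2, order (intercept, slope)
    r_squared: float
    composition: str = ""

    @property
    def valid_range(self) -> tuple[float, float]:
        """Concentration range spanned by the standards."""
        return float(self.concentrations.min()), float(self.concentrations.max())


@dataclass(frozen=True)
class StewartPrediction:
    concentration_mg_ml: float
    se: float
    extrapolated: bool


def fit_calibration(
    concentrations,
    absorbances,
    absorbance_se=None,
    composition: str = "",
    force_origin: bool = False,
) -> CalibrationCurve:
    """Weighted linear least-squares fit of absorbance on concentration.

    Weights are proportional to 1/SE^2; with ``absorbance_se=None`` (or
    all-equal SEs) the fit reduces to ordinary least squares.  The line is
    not forced through the origin by default (Beer-Lambert linearity with
    a free blank); ``force_origin=True`` pins the intercept at 0.
    """
    c = np.asarray(concentrations, dtype=float)
    a = np.asarray(absorbances, dtype=float)
    if c.ndim != 1 or c.size != a.size:
        raise ValueError("concentrations and absorbances must be 1-D of equal length")
    if c.size < 3:
        raise ValueError(f"need at least 3 calibration standards, got {c.size}")
    if np.any(c <= 0):
        raise ValueError("standard concentrations must be strictly positive")
    if np.unique(c).size < (2 if force_origin else 3):
        raise ValueError("calibration standards are degenerate (too few distinct concentrations)")

    if absorbance_se is None:
        se = np.zeros_like(a)
        weights = np.ones_like(a)
    else:
        se = np.asarray(absorbance_se, dtype=float)
        if se.shape != a.shape:
            raise ValueError("absorbance_se must match absorbances in shape")
        if np.any(se < 0):
            raise ValueError("absorbance SEs must be non-negative")
        if np.any(se == 0):
            warnings.warn("zero absorbance SEs: falling back to unweighted fit", stacklevel=2)
            weights = np.ones_like(a)
        else:
            weights = 1.0 / se**2

    X = c[:, None] if force_origin else sm.add_constant(c)
    fit = sm.WLS(a, X, weights=weights).fit()

    if force_origin:
        slope = float(fit.params[0])
        slope_se = float(fit.bse[0])
        intercept, intercept_se = 0.0, 0.0
        cov = np.array([[0.0, 0.0], [0.0, fit.cov_params()[0, 0]]])
    else:
        intercept, slope = (float(p) for p in fit.params)
        intercept_se, slope_se = (float(p) for p in fit.bse)
        cov = np.asarray(fit.cov_params())
    if abs(slope) < 1e-12:
        raise ValueError("calibration slope is zero; standards do not respond")

    # R^2 on the weighted fit
    r2 = float(fit.rsquared) if not force_origin else float(fit.rsquared)

    return CalibrationCurve(
        concentrations=c,
        absorbances=a,
        absorbance_se=se,
        slope=slope,
        intercept=intercept,
        slope_se=slope_se,
        intercept_se=intercept_se,
        covariance=cov,
        r_squared=r2,
        composition=composition,
    )


def predict_concentration(
    curve: CalibrationCurve,
    abs_mean: float,
    abs_se: float = 0.0,
    dilution: float = 1.0,
) -> StewartPrediction:
    """Invert the calibration line for an unknown sample.

    C = dilution * (A - intercept) / slope, with the SE from first-order
    propagation of the absorbance SE and of the fit covariance of
    (intercept, slope).  Absorbances mapping outside the standards' range
    are flagged as extrapolation (a warning, not a failure).
    """
    if abs(curve.slope) < 1e-12:
        raise ValueError("calibration slope is zero; cannot invert")
    if dilution <= 0:
        raise ValueError("dilution must be positive")
    c0 = (abs_mean - curve.intercept) / curve.slope
    conc = dilution * c0

    lo, hi = curve.valid_range
    extrapolated = not (lo <= c0 <= hi)
    if extrapolated:
        warnings.warn(
            f"absorbance {abs_mean:.4g} maps to {c0:.4g} mg/mL, outside the "
            f"calibrated range [{lo:.4g}, {hi:.4g}] mg/mL",
            stacklevel=2,
        )

    # gradient wrt (A, intercept, slope)
    dA = dilution / curve.slope
    grad_fit = np.array([-dilution / curve.slope, -conc / curve.slope])
    var = (dA * abs_se) ** 2 + float(grad_fit @ curve.covariance @ grad_fit)
    return StewartPrediction(concentration_mg_ml=conc, se=math.sqrt(max(var, 0.0)),
                             extrapolated=extrapolated)
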