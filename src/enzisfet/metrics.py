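"""Assay arithmetic and regression evaluation.

Covers the enzyme-inhibition percentage, the 3-sigma limit-of-detection
criterion, ordinary least-squares calibration lines (pH sensitivity and
inhibition-vs-ln-concentration), and the MSE/MAE/R-squared triple used
to judge the regression models.

R-squared here is the literal variance-ratio form
``(Var(y) - MSE) / Var(y)`` with Var the population variance; it can be
negative when predictions do worse than the mean, and is reported
unclamped with a warning in that case.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .exceptions import DataError, DomainError, UsageError

__all__ = [
    "percent_inhibition",
    "InhibitionResult",
    "lod_check",
    "LODResult",
    "fit_line",
    "CalibrationLine",
    "sensitivity_acceptable",
    "evaluate",
    "Metrics",
    "molar_to_ppm",
    "CARBARYL_MOLAR_MASS",
]

#: molar mass of carbaryl (C12H11NO2), g/mol — external physical constant
CARBARYL_MOLAR_MASS = 201.22


@dataclass
class InhibitionResult:
    """One inhibition computation: the two signals and the percentage."""

    delta_vgs_ref: float
    delta_vgs_carbaryl: float
    inhibition: float


def percent_inhibition(ref: float, with_carbaryl: float) -> float:
    """Percent enzyme inhibition, |ref - with_carbaryl| / |ref| * 100.

    Carbaryl blocks AChE, fewer protons are released, and the response
    drops; the absolute value makes the readout non-negative regardless
    of sign conventions.
    """
    ref = float(ref)
    if ref == 0.0:
        raise DomainError("reference signal of 0 mV leaves inhibition undefined")
    return abs(ref - float(with_carbaryl)) / abs(ref) * 100.0


@dataclass
class LODResult:
    """3-sigma limit-of-detection check.

    ``lod_signal = 3 * sd + min_carbaryl_signal``; the sensor can claim
    the lowest tested concentration as its LOD when that signal stays
    below the no-carbaryl reference.
    """

    sd: float
    min_carbaryl_signal: float
    lod_signal: float
    reference: float
    passes: bool


def lod_check(sd: float, min_carbaryl_signal: float, reference: float) -> LODResult:
    """Apply the 3-sigma LOD criterion; ``passes`` iff lod_signal < reference."""
    sd = float(sd)
    if sd < 0:
        raise UsageError("standard deviation must be >= 0")
    lod_signal = 3.0 * sd + float(min_carbaryl_signal)
    return LODResult(
        sd=sd,
        min_carbaryl_signal=float(min_carbaryl_signal),
        lod_signal=lod_signal,
        reference=float(reference),
        passes=bool(lod_signal < float(reference)),
    )


@dataclass
class CalibrationLine:
    """An OLS calibration line y = slope * x + intercept with its R^2."""

    slope: float
    intercept: float
    r_squared: float
    x_domain: str = ""

    def predict(self, x):
        return self.slope * np.asarray(x, dtype=float) + self.intercept


def fit_line(x, y, x_domain: str = "") -> CalibrationLine:
    """Ordinary least-squares line through (x, y).

    ``x_domain`` tags what the abscissa is ("pH", "ln_concentration").
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or x.size != y.size:
        raise UsageError("need >= 2 paired points to fit a line")
    if np.ptp(x) == 0:
        raise DataError("x values are constant; the slope is undefined")
    res = stats.linregress(x, y)
    return CalibrationLine(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue**2),
        x_domain=x_domain,
    )


def sensitivity_acceptable(slope: float) -> bool:
    """True iff the pH sensitivity lies in the inclusive 45-55 mV/pH band."""
    return 45.0 <= float(slope) <= 55.0


@dataclass
class Metrics:
    """MSE, MAE, population variance of the targets, and R-squared.

    ``*_percent`` views express the normalized-unit errors multiplied by
    100, the convention the headline figures are quoted in.
    """

    mse: float
    mae: float
    var: float
    r_squared: float

    @property
    def mse_percent(self) -> float:
        return self.mse * 100.0

    @property
    def mae_percent(self) -> float:
        return self.mae * 100.0

    def to_dict(self) -> dict:
        return {
            "mse": self.mse,
            "mae": self.mae,
            "var": self.var,
            "r_squared": self.r_squared,
            "mse_percent": self.mse_percent,
            "mae_percent": self.mae_percent,
        }


def evaluate(y, yhat) -> Metrics:
    """MSE, MAE and variance-ratio R-squared of predictions against targets.

    Zero-variance targets leave R-squared undefined (NaN, with a
    warning); a negative R-squared (MSE above the target variance) is
    reported as-is.
    """
    y = np.asarray(y, dtype=float).ravel()
    yhat = np.asarray(yhat, dtype=float).ravel()
    if y.size == 0 or y.shape != yhat.shape:
        raise UsageError("evaluate needs equal-length non-empty vectors")
    resid = y - yhat
    mse = float(np.mean(resid**2))
    mae = float(np.mean(np.abs(resid)))
    var = float(np.mean((y - y.mean()) ** 2))
    if var == 0.0:
        warnings.warn("zero target variance: R^2 undefined", RuntimeWarning, stacklevel=2)
        r2 = float("nan")
    else:
        r2 = (var - mse) / var
        if r2 < 0:
            warnings.warn(
                f"R^2 = {r2:.4g} < 0: predictions are worse than the target mean",
                RuntimeWarning,
                stacklevel=2,
            )
    return Metrics(mse=mse, mae=mae, var=var, r_squared=float(r2))


def molar_to_ppm(concentration_m: float, molar_mass: float = CARBARYL_MOLAR_MASS) -> float:
    """Convert a molar concentration in water to ppm (mg/L).

    Uses carbaryl's molar mass by default; 1e-7 M -> ~0.02 ppm, below
    the 0.05 ppm maximum residue limit for carbaryl in cabbage.
    """
    if concentration_m < 0:
        raise DomainError("concentration must be >= 0")
    return concentration_m * molar_mass * 1000.0
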