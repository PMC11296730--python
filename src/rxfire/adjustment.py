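"""Burned-area adjustment by linear regression on matched pairs.

Grid-matched burned areas from the satellite product (y) and permits (x)
are related by a linear regression.  The through-origin slope
``b = sum(x*y) / sum(x^2)`` is the scaling factor applied to satellite
burned areas (a slope of 0.66 means satellite areas are reduced by 34%).
A with-intercept fit is also provided: a positive intercept indicates the
satellite product under-detects small burns.  Fits are ordinary least
squares via statsmodels; through-origin R^2 uses the uncentered total sum
of squares (the standard convention for no-intercept OLS).

Burned-area discrepancies are multiplicative — the error on a matched pair
scales with the size of the burn — so the homoscedastic OLS interval is
badly anti-conservative on these data (its variance estimate is off by
roughly the kurtosis of the regressor, a factor of e^(4 sigma_logA^2) for
log-normal burned areas).  Parameter uncertainty is therefore reported as
a 95% heteroscedasticity-robust (HC3 sandwich) confidence interval.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import statsmodels.api as sm
from sklearn.base import BaseEstimator, RegressorMixin

from .records import BurnType, RecordSet

__all__ = [
    "RegressionFit",
    "ScalingFactor",
    "ThroughOriginRegressor",
    "fit_through_origin",
    "fit_with_intercept",
    "derive_scaling_factor",
    "adjust_areas",
]


@dataclass(frozen=True)
class RegressionFit:
    """Slope/intercept summary of a linear fit with 95% CIs."""

    slope: float
    intercept: float | None
    r2: float
    n: int
    slope_ci95: tuple[float, float]
    intercept_ci95: tuple[float, float] | None
    through_origin: bool

    def to_dict(self) -> dict:
        return {
            "slope": self.slope,
            "intercept": self.intercept,
            "r2": self.r2,
            "n": self.n,
            "slope_ci95": list(self.slope_ci95),
            "intercept_ci95": None if self.intercept_ci95 is None else list(self.intercept_ci95),
            "through_origin": self.through_origin,
        }


@dataclass(frozen=True)
class ScalingFactor:
    """Multiplicative burned-area scaling with its implied percent change.

    ``percent_change = 100 * (1 - factor)``: positive is a reduction
    (factor 0.66 -> 34% reduction), negative an increase.
    """

    factor: float
    percent_change: float

    def __float__(self) -> float:
        return self.factor


class ThroughOriginRegressor(RegressorMixin, BaseEstimator):
    """No-intercept univariate least squares, y ≈ coef_ * x.

    Attributes
    ----------
    coef_ : float
    fit_ : RegressionFit
    """

    def fit(self, X, y):
        x = np.asarray(X, dtype=float).reshape(-1)
        y = np.asarray(y, dtype=float).reshape(-1)
        if len(x) != len(y):
            raise ValueError("x and y must have equal length")
        if len(x) < 2:
            raise ValueError("through-origin fit needs at least 2 pairs")
        if not np.any(x != 0):
            raise ValueError("degenerate regressor: all x are zero")
        res = sm.OLS(y, x[:, None]).fit(cov_type="HC3")
        lo, hi = res.conf_int(alpha=0.05)[0]
        self.coef_ = float(res.params[0])
        if res.uncentered_tss > 0:
            r2 = float(res.rsquared)  # uncentered for no-constant models
        else:
            r2 = 1.0  # y identically zero is fit exactly by slope 0
        self.fit_ = RegressionFit(
            slope=self.coef_,
            intercept=None,
            r2=r2,
            n=len(x),
            slope_ci95=(float(lo), float(hi)),
            intercept_ci95=None,
            through_origin=True,
        )
        return self

    def predict(self, X):
        return np.asarray(X, dtype=float).reshape(-1) * self.coef_


def fit_through_origin(pairs) -> RegressionFit:
    """Through-origin least squares on (x, y) pairs: slope = Σxy / Σx²."""
    arr = np.asarray(list(pairs), dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2:
        raise ValueError("pairs must be (x, y) tuples")
    return ThroughOriginRegressor().fit(arr[:, 0], arr[:, 1]).fit_


def fit_with_intercept(pairs) -> RegressionFit:
    """Ordinary least squares with intercept on (x, y) pairs."""
    arr = np.asarray(list(pairs), dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2:
        raise ValueError("pairs must be (x, y) tuples")
    x, y = arr[:, 0], arr[:, 1]
    if len(x) < 3:
        raise ValueError("with-intercept fit needs at least 3 pairs")
    if np.ptp(x) == 0:
        raise ValueError("degenerate regressor: x is constant")
    res = sm.OLS(y, sm.add_constant(x)).fit(cov_type="HC3")
    ci = res.conf_int(alpha=0.05)
    if res.centered_tss > 0:
        r2 = float(res.rsquared)
    else:
        r2 = 1.0 if res.ssr <= 1e-30 else 0.0  # constant y: exact fit or none
    return RegressionFit(
        slope=float(res.params[1]),
        intercept=float(res.params[0]),
        r2=r2,
        n=len(x),
        slope_ci95=(float(ci[1][0]), float(ci[1][1])),
        intercept_ci95=(float(ci[0][0]), float(ci[0][1])),
        through_origin=False,
    )


def derive_scaling_factor(fit: RegressionFit) -> ScalingFactor:
    """Scaling factor from a through-origin fit, with implied % change."""
    if not fit.through_origin:
        raise ValueError("scaling factor is defined for through-origin fits")
    if fit.slope <= 0:
        raise ValueError(f"non-positive slope {fit.slope}; no meaningful scaling factor")
    return ScalingFactor(factor=fit.slope, percent_change=100.0 * (1.0 - fit.slope))


def adjust_areas(rs: RecordSet, factor: float) -> RecordSet:
    """Multiply every PRESCRIBED record's burned area by ``factor``.

    Other burn types are untouched; the factor is recorded in provenance.
    """
    factor = float(factor)
    if factor <= 0:
        raise ValueError("scaling factor must be positive")
    df = rs.df.copy()
    mask = df["burn_type"] == BurnType.PRESCRIBED.value
    df.loc[mask, "area"] = df.loc[mask, "area"] * factor
    return rs.with_df(df, {"area_scaling_factor": factor})
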