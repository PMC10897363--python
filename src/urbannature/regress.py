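"""Per-city OLS machinery converting the area/access targets to NDVI levels.

Two simple regressions per city, both over masked 100 m cells:

* QTC conversion — NDVI regressed on the green-area fraction; evaluating
  the fitted line at green fractions 0.30 and 0.40 yields the NDVI level
  equivalent to the Quality Total Cover target, and at 0.75/0.90/1.00
  yields candidate thresholds for calling a 10 m pixel "green" on the
  NDVI scale.
* ESD conversion — the NDVI-threshold-based access fraction regressed on
  the landcover-based access fraction; evaluating at 0.70 converts the
  Equitable Spatial Distribution access target to the NDVI-based measure.

The response/predictor orientation of each regression is switchable:
the default orientation is the one that supports predicting the NDVI-side
quantity from a policy-target level, and the flipped orientation gives
the literal area-on-NDVI reading.  Fits use plain OLS (statsmodels) with
an intercept; no weights, robust errors, or spatial correction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, asdict

import numpy as np
import statsmodels.api as sm

from .grid import CityMask, Grid, masked_cells

__all__ = [
    "OlsFit",
    "QtcConversion",
    "EsdConversion",
    "ConversionResult",
    "fit_ols",
    "predict_at",
    "convert_qtc",
    "convert_esd",
    "QTC_LEVELS",
    "THRESHOLD_LEVELS",
]

#: Green-fraction levels at which the QTC fit is evaluated: the target
#: range (0.30, 0.40) plus the candidate NDVI-threshold levels.
QTC_LEVELS: tuple[float, ...] = (0.30, 0.40, 0.75, 0.90, 1.00)
THRESHOLD_LEVELS: tuple[float, ...] = (0.75, 0.90, 1.00)


class DegeneratePredictorError(ValueError):
    """The predictor has no variation; the slope is unidentifiable."""


@dataclass
class OlsFit:
    """Simple-regression summary: line, sample size, and fit quality.

    ``rmse`` is the plain root-mean-square of the residuals (denominator
    n, not n - 2): the typical distance between predicted and observed
    response values.  ``stderr_slope``/``stderr_intercept`` are the usual
    OLS standard errors, kept for uncertainty propagation in simulations.
    """

    intercept: float
    slope: float
    n: int
    r2: float
    rmse: float
    stderr_slope: float = float("nan")
    stderr_intercept: float = float("nan")

    def to_dict(self) -> dict:
        return asdict(self)

    def prediction_stderr(self, x0: float) -> float:
        """Standard error of the fitted mean response at ``x0``."""
        # var(a + b x0) = var(a) + x0^2 var(b) + 2 x0 cov(a, b);
        # recover cov from the centred form: cov(a,b) = -xbar var(b)
        return float(np.sqrt(self._pred_var(x0)))

    def _pred_var(self, x0: float) -> float:
        if not hasattr(self, "_cov_ab"):
            raise AttributeError("covariance not recorded for this fit")
        va, vb, cab = self._cov_ab
        return va + x0**2 * vb + 2 * x0 * cab


def fit_ols(x: np.ndarray, y: np.ndarray) -> OlsFit:
    """Least-squares line y = a + b x with R^2 and residual RMS.

    R^2 is 1 - SS_res/SS_tot; for a constant response (SS_tot = 0) it is
    reported as 0 with a warning rather than left undefined.
    """
    x = np.asarray(x, dtype=np.float64).ravel()
    y = np.asarray(y, dtype=np.float64).ravel()
    if x.shape != y.shape:
        raise ValueError(f"x and y lengths differ: {x.size} vs {y.size}")
    if x.size < 3:
        raise ValueError(f"need at least 3 points, got {x.size}")
    if np.ptp(x) == 0:
        raise DegeneratePredictorError(
            "degenerate predictor: x is constant, slope unidentifiable"
        )
    res = sm.OLS(y, sm.add_constant(x)).fit()
    a, b = res.params
    resid = y - (a + b * x)
    ss_res = float(resid @ resid)
    ss_tot = float(((y - y.mean()) ** 2).sum())
    if ss_tot == 0:
        warnings.warn("constant response: R^2 reported as 0", stacklevel=2)
        r2 = 0.0
    else:
        r2 = 1.0 - ss_res / ss_tot
    fit = OlsFit(
        intercept=float(a),
        slope=float(b),
        n=int(x.size),
        r2=float(r2),
        rmse=float(np.sqrt(ss_res / x.size)),
        stderr_slope=float(res.bse[1]),
        stderr_intercept=float(res.bse[0]),
    )
    cov = np.asarray(res.cov_params())
    fit._cov_ab = (float(cov[0, 0]), float(cov[1, 1]), float(cov[0, 1]))
    return fit


def predict_at(fit: OlsFit, x0: float) -> float:
    """Fitted mean response at ``x0``; extrapolations are reported as-is.

    Predictions outside the NDVI range [-1, 1] are not clamped — they are
    flagged with a warning so the caller can judge the extrapolation.
    """
    pred = fit.intercept + fit.slope * x0
    if not -1.0 <= pred <= 1.0:
        warnings.warn(
            f"prediction {pred:.3f} at x={x0} falls outside the NDVI range",
            stacklevel=2,
        )
    return float(pred)


@dataclass
class QtcConversion:
    """QTC regression with NDVI predictions at the standard levels."""

    fit: OlsFit
    predictions: dict[float, float]
    response: str  # "ndvi" (default) or "green_fraction" (literal reading)

    @property
    def ndvi_at_30(self) -> float:
        return self.predictions[0.30]

    @property
    def ndvi_at_40(self) -> float:
        return self.predictions[0.40]

    def threshold(self, level: float = 0.75) -> float:
        """NDVI 'green' threshold: the prediction at 75/90/100% green area."""
        return self.predictions[level]

    def to_dict(self) -> dict:
        return {
            "fit": self.fit.to_dict(),
            "predictions": {f"{k:.2f}": v for k, v in self.predictions.items()},
            "response": self.response,
        }


@dataclass
class EsdConversion:
    """ESD regression with the prediction at the 70% access level."""

    fit: OlsFit
    at_70: float
    response: str  # "ndvi_access" (default) or "landcover_access"

    def to_dict(self) -> dict:
        return {"fit": self.fit.to_dict(), "at_70": self.at_70,
                "response": self.response}


@dataclass
class ConversionResult:
    """Both target conversions for one city."""

    qtc: QtcConversion
    esd: EsdConversion | None
    threshold_level: float

    def to_dict(self) -> dict:
        return {
            "qtc": self.qtc.to_dict(),
            "esd": self.esd.to_dict() if self.esd is not None else None,
            "threshold_level": self.threshold_level,
        }


def convert_qtc(
    green_frac_100m: Grid,
    ndvi_100m: Grid,
    mask: CityMask,
    levels: tuple[float, ...] = QTC_LEVELS,
    response: str = "ndvi",
) -> QtcConversion:
    """Fit the per-city green-fraction/NDVI regression and predict at ``levels``.

    With ``response="ndvi"`` (default), NDVI is regressed on green
    fraction and the predictions are NDVI levels at given green-area
    fractions — the direction every target conversion uses.  With
    ``response="green_fraction"`` the orientation flips (the literal
    area-on-NDVI regression) and ``levels`` are interpreted as NDVI values.
    """
    green_frac_100m.require_aligned(ndvi_100m, "green fraction and NDVI grids")
    g = masked_cells(green_frac_100m, mask)
    v = masked_cells(ndvi_100m, mask)
    if g.size != v.size:
        # nodata patterns differ; intersect the valid sets
        keep = (
            mask.bool_array()
            & green_frac_100m.valid_mask()
            & ndvi_100m.valid_mask()
        )
        g = green_frac_100m.values[keep]
        v = ndvi_100m.values[keep]
    if response == "ndvi":
        x, y = g, v
    elif response == "green_fraction":
        x, y = v, g
    else:
        raise ValueError(f"unknown response {response!r}")
    try:
        fit = fit_ols(x, y)
    except DegeneratePredictorError as exc:
        raise DegeneratePredictorError(
            f"{exc}; the city is uniformly green or uniformly built, so no "
            "green-fraction/NDVI relationship can be estimated"
        ) from exc
    preds = {lv: predict_at(fit, lv) for lv in levels}
    return QtcConversion(fit=fit, predictions=preds, response=response)


def convert_esd(
    lc_access_100m: Grid,
    ndvi_access_100m: Grid,
    mask: CityMask,
    at: float = 0.70,
    response: str = "ndvi_access",
) -> EsdConversion:
    """Fit the access-vs-access regression and predict at the target level.

    Default orientation: the NDVI-threshold-based access fraction is the
    response and the landcover-based access fraction the predictor, so
    the prediction at 0.70 is the NDVI-based access level equivalent to
    the landcover-measured target.  ``response="landcover_access"`` flips
    the orientation.
    """
    lc_access_100m.require_aligned(ndvi_access_100m, "access grids")
    a_lc = masked_cells(lc_access_100m, mask)
    a_nv = masked_cells(ndvi_access_100m, mask)
    if response == "ndvi_access":
        x, y = a_lc, a_nv
    elif response == "landcover_access":
        x, y = a_nv, a_lc
    else:
        raise ValueError(f"unknown response {response!r}")
    fit = fit_ols(x, y)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # access fractions are not NDVI values
        pred = predict_at(fit, at)
    return EsdConversion(fit=fit, at_70=pred, response=response)
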