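"""Dose-response quantitation for activity assays.

Covers the colorimetric citrulline (COLDER) standard curve, four-parameter
logistic (4PL) fits of concentration-response data, and the half-maximal
read-outs used to summarise them: IC50 (inhibition), AC50 (activation),
K50(Ca2+) (calcium requirement for half-maximal deiminase activity), CP50
(cell penetration) and EC50 — all the same c50 parameter under different
role labels. Concentration units (nM / uM / mM / M) are carried explicitly
and converted at operation boundaries.

The 4PL model is

    y(x) = bottom + (top - bottom) / (1 + (x / c50)^h)

with bottom <= top after canonicalisation; h > 0 gives a decreasing
(inhibition-like) curve and h < 0 an increasing (activation-like) one. The
value at x = c50 is exactly (bottom + top) / 2.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats

UNIT_SCALE = {"M": 1.0, "mM": 1e-3, "uM": 1e-6, "µM": 1e-6, "nM": 1e-9,
              "pM": 1e-12}

ROLES = ("IC50", "AC50", "K50_Ca", "CP50", "EC50")


class UnitError(ValueError):
    """Incompatible or unknown concentration units."""


class FitError(RuntimeError):
    """Curve fit failed or is unidentifiable."""


@dataclass(frozen=True)
class Quantity:
    """A value with a concentration unit."""

    value: float
    unit: str

    def __post_init__(self):
        if self.unit not in UNIT_SCALE:
            raise UnitError(f"unknown unit {self.unit!r}")

    def to(self, unit: str) -> "Quantity":
        if unit not in UNIT_SCALE:
            raise UnitError(f"unknown unit {unit!r}")
        return Quantity(self.value * UNIT_SCALE[self.unit] / UNIT_SCALE[unit], unit)

    def __format__(self, spec):
        return f"{self.value:{spec or 'g'}} {self.unit}"


@dataclass(frozen=True)
class StandardCurve:
    """Linear absorbance-vs-concentration calibration."""

    slope: float
    intercept: float
    r_squared: float
    x_range: tuple

    def predict_absorbance(self, concentration: float) -> float:
        return self.slope * concentration + self.intercept

    def predict_concentration(self, absorbance: float,
                              allow_extrapolation: bool = False) -> float:
        """Inverse prediction; outside the fitted range is flagged unless allowed."""
        conc = (absorbance - self.intercept) / self.slope
        lo, hi = self.x_range
        if not allow_extrapolation and not (lo - 1e-12 <= conc <= hi + 1e-12):
            raise FitError(f"absorbance {absorbance} maps to concentration {conc:g} "
                           f"outside the fitted range [{lo:g}, {hi:g}]")
        return conc


def fit_standard_curve(concentrations, absorbances) -> StandardCurve:
    """Least-squares line through citrulline standards."""
    x = np.asarray(concentrations, float)
    y = np.asarray(absorbances, float)
    if len(x) < 3 or len(x) != len(y):
        raise FitError("need >= 3 paired standards")
    if len(np.unique(x)) < 2:
        raise FitError("standards must span >= 2 distinct concentrations")
    res = stats.linregress(x, y)
    if res.slope <= 0:
        raise FitError("standard curve slope must be positive")
    return StandardCurve(slope=res.slope, intercept=res.intercept,
                         r_squared=res.rvalue ** 2,
                         x_range=(float(x.min()), float(x.max())))


@dataclass(frozen=True)
class DoseResponseModel:
    """Fitted 4PL parameters and diagnostics."""

    bottom: float
    top: float
    c50: float
    hill: float
    residual_ss: float
    converged: bool
    identifiable: bool
    x_unit: str | None = None

    def predict(self, x):
        x = np.asarray(x, float)
        return self.bottom + (self.top - self.bottom) / (1 + (x / self.c50) ** self.hill)


def four_pl(x, bottom, top, c50, hill):
    """The four-parameter logistic response function."""
    x = np.asarray(x, float)
    return bottom + (top - bottom) / (1 + (x / c50) ** hill)


def _fit_once(x, y, p0):
    b0, t0, c0, h0 = p0

    def model(xv, b, t, logc, h):
        return b + (t - b) / (1 + (xv / 10.0 ** logc) ** h)

    import warnings

    with warnings.catch_warnings():
        # zero-residual fits legitimately have a singular covariance
        warnings.simplefilter("ignore", optimize.OptimizeWarning)
        popt, _ = optimize.curve_fit(
            model, x, y, p0=[b0, t0, np.log10(c0), h0],
            maxfev=20000, xtol=1e-14, ftol=1e-14, gtol=1e-14)
    b, t, logc, h = popt
    resid = y - model(x, *popt)
    return b, t, 10.0 ** logc, h, float(resid @ resid)


def fit_4pl(x, y, direction: str = "infer",
            x_unit: str | None = None) -> DoseResponseModel:
    """Fit a 4PL dose-response curve.

    *direction* sets the initial Hill-slope sign: ``inhibition`` (response
    falls with dose), ``activation`` (rises), or ``infer`` from the data.
    c50 is fitted on a log10 scale internally, with bottom/top initialised
    from the response extremes and c50 from the dose whose response is
    nearest mid-range. Flat data is flagged unidentifiable.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if len(x) != len(y) or len(x) < 5:
        raise FitError("need >= 5 paired points")
    if (x <= 0).any():
        raise FitError("concentrations must be positive")
    yspan = float(np.ptp(y))
    if yspan <= 1e-12 * max(1.0, float(np.max(np.abs(y)))):
        return DoseResponseModel(bottom=float(y.mean()), top=float(y.mean()),
                                 c50=float(np.sqrt(x.min() * x.max())), hill=1.0,
                                 residual_ss=0.0, converged=False,
                                 identifiable=False, x_unit=x_unit)
    if direction == "inhibition":
        h0 = 1.0
    elif direction == "activation":
        h0 = -1.0
    elif direction == "infer":
        h0 = 1.0 if np.polyfit(np.log10(x), y, 1)[0] < 0 else -1.0
    else:
        raise ValueError(f"unknown direction {direction!r}")
    mid = (y.min() + y.max()) / 2
    c0 = float(x[np.argmin(np.abs(y - mid))])
    try:
        b, t, c50, h, rss = _fit_once(x, y, (float(y.min()), float(y.max()), c0, h0))
    except RuntimeError as err:
        raise FitError(f"4PL fit did not converge: {err}") from None
    if b > t:
        # canonicalise: bottom <= top, flipping the Hill sign preserves y(x)
        b, t, h = t, b, -h
    return DoseResponseModel(bottom=float(b), top=float(t), c50=float(c50),
                             hill=float(h), residual_ss=rss, converged=True,
                             identifiable=True, x_unit=x_unit)


def half_max_readout(model: DoseResponseModel, role: str) -> Quantity:
    """Read the half-maximal concentration off a fitted model, role-labelled
    (IC50 / AC50 / K50_Ca / CP50 / EC50; for K50_Ca the dose axis is CaCl2)."""
    if role not in ROLES:
        raise ValueError(f"unknown read-out role {role!r}; expected one of {ROLES}")
    if not model.converged or not model.identifiable:
        raise FitError(f"model is not identifiable; cannot report {role}")
    return Quantity(model.c50, model.x_unit or "M")


def normalize_to_vehicle(responses, vehicle_responses):
    """Express responses relative to the mean vehicle (DMSO) control."""
    v = float(np.mean(vehicle_responses))
    if v == 0:
        raise ValueError("vehicle control mean is zero")
    return np.asarray(responses, float) / v


def fold_change(numerator, denominator, rounding: str = "none") -> float:
    """Unit-aware ratio of two concentrations (or plain numbers).

    ``rounding='nearest_int'`` reproduces printed integer fold-changes.
    """
    if isinstance(numerator, Quantity) != isinstance(denominator, Quantity):
        raise UnitError("cannot mix unitful and unitless values in a fold change")
    if isinstance(numerator, Quantity):
        num = numerator.value * UNIT_SCALE[numerator.unit]
        den = denominator.value * UNIT_SCALE[denominator.unit]
    else:
        num, den = float(numerator), float(denominator)
    if den <= 0:
        raise ValueError("denominator must be positive")
    ratio = num / den
    if rounding == "nearest_int":
        return int(round(ratio))
    if rounding != "none":
        raise ValueError(f"unknown rounding {rounding!r}")
    return ratio
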