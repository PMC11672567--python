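"""Assay analytics: 4PL dose–response, AC-SINS spectral shift, SEC calibration.

Three small pieces of assay math used when screening antibody candidates:

* **4PL** — the four-parameter logistic dose–response model
  ``y = bottom + (top − bottom) / (1 + (EC50 / c)^hill)`` fitted by least
  squares, with relative potency defined as
  ``log10(EC50_ref) / log10(EC50_sample) × 100`` (EC50 in pM);
* **AC-SINS** — the plasmon absorbance maximum of antibody-coated gold
  nanoparticles, located as the vertex ``λmax = −b/2a`` of an ordinary
  least-squares quadratic fitted over the 500–560 nm window, with the
  self-interaction readout Δλmax = λmax(sample) − λmax(control);
* **SEC** — molecular weight from a size-exclusion calibration line
  ``log10(MW) = slope · V + intercept`` over protein standards.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares

__all__ = [
    "BindingCurve",
    "FourPLFit",
    "Spectrum",
    "QuadraticPeakFit",
    "SecCalibration",
    "fit_4pl",
    "four_pl",
    "relative_potency",
    "acsins_lambda_max",
    "acsins_shift",
    "fit_sec_calibration",
    "sec_mw_estimate",
]


# ---------------------------------------------------------------------------
# 4PL dose–response
# ---------------------------------------------------------------------------

@dataclass
class BindingCurve:
    """ELISA-style dose–response data: concentrations in pM, responses in AU."""
    concentrations: np.ndarray
    responses: np.ndarray

    def __post_init__(self) -> None:
        self.concentrations = np.asarray(self.concentrations, dtype=float)
        self.responses = np.asarray(self.responses, dtype=float)
        if self.concentrations.shape != self.responses.shape:
            raise ValueError("concentrations and responses must have equal length")
        if np.any(self.concentrations <= 0):
            raise ValueError("concentrations must be positive")
        if len(np.unique(self.concentrations)) < 5:
            raise ValueError("need at least 5 distinct concentrations for a 4PL fit")


@dataclass
class FourPLFit:
    bottom: float
    top: float
    ec50: float          # pM
    hill: float
    residual_sse: float  # AU²
    converged: bool


def four_pl(conc, bottom: float, top: float, ec50: float, hill: float):
    conc = np.asarray(conc, dtype=float)
    return bottom + (top - bottom) / (1.0 + (ec50 / conc) ** hill)


def _init_4pl(curve: BindingCurve) -> tuple[float, float, float, float]:
    """Documented initialization: bottom/top from response extremes, EC50 by
    interpolating the concentration at half-maximal response, hill = ±1 by
    response direction."""
    c, y = curve.concentrations, curve.responses
    order = np.argsort(c)
    c_s, y_s = c[order], y[order]
    ascending = y_s[-1] >= y_s[0]
    bottom0, top0 = (y.min(), y.max())
    half = (bottom0 + top0) / 2.0
    # first concentration whose response crosses the half level
    crossing = c_s[np.argmin(np.abs(y_s - half))]
    return bottom0, top0, float(crossing), 1.0 if ascending else -1.0


def fit_4pl(curve: BindingCurve) -> FourPLFit:
    """Least-squares 4PL fit; flags rather than hides non-convergence.

    Fitting is done with EC50 in log space for conditioning. Degenerate
    (flat) data yields ``converged=False`` with the flat level in
    bottom/top.
    """
    c, y = curve.concentrations, curve.responses
    span = float(y.max() - y.min())
    if span == 0 or span < 1e-12 * max(1.0, abs(float(y.mean()))):
        return FourPLFit(bottom=float(y.mean()), top=float(y.mean()), ec50=float("nan"),
                         hill=0.0, residual_sse=0.0, converged=False)
    b0, t0, ec0, h0 = _init_4pl(curve)

    def residuals(p):
        bottom, top, log_ec50, hill = p
        return four_pl(c, bottom, top, 10.0 ** log_ec50, hill) - y

    result = least_squares(
        residuals, x0=[b0, t0, math.log10(ec0), h0],
        bounds=([-np.inf, -np.inf, math.log10(c.min()) - 3, -20],
                [np.inf, np.inf, math.log10(c.max()) + 3, 20]),
        method="trf")
    bottom, top, log_ec50, hill = result.x
    if top < bottom:
        # (bottom, top, hill) and (top, bottom, -hill) parametrize the same
        # curve; canonicalize to top > bottom
        bottom, top, hill = top, bottom, -hill
    sse = float(np.sum(result.fun ** 2))
    converged = bool(result.success and np.isfinite(result.x).all() and top > bottom)
    # a fit pinned to the extrapolation bounds did not localize the inflection
    if abs(log_ec50 - (math.log10(c.min()) - 3)) < 1e-6 or \
       abs(log_ec50 - (math.log10(c.max()) + 3)) < 1e-6:
        converged = False
    return FourPLFit(bottom=float(bottom), top=float(top), ec50=float(10.0 ** log_ec50),
                     hill=float(hill), residual_sse=sse, converged=converged)


def relative_potency(ec50_ref: float, ec50_sample: float) -> float:
    """Relative potency in percent: ``log10(EC50_ref)/log10(EC50_sample) × 100``.

    The log-ratio is unit dependent; the pinned convention is EC50 in pM
    with both values above 1 pM (below that the logarithm changes sign and
    the ratio inverts direction), so such inputs are refused.
    """
    if ec50_ref <= 0 or ec50_sample <= 0:
        raise ValueError("EC50 values must be positive")
    if ec50_ref <= 1.0 or ec50_sample <= 1.0:
        raise ValueError(
            "EC50 <= 1 pM is ambiguous under the log-ratio potency convention "
            "(log sign flip); supply values in pM above 1")
    return math.log10(ec50_ref) / math.log10(ec50_sample) * 100.0


# ---------------------------------------------------------------------------
# AC-SINS
# ---------------------------------------------------------------------------

@dataclass
class Spectrum:
    """Absorbance spectrum on a strictly increasing wavelength grid (nm, AU)."""
    wavelengths: np.ndarray
    absorbances: np.ndarray

    def __post_init__(self) -> None:
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        self.absorbances = np.asarray(self.absorbances, dtype=float)
        if self.wavelengths.shape != self.absorbances.shape:
            raise ValueError("wavelengths and absorbances must have equal length")
        if np.any(np.diff(self.wavelengths) <= 0):
            raise ValueError("wavelengths must be strictly increasing")


@dataclass
class QuadraticPeakFit:
    a: float
    b: float
    c: float
    lambda_max: float      # nm
    fit_window: tuple[float, float]
    valid: bool = True
    note: str = ""


def acsins_lambda_max(spectrum: Spectrum,
                      window: tuple[float, float] = (500.0, 560.0)) -> QuadraticPeakFit:
    """Locate the plasmon peak by a quadratic fit over the window.

    An ordinary least-squares parabola ``y = a x² + b x + c`` is fitted to
    the points with wavelength in the inclusive window; setting the
    derivative ``y' = 2 a x + b`` to zero gives the peak ``λmax = −b / 2a``.
    A non-concave fit (a ≥ 0) is returned flagged invalid rather than
    raising.
    """
    lo, hi = window
    mask = (spectrum.wavelengths >= lo) & (spectrum.wavelengths <= hi)
    x, y = spectrum.wavelengths[mask], spectrum.absorbances[mask]
    if len(x) < 5:
        raise ValueError(f"need at least 5 points inside the window, got {len(x)}")
    c0, b, a = np.polynomial.polynomial.polyfit(x, y, 2)
    if a >= 0:
        return QuadraticPeakFit(a=float(a), b=float(b), c=float(c0),
                                lambda_max=float("nan"), fit_window=(lo, hi),
                                valid=False, note="no concave peak (a >= 0)")
    lam = -b / (2.0 * a)
    valid = bool(lo <= lam <= hi)
    note = "" if valid else "vertex outside fit window"
    return QuadraticPeakFit(a=float(a), b=float(b), c=float(c0), lambda_max=float(lam),
                            fit_window=(lo, hi), valid=valid, note=note)


def acsins_shift(sample_fit: QuadraticPeakFit, control_fit: QuadraticPeakFit) -> float:
    """Plasmon shift Δλmax = λmax(sample) − λmax(control), in nm."""
    if not (sample_fit.valid and control_fit.valid):
        raise ValueError("cannot compute a shift from an invalid peak fit")
    return sample_fit.lambda_max - control_fit.lambda_max


# ---------------------------------------------------------------------------
# SEC calibration
# ---------------------------------------------------------------------------

@dataclass
class SecCalibration:
    """Linear calibration of log10(MW/kDa) against retention volume (mL)."""
    standards: list[tuple[float, float]]      # (MW kDa, retention mL)
    slope: float = field(init=False)
    intercept: float = field(init=False)

    def __post_init__(self) -> None:
        if len(self.standards) < 2:
            raise ValueError("need at least 2 calibration standards")
        mw = np.array([s[0] for s in self.standards], dtype=float)
        vol = np.array([s[1] for s in self.standards], dtype=float)
        if np.any(mw <= 0):
            raise ValueError("standard molecular weights must be positive")
        intercept, slope = np.polynomial.polynomial.polyfit(vol, np.log10(mw), 1)
        if slope >= 0:
            raise ValueError("calibration slope must be negative (larger proteins elute earlier)")
        self.slope, self.intercept = float(slope), float(intercept)


def fit_sec_calibration(standards: list[tuple[float, float]]) -> SecCalibration:
    return SecCalibration(standards=standards)


def sec_mw_estimate(retention_volume: float, calibration: SecCalibration,
                    extrapolation_guard: float = 0.1) -> float:
    """Molecular weight (kDa) at a retention volume from the calibration line.

    Warns when the query lies outside the standards' retention range by
    more than ``extrapolation_guard`` times the range width.
    """
    vols = [s[1] for s in calibration.standards]
    lo, hi = min(vols), max(vols)
    band = extrapolation_guard * (hi - lo)
    if retention_volume < lo - band or retention_volume > hi + band:
        warnings.warn(
            f"retention {retention_volume} mL is outside the calibrated range "
            f"[{lo}, {hi}] mL; extrapolated MW is unreliable", stacklevel=2)
    return float(10.0 ** (calibration.slope * retention_volume + calibration.intercept))
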