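"""Spectrophotometric validation-side computations.

Michaelis-Menten parameter estimation from initial-rate data (rates
derived from keto-acid absorbance via linear standard curves) and the
Salkowski-reagent tryptophan-aminotransferase turnover screen, where
indole-3-pyruvate formation is read at 530 nm against a no-keto-acid
background control.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit

__all__ = [
    "StandardCurve",
    "KineticDataset",
    "KineticFit",
    "absorbance_to_concentration",
    "fit_michaelis_menten",
    "salkowski_turnover",
]


@dataclass(frozen=True)
class StandardCurve:
    """Linear absorbance-to-concentration mapping: A = slope * C + intercept."""

    slope: float  # absorbance per concentration unit
    intercept: float = 0.0

    def __post_init__(self):
        if self.slope <= 0:
            raise ValueError("standard curve slope must be positive")


@dataclass
class KineticDataset:
    """Initial-rate data for one enzyme/substrate pair.

    ``concentrations`` in mM (increasing), ``rates`` in concentration per
    time (already standard-curve converted), ``enzyme_conc`` in the same
    units the reported kcat should be normalized by.
    """

    concentrations: np.ndarray
    rates: np.ndarray
    enzyme_conc: float = 1.0

    def __post_init__(self):
        self.concentrations = np.asarray(self.concentrations, dtype=float)
        self.rates = np.asarray(self.rates, dtype=float)
        if np.any(self.concentrations < 0) or np.any(self.rates < 0):
            raise ValueError("concentrations and rates must be non-negative")
        if len(self.concentrations) != len(self.rates):
            raise ValueError("concentrations and rates must align")


@dataclass
class KineticFit:
    vmax: float
    km: float
    kcat: float
    kcat_over_km: float
    vmax_se: float = math.nan
    km_se: float = math.nan
    flagged: bool = False
    message: str = ""


def absorbance_to_concentration(A: float, curve: StandardCurve) -> float:
    """Invert a linear standard curve; negative results floor at 0."""
    conc = (A - curve.intercept) / curve.slope
    if conc < 0:
        warnings.warn(f"absorbance {A} below curve intercept; flooring at 0")
        return 0.0
    return conc


def _mm(s, vmax, km):
    return vmax * s / (km + s)


def fit_michaelis_menten(data: KineticDataset) -> KineticFit:
    """Unweighted nonlinear least-squares fit of v = Vmax [S] / (Km + [S]).

    kcat = Vmax / [E].  The fit is flagged (not failed) when Km falls
    outside the tested concentration range or the design is degenerate
    (e.g. saturating rates only), since the estimate is then extrapolated.
    """
    s, v = data.concentrations, data.rates
    if len(np.unique(s[s > 0])) < 5:
        raise ValueError("need >= 5 distinct non-zero substrate concentrations")
    vmax0 = float(v.max())
    if vmax0 <= 0:
        return KineticFit(0.0, math.nan, 0.0, math.nan, flagged=True,
                          message="all rates zero")
    km0 = float(s[np.argmin(np.abs(v - vmax0 / 2))])
    km0 = max(km0, 1e-9)
    try:
        popt, pcov = curve_fit(_mm, s, v, p0=[vmax0, km0],
                               bounds=([0, 1e-12], [np.inf, np.inf]), maxfev=20000)
    except RuntimeError as exc:
        raise RuntimeError(f"Michaelis-Menten fit did not converge: {exc}") from exc
    vmax, km = float(popt[0]), float(popt[1])
    ses = np.sqrt(np.diag(pcov)) if np.all(np.isfinite(pcov)) else [math.nan, math.nan]
    flagged, message = False, ""
    tested = s[s > 0]
    if not (tested.min() <= km <= tested.max()):
        flagged = True
        message = "Km outside tested concentration range"
    # saturation-only designs: relative spread of rates carries no curvature
    if np.ptp(v) < 0.02 * vmax0:
        flagged = True
        message = "rates nearly constant; Km unidentifiable"
    kcat = vmax / data.enzyme_conc
    return KineticFit(vmax, km, kcat, kcat / km if km > 0 else math.nan,
                      vmax_se=float(ses[0]), km_se=float(ses[1]),
                      flagged=flagged, message=message)


def salkowski_turnover(
    A530_sample: float,
    A530_background: float,
    curve: StandardCurve,
    enzyme_conc: float,
    time: float,
) -> float:
    """Background-subtracted turnover from the 530 nm Salkowski readout.

    Converts the background-subtracted absorbance to indole-3-pyruvate
    concentration via the standard curve and normalizes per enzyme per
    time.  A sample reading below background floors at 0 with a warning.
    """
    if time <= 0 or enzyme_conc <= 0:
        raise ValueError("time and enzyme concentration must be positive")
    delta = A530_sample - A530_background
    if delta < 0:
        warnings.warn("sample absorbance below background; turnover floored at 0")
        return 0.0
    conc = (delta) / curve.slope  # background subtraction removes the intercept
    return conc / (enzyme_conc * time)
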