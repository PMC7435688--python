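"""Targeted-quantification utilities: standard curves and sterol molar ratios.

Converts integrated LC-MS responses to concentrations via a linear standard
curve (inverse prediction, with an optional dilution factor) and expresses
each sample's sterol composition as molar ratios of cholesterol,
cholestenone, and coprostanol — each concentration divided by the sum of the
three within the sample.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import scipy.stats as st

__all__ = ["StandardCurve", "fit_standard_curve", "quantify", "molar_ratios"]

STEROLS = ("cholesterol", "cholestenone", "coprostanol")


@dataclass(frozen=True)
class StandardCurve:
    slope: float
    intercept: float
    r_squared: float
    analyte: str = ""

    def __post_init__(self) -> None:
        if self.slope == 0:
            raise ValueError("a zero-slope curve is not invertible")


def fit_standard_curve(concentrations, responses, analyte: str = "") -> StandardCurve:
    """Least-squares line response = slope * concentration + intercept."""
    x = np.asarray(concentrations, dtype=float)
    y = np.asarray(responses, dtype=float)
    if x.shape != y.shape:
        raise ValueError("concentrations and responses differ in length")
    if np.unique(x).size < 2:
        raise ValueError("need at least two distinct concentrations")
    fit = st.linregress(x, y)
    return StandardCurve(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r_squared=float(fit.rvalue**2),
        analyte=analyte,
    )


def quantify(responses, curve: StandardCurve, dilution: float = 1.0):
    """Inverse prediction: (response - intercept) / slope, times the dilution factor.

    Negative predictions (responses below the curve) are returned with a
    warning, never clipped.
    """
    y = np.asarray(responses, dtype=float)
    conc = (y - curve.intercept) / curve.slope * dilution
    if (conc < 0).any():
        warnings.warn("response below the standard curve: negative concentration",
                      stacklevel=2)
    if conc.ndim == 0:
        return float(conc)
    return conc


def molar_ratios(concentrations: dict[str, float]) -> dict[str, float]:
    """Each sterol's share of the summed sterol concentration in a sample."""
    values = np.array([float(concentrations[s]) for s in STEROLS])
    if (values < 0).any():
        raise ValueError("concentrations must be non-negative")
    total = values.sum()
    if total == 0:
        raise ValueError("all concentrations are zero: molar ratios undefined")
    return dict(zip(STEROLS, values / total))
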