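"""Iron speciation from redox potential via a calibratable Nernst relation.

In acidic sulfate bioleaching liquors the Fe3+/Fe2+ couple dominates the
measured redox potential (Eh, vs SHE), so the concentration ratio
r = [Fe3+]/[Fe2+] follows a one-parameter Nernst law

    Eh = E°' + s·log10(r),      s = ln(10)·R·T/F   (in mV)

where E°' is an *effective* formal potential that absorbs activity,
ionic-strength and sulfate-complexation effects of the actual medium.
E°' is calibrated from a single (Eh, Fe(III) fraction) anchor point; the
default anchor is the mean of the two continuous-pilot steady states
(680 mV ↦ 53 % Fe(III) and 650 mV ↦ 27 % Fe(III) at 308.15 K), which agree
with each other to within 1 mV.

`NernstSpeciator` is a scikit-learn style transformer: ``fit`` calibrates
E°' from (Eh, fraction) pairs, ``transform`` maps Eh to Fe(III) fractions.
The module-level functions are thin wrappers for one-off conversions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

from .constants import DEFAULT_TEMPERATURE_K, FARADAY, GAS_CONSTANT

__all__ = [
    "RedoxCalibration",
    "IronSpeciation",
    "NernstSpeciator",
    "nernst_slope_mV",
    "ratio_from_eh",
    "eh_from_ratio",
    "fe3_fraction_from_eh",
    "calibrate_formal_potential",
    "speciate",
    "DEFAULT_CALIBRATION",
]


def nernst_slope_mV(temperature: float) -> float:
    """Nernst slope ln(10)·R·T/F in mV per decade of [Fe3+]/[Fe2+].

    ≈ 61.1 mV per decade at 308.15 K.
    """
    if temperature <= 273.15:
        raise ValueError(f"temperature must exceed 273.15 K, got {temperature}")
    return np.log(10.0) * GAS_CONSTANT * temperature / FARADAY * 1000.0


@dataclass(frozen=True)
class RedoxCalibration:
    """Effective formal potential and temperature defining the Eh ↔ Fe(III)/Fe(II) map.

    Parameters
    ----------
    formal_potential : float
        Effective midpoint potential E°' of the Fe3+/Fe2+ couple in the
        medium, mV vs SHE. At Eh = E°' the iron is 50 % Fe(III).
    temperature : float
        Absolute temperature, K. Must exceed 273.15 K.
    """

    formal_potential: float = 676.6
    temperature: float = DEFAULT_TEMPERATURE_K
    nernst_slope: float = field(init=False)

    def __post_init__(self) -> None:
        object.__setattr__(self, "nernst_slope", nernst_slope_mV(self.temperature))


#: Calibration anchored on the continuous-pilot steady states at 35 °C.
DEFAULT_CALIBRATION = RedoxCalibration()


@dataclass(frozen=True)
class IronSpeciation:
    """Total iron split into ferrous and ferric fractions, mg·L⁻¹."""

    fe_total: float
    fe2: float
    fe3: float

    def __post_init__(self) -> None:
        if min(self.fe_total, self.fe2, self.fe3) < 0:
            raise ValueError("iron concentrations must be nonnegative")
        if abs(self.fe2 + self.fe3 - self.fe_total) > 1e-9 * max(self.fe_total, 1.0):
            raise ValueError("fe2 + fe3 must equal fe_total")

    @property
    def fe3_fraction(self) -> float:
        return self.fe3 / self.fe_total if self.fe_total > 0 else 0.0


def ratio_from_eh(eh, calib: RedoxCalibration = DEFAULT_CALIBRATION):
    """[Fe3+]/[Fe2+] ratio at redox potential `eh` (mV vs SHE).

    Strictly increasing in eh; equals 1 at the formal potential and
    multiplies by 10 per Nernst-slope increment.
    """
    return 10.0 ** ((np.asarray(eh, dtype=float) - calib.formal_potential) / calib.nernst_slope)


def eh_from_ratio(r, calib: RedoxCalibration = DEFAULT_CALIBRATION):
    """Redox potential (mV vs SHE) at ratio r = [Fe3+]/[Fe2+]; inverse of `ratio_from_eh`."""
    r = np.asarray(r, dtype=float)
    if np.any(r <= 0):
        raise ValueError("ratio must be strictly positive; the potential is undefined otherwise")
    return calib.formal_potential + calib.nernst_slope * np.log10(r)


def fe3_fraction_from_eh(eh, calib: RedoxCalibration = DEFAULT_CALIBRATION):
    """Fraction of total iron present as Fe(III) at potential `eh`.

    Equals r/(1+r) with r the Nernst ratio; monotone in eh with limits 0
    and 1 at ∓∞. Computed via a logistic form stable for extreme eh.
    """
    x = (np.asarray(eh, dtype=float) - calib.formal_potential) / calib.nernst_slope * np.log(10.0)
    # r/(1+r) = 1/(1+exp(-x)) : scipy.special.expit without the import
    return 0.5 * (1.0 + np.tanh(x / 2.0))


def calibrate_formal_potential(
    eh: float, fe3_fraction: float, temperature: float = DEFAULT_TEMPERATURE_K
) -> RedoxCalibration:
    """Fix the effective formal potential from one (Eh, Fe(III) fraction) anchor.

    E°' = Eh − s·log10(f/(1−f)); the anchor is recovered exactly.
    """
    if not 0.0 < fe3_fraction < 1.0:
        raise ValueError("fe3_fraction must lie strictly between 0 and 1")
    s = nernst_slope_mV(temperature)
    e0 = eh - s * np.log10(fe3_fraction / (1.0 - fe3_fraction))
    return RedoxCalibration(formal_potential=float(e0), temperature=temperature)


def speciate(fe_total: float, eh: float, calib: RedoxCalibration = DEFAULT_CALIBRATION) -> IronSpeciation:
    """Split a total iron concentration into Fe(II)/Fe(III) at potential `eh`."""
    if fe_total < 0:
        raise ValueError("fe_total must be nonnegative")
    frac = float(fe3_fraction_from_eh(eh, calib))
    fe3 = fe_total * frac
    return IronSpeciation(fe_total=fe_total, fe2=fe_total - fe3, fe3=fe3)


class NernstSpeciator(BaseEstimator, TransformerMixin):
    """Eh → Fe(III) fraction transformer with a calibratable formal potential.

    Parameters
    ----------
    formal_potential_mV : float or None
        Effective formal potential E°', mV vs SHE. ``None`` until fitted;
        the class default 676.6 mV is the 35 °C pilot calibration.
    temperature_K : float
        Absolute temperature used for the Nernst slope.

    Attributes
    ----------
    formal_potential_ : float
        Calibrated formal potential after ``fit`` (mean over anchor points).
    calibration_ : RedoxCalibration
        The fitted calibration object.

    Examples
    --------
    >>> sp = NernstSpeciator().fit([[680.0]], [0.53])
    >>> round(float(sp.transform([[650.0]])[0]) * 100)
    27
    """

    def __init__(self, formal_potential_mV: float | None = 676.6,
                 temperature_K: float = DEFAULT_TEMPERATURE_K):
        self.formal_potential_mV = formal_potential_mV
        self.temperature_K = temperature_K

    def _as_column(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.ndim == 2 and X.shape[1] == 1:
            X = X[:, 0]
        if X.ndim != 1:
            raise ValueError("X must be a 1d array of potentials or a single column")
        return X

    def fit(self, X, y=None):
        """Calibrate E°' from potentials X (mV) and Fe(III) fractions y.

        With multiple anchors the per-anchor formal potentials are averaged.
        Without y, the configured `formal_potential_mV` is adopted as-is.
        """
        if y is None:
            if self.formal_potential_mV is None:
                raise ValueError("either y anchors or formal_potential_mV must be given")
            e0 = float(self.formal_potential_mV)
        else:
            eh = self._as_column(X)
            f = np.asarray(y, dtype=float)
            if eh.shape != f.shape:
                raise ValueError("X and y must have matching lengths")
            if np.any((f <= 0) | (f >= 1)):
                raise ValueError("fractions must lie strictly between 0 and 1")
            s = nernst_slope_mV(self.temperature_K)
            e0 = float(np.mean(eh - s * np.log10(f / (1.0 - f))))
        self.formal_potential_ = e0
        self.calibration_ = RedoxCalibration(formal_potential=e0, temperature=self.temperature_K)
        return self

    def transform(self, X) -> np.ndarray:
        """Map potentials (mV vs SHE) to Fe(III) fractions in [0, 1]."""
        if not hasattr(self, "calibration_"):
            self.fit(None)
        return np.asarray(fe3_fraction_from_eh(self._as_column(X), self.calibration_))

    def inverse_transform(self, fractions) -> np.ndarray:
        """Map Fe(III) fractions back to potentials (mV vs SHE)."""
        if not hasattr(self, "calibration_"):
            self.fit(None)
        f = np.asarray(fractions, dtype=float)
        if np.any((f <= 0) | (f >= 1)):
            raise ValueError("fractions must lie strictly between 0 and 1")
        return np.asarray(eh_from_ratio(f / (1.0 - f), self.calibration_))
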