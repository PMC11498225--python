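"""Gap-junction dye-transfer quantification via a calcein loading curve.

Donor cells are loaded with calcein-AM; after coculture, the dye
concentration reached in acceptor cells is read off a standard curve of
mean fluorescence intensity (MFI) against loading concentration.  Over the
calibrated range the response is log-linear,

    MFI = intercept + slope * log10(concentration),

so an acceptor MFI inverts to ``c = 10 ** ((MFI - intercept) / slope)``;
estimates falling below the lowest calibrated concentration are flagged as
extrapolated.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "StandardCurve",
    "ConcentrationEstimate",
    "fit_standard_curve",
    "estimate_concentration",
]


@dataclass
class StandardCurve:
    """Fitted log-linear calcein loading curve."""

    slope: float
    intercept: float
    r_squared: float
    concentrations_um: np.ndarray
    mfi: np.ndarray

    @property
    def min_concentration_um(self) -> float:
        return float(self.concentrations_um.min())

    @property
    def max_concentration_um(self) -> float:
        return float(self.concentrations_um.max())

    def predict_mfi(self, concentration_um) -> np.ndarray:
        c = np.asarray(concentration_um, dtype=float)
        return self.intercept + self.slope * np.log10(c)

    def summary(self) -> str:
        return "\n".join([
            "Calcein standard curve (MFI vs log10 concentration)",
            "---------------------------------------------------",
            f"slope       : {self.slope:.4g} MFI/decade",
            f"intercept   : {self.intercept:.4g} MFI at 1 uM",
            f"R^2         : {self.r_squared:.5f}",
            f"range       : {self.min_concentration_um:.4g} - "
            f"{self.max_concentration_um:.4g} uM "
            f"({len(self.concentrations_um)} standards)",
        ])


@dataclass
class ConcentrationEstimate:
    concentration_nm: float | None
    extrapolated: bool
    reason: str = ""


def fit_standard_curve(table) -> StandardCurve:
    """Least-squares line through (log10 concentration, MFI) standards.

    ``table`` is a DataFrame with columns ``concentration_um`` and ``mfi``
    (replicate rows per concentration are averaged) or a pair of arrays.
    Requires at least 3 distinct concentrations spanning at least one decade.
    """
    if isinstance(table, pd.DataFrame):
        grouped = table.groupby("concentration_um")["mfi"].mean()
        conc = grouped.index.to_numpy(dtype=float)
        mfi = grouped.to_numpy(dtype=float)
    else:
        conc, mfi = (np.asarray(a, dtype=float) for a in table)
    if np.any(conc <= 0):
        raise ValueError("concentrations must be positive")
    if len(np.unique(conc)) < 3:
        raise ValueError("need at least 3 distinct concentrations")
    if np.log10(conc.max() / conc.min()) < 1.0:
        raise ValueError("standards must span at least one decade")
    res = stats.linregress(np.log10(conc), mfi)
    return StandardCurve(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue ** 2),
        concentrations_um=conc,
        mfi=mfi,
    )


def estimate_concentration(
    curve: StandardCurve,
    acceptor_mfi: float,
    background_mfi: float = 0.0,
) -> ConcentrationEstimate:
    """Invert the standard curve at an acceptor-population MFI.

    The result is reported in nM.  Acceptor MFIs at or below the unstained
    background return no estimate; estimates below the lowest calibrated
    standard are flagged ``extrapolated``.
    """
    if acceptor_mfi - background_mfi <= 0:
        return ConcentrationEstimate(
            None, False, "acceptor MFI at or below background"
        )
    if curve.slope == 0:
        return ConcentrationEstimate(None, False, "flat standard curve")
    mfi = acceptor_mfi - background_mfi
    c_um = 10.0 ** ((mfi - curve.intercept) / curve.slope)
    extrapolated = bool(
        c_um < curve.min_concentration_um or c_um > curve.max_concentration_um
    )
    return ConcentrationEstimate(
        concentration_nm=float(c_um * 1e3),
        extrapolated=extrapolated,
        reason="outside calibrated range" if extrapolated else "",
    )
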