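"""Indicator-to-physiology calibrations.

Three tools: the drought curve mapping leaf water potential to PhiPSII
(steep between −0.5 and −1.0 MPa, nearly flat beyond), the linear
Fv/Fm vs total-nitrogen fit, and the Nessler standard-curve bookkeeping
that turns an OD480 reading into total nitrogen per gram dry weight.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats

#: Working points of the PhiPSII / water-potential relation:
#: 0.43 at −0.5 MPa, 0.28 at −1.0 MPa, 0.21 at −2.5 MPa.
DEFAULT_DROUGHT_ANCHORS = ((-0.5, 0.43), (-1.0, 0.28), (-2.5, 0.21))

#: Mass fraction of nitrogen in ammonium sulfate (NH4)2SO4.
N_FRACTION_AMMONIUM_SULFATE = 2 * 14.007 / 132.14


class DegenerateFitError(ValueError):
    """Raised when a fit has no usable variation in its regressor."""


@dataclass
class DroughtCurve:
    """Monotone piecewise-linear PhiPSII(water potential) relation.

    Only the quoted working points of the relation are trusted; between
    them the curve is linear, outside them it clamps to the endpoint
    value (with a warning).  Anchors are (water potential MPa, PhiPSII)
    pairs with both coordinates strictly decreasing.
    """

    anchors: tuple = DEFAULT_DROUGHT_ANCHORS

    def __post_init__(self) -> None:
        wp = [a[0] for a in self.anchors]
        phi = [a[1] for a in self.anchors]
        if len(self.anchors) < 2:
            raise ValueError("need at least two anchors")
        if any(b >= a for a, b in zip(wp, wp[1:])):
            raise ValueError("water potentials must be strictly decreasing")
        if any(b >= a for a, b in zip(phi, phi[1:])):
            raise ValueError("PhiPSII must be strictly decreasing along anchors")
        # ascending order for interpolation
        self._wp = np.array(wp[::-1])
        self._phi = np.array(phi[::-1])

    def phipsii_at(self, water_potential: float) -> float:
        """PhiPSII expected at a leaf water potential (MPa)."""
        lo, hi = self._wp[0], self._wp[-1]
        if water_potential < lo or water_potential > hi:
            warnings.warn(
                f"water potential {water_potential} MPa outside the calibrated "
                f"range [{lo}, {hi}]; clamping",
                stacklevel=2,
            )
            water_potential = float(np.clip(water_potential, lo, hi))
        return float(np.interp(water_potential, self._wp, self._phi))

    def water_potential_from_phipsii(self, phipsii: float) -> float:
        """Inverse mapping: water potential (MPa) at an observed PhiPSII."""
        lo, hi = self._phi[0], self._phi[-1]
        if phipsii < lo or phipsii > hi:
            warnings.warn(
                f"PhiPSII {phipsii} outside the calibrated range [{lo}, {hi}]; clamping",
                stacklevel=2,
            )
            phipsii = float(np.clip(phipsii, lo, hi))
        return float(np.interp(phipsii, self._phi, self._wp))


@dataclass
class LinearCalibration:
    """Ordinary least-squares indicator-vs-analyte line."""

    slope: float
    intercept: float
    r_squared: float
    n: int

    def __post_init__(self) -> None:
        if self.n < 3:
            raise ValueError("calibration needs n >= 3")
        if not 0.0 <= self.r_squared <= 1.0:
            raise ValueError("r_squared must lie in [0, 1]")

    def predict(self, x: float) -> float:
        """Indicator value expected at analyte level ``x``."""
        return self.intercept + self.slope * x

    def invert(self, y: float) -> float:
        """Analyte level estimated from an indicator value ``y``."""
        if self.slope == 0:
            raise DegenerateFitError("zero slope; cannot invert")
        return (y - self.intercept) / self.slope


def fit_nitrogen_calibration(pairs: Sequence[tuple[float, float]]) -> LinearCalibration:
    """Fit Fv/Fm against total nitrogen content by ordinary least squares.

    ``pairs`` are (total_N, fvfm) tuples (or an (n, 2) array / DataFrame
    with those columns first).  Returns the line with its coefficient of
    determination.
    """
    arr = np.asarray(pairs, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2:
        raise ValueError("pairs must be (total_N, fvfm) tuples")
    if arr.shape[0] < 3:
        raise ValueError("need at least 3 calibration pairs")
    x, y = arr[:, 0], arr[:, 1]
    if np.ptp(x) == 0:
        raise DegenerateFitError("total-N values are constant; fit is degenerate")
    res = stats.linregress(x, y)
    return LinearCalibration(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue**2),
        n=len(x),
    )


@dataclass
class NesslerAssay:
    """One Nessler total-nitrogen determination.

    Standards are 0–10 mL of a 10 mg/L ammonium-sulfate solution; the
    digested sample (``sample_mass`` g dry weight brought to
    ``digest_volume`` mL) contributes a 1 mL aliquot to the color
    reaction, read at 480 nm.
    """

    standard_od480: Sequence[float]
    sample_od480: float
    standard_volumes_ml: Sequence[float] = (0.0, 2.0, 4.0, 6.0, 8.0, 10.0)
    standard_conc_mg_l: float = 10.0  # (NH4)2SO4
    sample_mass_g: float = 0.1
    digest_volume_ml: float = 50.0
    aliquot_ml: float = 1.0

    def __post_init__(self) -> None:
        vols = np.asarray(self.standard_volumes_ml, dtype=float)
        ods = np.asarray(self.standard_od480, dtype=float)
        if len(vols) != len(ods):
            raise ValueError("one OD per standard volume required")
        if np.any(np.diff(vols) <= 0):
            raise ValueError("standard volumes must be strictly increasing")
        if np.any(ods < 0) or self.sample_od480 < 0:
            raise ValueError("absorbances must be non-negative")


def nessler_total_nitrogen(assay: NesslerAssay) -> float:
    """Total nitrogen of the sample in mg N per g dry weight.

    The standard curve is the least-squares line of OD480 against the
    nitrogen mass in each standard (ammonium-sulfate mass times the N
    mass fraction of (NH4)2SO4).  The sample's aliquot N mass is read
    off the inverted line, scaled by digest volume / aliquot volume,
    and divided by the dry sample mass.
    """
    vols = np.asarray(assay.standard_volumes_ml, dtype=float)
    ods = np.asarray(assay.standard_od480, dtype=float)
    if np.any(np.diff(ods) < 0):
        warnings.warn("standard ODs are not monotone increasing", stacklevel=2)
    if assay.sample_od480 > ods.max():
        raise ValueError(
            f"sample OD {assay.sample_od480} exceeds the top standard "
            f"({ods.max()}); dilute and re-read rather than extrapolate"
        )
    if assay.sample_od480 < ods.min():
        raise ValueError(
            f"sample OD {assay.sample_od480} below the blank ({ods.min()})"
        )
    # N mass (mg) in each standard reaction.
    n_mass = vols / 1000.0 * assay.standard_conc_mg_l * N_FRACTION_AMMONIUM_SULFATE
    res = stats.linregress(n_mass, ods)
    if res.slope == 0:
        raise DegenerateFitError("flat standard curve")
    n_aliquot_mg = (assay.sample_od480 - res.intercept) / res.slope
    n_aliquot_mg = max(n_aliquot_mg, 0.0)
    total_mg = n_aliquot_mg * assay.digest_volume_ml / assay.aliquot_ml
    return total_mg / assay.sample_mass_g
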