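"""Closed-form pixel <-> wavelength model of a grating spectrometer.

The model covers a spectrometer in which collimated light strikes a plane
grating rotated by an angle ``theta_d`` from a reference ("flat") position,
and the diffracted beam is focused by an optic of focal length ``f`` onto a
linear array detector with pixel pitch ``T``.  With all angles signed
(counterclockwise positive) the grating equation for the rotated grating
reads

    n*lambda / d' = sin(beta - theta_d) + k * sin(-alpha - theta_d)

where ``alpha`` is the half-deviation angle between the input arm and the
optical axis, ``beta`` the diffracted-ray angle with respect to the
unrotated grating normal, ``d' = d*cos(gamma)`` the effective grating
period (oblique-incidence corrected; only the product is identifiable so
only ``d'`` is modeled), ``n`` the diffraction order and ``k`` the sign of
the incident-angle term.  ``k = +1`` describes a transmission grating whose
detector sits on the straight-through (zero-order) axis; ``k = -1`` applies
to reflection geometries and to fixed transmission gratings whose detector
sits on the first-order arm, where the incident and diffracted sine terms
add.

Solving for the diffracted angle and projecting on the detector gives the
forward map (wavelength -> pixel)

    x = (f/T) * tan(theta_d + asin(u) - alpha) + C/T,
    u = n*lambda/d' - k*sin(-alpha - theta_d)

and its exact algebraic inverse (pixel -> wavelength)

    lambda = (d'/n) * ( sin(atan((x*T - C)/f) + alpha - theta_d)
                        + k*sin(-alpha - theta_d) )

with ``C`` the misalignment of the detector center along the dispersion
axis.  ``x`` above is a detector-frame coordinate with origin on the
optical axis; the public functions work in a 1-based pixel frame obtained
by adding the fixed offset ``(n_pixels + 1)/2`` so that with ``C = 0`` the
axial wavelength lands at the detector center and ``C`` stays interpretable
as a physical misalignment.

All lengths are canonically in nanometres (``f = 5e8`` nm for a 500 mm
focal length) and all angles in radians; degree/millimetre/micrometre
conversions happen only at the configuration-file boundary (see
:mod:`speccal.io`).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .errors import OutOfPhysicalRangeError, ValidationError

__all__ = [
    "SpectrometerParams",
    "OffDetectorWarning",
    "diffraction_angle",
    "wavelength_to_pixel",
    "pixel_to_wavelength",
    "wavelength_band",
    "dispersion_curve",
    "nonlinearity",
]

#: tolerance on the asin argument; |u| up to 1 + _U_TOL is clipped to +-1
_U_TOL = 1e-12


class OffDetectorWarning(UserWarning):
    """A predicted pixel position lies outside [1, n_pixels] (non-fatal)."""


@dataclass(frozen=True)
class SpectrometerParams:
    """Full physical parameter set of the spectrometer model.

    Parameters
    ----------
    f : float
        Focal length of the focusing optic, nm.
    T : float
        Detector pixel pitch, nm.
    C : float
        Detector-center misalignment along the dispersion axis, nm.
    d_eff : float
        Effective grating period ``d' = d*cos(gamma)``, nm.
    alpha : float
        Half-deviation angle, radians, signed (counterclockwise positive).
    theta_d : float
        Grating rotation angle from the flat position, radians
        (counterclockwise positive).
    k : int
        Sign of the incident-angle term in the grating equation
        (+1 straight-through transmission, -1 reflection / detector on the
        diffracted arm; see module docstring).
    n_order : int
        Diffraction order (signed, typically +-1).
    n_pixels : int
        Number of detector pixels along the dispersion axis.
    """

    f: float
    T: float
    C: float
    d_eff: float
    alpha: float
    theta_d: float
    k: int
    n_order: int
    n_pixels: int

    def __post_init__(self) -> None:
        if not (self.f > 0 and self.T > 0 and self.d_eff > 0):
            raise ValidationError("f, T and d_eff must be positive")
        if self.n_pixels < 2:
            raise ValidationError("n_pixels must be >= 2")
        if self.n_order == 0:
            raise ValidationError("diffraction order must be nonzero")
        if self.k not in (+1, -1):
            raise ValidationError("k must be +1 or -1")

    @property
    def pixel_offset(self) -> float:
        """Offset between the detector-frame origin and the 1-based pixel frame."""
        return (self.n_pixels + 1) / 2.0

    def replace(self, **changes) -> "SpectrometerParams":
        """Return a copy with the given fields replaced."""
        return replace(self, **changes)


def _asin_argument(params: SpectrometerParams, wavelength):
    lam = np.asarray(wavelength, dtype=float)
    return params.n_order * lam / params.d_eff - params.k * np.sin(
        -params.alpha - params.theta_d
    )


def diffraction_angle(params: SpectrometerParams, wavelength):
    """Diffracted-ray angle beta (radians) for ``wavelength`` (nm).

    beta = asin(u) + theta_d with u = n*lambda/d' - k*sin(-alpha-theta_d).
    Strictly monotone and continuous in the wavelength wherever defined.

    Raises
    ------
    OutOfPhysicalRangeError
        If |u| > 1 for any requested wavelength: that wavelength is not
        diffracted toward the detector for these parameters.
    """
    u = _asin_argument(params, wavelength)
    bad = np.abs(u) > 1.0 + _U_TOL
    if np.any(bad):
        lam = np.asarray(wavelength, dtype=float)
        raise OutOfPhysicalRangeError(
            np.atleast_1d(lam)[np.atleast_1d(bad)][:5].tolist(),
            np.atleast_1d(u)[np.atleast_1d(bad)][:5].tolist(),
        )
    beta = np.arcsin(np.clip(u, -1.0, 1.0)) + params.theta_d
    if np.isscalar(wavelength):
        return float(beta)
    return beta


def wavelength_to_pixel(params: SpectrometerParams, wavelength, *, warn: bool = True):
    """Map wavelength (nm) to a real-valued 1-based pixel position.

    Propagates :class:`OutOfPhysicalRangeError` from the grating equation.
    Positions falling outside ``[1, n_pixels]`` are returned as-is but
    trigger an :class:`OffDetectorWarning` unless ``warn=False``.
    """
    beta = diffraction_angle(params, wavelength)
    x = (
        (params.f / params.T) * np.tan(beta - params.alpha)
        + params.C / params.T
        + params.pixel_offset
    )
    if warn:
        off = (np.asarray(x) < 1.0) | (np.asarray(x) > params.n_pixels)
        if np.any(off):
            warnings.warn(
                f"{int(np.count_nonzero(off))} wavelength(s) map outside the "
                f"detector [1, {params.n_pixels}]",
                OffDetectorWarning,
                stacklevel=2,
            )
    if np.isscalar(wavelength):
        return float(x)
    return x


def pixel_to_wavelength(params: SpectrometerParams, pixel):
    """Map a (real) 1-based pixel position to wavelength (nm).

    Total in the pixel coordinate: every real pixel maps to a wavelength.
    Pixels far off the physical detector may map to negative wavelengths;
    callers needing physically meaningful output should range-check (see
    :func:`dispersion_curve`'s validity column).
    """
    p = np.asarray(pixel, dtype=float)
    x_det = (p - params.pixel_offset) * params.T - params.C
    lam = (params.d_eff / params.n_order) * (
        np.sin(np.arctan(x_det / params.f) + params.alpha - params.theta_d)
        + params.k * np.sin(-params.alpha - params.theta_d)
    )
    if np.isscalar(pixel):
        return float(lam)
    return lam


def wavelength_band(params: SpectrometerParams):
    """(min, max) wavelength imaged on the detector, i.e. at pixels 1 and n."""
    ends = pixel_to_wavelength(params, np.array([1.0, float(params.n_pixels)]))
    return float(ends.min()), float(ends.max())


def dispersion_curve(params: SpectrometerParams) -> pd.DataFrame:
    """Wavelength and min-max-normalized wavelength on the integer pixel grid.

    Used for dispersion-linearity diagnostics: the ``normalized`` column is
    0 and 1 at the detector ends (1 and 0 for reversed dispersion), and its
    deviation from a straight line quantifies dispersion nonlinearity.  The
    ``valid`` column marks pixels mapping to a positive (physical)
    wavelength.
    """
    pixels = np.arange(1, params.n_pixels + 1, dtype=float)
    lam = pixel_to_wavelength(params, pixels)
    lo, hi = lam.min(), lam.max()
    norm = (lam - lo) / (hi - lo)
    return pd.DataFrame(
        {
            "pixel": pixels.astype(int),
            "wavelength_nm": lam,
            "normalized": norm,
            "valid": lam > 0,
        }
    )


def nonlinearity(params: SpectrometerParams) -> float:
    """Max |deviation| of the normalized dispersion curve from a straight line."""
    curve = dispersion_curve(params)
    n = len(curve)
    line = np.linspace(curve["normalized"].iloc[0], curve["normalized"].iloc[-1], n)
    return float(np.abs(curve["normalized"].to_numpy() - line).max())
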