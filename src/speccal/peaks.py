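"""Peak detection, Lorentzian sub-pixel localization, and line matching.

Reference-lamp emission lines are located in three stages: candidate apex
pixels from a prominence/separation rule (``scipy.signal.find_peaks``),
sub-pixel refinement by least-squares fitting of a four-parameter
Lorentzian

    I(x) = P1 / ((x - P2)^2 + P3) + P4

to a small window around each apex, and assignment of known lamp
wavelengths to the fitted positions through an approximate spectrometer
model, producing the (position, wavelength) pairs that drive calibration.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit
from scipy.signal import find_peaks

from .errors import (
    AmbiguousMatchError,
    FitFailureError,
    SaturationError,
    ValidationError,
)
from .optics_model import SpectrometerParams, pixel_to_wavelength

__all__ = [
    "Spectrum",
    "LampLineList",
    "LorentzianFit",
    "PeakSet",
    "MatchResult",
    "lorentzian",
    "detect_peaks",
    "fit_lorentzian",
    "match_lines",
]


@dataclass
class Spectrum:
    """A 1-D recorded spectrum: counts per pixel, pixel axis implicit 1..n."""

    intensities: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.intensities.ndim != 1 or self.intensities.size < 8:
            raise ValidationError("spectrum must be 1-D with at least 8 samples")
        if not np.all(np.isfinite(self.intensities)):
            raise ValidationError("spectrum contains non-finite samples")
        if np.any(self.intensities < 0):
            raise ValidationError("spectrum contains negative intensities")

    @property
    def n_pixels(self) -> int:
        return self.intensities.size

    @property
    def pixels(self) -> np.ndarray:
        return np.arange(1, self.n_pixels + 1)


@dataclass
class LampLineList:
    """Reference lamp lines: vacuum/air wavelengths in nm with uncertainties."""

    wavelengths: np.ndarray
    uncertainties: np.ndarray | None = None
    labels: list[str] | None = None
    name: str = ""

    def __post_init__(self) -> None:
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        if self.wavelengths.ndim != 1:
            raise ValidationError("line list must be 1-D")
        if self.wavelengths.size and np.any(self.wavelengths <= 0):
            raise ValidationError("line wavelengths must be positive")
        if np.any(np.diff(self.wavelengths) <= 0):
            raise ValidationError("line wavelengths must be strictly increasing")
        if self.uncertainties is not None:
            self.uncertainties = np.asarray(self.uncertainties, dtype=float)
            if self.uncertainties.shape != self.wavelengths.shape:
                raise ValidationError("uncertainty column length mismatch")

    def __len__(self) -> int:
        return self.wavelengths.size

    def within(self, lo: float, hi: float) -> "LampLineList":
        """Lines with lo <= wavelength <= hi."""
        m = (self.wavelengths >= lo) & (self.wavelengths <= hi)
        return LampLineList(
            self.wavelengths[m],
            None if self.uncertainties is None else self.uncertainties[m],
            None if self.labels is None else [l for l, keep in zip(self.labels, m) if keep],
            self.name,
        )


@dataclass(frozen=True)
class LorentzianFit:
    """Fitted peak-shape parameters and diagnostics.

    ``p1`` amplitude scale (counts*px^2), ``p2`` sub-pixel center (px),
    ``p3`` width parameter (px^2; HWHM = sqrt(p3)), ``p4`` baseline
    (counts).
    """

    p1: float
    p2: float
    p3: float
    p4: float
    window: tuple[int, int]
    residual_norm: float

    def __post_init__(self) -> None:
        if self.p3 <= 0:
            raise FitFailureError(f"non-positive width parameter P3={self.p3}")
        lo, hi = self.window
        if not (lo <= self.p2 <= hi):
            raise FitFailureError(
                f"fitted center {self.p2} outside window [{lo}, {hi}]"
            )

    @property
    def center(self) -> float:
        return self.p2

    @property
    def fwhm(self) -> float:
        return 2.0 * float(np.sqrt(self.p3))


@dataclass
class PeakSet:
    """Paired observed sub-pixel positions and reference wavelengths."""

    x: np.ndarray
    wavelengths: np.ndarray

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        if self.x.shape != self.wavelengths.shape or self.x.ndim != 1:
            raise ValidationError("positions and wavelengths must be matched 1-D")
        if self.x.size < 1:
            raise ValidationError("empty PeakSet")
        order = np.argsort(self.x)
        self.x = self.x[order]
        self.wavelengths = self.wavelengths[order]
        if np.any(np.diff(self.x) <= 0):
            raise ValidationError("peak positions must be strictly increasing")
        if self.x.size >= 2:
            d = np.diff(self.wavelengths)
            if not (np.all(d > 0) or np.all(d < 0)):
                raise ValidationError(
                    "wavelengths must be strictly monotone in position"
                )

    @property
    def n(self) -> int:
        return self.x.size

    def subset(self, indices) -> "PeakSet":
        idx = np.asarray(indices, dtype=int)
        return PeakSet(self.x[idx], self.wavelengths[idx])

    def drop(self, i: int) -> "PeakSet":
        keep = np.ones(self.n, dtype=bool)
        keep[i] = False
        return PeakSet(self.x[keep], self.wavelengths[keep])


@dataclass
class MatchResult:
    """Outcome of line matching: matched pairs plus everything left over."""

    peaks: PeakSet | None
    unmatched_positions: np.ndarray
    unmatched_lines: np.ndarray


def lorentzian(x, p1, p2, p3, p4):
    """Four-parameter Lorentzian line shape."""
    return p1 / ((x - p2) ** 2 + p3) + p4


def detect_peaks(
    spectrum: Spectrum, min_prominence: float, min_separation: float
) -> np.ndarray:
    """Candidate apex pixels (1-based) by prominence and separation.

    An empty result is legitimate (flat spectrum); the caller decides.
    """
    if min_prominence <= 0 or min_separation < 1:
        raise ValidationError("need min_prominence > 0 and min_separation >= 1")
    idx, _ = find_peaks(
        spectrum.intensities,
        prominence=min_prominence,
        distance=max(1, int(round(min_separation))),
    )
    return idx + 1  # 0-based sample index -> 1-based pixel


def fit_lorentzian(
    spectrum: Spectrum,
    apex: int,
    half_window: int = 5,
    full_scale: float | None = None,
) -> LorentzianFit:
    """Least-squares Lorentzian fit around ``apex``, sub-pixel center in P2.

    The window ``[apex-half_window, apex+half_window]`` must lie on the
    detector and contain at least 5 samples.  Initial guesses: P2 at the
    apex, P4 at the window minimum, the half-maximum crossing sets P3 and
    P1.  ``full_scale``, when given, rejects windows containing saturated
    samples (the recording protocol keeps counts just below saturation).
    """
    lo, hi = apex - half_window, apex + half_window
    if lo < 1 or hi > spectrum.n_pixels:
        raise ValidationError(f"fit window [{lo}, {hi}] outside the detector")
    if hi - lo + 1 < 5:
        raise ValidationError("fit window must contain at least 5 samples")
    xs = np.arange(lo, hi + 1, dtype=float)
    ys = spectrum.intensities[lo - 1 : hi]
    if full_scale is not None and np.any(ys >= full_scale):
        raise SaturationError(f"saturated samples in window around apex {apex}")

    p4_0 = float(ys.min())
    height = float(spectrum.intensities[apex - 1] - p4_0)
    if height <= 0:
        raise FitFailureError(f"no peak above baseline at apex {apex}")
    # half-maximum crossing distance -> HWHM estimate -> P3
    above = ys - p4_0 > height / 2.0
    hwhm = max(0.5, np.count_nonzero(above) / 2.0)
    p3_0 = hwhm**2
    p1_0 = height * p3_0
    try:
        popt, _ = curve_fit(
            lorentzian,
            xs,
            ys,
            p0=[p1_0, float(apex), p3_0, p4_0],
            bounds=([0.0, lo, 1e-6, -np.inf], [np.inf, hi, np.inf, np.inf]),
            maxfev=20000,
        )
    except (RuntimeError, ValueError) as exc:
        raise FitFailureError(f"Lorentzian fit failed at apex {apex}: {exc}") from exc
    resid = ys - lorentzian(xs, *popt)
    return LorentzianFit(
        p1=float(popt[0]),
        p2=float(popt[1]),
        p3=float(popt[2]),
        p4=float(popt[3]),
        window=(lo, hi),
        residual_norm=float(np.sqrt(np.sum(resid**2))),
    )


def match_lines(
    positions,
    lines: LampLineList,
    approx_params: SpectrometerParams,
    tolerance: float,
) -> MatchResult:
    """Pair detected sub-pixel positions with reference-line wavelengths.

    Each position is mapped to an approximate wavelength through the
    (step-1, coarse) spectrometer model and matched to the nearest line
    within ``tolerance`` nm.  Matching in wavelength space gives the
    tolerance physical meaning.  The result is one-to-one and
    order-preserving; unmatched positions and lines are reported, never
    silently dropped.

    Raises
    ------
    AmbiguousMatchError
        If two or more lines lie within tolerance of a single position.
    """
    pos = np.sort(np.asarray(positions, dtype=float))
    if pos.size == 0 or len(lines) == 0:
        return MatchResult(None, pos, lines.wavelengths.copy())
    approx = pixel_to_wavelength(approx_params, pos)

    claims: dict[int, tuple[int, float]] = {}  # line index -> (pos index, dist)
    unmatched_pos = []
    for i, lam in enumerate(np.atleast_1d(approx)):
        dist = np.abs(lines.wavelengths - lam)
        within = np.flatnonzero(dist <= tolerance)
        if within.size == 0:
            unmatched_pos.append(pos[i])
            continue
        if within.size > 1:
            raise AmbiguousMatchError(
                f"position {pos[i]:.3f} px (~{lam:.3f} nm) matches "
                f"{within.size} lines within {tolerance} nm: "
                f"{lines.wavelengths[within].tolist()}"
            )
        j = int(within[0])
        if j in claims and claims[j][1] <= dist[j]:
            unmatched_pos.append(pos[i])  # an earlier, closer position keeps the line
        else:
            if j in claims:
                unmatched_pos.append(pos[claims[j][0]])
            claims[j] = (i, float(dist[j]))

    matched_lines = sorted(claims)
    matched_pos_idx = [claims[j][0] for j in matched_lines]
    unmatched_lines = lines.wavelengths[
        [j for j in range(len(lines)) if j not in claims]
    ]
    if not matched_lines:
        return MatchResult(None, np.sort(np.array(unmatched_pos)), unmatched_lines)
    peaks = PeakSet(pos[matched_pos_idx], lines.wavelengths[matched_lines])
    return MatchResult(peaks, np.sort(np.array(unmatched_pos)), unmatched_lines)
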