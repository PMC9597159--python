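"""Error metrics and ALL / leave-one-out / leave-half-out evaluation.

A calibrated reference peak contributes the signed error

    error(lambda_i) = calibrated(lambda_i) - reference(lambda_i)   [nm]

evaluated with the calibration method's *continuous* pixel->wavelength map
at the observed sub-pixel peak position (not by interpolating the
per-pixel table, which would add an avoidable ~1e-4 nm artifact).  From a
vector of such errors the per-spectrum metrics are

    MAE  = mean |e|,   RMSE = sqrt(mean e^2),
    SD   = sqrt( sum (e - ME)^2 / (N - 1) ),  ME = signed mean,

and ensemble metrics over M spectra are the unweighted arithmetic means of
the per-spectrum metrics (never a pooled recomputation).

Evaluation schemes:

* ``ALL`` -- calibrate on all N peaks, score all N (traditional, biased
  low because scored peaks trained the fit).
* ``LOO`` -- leave-one-out cross-validation: for each peak, calibrate on
  the other N-1 and score only the held-out peak; metrics over the N
  held-out errors.  Probes accuracy *between* the reference lines.
* ``LHO`` -- leave-half-out: calibrate on the left half (by position),
  score the right half, then swap.  Probes extrapolation *outside* the
  outermost reference lines, where polynomial fits degrade most.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import ceil
from typing import Callable, NamedTuple, Protocol, runtime_checkable

import numpy as np

from .calibrate import (
    CalibrationResult,
    SearchGrid,
    calibrate_physical,
    calibrate_polynomial,
)
from .errors import InsufficientPeaksError, ValidationError
from .optics_model import SpectrometerParams
from .peaks import PeakSet

__all__ = [
    "Summary",
    "MetricsReport",
    "EnsembleSummary",
    "PhysicalCalibrator",
    "PolynomialCalibrator",
    "peak_errors",
    "summarize",
    "ensemble",
    "evaluate_scheme",
]

SCHEMES = ("ALL", "LOO", "LHO")


class Summary(NamedTuple):
    mae: float
    rmse: float
    sd: float | None  # None when N < 2 (undefined, not zero)


@dataclass
class MetricsReport:
    """Per-spectrum evaluation outcome under one scheme and method."""

    errors: np.ndarray
    mae: float
    rmse: float
    sd: float | None
    scheme: str
    method: str
    n_peaks: int
    n_calibrations: int
    lho_sides: dict | None = None
    meta: dict = field(default_factory=dict)


class EnsembleSummary(NamedTuple):
    mae: float
    rmse: float
    sd: float | None
    m: int


@runtime_checkable
class Calibrator(Protocol):
    min_peaks: int
    tag: str

    def __call__(self, peaks: PeakSet) -> CalibrationResult: ...


@dataclass
class PhysicalCalibrator:
    """Physical-model calibrator bound to nominal parameters and a grid."""

    params0: SpectrometerParams
    grid: SearchGrid | None = None
    refine: bool = False
    min_peaks: int = 4
    tag: str = "physical"

    def __call__(self, peaks: PeakSet) -> CalibrationResult:
        return calibrate_physical(peaks, self.params0, self.grid, refine=self.refine)


@dataclass
class PolynomialCalibrator:
    """Polynomial baseline calibrator of a fixed order."""

    order: int
    n_pixels: int

    def __post_init__(self) -> None:
        self.min_peaks = self.order + 1
        self.tag = f"poly{self.order}"

    def __call__(self, peaks: PeakSet) -> CalibrationResult:
        return calibrate_polynomial(peaks, self.order, self.n_pixels)


def peak_errors(result: CalibrationResult, peaks: PeakSet) -> np.ndarray:
    """Signed errors calibrated-minus-reference at the observed positions."""
    n = result.lambda_cal.size
    if np.any(peaks.x < 1.0) or np.any(peaks.x > n):
        raise ValidationError("peak position outside the detector")
    return np.atleast_1d(result.wavelength_at(peaks.x)) - peaks.wavelengths


def summarize(errors) -> Summary:
    """MAE, RMSE and (N-1)-denominator SD of an error vector."""
    e = np.asarray(errors, dtype=float)
    if e.ndim != 1 or e.size < 1:
        raise ValidationError("error vector must be 1-D and non-empty")
    mae = float(np.mean(np.abs(e)))
    rmse = float(np.sqrt(np.mean(e**2)))
    sd = float(np.std(e, ddof=1)) if e.size >= 2 else None
    return Summary(mae, rmse, sd)


def ensemble(reports) -> EnsembleSummary:
    """Unweighted means of per-spectrum metrics over M spectra."""
    if len(reports) < 1:
        raise ValidationError("ensemble needs at least one spectrum")

    def fields(r):
        if isinstance(r, (MetricsReport, Summary)):
            return r.mae, r.rmse, r.sd
        mae, rmse, sd = r
        return mae, rmse, sd

    maes, rmses, sds = zip(*(fields(r) for r in reports))
    sd_bar = None if any(s is None for s in sds) else float(np.mean(sds))
    return EnsembleSummary(
        float(np.mean(maes)), float(np.mean(rmses)), sd_bar, len(reports)
    )


def _held_out_error(calibrator, train: PeakSet, test: PeakSet) -> np.ndarray:
    return peak_errors(calibrator(train), test)


def evaluate_scheme(peaks: PeakSet, calibrator, scheme: str) -> MetricsReport:
    """Evaluate one calibration method on one spectrum under one scheme.

    LHO reporting: the headline metrics pool the held-out errors of both
    sides; ``lho_sides`` additionally carries per-side summaries and the
    average of the two side MAEs/RMSEs/SDs, since either convention
    appears in practice.
    """
    scheme = scheme.upper()
    if scheme not in SCHEMES:
        raise ValidationError(f"unknown scheme {scheme!r}; expected one of {SCHEMES}")
    need = {
        "ALL": calibrator.min_peaks,
        "LOO": calibrator.min_peaks + 1,
        "LHO": 2 * calibrator.min_peaks,
    }[scheme]
    if peaks.n < need:
        raise InsufficientPeaksError(
            f"{scheme} with {calibrator.tag} needs >= {need} peaks, got {peaks.n}"
        )

    lho_sides = None
    if scheme == "ALL":
        result = calibrator(peaks)
        errors = peak_errors(result, peaks)
        n_cal = 1
    elif scheme == "LOO":
        errors = np.empty(peaks.n)
        for i in range(peaks.n):
            errors[i] = _held_out_error(
                calibrator, peaks.drop(i), peaks.subset([i])
            )[0]
        n_cal = peaks.n
    else:  # LHO; odd N puts the extra peak on the left
        n_left = ceil(peaks.n / 2)
        left = peaks.subset(np.arange(n_left))
        right = peaks.subset(np.arange(n_left, peaks.n))
        err_right = _held_out_error(calibrator, left, right)
        err_left = _held_out_error(calibrator, right, left)
        errors = np.empty(peaks.n)
        errors[:n_left] = err_left
        errors[n_left:] = err_right
        n_cal = 2
        s_r, s_l = summarize(err_right), summarize(err_left)
        lho_sides = {
            "calibrate_left_score_right": s_r,
            "calibrate_right_score_left": s_l,
            "side_average_mae": (s_r.mae + s_l.mae) / 2.0,
            "side_average_rmse": (s_r.rmse + s_l.rmse) / 2.0,
            "side_average_sd": (
                None
                if s_r.sd is None or s_l.sd is None
                else (s_r.sd + s_l.sd) / 2.0
            ),
        }

    s = summarize(errors)
    return MetricsReport(
        errors=errors,
        mae=s.mae,
        rmse=s.rmse,
        sd=s.sd,
        scheme=scheme,
        method=calibrator.tag,
        n_peaks=peaks.n,
        n_calibrations=n_cal,
        lho_sides=lho_sides,
    )
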