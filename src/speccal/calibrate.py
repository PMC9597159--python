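"""Spectrometer calibration from (position, wavelength) peak pairs.

Two model-based estimators plus the traditional polynomial baselines:

* :func:`calibrate_bruteforce` -- exhaustive grid search over any subset of
  the six model parameters ``[f, T, C, d', alpha, theta_d]``, minimizing
  the pixel-domain squared error ``err = sum_i (x_i^j - x_i^0)^2``.
  Conceptually simple; intended for tiny grids and as the oracle the
  faster algorithm is checked against.
* :func:`calibrate_physical` -- grid search over ``(alpha, d', theta_d)``
  only.  ``f``, ``T`` and ``C`` enter the model purely as a scale and a
  shift of the detector coordinate, so inside every grid cell they are
  absorbed by an ordinary least-squares first-order map fitted from the
  model-predicted positions to the observed ones.  The search space loses
  three dimensions while still accounting for all six parameters (and for
  anything else that only shifts/scales the pixel axis, e.g. in-plane
  camera rotation).
* :func:`calibrate_polynomial` -- direct least-squares polynomial
  ``lambda(x)`` of order 1..3 fitted to the peak pairs.

The per-pixel wavelength axis of the physical method is produced by
sending the integer pixel grid through the *exact algebraic inverse* of
the fitted first-order map (observed frame -> model frame) and then
through the inverse model, so the composition is self-consistent: nuisance
scale/shift perturbations are absorbed exactly.

No gradient or simplex optimizer replaces the grid: the selection is a
deterministic argmin with an order-independent tie-break, so results are
reproducible bit-for-bit and independent of cell-evaluation order.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Callable

import numpy as np

from .errors import (
    GridBudgetError,
    InsufficientPeaksError,
    NumericalError,
    ValidationError,
)
from .optics_model import SpectrometerParams, pixel_to_wavelength
from .peaks import PeakSet

__all__ = [
    "PARAM_NAMES",
    "GridAxis",
    "SearchGrid",
    "LinearPixelMap",
    "CalibrationResult",
    "fit_error",
    "estimate_initial",
    "calibrate_bruteforce",
    "calibrate_physical",
    "calibrate_polynomial",
    "default_physical_grid",
]

#: canonical ordering of the searchable model parameters
PARAM_NAMES = ("f", "T", "C", "d_eff", "alpha", "theta_d")

_CHUNK_CELLS = 100_000  # grid cells evaluated per vectorized block


@dataclass(frozen=True)
class GridAxis:
    """One search dimension: ``center ± half_range`` sampled every ``step``.

    The center is always on the grid; values are symmetric about it.
    """

    center: float
    half_range: float
    step: float

    def __post_init__(self) -> None:
        if self.step <= 0:
            raise ValidationError("grid step must be positive")
        if self.half_range < 0:
            raise ValidationError("grid half-range must be non-negative")

    @property
    def values(self) -> np.ndarray:
        m = int(round(self.half_range / self.step))
        return self.center + self.step * np.arange(-m, m + 1, dtype=float)

    @property
    def size(self) -> int:
        return 2 * int(round(self.half_range / self.step)) + 1


@dataclass
class SearchGrid:
    """Named grid axes over a subset of the model parameters, plus a budget."""

    axes: dict[str, GridAxis]
    budget: int = 10_000_000

    def __post_init__(self) -> None:
        unknown = set(self.axes) - set(PARAM_NAMES)
        if unknown:
            raise ValidationError(f"unknown grid parameters: {sorted(unknown)}")
        if not self.axes:
            raise ValidationError("search grid needs at least one axis")

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(self.axes)

    @property
    def n_cells(self) -> int:
        return math.prod(ax.size for ax in self.axes.values())

    def check_budget(self) -> None:
        if self.n_cells > self.budget:
            raise GridBudgetError(self.n_cells, self.budget)

    def cell_values(self) -> dict[str, np.ndarray]:
        """Flattened per-parameter value arrays, one entry per grid cell."""
        mesh = np.meshgrid(*(ax.values for ax in self.axes.values()), indexing="ij")
        return {name: m.ravel() for name, m in zip(self.axes, mesh)}

    def cell_indices(self) -> dict[str, np.ndarray]:
        mesh = np.meshgrid(
            *(np.arange(ax.size) for ax in self.axes.values()), indexing="ij"
        )
        return {name: m.ravel() for name, m in zip(self.axes, mesh)}

    def refined_about(self, cell: dict[str, float]) -> "SearchGrid":
        """Halved ranges and steps, centered on a selected cell."""
        return SearchGrid(
            {
                name: GridAxis(cell[name], ax.half_range / 2.0, ax.step / 2.0)
                for name, ax in self.axes.items()
            },
            budget=self.budget,
        )


def default_physical_grid(params0: SpectrometerParams) -> SearchGrid:
    """Default (alpha, d', theta_d) search ranges about the nominal values.

    alpha0 ± 0.5 deg step 0.01 deg, d'0 ± 0.2% step 0.005%, theta0 ± 0.5 deg
    step 0.005 deg.  Sized for desk-scale runtime with vectorized
    evaluation; all three are freely configurable.
    """
    deg = np.pi / 180.0
    return SearchGrid(
        {
            "alpha": GridAxis(params0.alpha, 0.5 * deg, 0.01 * deg),
            "d_eff": GridAxis(params0.d_eff, 0.002 * params0.d_eff, 5e-5 * params0.d_eff),
            "theta_d": GridAxis(params0.theta_d, 0.5 * deg, 0.005 * deg),
        }
    )


@dataclass(frozen=True)
class LinearPixelMap:
    """First-order map between model-predicted and observed pixel positions."""

    slope: float
    intercept: float
    direction: str = "model_to_observed"

    def __post_init__(self) -> None:
        if self.slope == 0:
            raise ValidationError("degenerate linear pixel map (zero slope)")

    def apply(self, x):
        return self.slope * np.asarray(x, dtype=float) + self.intercept

    def invert(self, x):
        return (np.asarray(x, dtype=float) - self.intercept) / self.slope


@dataclass
class CalibrationResult:
    """Per-pixel calibrated wavelengths plus the fitted parameterization.

    ``err`` is the minimized squared-residual: pixel-domain (px^2) for the
    model-based methods, wavelength-domain (nm^2) for the polynomial
    baselines (which predict wavelength, not position).
    ``wavelength_at`` is the method's continuous pixel->wavelength map,
    used to evaluate calibrated wavelengths at sub-pixel positions without
    table-interpolation artifacts.
    """

    lambda_cal: np.ndarray
    method: str
    err: float
    peak_residuals_nm: np.ndarray
    wavelength_at: Callable = field(repr=False)
    params: SpectrometerParams | None = None
    pixel_map: LinearPixelMap | None = None
    grid_cell: dict[str, float] | None = None
    monotone: bool = True
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.lambda_cal = np.asarray(self.lambda_cal, dtype=float)
        if self.err < 0:
            raise ValidationError("negative residual error")
        d = np.diff(self.lambda_cal)
        self.monotone = bool(np.all(d > 0) or np.all(d < 0))
        if not self.monotone:
            if self.method in ("physical", "bruteforce"):
                raise NumericalError(
                    f"{self.method} calibration produced a non-monotone "
                    "wavelength axis"
                )
            warnings.warn(
                f"{self.method} calibration is non-monotone over the detector "
                "(extrapolated polynomial); use with care",
                UserWarning,
                stacklevel=2,
            )


def fit_error(predicted, observed) -> float:
    """Sum of squared differences between predicted and observed positions."""
    p = np.asarray(predicted, dtype=float)
    o = np.asarray(observed, dtype=float)
    if p.shape != o.shape or p.ndim != 1 or p.size < 1:
        raise ValidationError("predicted/observed must be matched 1-D, N >= 1")
    return float(np.sum((p - o) ** 2))


def _predict_cells(
    params0: SpectrometerParams, values: dict[str, np.ndarray], wavelengths: np.ndarray
) -> np.ndarray:
    """Model-predicted pixel positions, one row per grid cell.

    Cells for which any wavelength violates the asin domain are returned as
    NaN rows (unphysical cell, excluded from the argmin).
    """

    def col(name, default):
        v = values.get(name)
        return v[:, None] if v is not None else default

    f = col("f", params0.f)
    T = col("T", params0.T)
    C = col("C", params0.C)
    d_eff = col("d_eff", params0.d_eff)
    alpha = col("alpha", params0.alpha)
    theta = col("theta_d", params0.theta_d)
    lam = wavelengths[None, :]

    u = params0.n_order * lam / d_eff - params0.k * np.sin(-alpha - theta)
    with np.errstate(invalid="ignore"):
        beta = np.arcsin(np.where(np.abs(u) <= 1.0, u, np.nan)) + theta
        x = (f / T) * np.tan(beta - alpha) + C / T + params0.pixel_offset
    return np.broadcast_to(x, (_n_cells(values), wavelengths.size)).copy() if x.ndim == 1 else x


def _n_cells(values: dict[str, np.ndarray]) -> int:
    return next(iter(values.values())).size


def _select_cell(
    grid: SearchGrid,
    err: np.ndarray,
    extra_key: np.ndarray | None = None,
) -> int:
    """Deterministic, evaluation-order-independent argmin with tie-break.

    Cells whose error is within 1e-15 (relative) of the minimum are tied;
    among ties the cell closest to the grid center in normalized
    coordinates wins, then the lexicographically smallest index tuple.
    """
    finite = np.isfinite(err)
    if not np.any(finite):
        raise NumericalError("no grid cell yields a physical solution")
    err_min = np.min(err[finite])
    tol = 1e-15 * max(err_min, np.finfo(float).tiny)
    ties = np.flatnonzero(finite & (err <= err_min + tol))
    if ties.size == 1:
        return int(ties[0])
    indices = grid.cell_indices()
    dist2 = np.zeros(ties.size)
    for name, ax in grid.axes.items():
        if ax.half_range > 0:
            v = ax.values[indices[name][ties]]
            dist2 += ((v - ax.center) / ax.half_range) ** 2
    keys = [dist2] + [indices[name][ties] for name in grid.names]
    order = np.lexsort(tuple(reversed([*keys])))  # primary = dist2, then indices
    return int(ties[order[0]])


def estimate_initial(
    params_nominal: SpectrometerParams,
    one_peak: tuple[float, float],
    grid: SearchGrid,
) -> SpectrometerParams:
    """Step-1 initial estimate of (C, theta_d) from a single peak pair.

    ``f``, ``T``, ``d'`` come from manufacturer specifications and alpha is
    measured manually; only the detector offset and grating angle are
    unknown enough to need a 2-D brute-force search, and a single
    (position, wavelength) pair suffices to constrain them.
    """
    if set(grid.names) != {"C", "theta_d"}:
        raise ValidationError("initial-estimate grid must cover exactly (C, theta_d)")
    grid.check_budget()
    x0, lam0 = float(one_peak[0]), float(one_peak[1])
    values = grid.cell_values()
    x = _predict_cells(params_nominal, values, np.array([lam0]))[:, 0]
    resid = np.abs(x - x0)
    best = _select_cell(grid, np.where(np.isfinite(resid), resid, np.inf))
    return params_nominal.replace(
        C=float(values["C"][best]), theta_d=float(values["theta_d"][best])
    )


def _lambda_axis(params: SpectrometerParams, pixel_map: LinearPixelMap | None):
    pixels = np.arange(1, params.n_pixels + 1, dtype=float)
    frame = pixel_map.invert(pixels) if pixel_map is not None else pixels
    return pixel_to_wavelength(params, frame)


def calibrate_bruteforce(
    peaks: PeakSet, params0: SpectrometerParams, grid: SearchGrid
) -> CalibrationResult:
    """Exhaustive search over any subset of the six model parameters.

    Every grid cell is evaluated with the forward model at the reference
    wavelengths and scored with :func:`fit_error` against the observed
    positions; the winning parameter set generates the wavelength axis via
    the inverse model on the integer pixel grid.  Intended for small grids
    (the cell budget is enforced): this is the oracle against which
    :func:`calibrate_physical` is validated.
    """
    grid.check_budget()
    values = grid.cell_values()
    n_cells = _n_cells(values)
    err = np.empty(n_cells)
    for start in range(0, n_cells, _CHUNK_CELLS):
        sl = slice(start, min(start + _CHUNK_CELLS, n_cells))
        chunk = {k: v[sl] for k, v in values.items()}
        x = _predict_cells(params0, chunk, peaks.wavelengths)
        r = x - peaks.x[None, :]
        e = np.sum(r * r, axis=1)
        err[sl] = np.where(np.isfinite(e), e, np.inf)
    best = _select_cell(grid, err)
    cell = {name: float(values[name][best]) for name in grid.names}
    params = params0.replace(**cell)

    def wavelength_at(x, _p=params):
        return pixel_to_wavelength(_p, x)

    residuals = wavelength_at(peaks.x) - peaks.wavelengths
    return CalibrationResult(
        lambda_cal=_lambda_axis(params, None),
        method="bruteforce",
        err=float(err[best]),
        peak_residuals_nm=np.atleast_1d(residuals),
        wavelength_at=wavelength_at,
        params=params,
        grid_cell=cell,
    )


def calibrate_physical(
    peaks: PeakSet,
    params0: SpectrometerParams,
    grid: SearchGrid | None = None,
    *,
    refine: bool = False,
) -> CalibrationResult:
    """Hybrid search: 3-D grid over (alpha, d', theta_d) with nested OLS.

    For each cell the forward model (with the nominal ``f0, T0, C0``)
    predicts peak positions; a first-order least-squares map from predicted
    to observed positions absorbs errors in focal length, pixel pitch and
    detector offset; the cell minimizing the post-map squared error wins.
    Requires at least 4 peaks (as many as the effective free parameters)
    with at least 2 distinct positions.

    ``refine=True`` adds one optional refinement pass on a halved,
    finer grid centered on the selected cell (off by default: the method
    is single-pass by design).
    """
    if peaks.n < 4:
        raise InsufficientPeaksError(
            f"physical calibration needs >= 4 peaks, got {peaks.n}"
        )
    if np.unique(peaks.x).size < 2:
        raise InsufficientPeaksError("degenerate regression: < 2 distinct positions")
    if grid is None:
        grid = default_physical_grid(params0)
    if set(grid.names) != {"alpha", "d_eff", "theta_d"}:
        raise ValidationError(
            "physical-calibration grid must cover exactly (alpha, d_eff, theta_d)"
        )
    grid.check_budget()

    x0 = peaks.x
    x0_mean = x0.mean()
    values = grid.cell_values()
    n_cells = _n_cells(values)
    err = np.empty(n_cells)
    slopes = np.empty(n_cells)
    intercepts = np.empty(n_cells)
    for start in range(0, n_cells, _CHUNK_CELLS):
        sl = slice(start, min(start + _CHUNK_CELLS, n_cells))
        chunk = {k: v[sl] for k, v in values.items()}
        xj = _predict_cells(params0, chunk, peaks.wavelengths)
        xm = xj.mean(axis=1, keepdims=True)
        dx = xj - xm
        sxx = np.sum(dx * dx, axis=1)
        sxy = dx @ (x0 - x0_mean)
        with np.errstate(invalid="ignore", divide="ignore"):
            a = sxy / sxx
            b = x0_mean - a * xm[:, 0]
            r = a[:, None] * xj + b[:, None] - x0[None, :]
            e = np.sum(r * r, axis=1)
        bad = ~np.isfinite(e) | (sxx <= 0) | (a == 0)
        err[sl] = np.where(bad, np.inf, e)
        slopes[sl] = a
        intercepts[sl] = b

    best = _select_cell(grid, err)
    cell = {name: float(values[name][best]) for name in grid.names}
    if refine:
        return calibrate_physical(
            peaks, params0, grid.refined_about(cell), refine=False
        )
    params = params0.replace(**cell)
    pmap = LinearPixelMap(float(slopes[best]), float(intercepts[best]))

    def wavelength_at(x, _p=params, _m=pmap):
        return pixel_to_wavelength(_p, _m.invert(x))

    residuals = np.atleast_1d(wavelength_at(peaks.x) - peaks.wavelengths)
    result = CalibrationResult(
        lambda_cal=_lambda_axis(params, pmap),
        method="physical",
        err=float(err[best]),
        peak_residuals_nm=residuals,
        wavelength_at=wavelength_at,
        params=params,
        pixel_map=pmap,
        grid_cell=cell,
        meta={
            # C is frozen during the search; the map intercept carries the
            # same degree of freedom, so report the effective total offset.
            "effective_offset_px": params.C / params.T + pmap.intercept,
        },
    )
    return result


def calibrate_polynomial(
    peaks: PeakSet, order: int, n_pixels: int
) -> CalibrationResult:
    """Traditional baseline: least-squares polynomial lambda(x) of order 1-3."""
    if order not in (1, 2, 3):
        raise ValidationError("polynomial order must be 1, 2 or 3")
    if peaks.n < order + 1:
        raise InsufficientPeaksError(
            f"order-{order} polynomial needs >= {order + 1} peaks, got {peaks.n}"
        )
    poly = np.polynomial.Polynomial.fit(peaks.x, peaks.wavelengths, order)

    def wavelength_at(x, _p=poly):
        out = _p(np.asarray(x, dtype=float))
        return float(out) if np.isscalar(x) else out

    residuals = np.atleast_1d(wavelength_at(peaks.x) - peaks.wavelengths)
    return CalibrationResult(
        lambda_cal=wavelength_at(np.arange(1, n_pixels + 1, dtype=float)),
        method=f"poly{order}",
        err=float(np.sum(residuals**2)),
        peak_residuals_nm=residuals,
        wavelength_at=wavelength_at,
        meta={"coefficients": poly.convert().coef.tolist()},
    )
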