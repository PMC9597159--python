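"""Synthetic reference-lamp spectra with known ground truth.

The generator runs the forward optics model: each lamp line is placed at
its exact sub-pixel detector position, rendered with the same Lorentzian
line shape the peak fitter assumes (a Gaussian option exists to study
shape mismatch), summed over lines on a flat baseline, and sampled at the
integer pixel centers.  Counting noise is Poisson on baseline-plus-signal
by default (Gaussian and noiseless variants available).  Every render
returns the exact line positions as ground truth, so detection, fitting,
matching, calibration and evaluation are all testable without instrument
data.

Ensembles emulate repeated acquisitions with slight movements of the
grating rotation angle: each member draws a theta_d jitter, and the
per-spectrum true parameters are recorded.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .errors import ValidationError
from .optics_model import SpectrometerParams, wavelength_to_pixel
from .peaks import PeakSet, Spectrum, lorentzian

__all__ = ["SimulationSpec", "RenderedSpectrum", "render_spectrum", "render_ensemble"]

NOISE_MODELS = ("none", "poisson", "gaussian")


@dataclass
class SimulationSpec:
    """Everything needed to render reproducible synthetic lamp spectra.

    Defaults emulate a lamp exposure accumulated to just below detector
    saturation: peak apex ~1e4 counts over a 1e2-count baseline with
    Poisson counting noise, and Lorentzian width P3 = 4 px^2 (HWHM 2 px).

    ``perturb_abs`` / ``perturb_rel`` shift the *true* instrument away from
    the nominal ``params`` (absolute deltas in canonical units / relative
    factors minus one), emulating manufacturing tolerances the calibration
    must recover.  ``seed`` is mandatory and recorded in all outputs.
    """

    params: SpectrometerParams
    line_wavelengths: np.ndarray
    seed: int
    line_amplitudes: np.ndarray | float = 1.0e4  # apex height above baseline, counts
    line_widths: np.ndarray | float = 4.0  # Lorentzian P3, px^2
    baseline: float = 100.0
    noise: str = "poisson"
    noise_sigma: float = 0.0  # for the additive-Gaussian model
    line_shape: str = "lorentzian"  # or "gaussian" (model-mismatch studies)
    n_spectra: int = 1
    theta_jitter: float = 0.0  # radians, uniform +- jitter per spectrum
    perturb_abs: dict[str, float] = field(default_factory=dict)
    perturb_rel: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.line_wavelengths = np.asarray(self.line_wavelengths, dtype=float)
        self.line_amplitudes = np.broadcast_to(
            np.asarray(self.line_amplitudes, dtype=float), self.line_wavelengths.shape
        ).copy()
        self.line_widths = np.broadcast_to(
            np.asarray(self.line_widths, dtype=float), self.line_wavelengths.shape
        ).copy()
        if np.any(self.line_amplitudes <= 0) or np.any(self.line_widths <= 0):
            raise ValidationError("line amplitudes and widths must be positive")
        if self.noise not in NOISE_MODELS:
            raise ValidationError(f"noise must be one of {NOISE_MODELS}")
        if self.line_shape not in ("lorentzian", "gaussian"):
            raise ValidationError("line_shape must be 'lorentzian' or 'gaussian'")
        if self.n_spectra < 1:
            raise ValidationError("n_spectra must be >= 1")
        if self.seed is None:
            raise ValidationError("a seed is mandatory")

    def true_params(self) -> SpectrometerParams:
        """Nominal parameters with the perturbation spec applied."""
        changes: dict[str, float] = {}
        for name, delta in self.perturb_abs.items():
            changes[name] = getattr(self.params, name) + delta
        for name, rel in self.perturb_rel.items():
            base = changes.get(name, getattr(self.params, name))
            changes[name] = base * (1.0 + rel)
        return replace(self.params, **changes) if changes else self.params


@dataclass
class RenderedSpectrum:
    """One synthetic acquisition with its ground truth.

    ``truth`` is ``None`` for a line-less (flat baseline) render.
    """

    spectrum: Spectrum
    truth: PeakSet | None
    params_true: SpectrometerParams
    dropped_lines: np.ndarray  # wavelengths that fell off the detector
    seed: int


def _profile(spec: SimulationSpec, pixels, centers, widths, amps):
    total = np.full(pixels.shape, float(spec.baseline))
    for x0, p3, amp in zip(centers, widths, amps):
        if spec.line_shape == "lorentzian":
            total += lorentzian(pixels, amp * p3, x0, p3, 0.0)
        else:  # gaussian with matched HWHM
            sigma = np.sqrt(p3) / np.sqrt(2.0 * np.log(2.0))
            total += amp * np.exp(-0.5 * ((pixels - x0) / sigma) ** 2)
    return total


def render_spectrum(
    spec: SimulationSpec, rng: np.random.Generator | None = None
) -> RenderedSpectrum:
    """Render one spectrum; returns exact sub-pixel line positions as truth.

    Lines falling off the detector are dropped (and reported).  An empty
    line list renders a flat baseline (truth ``None``); a non-empty list
    with no line landing on the detector is an error.
    """
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    params = spec.true_params()
    if spec.line_wavelengths.size == 0:
        x_line = np.empty(0)
        in_band = np.zeros(0, dtype=bool)
    else:
        x_line = np.atleast_1d(
            wavelength_to_pixel(params, spec.line_wavelengths, warn=False)
        )
        in_band = (x_line >= 1.0) & (x_line <= params.n_pixels)
        if not np.any(in_band):
            raise ValidationError(
                "no line lands on the detector for these parameters"
            )
    dropped = spec.line_wavelengths[~in_band]

    pixels = np.arange(1, params.n_pixels + 1, dtype=float)
    clean = _profile(
        spec,
        pixels,
        x_line[in_band],
        spec.line_widths[in_band],
        spec.line_amplitudes[in_band],
    )
    if spec.noise == "poisson":
        data = rng.poisson(clean).astype(float)
    elif spec.noise == "gaussian":
        data = np.clip(clean + rng.normal(0.0, spec.noise_sigma, clean.shape), 0.0, None)
    else:
        data = clean
    spectrum = Spectrum(data, meta={"seed": spec.seed, "noise": spec.noise})
    truth = (
        PeakSet(x_line[in_band], spec.line_wavelengths[in_band])
        if np.any(in_band)
        else None
    )
    return RenderedSpectrum(spectrum, truth, params, dropped, spec.seed)


def render_ensemble(spec: SimulationSpec) -> list[RenderedSpectrum]:
    """Render ``n_spectra`` acquisitions with per-spectrum theta_d jitter.

    Deterministic under a fixed seed; with ``n_spectra=1`` and zero jitter
    the single member is identical to :func:`render_spectrum`.
    """
    rng = np.random.default_rng(spec.seed)
    members = []
    for _ in range(spec.n_spectra):
        if spec.theta_jitter > 0:
            jitter = rng.uniform(-spec.theta_jitter, spec.theta_jitter)
            member_spec = replace(
                spec,
                params=spec.params.replace(theta_d=spec.params.theta_d + jitter),
            )
        else:
            member_spec = spec
        members.append(render_spectrum(member_spec, rng))
    return members
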