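"""Exception hierarchy.

``ValidationError`` maps to CLI exit code 2 (bad inputs or configuration),
``NumericalError`` to exit code 3 (a computation that could not be carried
out for physically/numerically valid reasons).
"""

from __future__ import annotations


class SpecCalError(Exception):
    """Base class for all speccal errors."""


class ValidationError(SpecCalError):
    """Invalid input data, parameters, or configuration."""


class NumericalError(SpecCalError):
    """A numerical procedure failed (non-convergence, no physical solution)."""


class OutOfPhysicalRangeError(NumericalError):
    """The grating equation has no diffracted solution for a wavelength.

    Raised when the arcsine argument ``u = n*lambda/d' - k*sin(-alpha-theta_d)``
    leaves [-1, 1]: the wavelength is not diffracted toward the detector for
    these parameters.
    """

    def __init__(self, wavelength_nm, u):
        self.wavelength_nm = wavelength_nm
        self.u = u
        super().__init__(
            f"no diffracted ray: |u| > 1 (wavelength={wavelength_nm} nm, u={u})"
        )


class FitFailureError(NumericalError):
    """A least-squares peak fit failed to converge or gave unphysical shape."""


class SaturationError(ValidationError):
    """A fit window contains detector-saturated samples; the peak is rejected."""


class AmbiguousMatchError(ValidationError):
    """Two or more reference lines fall within tolerance of one detected peak."""


class InsufficientPeaksError(ValidationError):
    """Fewer peaks than the calibrator or evaluation scheme requires."""


class GridBudgetError(ValidationError):
    """A search grid exceeds the configured cell budget."""

    def __init__(self, n_cells, budget):
        self.n_cells = n_cells
        self.budget = budget
        super().__init__(f"search grid has {n_cells} cells, exceeding budget {budget}")


class ConfigError(ValidationError):
    """Malformed or unknown entries in a configuration or data file."""
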