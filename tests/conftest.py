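"""Shared fixtures: packaged instrument configurations, lamp lines, and
helpers for building small search grids and well-separated line subsets."""

from __future__ import annotations

import math

import numpy as np
import pytest

from speccal import GridAxis, SearchGrid, wavelength_to_pixel
from speccal.io import PACKAGED_CONFIGS, packaged_config, packaged_lines

DEG = math.pi / 180.0


@pytest.fixture(scope="session")
def configs():
    """All four packaged instrument configurations, keyed by short name."""
    return {name: packaged_config(name) for name in PACKAGED_CONFIGS}


@pytest.fixture(scope="session")
def ct600(configs):
    return configs["czerny_turner_600"]


@pytest.fixture(scope="session")
def trans2455(configs):
    return configs["transmission_2455"]


@pytest.fixture(scope="session")
def neon():
    return packaged_lines("neon_nist_air")


@pytest.fixture(scope="session")
def krypton():
    return packaged_lines("krypton_synthetic")


def in_band_lines(params, lines, margin_nm=3.0, min_separation_px=0.0):
    """Line wavelengths inside the detector band, optionally thinned so
    consecutive detector positions are at least ``min_separation_px`` apart
    (isolates peak-shape tests from tail-overlap bias)."""
    from speccal import wavelength_band

    lo, hi = wavelength_band(params)
    lam = lines.within(lo + margin_nm, hi - margin_nm).wavelengths
    if min_separation_px <= 0:
        return lam
    x = np.sort(wavelength_to_pixel(params, lam, warn=False))
    order = np.argsort(wavelength_to_pixel(params, lam, warn=False))
    lam_by_x = lam[order]
    keep = [0]
    for i in range(1, len(x)):
        if x[i] - x[keep[-1]] >= min_separation_px:
            keep.append(i)
    return np.sort(lam_by_x[keep])


def small_physical_grid(params0, half_alpha=0.04, step_alpha=0.02,
                        half_d=4e-4, step_d=2e-4, half_theta=0.04, step_theta=0.02):
    """A compact (alpha, d', theta_d) grid centered on the nominal values.

    Angle arguments in degrees, d' arguments relative to the nominal d'.
    """
    return SearchGrid(
        {
            "alpha": GridAxis(params0.alpha, half_alpha * DEG, step_alpha * DEG),
            "d_eff": GridAxis(params0.d_eff, half_d * params0.d_eff, step_d * params0.d_eff),
            "theta_d": GridAxis(params0.theta_d, half_theta * DEG, step_theta * DEG),
        }
    )
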