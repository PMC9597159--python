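"""Tests of the grid-search calibrators and polynomial baselines."""

from __future__ import annotations

import numpy as np
import pytest

import speccal as sc

from conftest import DEG, in_band_lines, small_physical_grid


@pytest.fixture()
def neon_peaks_600(ct600, neon):
    lam = in_band_lines(ct600, neon)
    x = sc.wavelength_to_pixel(ct600, lam, warn=False)
    return sc.PeakSet(x, lam)


class TestFitError:
    def test_identical_vectors(self):
        assert sc.fit_error([1.0, 2.0], [1.0, 2.0]) == 0.0

    def test_half_pixel_shift(self):
        assert sc.fit_error([1.5, 2.5], [1.0, 2.0]) == pytest.approx(0.5)

    def test_loop_oracle(self):
        rng = np.random.default_rng(5)
        a, b = rng.normal(size=7), rng.normal(size=7)
        expected = sum((ai - bi) ** 2 for ai, bi in zip(a, b))
        assert sc.fit_error(a, b) == pytest.approx(expected, rel=1e-14)

    def test_length_mismatch(self):
        with pytest.raises(sc.ValidationError):
            sc.fit_error([1.0], [1.0, 2.0])


class TestSearchGrid:
    def test_center_always_on_grid(self):
        ax = sc.GridAxis(10.0, 1.0, 0.3)
        assert 10.0 in ax.values
        assert ax.values.size == 2 * 3 + 1

    def test_zero_half_range_single_value(self):
        assert list(sc.GridAxis(5.0, 0.0, 1.0).values) == [5.0]

    def test_budget_enforced(self, ct600):
        grid = sc.SearchGrid(
            {"theta_d": sc.GridAxis(ct600.theta_d, 1.0, 1e-6)}, budget=1000
        )
        with pytest.raises(sc.GridBudgetError):
            grid.check_budget()

    def test_unknown_parameter_rejected(self):
        with pytest.raises(sc.ValidationError):
            sc.SearchGrid({"gamma": sc.GridAxis(0, 1, 1)})


class TestEstimateInitial:
    def grid(self, p0, theta_values=0.04):
        return sc.SearchGrid(
            {
                "C": sc.GridAxis(0.0, 2 * p0.T, 0.5 * p0.T),
                "theta_d": sc.GridAxis(p0.theta_d, theta_values * DEG, 0.02 * DEG),
            }
        )

    def test_on_grid_recovery(self, ct600):
        lam = 600.0
        x0 = sc.wavelength_to_pixel(ct600, lam, warn=False)
        est = sc.estimate_initial(ct600, (x0, lam), self.grid(ct600))
        assert est.C == 0.0
        assert est.theta_d == ct600.theta_d

    def test_shifted_position_recovered_as_offset(self, ct600):
        # theta axis pinned at truth: a +delta px shift must become C = delta*T
        lam, delta = 600.0, 1.5
        x0 = sc.wavelength_to_pixel(ct600, lam, warn=False) + delta
        grid = sc.SearchGrid(
            {
                "C": sc.GridAxis(0.0, 4 * ct600.T, 0.5 * ct600.T),
                "theta_d": sc.GridAxis(ct600.theta_d, 0.0, 1.0),
            }
        )
        est = sc.estimate_initial(ct600, (x0, lam), grid)
        assert est.C == pytest.approx(delta * ct600.T, rel=1e-12)

    def test_off_grid_matches_exhaustive_loop(self, ct600):
        lam = 610.0
        truth = ct600.replace(C=0.37 * ct600.T, theta_d=ct600.theta_d + 0.013 * DEG)
        x0 = sc.wavelength_to_pixel(truth, lam, warn=False)
        grid = self.grid(ct600)
        est = sc.estimate_initial(ct600, (x0, lam), grid)
        # independent exhaustive double loop
        best = (np.inf, None, None)
        for C in grid.axes["C"].values:
            for th in grid.axes["theta_d"].values:
                x = sc.wavelength_to_pixel(
                    ct600.replace(C=C, theta_d=th), lam, warn=False
                )
                if abs(x - x0) < best[0]:
                    best = (abs(x - x0), C, th)
        assert est.C == pytest.approx(best[1])
        assert est.theta_d == pytest.approx(best[2])

    def test_wrong_axes_rejected(self, ct600):
        with pytest.raises(sc.ValidationError):
            sc.estimate_initial(
                ct600, (500.0, 600.0),
                sc.SearchGrid({"f": sc.GridAxis(ct600.f, 0, 1)}),
            )


def bruteforce_grid(p0, with_nuisance=True):
    axes = {
        "alpha": sc.GridAxis(p0.alpha, 0.02 * DEG, 0.01 * DEG),
        "d_eff": sc.GridAxis(p0.d_eff, 2e-4 * p0.d_eff, 1e-4 * p0.d_eff),
        "theta_d": sc.GridAxis(p0.theta_d, 0.02 * DEG, 0.01 * DEG),
    }
    if with_nuisance:
        axes["f"] = sc.GridAxis(p0.f, 1e-3 * p0.f, 1e-3 * p0.f)
        axes["C"] = sc.GridAxis(p0.C, p0.T, p0.T)
    return sc.SearchGrid(axes)


class TestBruteforce:
    def test_exact_cell_selected(self, ct600, neon_peaks_600):
        res = sc.calibrate_bruteforce(neon_peaks_600, ct600, bruteforce_grid(ct600))
        assert res.err < 1e-18
        assert res.grid_cell["alpha"] == ct600.alpha
        assert res.grid_cell["f"] == ct600.f

    def test_axis_order_independent(self, ct600, neon_peaks_600):
        g1 = bruteforce_grid(ct600)
        g2 = sc.SearchGrid(dict(reversed(list(g1.axes.items()))))
        r1 = sc.calibrate_bruteforce(neon_peaks_600, ct600, g1)
        r2 = sc.calibrate_bruteforce(neon_peaks_600, ct600, g2)
        assert r1.grid_cell == r2.grid_cell
        assert np.array_equal(r1.lambda_cal, r2.lambda_cal)

    def test_single_peak_reduces_to_initial_estimate(self, ct600):
        lam = 600.0
        truth = ct600.replace(C=0.8 * ct600.T)
        x0 = float(sc.wavelength_to_pixel(truth, lam, warn=False))
        c_axis = sc.GridAxis(0.0, 2 * ct600.T, 0.25 * ct600.T)
        res = sc.calibrate_bruteforce(
            sc.PeakSet([x0], [lam]), ct600, sc.SearchGrid({"C": c_axis})
        )
        est = sc.estimate_initial(
            ct600, (x0, lam),
            sc.SearchGrid({"C": c_axis, "theta_d": sc.GridAxis(ct600.theta_d, 0.0, 1.0)}),
        )
        assert res.grid_cell["C"] == est.C

    def test_budget_refusal(self, ct600, neon_peaks_600):
        grid = bruteforce_grid(ct600)
        grid.budget = 10
        with pytest.raises(sc.GridBudgetError):
            sc.calibrate_bruteforce(neon_peaks_600, ct600, grid)


class TestCalibratePhysical:
    def test_identity_when_truth_is_nominal(self, ct600, neon_peaks_600):
        res = sc.calibrate_physical(neon_peaks_600, ct600, small_physical_grid(ct600))
        assert abs(res.pixel_map.slope - 1.0) < 1e-12
        assert abs(res.pixel_map.intercept) < 1e-9
        assert res.err < 1e-18
        assert res.monotone

    def test_absorbs_focal_and_offset_nuisance(self, ct600, neon):
        lam = in_band_lines(ct600, neon)
        truth = ct600.replace(f=1.01 * ct600.f, C=ct600.C + 30e3)  # +30 um
        x0 = sc.wavelength_to_pixel(truth, lam, warn=False)
        peaks = sc.PeakSet(x0, lam)
        res = sc.calibrate_physical(peaks, ct600, small_physical_grid(ct600))
        assert res.grid_cell["alpha"] == ct600.alpha
        assert res.grid_cell["theta_d"] == ct600.theta_d
        assert np.abs(res.peak_residuals_nm).max() < 1e-6

    def test_agrees_with_bruteforce_oracle(self, ct600, neon_peaks_600):
        shared = small_physical_grid(ct600, half_alpha=0.02, step_alpha=0.01,
                                     half_d=2e-4, step_d=1e-4,
                                     half_theta=0.02, step_theta=0.01)
        ph = sc.calibrate_physical(neon_peaks_600, ct600, shared)
        bf = sc.calibrate_bruteforce(neon_peaks_600, ct600, bruteforce_grid(ct600))
        assert np.abs(ph.lambda_cal - bf.lambda_cal).max() < 1e-6

    def test_refinement_never_increases_error(self, ct600, neon):
        lam = in_band_lines(ct600, neon)
        truth = ct600.replace(theta_d=ct600.theta_d + 0.013 * DEG)  # off-grid
        x0 = sc.wavelength_to_pixel(truth, lam, warn=False)
        peaks = sc.PeakSet(x0, lam)
        grid = small_physical_grid(ct600)
        single = sc.calibrate_physical(peaks, ct600, grid)
        refined = sc.calibrate_physical(peaks, ct600, grid, refine=True)
        assert refined.err <= single.err

    def test_requires_four_peaks(self, ct600, neon_peaks_600):
        with pytest.raises(sc.InsufficientPeaksError):
            sc.calibrate_physical(
                neon_peaks_600.subset([0, 1, 2]), ct600, small_physical_grid(ct600)
            )

    def test_wrong_grid_axes_rejected(self, ct600, neon_peaks_600):
        with pytest.raises(sc.ValidationError):
            sc.calibrate_physical(
                neon_peaks_600, ct600,
                sc.SearchGrid({"f": sc.GridAxis(ct600.f, 0, 1)}),
            )

    def test_effective_offset_reported(self, ct600, neon):
        lam = in_band_lines(ct600, neon)
        truth = ct600.replace(C=ct600.C + 52e3)  # +2 px worth of offset
        peaks = sc.PeakSet(sc.wavelength_to_pixel(truth, lam, warn=False), lam)
        res = sc.calibrate_physical(peaks, ct600, small_physical_grid(ct600))
        # C was frozen at nominal; the map intercept carries the 2 px shift
        assert res.meta["effective_offset_px"] == pytest.approx(2.0, abs=1e-6)


class TestCalibratePolynomial:
    def test_two_peaks_exact_line(self):
        peaks = sc.PeakSet([100.0, 900.0], [500.0, 580.0])
        res = sc.calibrate_polynomial(peaks, 1, 1024)
        assert np.abs(res.peak_residuals_nm).max() < 1e-10
        assert res.wavelength_at(500.0) == pytest.approx(540.0)

    def test_collinear_points_cubic_reduces_to_line(self):
        x = np.array([100.0, 300.0, 600.0, 900.0])
        lam = 500.0 + 0.1 * x
        res = sc.calibrate_polynomial(sc.PeakSet(x, lam), 3, 1024)
        coef = res.meta["coefficients"]
        assert abs(coef[2]) < 1e-10 and abs(coef[3]) < 1e-12
        assert np.abs(res.lambda_cal - (500.0 + 0.1 * np.arange(1, 1025))).max() < 1e-6

    def test_extrapolation_worse_than_physical(self, trans2455, krypton):
        # 8 peaks from the high-dispersion model, cubic fitted, then both
        # methods evaluated 200 px beyond the last peak
        lam = krypton.wavelengths[:8]
        x0 = sc.wavelength_to_pixel(trans2455, lam, warn=False)
        peaks = sc.PeakSet(x0, lam)
        poly = sc.calibrate_polynomial(peaks, 3, trans2455.n_pixels)
        phys = sc.calibrate_physical(peaks, trans2455, small_physical_grid(trans2455))
        x_out = x0.max() + 200.0
        lam_true = sc.pixel_to_wavelength(trans2455, x_out)
        assert abs(poly.wavelength_at(x_out) - lam_true) > abs(
            phys.wavelength_at(x_out) - lam_true
        )

    def test_insufficient_peaks(self):
        with pytest.raises(sc.InsufficientPeaksError):
            sc.calibrate_polynomial(sc.PeakSet([1.0, 2.0], [500.0, 501.0]), 2, 1024)

    def test_bad_order(self):
        peaks = sc.PeakSet([1.0, 2.0], [500.0, 501.0])
        with pytest.raises(sc.ValidationError):
            sc.calibrate_polynomial(peaks, 4, 1024)
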