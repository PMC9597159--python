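# Methods

## Optical model

The instrument is reduced to six parameters S = [f, T, C, d′, α, θd] plus
two discrete signs (diffraction order n, grating-equation sign k).  A
collimated beam strikes a plane grating rotated by θd from a reference
("flat") position; the diffracted beam passes through a focusing optic of
focal length f and lands on a linear detector of pixel pitch T whose
center is offset by C from the optical axis.  With all angles signed
counterclockwise, the rotated grating equation is

    n λ / d′ = sin(β − θd) + k sin(−α − θd),

and the detector position of wavelength λ follows from β by
x = (f/T) tan(β − α) + C/T.  Both directions of the map are closed-form
(an arcsine and an arctangent); they are exact algebraic inverses of each
other, which the test suite verifies to below 1e−9 nm.

Assumptions and deliberate omissions:

* Out-of-plane ("oblique") incidence is folded into the effective period
  d′ = d cos γ; γ and d are not separately identifiable and are never
  modeled separately.
* Detector-plane tilt/defocus, 2-D image distortion and aberrations are
  outside the model: the input is a single cropped detector row.
* Reference wavelengths are used as given; no refractive-index-of-air
  correction is applied to the line lists.
* Pixel frame: 1-based pixel centers.  The raw model coordinate has its
  origin where the optical axis meets the detector; the implementation
  adds the fixed offset (n_pixels+1)/2 so that C = 0 places the axial
  wavelength at the detector center and C keeps its meaning of physical
  misalignment.
* Units: all lengths in nm internally (f = 5e8 nm for 500 mm), all angles
  in radians; mm/µm/degrees exist only at the configuration-file boundary.

### Sign conventions of the packaged configurations

Two conventions are resolved empirically and deserve a note.

*Fixed transmission instrument.*  With the grating at α = 45°, θd = 0 and
the "straight-through" transmission sign k = +1, the detector center maps
to λ = 0 for every choice of the signs of n and α — that axis carries the
zero order.  The physical instrument places its detector on the
first-order arm (total deviation ≈ 90°), where the incident and
diffracted sine terms of the grating equation *add*.  The packaged
2455 lines/mm configuration therefore carries `model_sign = -1` with
n = +1, which puts the first order on-axis at 2 d′ sin 45° ≈ 576.1 nm and
yields a modeled band of 528.1–617.1 nm, matching the instrument's
printed 530–610 nm operating band.  The mirror-image parametrization
(k = +1, n = −1, detector coordinate reversed) is algebraically
identical.

*Reflection instrument.*  With k = −1 the on-axis wavelength is
(d′/n)·2 sin α cos θd, so capturing the n = −1 order with a positive
wavelength band requires α < 0 under the counterclockwise convention.
The packaged Czerny–Turner configurations store
half_deviation_deg = −21.88 (measured magnitude 21.88°).  Note that in
this parametrization the "flat" θd = 0 reference is *not* the
zero-order-on-axis position; grating angles are model-frame values chosen
to center realistic lamp bands: −74.0° (300 l/mm, ≈631–740 nm), −61.0°
(600 l/mm, ≈568–637 nm), +18.5° (1000 l/mm, ≈686–727 nm, redder per that
grating's 760 nm blaze).  The 600 l/mm geometry is the most linear of the
four and the 2455 l/mm transmission geometry by far the least
(normalized nonlinearity 0.0054 vs 0.039), reproducing the expected
ordering.

## Calibration algorithms

`calibrate_bruteforce` evaluates the forward model on every cell of a
user-defined grid over any subset of S and minimizes
err = Σ (xᵢ − x⁰ᵢ)².  It is exact but exponential in the number of
searched parameters; it exists as the oracle.

`calibrate_physical` searches only (α, d′, θd).  f, T and C enter the
model purely as a scale and a shift of the detector coordinate, so inside
each grid cell the model-predicted positions are regressed onto the
observed ones with a first-order least-squares map, absorbing all three
(and any other pure shift/scale effect such as in-plane camera rotation)
at the cost of two linear degrees of freedom.  The cell (and its map)
minimizing the post-map error wins.  This drops three dimensions from the
search while effectively fitting seven instrument effects.

Numerical choices:

* The per-pixel wavelength axis applies the *exact inverse* of the fitted
  model→observed map to the integer pixel grid and then the inverse
  model, so the composition is self-consistent: a pure f-scale or C-shift
  perturbation of the truth is absorbed exactly (verified to 1e−13 nm).
  Applying the forward map instead would differ at second order.
* The regression order is fixed at one; higher orders would re-introduce
  exactly the unconstrained-polynomial behavior the method avoids.
* Grid cells whose arcsine argument leaves [−1, 1] for any reference
  wavelength are unphysical and excluded; if all cells are unphysical the
  calibration fails with a numerical error.
* Tie-break: cells within 1e−15 relative error of the minimum are tied;
  the tie goes to the cell closest to the grid center in normalized
  coordinates, then to the lexicographically smallest index tuple.  The
  argmin is therefore deterministic and independent of evaluation order.
* Default grid: α₀ ± 0.5° step 0.01°, d′₀ ± 0.2% step 0.005%, θd₀ ± 0.5°
  step 0.005°, with a 1e7-cell budget guard; tests and the acceptance
  script pass smaller explicit grids sized to their problems.  An
  optional single refinement pass (halved ranges and steps, centered on
  the selected cell) is off by default — the method is single-pass by
  design, and refinement never increases the error because the selected
  cell stays on the refined grid.
* No gradient or simplex polish replaces the grid: determinism and
  robustness to a bad single peak are preferred over speed, and the
  vectorized grid evaluation is fast at these sizes.
* C stays frozen at its nominal value during the search (the map
  intercept carries the same degree of freedom); the result reports the
  effective total offset C₀/T + intercept.
* `estimate_initial` provides the step-1 coarse estimate: f, T, d′ from
  manufacturer specifications, α measured, and (C, θd) from a 2-D
  brute-force search on a single peak pair.
* err is pixel-domain (px²) for the model-based methods, per its
  definition; the polynomial baselines predict wavelength, not position,
  so their err is the analogous wavelength-domain sum of squares.
* λcal monotonicity is a hard invariant for the model-based methods.  An
  extrapolated cubic baseline can legitimately turn over within the
  detector, so polynomial results carry a `monotone` flag and a warning
  instead of an error.

## Peak localization

Apex candidates come from a prominence/separation rule
(`scipy.signal.find_peaks`); each is refined by least-squares fitting of
the four-parameter Lorentzian P1/((x−P2)²+P3) + P4 over a ±5 px window
(default).  Initial guesses: P2 at the apex, P4 at the window minimum,
the half-maximum crossing sets P3 = HWHM² and P1 = height·P3.  The fit is
bounded (P1 > 0, P2 inside the window, P3 > 0); non-convergence or a
non-positive width is a fit failure naming the apex.  Windows containing
samples at the detector full scale are rejected — the acquisition
protocol this emulates keeps counts just below saturation.  Lorentzian
fitting is used rather than Fourier zero-padding upsampling (slightly
more accurate in practice, and it yields an analytic center);
Voigt profiles and instrument-response deconvolution are out of scope.

Matching to the lamp line list happens in wavelength space through the
coarse step-1 model, where the tolerance (default 0.5 nm) has physical
meaning.  Matching is one-to-one and order-preserving; ambiguous matches
(two lines within tolerance of one peak) are an error, and unmatched
positions/lines are reported, never dropped silently.

## Evaluation framework

Per-spectrum metrics over the signed errors e = calibrated − reference:
MAE, RMSE, and SD with the N−1 denominator (SD is *absent*, not zero, for
N < 2).  Ensemble metrics over M spectra are unweighted means of the
per-spectrum metrics, never pooled recomputations.  Errors at sub-pixel
peak positions are evaluated with each method's continuous map
(model∘map⁻¹ or the polynomial), not by interpolating the per-pixel
table, removing a ~1e−4 nm interpolation artifact; the per-pixel table
remains the exported product.

Schemes: ALL (1 calibration, score all peaks), LOO (N calibrations, score
each held-out peak), LHO (2 calibrations: calibrate on the left half by
position — the extra peak goes left for odd N — score the right half,
then swap).  LHO reports both the pooled held-out metrics and the
per-side metrics with their average, since both conventions appear in
practice.

## Synthetic data

The generator runs the forward model: each line is placed at its exact
sub-pixel position, rendered with the same Lorentzian shape the fitter
assumes (apex amplitude 1e4 counts over a 1e2-count baseline, width
P3 = 4 px² by default — i.e. a lamp exposure accumulated to just below
the full scale of a 16-bit CCD with ~2 px HWHM lines), sampled at integer
pixel centers, and given Poisson counting noise on baseline-plus-signal
(noiseless and additive-Gaussian variants exist, and a Gaussian line
shape for model-mismatch studies).  Ensembles draw a uniform θd jitter
per member, emulating repeated acquisitions with slight grating
movements; a perturbation spec shifts the *true* instrument away from
the nominal configuration to emulate manufacturing tolerances.  A seed is
mandatory and recorded in every output.

What the generator does **not** emulate — and hence what passing tests do
not show about real data: 2-D slit-image curvature and its cropping
residuals, stray light, cosmic-ray spikes, detector nonlinearity or
fixed-pattern noise, line-shape asymmetry, and blends below the detection
separation.  Results on synthetic spectra demonstrate algorithmic
correctness and noise behavior of the estimators, not instrument-level
accuracy claims.

## Problem sizes and study conditions

The test suite and `scripts/acceptance.py` use desk-scale sizes chosen as
this package's own defaults: 1e4 wavelengths per configuration for the
round-trip identity; 1e3 random geometries for the ray-trace oracle; 50
trials at position noise σ = 0.02 px for noisy recovery on the
600 lines/mm configuration (σ consistent with the Lorentzian fitter's
shot-noise accuracy); 100 Poisson trials for sub-pixel localization; and,
for the extrapolation comparison on the transmission configuration, the
twelve krypton-like lines (clustered toward the left of the band, as for
the real lamp) with σ = 0.02 px over 10 seeded realizations, comparing
ensemble-averaged MAEs.  Identity-type tests use lines thinned to ≥60 px
separation so Lorentzian tail overlap cannot bias sub-pixel centers;
closely spaced lines are exercised separately by the merged-peak
detection tests.

## Known limitations

* The three searched parameters are nearly degenerate after the linear
  map (they differ mainly through the curvature of the dispersion), so
  with noisy peaks the selected (α, d′, θd) cell may sit a few steps from
  the generating values while the *wavelength axis* remains accurate;
  recovery of individual parameters is only meaningful at high SNR or
  with a pinned subset.
* A single grid pass limits parameter resolution to the step size;
  wavelength accuracy is much less sensitive (second order) because the
  linear map absorbs the first-order effect of any cell offset.
* The model cannot represent detector-plane tilt; spectra from visibly
  defocused or tilted detectors will show systematic residuals no cell
  can remove.
* Line lists are treated as exact; line-wavelength uncertainties are
  carried through IO but not propagated into the metrics.
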