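# Methods

## Scope

`ftirdeconv` quantifies two things from mid-infrared absorbance spectra of
bread model systems (inulin + gluten + starch + polyols):

1. protein secondary-structure composition, as relative peak areas (RPA)
   of Gaussian–Lorentzian sub-bands fitted to the amide I band
   (1600–1700 cm⁻¹);
2. the degree of starch order, as the ratio of baseline-corrected
   absorbance heights at 1047 cm⁻¹ (ordered/crystalline) and 1022 cm⁻¹
   (amorphous).

A statistics layer (one-way ANOVA, pooled SEM, Duncan's multiple range
test) compares treatment groups measured in triplicate, and a synthetic
generator produces spectra with exact ground truth for validation.

## Line-shape model

Every band is an *additive* pseudo-Voigt: a linear blend
η·L + (1−η)·G of a Lorentzian and a Gaussian sharing one center and FWHM.
This form is standard in amide I work and has the closed-form area
h·w·[η·π/2 + (1−η)·(√(π/ln 2))/2], so fitted areas need no quadrature.
The product form and the true Voigt (convolution) are not implemented.

The Lorentzian fraction η is **fixed at 0.5 for all bands by default**
(`eta_mode="fixed"`). A per-band free η (`"free_per_band"`) is available
but not the default: η trades off almost perfectly against height and
width between heavily overlapped bands, and in noise-free synthetic
recovery experiments the free-η fit reproducibly converged to wrong local
optima with class-area errors of 10–25 percentage points while the
fixed-η fit recovered the truth to machine precision.

## Conditioning chain

Order of operations (each step optional and configurable):

1. average replicate spectra (pointwise mean on a common grid);
2. resample to a uniform 1 cm⁻¹ grid over the analysis window
   (derivatives and the height readout require a uniform grid);
3. subtract interfering component spectra: mixture − k·component with
   k ≥ 0 chosen by least squares over a reference region where the
   remaining matrix is flat (default 1000–1150 cm⁻¹ for starch), because
   absorption coefficients differ between components and formulation
   weight ratios would over- or under-subtract; an explicit factor may be
   given instead;
4. multipoint linear baseline correction: the piecewise-linear baseline
   through the spectrum's own values at the anchor wavenumbers is
   subtracted, so the result is exactly zero at each anchor. Defaults:
   anchors 1590/1710 cm⁻¹ for amide I, 900/1200 cm⁻¹ for the fingerprint.
5. for band *localization only*, a vector-normalized Savitzky–Golay
   second derivative (window 13 points on the 1 cm⁻¹ grid, polyorder 3 —
   wide enough to suppress noise amplification yet narrow enough to
   resolve bands of ≥ 10 cm⁻¹ FWHM). Curve fitting operates on the
   baseline-corrected absorbance, not on the derivative.

**A caveat on baseline correction of overlapped bands.** Amide I
sub-bands with Lorentzian character have long tails, so the spectrum is
not zero at any practical anchor position. Pinning a line to those tail
values subtracts a small but broad wedge (≈ 9 % of the total band area
for the default synthetic composite) and biases fitted areas by several
RPA percentage points. This is inherent to tail-anchored linear baselines,
not to the optimizer. Consequently the validation and acceptance analyses
of generator output — which is synthesized on a zero baseline — skip the
baseline step (`analyze_amide(..., anchors=None)`); real spectra with
drift need the correction and inherit the bias, which cancels to first
order when treatments are *compared* under identical processing.

## Band detection and fitting

Candidate centers are local minima of the second derivative within the
fit region whose depth reaches 5 % (`prominence_frac`) of the deepest
minimum. Initial heights are obtained by non-negative least squares on
the fixed initial shapes (FWHM 16 cm⁻¹, η 0.5); bounded trust-region
least squares (`scipy.optimize.least_squares`, ftol 1e-10 / xtol 1e-8)
then refines all parameters with centers confined to ± 5 cm⁻¹
(`center_slack`) of their starting values, heights ≥ 0 and FWHM within
[8, 40] cm⁻¹ — typical amide I bandwidths.

Because strongly overlapped shoulders (e.g. a weak band 9 cm⁻¹ from a
strong one) rarely produce separate derivative minima, the fit then
iterates: one band is proposed at the largest positive residual extremum
and the whole set is refit; the new band is kept only while it reduces
the residual sum of squares by at least 20 % (`min_ss_improvement`),
up to `max_bands` = 8. A fixed R² acceptance threshold alone cannot drive
this loop — an underfit with one band too few already reaches R² ≈ 0.9998
on noise-free 5-band composites while the correct model reaches 1 — so
R² ≥ `r2_accept` (default 0.9999) only labels the result `converged`.
Discarded or degenerate proposals converge to zero height and carry no
area. The fit is deterministic: no random restarts.

Identifiability limits: with additive noise of 0.5 % of the peak height,
a shoulder carrying ~3 % of the total area 9 cm⁻¹ from a band six times
larger is at the edge of what the data determine — even with centers and
widths known exactly, the linear-model standard error of its height is
≈ 3 % relative, and any realistic freedom in centers/widths inflates its
area error to tens of percent. Class-level RPA (window sums) is much more
stable than individual band parameters, because splitting or trading area
between bands inside one window leaves the class total unchanged.

## Structure readouts

RPA: each fitted band contributes its full closed-form area to the class
whose half-open window [low, high) contains its center; windows are
intermolecular β-sheet [1620, 1640), α-helix [1650, 1660), β-turn
[1660, 1680), intramolecular β-sheet [1680, 1695). The windows do not
tile 1600–1700 cm⁻¹; centers in the gaps (notably the 1640–1650 cm⁻¹
random-coil region) form an explicit "unassigned" class that closes the
sum to exactly 100 %. Published row sums of ≈ 97 % for the four named
classes are consistent with this remainder. (Assignments of a band near
1641 cm⁻¹ to intermolecular β-sheet appear in the literature; this
package keeps the stated [1620, 1640) window and counts 1641 as
unassigned rather than silently widening the window.)

Starch order: heights are read at the grid points nearest the *nominal*
positions 1047 and 1022 cm⁻¹ after resampling to 1 cm⁻¹ and baseline
correction — the ratio names fixed positions, not local maxima. The
third fingerprint band near 995 cm⁻¹ (water-sensitive) is modeled in the
generator but never used in the ratio.

## Statistics

One-way fixed-effects ANOVA is computed from the textbook
sums-of-squares decomposition (the error mean square and its df are
needed downstream). Duncan's multiple range test compares ranked means:
a span of p consecutive ranked means differs when its range exceeds
LSR_p = q(γ_p, p, df_error)·√(MSE/n) with protection level
γ_p = (1−α)^(p−1); a span enclosed by any non-significant span is
non-significant (step-down rule). Studentized-range quantiles come from
`scipy.stats.studentized_range` (numerical distribution function), which
reproduces the classical printed 5 % significant ranges at 14 df to
± 0.01. Under the step-down rule non-significance is interval-shaped in
ranked order, so the compact letter display is built from the maximal
non-significant runs (insert-and-absorb). Groups must be balanced — the
design is a completely randomized triplicate — and MSE = 0 (identical
replicates) degenerates gracefully to exact-equality comparisons.
The protected familywise error with k groups approaches
1 − (1−α)^(k−1) (≈ 0.26 for k = 7, α = 0.05), which the test suite
checks as a broad calibration band, not a sharp value.

## Synthetic generator

The generator is the package's validation instrument; all of its
randomness flows from one integer seed and every output carries a truth
record sufficient to score downstream estimates.

* **Component library**: six ingredients with bands at their
  characteristic positions (starch 1010/1080/1150, sorbitol
  890/1046/1084/1411, glycerol 962/1145, propylene glycol 1374/1442,
  gluten 2934/3397 plus amide I/II at 1654/1560, inulin 1653/1030/700,
  and generic C–H/O–H stretches near 2920/3300 cm⁻¹). Heights
  (0.2–1.0 AU) and widths (10–60 cm⁻¹) are package inventions chosen for
  plausibility only.
* **Model spectra**: formulation-weighted sums of component spectra on
  the 400–4000 cm⁻¹ instrument grid (4 cm⁻¹ step), plus optional linear
  baseline drift and additive Gaussian noise. Formulation defaults are
  the base blend inulin : gluten : starch = 0.8 : 1 : 7 with water 3 : 1
  to solids; polyol levels of 1 % and 5 % of the solids mass give weights
  0.088 and 0.44 on the 8.8 basis.
* **Amide I composites**: five bands at 1627/1645/1654/1670/1685 cm⁻¹
  (FWHM 20, η 0.5, grid 1590–1710 cm⁻¹ at 1 cm⁻¹) whose areas are
  prescribed class fractions of a total area (default 10 AU·cm⁻¹). The
  1645 cm⁻¹ band carries the unassigned remainder so that four-class
  row sums below 100 % are exactly representable.
* **Fingerprints**: bands at 1047/1022/995 cm⁻¹ (FWHM 18, η 0.5) on
  900–1200 cm⁻¹; the 1047/1022 amplitudes solve a 2×2 linear system so
  that the *baseline-corrected total* heights at the two positions equal
  (r·h₀, h₀), h₀ = 0.5 AU — the pipeline ratio then equals r exactly,
  noise-free, and remains invariant to any added linear drift.
* **Replicates**: i.i.d. normal values around prescribed group means.

What the generator does *not* emulate: wavenumber-correlated noise,
atmospheric CO₂/H₂O residuals, scattering artifacts, detector
nonlinearity, water-content band shifts, or physically calibrated
absorption coefficients. Passing the recovery suite therefore
demonstrates correctness of the inference chain under the stated band
model, not instrument-grade robustness.

## Problem sizes and determinism

Validation runs use single spectra per condition: 121-point amide I
windows and 301-point fingerprints, with 5-band fits completing in well
under a second and the iterative chain in a few seconds. The acceptance
script runs two amide recoveries and one fingerprint recovery
end-to-end. All fits are deterministic given inputs; the only stochastic
elements (noise, replicates) are seeded.

## Known limitations

* Only AFFN-encoded JCAMP-DX (XYDATA/XYPOINTS) is read; SQZ/DIF
  compression is rejected with a clear error.
* The baseline model is multipoint linear only; rubber-band, asymmetric
  least squares and scatter-correction methods are out of scope.
* Duncan's test requires balanced groups; unbalanced designs raise.
* Fitted-parameter uncertainties are not propagated into the RPA; group
  variability is assessed across replicates instead.
* The fitted quantity is the baseline-corrected absorbance; fitting the
  second derivative or a Fourier self-deconvolved spectrum is not
  supported.
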