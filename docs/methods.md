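# Methods

## The circuit model

`circphot` computes the drive that a corneal light stimulus delivers to the
human circadian system through the M1 ipRGC, following the retinal wiring of
the circadian phototransduction circuit: rods, the three cone classes and
melanopsin feed a small set of interneurons — the H2 horizontal cell (blue–
yellow opponency in the S-cone bipolar, SB), the AII amacrine (rod shunting
inhibition of the ipRGC), the A18 amacrine (dopaminergic decoupling of that
shunt) and the S-cone amacrine (rectification of the SB signal).

For a corneal spectral irradiance E(λ) (W·m⁻²·nm⁻¹):

1. **Excitations.** Each photoreceptor class i has a corneal sensitivity
   sᵢ(λ): a peak-normalized Gaussian-in-wavelength opsin template
   (FWHM 80 nm; λmax 498/480/565/535/430 nm for rod/mel/L/M/S) multiplied by
   the crystalline-lens transmittance and re-normalized to unit peak.
   Excitations are Xᵢ = ∫ sᵢ(λ)E(λ)dλ, and the achromatic channel is
   V_ach = X_L + X_M (unit weights — the simplest reading of a combined
   L+M drive through H1; the opponent gain k absorbs any scale choice).
2. **Opponency.** The SB output is b − y = X_S − k·V_ach. Its zero crossing
   for monochromatic light defines the spectral cross-point; k is set in
   closed form so that a monochromatic line at 500 nm is exactly balanced,
   k = s_S(500) / (s_L(500) + s_M(500)). b − y ≤ 0 is the "yellow" (warm)
   branch, b − y > 0 the "blue" (cool) branch.
3. **Rod shunt.** The AII amacrine bleeds ipRGC current in proportion to a
   saturating rod drive with divisive cone release:
   shunt = a2·(1 − exp(−X_rod_eff / rod_sat)),
   X_rod_eff = X_rod / (1 + a3·V_ach).
   This is the minimal form with the two required properties — rod-dominated
   and saturating, released as cones silence rods — using the standard
   saturating-exponential and divisive-normalization motifs.
4. **Piecewise response.** On the blue branch the ipRGC sums its intrinsic
   melanopsin response and the rectified SB input and loses the shunt
   current: R = max(0, X_mel + a1·(b−y) − shunt). On the yellow branch the
   A18 amacrine disconnects the shunt entirely and rectification removes
   the yellow-OFF signal, so R = X_mel. The decoupling is modelled as a
   hard switch (the A18 acts as a diode), which is what produces the
   discontinuity in the predicted spectral sensitivity; a graded decoupling
   would smooth it away. The clamp at zero embodies the circuit's elevated
   threshold: dim blue-branch stimuli produce no output at all.

M1 and displaced-M1 ipRGCs are treated as one functional unit, and only ON
signals propagate — both standing assumptions of the circuit. The rod shunt
is applied to the summed blue-branch signal (intrinsic + SB); the anatomy
does not disambiguate whether the SB input is shunted too, and this choice
keeps the blue branch a single subtractive node.

## Sensitivity curves and metrics

The predicted action spectrum at a criterion level L (default 300 scotopic
lx, the level at which rod shunting controls the ipRGC threshold and which
sits near the half-saturation of melatonin-suppression dose–response data)
is built per the standard action-spectrum convention: at each wavelength of
the 400–650 nm evaluation span a monochromatic line is scaled to criterion
power P(λ) = L / (1700·V′(λ)), and sensitivity is R/P, peak-normalized.
The ordinate is per-irradiance (not per-quantum) sensitivity — the
convention adopted here since either is defensible. The
`melanopsin_only` variant runs the same pipeline with R = X_mel and is the
reference for the curve comparisons. Cross-curve comparisons (enhancement
below 470 nm, reduction at 470–500 nm, notch depth) are made on a common
absolute scale (both curves divided by the reference peak); on the yellow
branch the two curves then coincide exactly.

Metrics: FWHM is the distance between the outermost half-maximum crossings,
each located by linear interpolation between bracketing grid points (so the
notch dip never masquerades as a flank). The notch wavelength is the right
edge of the largest adjacent-step jump — at the branch discontinuity this
is the first yellow-branch grid point. The subadditivity index is
R(A+B)/(R(A)+R(B)).

Because excitations are linear and a line stimulus excites class i by
exactly sᵢ(λ)·P, curves are evaluated from a precomputed sensitivity table;
the test suite verifies this equals running the per-stimulus pipeline at
every sampled wavelength to machine precision.

## Calibration

k has the closed form above (nudged by at most a few ulps so the
cross-point line lands on the yellow branch under floating-point rounding).
The four free gains (a1, a2, a3, rod_sat) have no published values; they
are set by a deterministic lexicographic grid search over fixed
geometrically spaced lattices, minimizing |FWHM(full curve at criterion) −
100 nm| subject to three constraints: enhancement at 460 nm and reduction
at 490 nm relative to the melanopsin-only curve, and "threshold dominance"
— the low-power shunt slope a2·s_rod/rod_sat must exceed the direct-plus-SB
drive at 480 nm, so that rod shunting genuinely imposes an elevated
threshold on short-wavelength stimuli. Ties keep the earlier lattice point,
so calibration is bit-reproducible. The default calibration returns
a1 = 1.0, a2 = 0.15 W·m⁻², a3 = 10 per unit V_ach, rod_sat = 0.05 W·m⁻²,
k ≈ 0.4889, giving FWHM ≈ 99.9 nm at 300 scotopic lx with the notch at
500 nm.

## Parameters

| parameter | meaning | units | default |
|---|---|---|---|
| λmax (rod/mel/L/M/S) | template peaks (retinal, pre-lens) | nm | 498/480/565/535/430 |
| half-bandwidth | template FWHM | nm | 80 |
| k | opponent balance gain | – | calibrated (≈0.4889) |
| a1 | SB→ipRGC input gain | – | calibrated (1.0) |
| a2 | maximum shunt amplitude | W·m⁻² | calibrated (0.15) |
| a3 | cone release gain | per unit V_ach | calibrated (10) |
| rod_sat | rod half-saturation constant | W·m⁻² | calibrated (0.05) |
| criterion | curve light level | scotopic lx | 300 |
| grid | computational wavelength grid | nm | 380–780 at 1 |
| evaluation span | curve abscissa | nm | 400–650 |

## Bundled data

* CIE 1924 photopic V(λ) and CIE 1951 scotopic V′(λ), written from the
  standard published 5–10 nm tabulations and monotone-interpolated (PCHIP)
  to 1 nm; V′(507) = 1 and V(555) = 1 exactly. Luminous-efficacy constants:
  1700 lm·W⁻¹ (scotopic), 683 lm·W⁻¹ (photopic).
* A **synthetic** crystalline-lens transmittance table,
  T(λ) = 10^(−2.0·exp(−(λ−380)/50)): an analytic stand-in with the
  qualitative shape of standard-observer lens-density data (strong
  short-wavelength absorption, monotone recovery, ≥0.99 above 700 nm).
  It is a fixed-age average; no age dependence, macular pigment or pupil
  correction is modelled. A `unity` lens is available for ablations.

λmax values are treated as retinal (pre-lens) peaks with lens filtering
applied on top; with the bundled lens the corneal melanopsin peak lands at
491 nm.

## Synthetic stimuli

The generators emulate the stimulus classes of the melatonin-suppression
literature: monochromatic lines and Gaussian narrowbands (interference-
filter stimuli of action-spectrum studies), peak-normalized Planck
blackbody radiators ("warm" 2700 K vs "cool" 6500 K white sources
straddling the b−y cross-point), and weighted mixtures (two-primary
experiments). They are idealized: no real-lamp spectral structure,
no stray light, no field-size or pupil variation, and the model itself has
no temporal dynamics or retinal spatial structure — passing tests show the
circuit's spectral logic, not fidelity to any individual observer.

## Numerical choices and edge cases

* Trapezoid quadrature for continuous spectra; rectangle (value × step) for
  generated line spectra. The two coincide for lines strictly inside the
  grid; the tag matters only at grid endpoints.
* Off-grid monochromatic requests and unknown tags raise `ValidationError`;
  nothing is silently snapped or interpolated.
* SPD files outside the grid range are zero-filled with a logged warning.
* Corneal sensitivities are renormalized after lens multiplication; an
  all-zero product is an error. Sampled-maximum ties break to the first
  (shortest-wavelength) index.
* Wavelengths where V′(λ) = 0 on the grid cannot reach a scotopic criterion;
  the curve builder refuses to interpolate over such points (none occur on
  the default grid and span).
* Degenerate metric inputs (constant curves, both-dark subadditivity pairs)
  raise `MetricUndefinedError` rather than returning a number.

## Known limitations

* The model is steady-state and spatially lumped; no depolarization block,
  no receptive-field structure, no melatonin-suppression dose–response
  transform (the pipeline stops at circadian drive).
* For two identical blue-branch stimuli the saturating (concave) shunt
  makes doubling slightly *super*additive; subadditivity is a property of
  blue+yellow (opponent-differenced) mixtures, which is the regime the
  index is designed for.
* The Gaussian template is an idealization of opsin nomograms; a nomogram
  backend could replace it behind the same `pigment_template` signature.
* The lens table is synthetic (above); absolute corneal sensitivities
  below ~430 nm depend on it more than any other choice.
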