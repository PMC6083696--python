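# Methods

## Model and procedure

The analysis assumes resonance Raman spectra of a conjugated polyene
pigment embedded in a β-keratin matrix, collected at several excitation
wavelengths from one region. The two backbone stretching modes — ν̃(C−C)
in 1130–1145 cm⁻¹ and ν̃(C=C) in 1525–1550 cm⁻¹ — are located per
excitation, referenced to the band position at the lowest excitation
energy (ν̃0R), and combined through the amplitude-mode-model product rule
∏ₙ(ν̃nR/ν̃0R)² = 2λ̄. The dispersion rate D is the ordinary-least-squares
slope of 2λ̄ on excitation energy E_L. The model is agnostic to the
microscopic origin of the dispersion (conformational distribution vs
intermolecular coupling); it only quantifies how strongly the effective
chromophore population re-weights with E_L.

Key statistical conventions:

- Regressions use `scipy.stats.linregress`: slope, intercept, R², standard
  error, and a two-sided t-test p-value with n−2 degrees of freedom. No
  multiple-testing correction is applied. R² and p are invariant to the
  energy axis; D is reported in both unit systems, related by exactly
  8065.544 cm⁻¹/eV.
- "Fit error" is defined as 100·SE(D)/|D| from the product-rule
  regression — a standard relative-precision measure; the definition is
  recorded in the output (`fit_error_definition`). It is undefined
  (reported as not applicable) when |D| vanishes.
- The `significant` flag fires when any tracked band's center range across
  included excitations exceeds 3 cm⁻¹, the combined spectral-resolution
  and calibration tolerance of the acquisition protocol this pipeline
  models. It deliberately tests the *shift*, not the regression p-value:
  a tiny but well-resolved slope is instrumentally indistinguishable from
  calibration drift.
- D is printed in cm on the cm⁻¹ energy axis. Dimensional analysis of the
  defining slope (dimensionless over cm⁻¹) fixes this unit; the eV⁻¹
  value is the same slope times 8065.544.

## Tunable parameters

| parameter | default | units | rationale |
|---|---|---|---|
| crop window | 900–1800 | cm⁻¹ | fingerprint region holding the doublet and all matrix bands |
| Savitzky–Golay | window 11 pts, order 3 | — | mild smoothing that preserves 10–16 cm⁻¹ wide bands; reproduces cubics exactly |
| AsLS baseline | λ = 1e5, p = 0.01, ≤ 50 iterations | — | common robust defaults for Raman backgrounds; polynomial (order 3) alternative |
| band windows | C−C (1090, 1190), C=C (1490, 1590) | cm⁻¹ | ±50 cm⁻¹ around the nominal 1140/1540 cm⁻¹ positions, matching the map sum filters |
| keratin windows | ±20 around 1006, 1240, 1450, 1670 | cm⁻¹ | narrow enough to exclude the pigment bands |
| detection `min_snr` | 5 | — | both doublet bands must clear it as interior maxima |
| significance threshold | 3 | cm⁻¹ | instrument resolution + calibration tolerance |
| exclusions (replication runs) | 351, 448, 785 nm | — | pre-resonant wavelengths and one spurious acquisition; configuration, not hard-coded |

Preprocessing order is crop → smooth → baseline → normalize → average for
the survey workflow; for excitation series, raw replicates are averaged
before normalization. Band *positions*, the only preprocessing-sensitive
input to the dispersion fit, shift by < 0.5 cm⁻¹ under the full chain on
noiseless fixtures (tested).

## Peak location and SNR

`argmax_parabolic` refines the in-window grid maximum with a parabola
through it and its two neighbours (ties resolve to the lower wavenumber;
maxima on the window edge are flagged, not refined). `lorentzian_ls` fits
amplitude, center, width and a linear offset by bounded least squares,
initialized at the grid maximum, falling back to the parabolic estimate
with a flag on non-convergence. On a 1 cm⁻¹ grid the parabolic center
error for noiseless Lorentzian bands is below 0.01 cm⁻¹; the Lorentzian
fit is exact to numerical precision.

Peak height is measured above the window *median* — a floor a lone band
barely moves — and the noise level is 1.4826 × MAD of the residuals from
a quadratic fitted to the off-peak points (±fwhm around the candidate is
excluded, capped at a quarter of the window span). Fitting the detrend
only to off-peak points keeps band tails out of the noise estimate in
narrow windows, and using residual spread rather than point-to-point
differences keeps the estimate honest on smoothed (noise-correlated)
spectra, where empty windows would otherwise produce spuriously high SNR.

## Synthetic generator

The generator emulates the statistical structure the analysis assumes:

- Lorentzian bands (standard for Raman line shapes): pigment doublet at
  1135/1528 cm⁻¹ (heights 1.0/1.2, FWHM 12/14 cm⁻¹), keratin bands at
  1006/1240/1450/1670 cm⁻¹ at ~0.2–0.25 relative height; optional first
  overtones at twice the fundamental positions.
- Dispersion models: `none` (yellow-like single chromophore), `linear`
  (center = ν̃₀ + s·(E_L − E_ref), the analytically tractable case), and
  `ensemble` — members with individual band centers, absorption maxima
  and a Lorentzian resonance profile Γ²/((E_L−E_abs)²+Γ²) weighting their
  contribution to the observed (population-averaged) center. The red-like
  preset uses three members with C=C centers 1524–1544 cm⁻¹, absorption
  maxima at 450–600 nm equivalents and Γ = 3000 cm⁻¹, calibrated to give
  D of order 10⁻⁶ cm; these are modelling choices, not measured values.
  Beyond the ensemble's absorption span the resonance weighting flattens
  and centers roll over — the pre-resonant regime that motivates excluding
  extreme wavelengths from dispersion fits.
- Backgrounds: broad Gaussian emission (yellow-like preset, amplitude 0.6),
  polynomial baseline drift, i.i.d. Gaussian intensity noise, and optional
  per-spectrum Gaussian jitter of band centers. All randomness flows from
  one seed; identical (config, seed) gives bit-identical output.
- Study-sized defaults: the 13-wavelength excitation list (351–785 nm),
  3 replicates per excitation, 1 cm⁻¹ grid over 900–1800 cm⁻¹, a
  26-record hue panel (5 magenta, 7 each red/orange/yellow) with hue-step
  trend 3–4 cm⁻¹ against 2 cm⁻¹ spread.

What the generator does **not** emulate: cosmic-ray spikes, detector
etaloning and wavenumber-calibration drift, non-Lorentzian (Voigt)
broadening, resonance-enhanced *intensity* changes across excitations,
and any quantitative link between conjugation length and band position or
absorption maximum. Passing tests therefore demonstrate correctness of
the estimators under the assumed signal model, not robustness to every
instrumental artefact of real acquisitions.

## Numerical choices and degenerate inputs

- Descending wavenumber axes are silently normalized; duplicate axis
  values are rejected as ambiguous. Resampling is linear-only (no spline
  ringing near narrow bands) and refuses extrapolation.
- Constant spectra cannot be 0–1 normalized (degenerate-input error);
  constant tracks give D = 0 with fit error reported as not applicable,
  R² = 0, p = 1.
- AsLS iterates to a weight fixed point or relative tolerance 1e-6 within
  50 iterations; hitting the cap attaches a non-fatal flag.
- Hue-trend Spearman uses average ranks; the all-tied case is reported as
  ρ = 0, p = 1.
- Fewer than 3 included excitations is an insufficient-data error
  (exit code 4 from the CLI); a zero-variance energy design is a
  degenerate-input error.

## Problem sizes

The test suite and the acceptance script run Monte-Carlo checks at 100
seeds with single-replicate series on the 901-point grid — sizes at which
the estimator distributions are already stable (the recovery median moves
by < 1 point of relative error between seed sets) while the whole suite
completes in seconds.

## Known limitations

- The dispersion fit treats per-excitation band centers as independent
  observations; correlated calibration error across a series would bias D
  in a way the model cannot detect.
- The product rule multiplies squared ratios from whichever bands are
  tracked (default: the two pigment bands). If only a subset of dispersing
  modes is tracked, 2λ̄ and D are correspondingly partial.
- The emission index is an operational background-level measure (median
  over peak-free windows), not a photophysical emission measurement.
- With ~10 excitations, R² and p from the product regression are coarse;
  the 3 cm⁻¹ shift criterion is the primary significance gate.
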