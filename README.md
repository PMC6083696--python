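# ramanfd

Resonance Raman frequency-dispersion analysis of conjugated pigments in
feathers.

## The problem

Parrot feathers owe their magenta-to-yellow colours to psittacofulvins —
linear polyenal pigments with a conjugated carbon backbone. Their Raman
spectrum is a simple doublet: the C−C stretch near 1130–1145 cm⁻¹ and the
C=C stretch near 1525–1550 cm⁻¹, labelled ν̃(C−C) and ν̃(C=C), on top of
fixed β-keratin matrix bands (1006, 1240, 1450, 1670 cm⁻¹). When the
excitation wavelength is tuned through the pigment's absorption band,
resonance selectively enhances chromophore sub-populations. If the sample
hosts a *distribution* of effective conjugation lengths (conformers, or
molecules coupled through π–π interactions), the band centers shift with
excitation energy — **frequency dispersion**. A single chromophore shows no
dispersion. Quantifying this distinguishes structurally organized pigment
(red barbs) from a homogeneous, single-chromophore-like mixture (yellow
barbs).

## The model

The amplitude mode model (AMM) condenses an excitation series into two
numbers. With ν̃₀R the band wavenumber at the lowest excitation energy used
and ν̃nR the same band at other excitation energies E_L, the *product rule*

```
∏ₙ (ν̃nR / ν̃0R)² = 2λ̄
```

taken over the dispersing modes gives an effective electron–phonon coupling
constant λ̄ per excitation energy, and the *dispersion rate*

```
D = Δ ∏ₙ(ν̃nR/ν̃0R)² / ΔE_L
```

is the slope of 2λ̄ against E_L (units cm when E_L is in cm⁻¹, eV⁻¹ when
in eV; 1 eV = 8065.544 cm⁻¹). D ≈ 0 means one chromophore; larger D means
coupled or heterogeneous chromophores. Band shifts greater than 3 cm⁻¹
exceed the combined spectral and calibration resolution and are treated as
sample-related.

The package provides the full chain: plain-text spectrum/manifest I/O,
preprocessing (crop to 900–1800 cm⁻¹, Savitzky–Golay smoothing, AsLS or
polynomial baseline correction, 0–1 normalization, replicate averaging),
band localization (parabolic refinement or Lorentzian least squares),
excitation-series tracking, the AMM fit with per-band regressions (R², p,
fit error = 100·SE(D)/|D|), ±50 cm⁻¹ band-sum hyperspectral maps, a
hue-trend survey (Spearman rank correlation of band position against the
magenta < red < orange < yellow hue order), and a synthetic generator with
ground truth for closed-loop testing.

## Worked example

Simulate a red-like excitation series (three-member chromophore ensemble,
13 excitation wavelengths, 3 replicates each) and fit the dispersion rate,
excluding the two pre-resonant wavelengths and one spurious acquisition:

```
$ ramanfd simulate series --preset red --seed 11 --out red_series
$ ramanfd dispersion --manifest red_series/manifest.csv \
      --exclude 351,448,785 --out red_fit.json
AMM dispersion fit (10 excitations)
  D = 2.568e-06 cm  (0.02071 eV^-1)
  product rule: R^2 = 0.892, p = 3.9e-05
  fit error = 12.3%
  cc: slope 1.241e-06, R^2 = 0.892, p = 3.91e-05, range 7.04 cm^-1
  cc2: slope 1.309e-06, R^2 = 0.892, p = 3.96e-05, range 9.99 cm^-1
  dispersion significant (> 3 cm^-1 band-shift threshold)
```

Reading: across the 10 included excitations the product-rule values 2λ̄
rise with excitation energy at D = 2.57 × 10⁻⁶ cm (2.07 × 10⁻² eV⁻¹), the
C−C and C=C centers move by 7 and 10 cm⁻¹ — far beyond the 3 cm⁻¹
resolution threshold — so the series is flagged as dispersive: multiple
chromophores. A `--preset yellow` series (single chromophore plus an
emission background) comes back `not significant` with D two to three
orders of magnitude smaller.

Measured band positions can be fed directly as a table
(`ramanfd dispersion --peak-table peaks.csv`, columns
`band, excitation_nm, center`); `ramanfd survey` handles multi-feather
triplicate manifests, and `ramanfd map` produces band-sum images from
hyperspectral stacks. Everything is also available as library functions
(`ramanfd.fit_dispersion`, `ramanfd.track_band`, ...).

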