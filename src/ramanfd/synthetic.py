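"""Synthetic feather-Raman generator.

Every analysis stage in this package is exercised against fixtures from
this module, which emulates the statistical structure the analysis
assumes: a pigment doublet (C−C near 1135 cm⁻¹, C=C near 1528 cm⁻¹)
whose centers either stay put (yellow-like, single chromophore) or
shift with excitation energy (red-like, a resonance-weighted ensemble
of chromophores with different effective conjugation lengths), riding
on β-keratin matrix bands, an optional broad emission background,
polynomial baseline drift, optional first overtones at twice the
fundamentals, and additive Gaussian noise.  Ground-truth band centers
accompany every output so downstream tests are closed-loop.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np

from .errors import ConfigurationError, ValidationError
from .spectra_io import ExcitationSeries, HyperMap, Spectrum, write_spectrum
from .units import nm_to_invcm

__all__ = [
    "BandShape",
    "EnsembleMember",
    "SimConfig",
    "PAPER_EXCITATIONS_NM",
    "DEFAULT_EXCLUSIONS",
    "red_like_config",
    "yellow_like_config",
    "keratin_only_config",
    "ensemble_band_center",
    "band_centers_at",
    "simulate_spectrum",
    "simulate_series",
    "true_dispersion",
    "simulate_hue_panel",
    "simulate_hypermap",
    "write_series_fixture",
]

#: The thirteen excitation wavelengths (nm) of the resonance series:
#: krypton-ion lines, solid-state lines, and a 785 nm non-resonant line.
PAPER_EXCITATIONS_NM: tuple[float, ...] = (
    351.0, 375.0, 407.0, 413.0, 448.0, 458.0, 491.0, 515.0,
    532.0, 568.0, 594.0, 648.0, 785.0)

#: Default exclusions for replication-style dispersion runs: the two
#: pre-resonant wavelengths and the one spurious acquisition.
DEFAULT_EXCLUSIONS: dict[float, str] = {
    351.0: "pre-resonant", 448.0: "spurious", 785.0: "pre-resonant"}


@dataclass(frozen=True)
class BandShape:
    """Lorentzian band: center (cm⁻¹), peak height (a.u.), FWHM (cm⁻¹)."""
    center: float
    height: float
    fwhm: float


@dataclass(frozen=True)
class EnsembleMember:
    """One chromophore sub-population: population weight, its band
    centers, its absorption maximum E_abs (cm⁻¹) and resonance width
    Γ (cm⁻¹).  Longer effective conjugation → lower E_abs and lower
    stretching wavenumbers."""
    weight: float
    centers: Mapping[str, float]
    e_abs_invcm: float
    gamma_invcm: float


@dataclass
class SimConfig:
    """Ground-truth parameters of the generator (one feather region)."""

    grid: tuple[float, float, float] = (900.0, 1800.0, 1.0)  # lo, hi, step cm⁻¹
    pigment_bands: dict[str, BandShape] = field(default_factory=lambda: {
        "cc": BandShape(1135.0, 1.0, 12.0),
        "cc2": BandShape(1528.0, 1.2, 14.0),
    })
    keratin_bands: dict[str, BandShape] = field(default_factory=lambda: {
        "keratin_1006": BandShape(1006.0, 0.25, 10.0),
        "keratin_1240": BandShape(1240.0, 0.20, 14.0),
        "keratin_1450": BandShape(1450.0, 0.22, 12.0),
        "keratin_1670": BandShape(1670.0, 0.25, 16.0),
    })
    dispersion_model: str = "none"             # none | linear | ensemble
    linear_slopes: dict[str, float] = field(default_factory=dict)  # cm⁻¹ per cm⁻¹ E_L
    reference_energy_invcm: float = nm_to_invcm(648.0)
    ensemble: list[EnsembleMember] = field(default_factory=list)
    center_jitter_sd: float = 0.0              # cm⁻¹, per spectrum per band
    overtones: bool = False
    overtone_rel_height: float = 0.15
    emission_amplitude: float = 0.0            # broad Gaussian background
    emission_center: float = 1300.0
    emission_fwhm: float = 1600.0
    baseline_coeffs: tuple[float, ...] = ()    # polynomial on scaled axis
    noise_sd: float = 0.01
    region_label: str = "synthetic"
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi, step = self.grid
        if step <= 0 or hi <= lo:
            raise ConfigurationError("grid must be (lo, hi, step) with step > 0, hi > lo")
        if self.noise_sd < 0 or self.center_jitter_sd < 0:
            raise ConfigurationError("noise levels must be non-negative")
        for name, b in {**self.pigment_bands, **self.keratin_bands}.items():
            if b.height < 0 or b.fwhm <= 0:
                raise ConfigurationError(f"band {name}: height >= 0 and fwhm > 0 required")
            if not lo <= b.center <= hi:
                raise ConfigurationError(f"band {name} center {b.center} outside grid")
        if self.dispersion_model not in ("none", "linear", "ensemble"):
            raise ConfigurationError(f"unknown dispersion_model {self.dispersion_model!r}")
        if self.dispersion_model == "ensemble":
            if not self.ensemble:
                raise ConfigurationError("ensemble model requires ensemble members")
            if all(m.weight == 0 for m in self.ensemble):
                raise ConfigurationError("ensemble weights must not all be zero")
            if any(m.weight < 0 or m.gamma_invcm <= 0 for m in self.ensemble):
                raise ConfigurationError("weights >= 0 and gamma > 0 required")

    def axis(self) -> np.ndarray:
        lo, hi, step = self.grid
        n = int(round((hi - lo) / step)) + 1
        return lo + step * np.arange(n)


def red_like_config(**overrides) -> SimConfig:
    """Red-region study conditions: a resonance-weighted three-member
    chromophore ensemble giving a dispersion rate of order 1e-6 cm."""
    ensemble = [
        EnsembleMember(1.0, {"cc": 1130.0, "cc2": 1524.0},
                       e_abs_invcm=nm_to_invcm(600.0), gamma_invcm=3000.0),
        EnsembleMember(1.0, {"cc": 1137.0, "cc2": 1534.0},
                       e_abs_invcm=nm_to_invcm(520.0), gamma_invcm=3000.0),
        EnsembleMember(1.0, {"cc": 1144.0, "cc2": 1544.0},
                       e_abs_invcm=nm_to_invcm(450.0), gamma_invcm=3000.0),
    ]
    cfg = SimConfig(dispersion_model="ensemble", ensemble=ensemble,
                    region_label="red")
    return replace(cfg, **overrides) if overrides else cfg


def yellow_like_config(**overrides) -> SimConfig:
    """Yellow-region study conditions: one chromophore (no dispersion),
    higher band positions, broad emission background."""
    cfg = SimConfig(
        pigment_bands={
            "cc": BandShape(1142.0, 0.8, 12.0),
            "cc2": BandShape(1545.0, 1.0, 14.0),
        },
        dispersion_model="none",
        emission_amplitude=0.6,
        region_label="yellow",
    )
    return replace(cfg, **overrides) if overrides else cfg


def keratin_only_config(**overrides) -> SimConfig:
    """White-feather emulation: β-keratin bands only, no pigment."""
    cfg = SimConfig(
        pigment_bands={
            "cc": BandShape(1135.0, 0.0, 12.0),
            "cc2": BandShape(1528.0, 0.0, 14.0),
        },
        keratin_bands={
            "keratin_1006": BandShape(1006.0, 1.0, 10.0),
            "keratin_1240": BandShape(1240.0, 0.8, 14.0),
            "keratin_1450": BandShape(1450.0, 0.9, 12.0),
            "keratin_1670": BandShape(1670.0, 1.0, 16.0),
        },
        region_label="white",
    )
    return replace(cfg, **overrides) if overrides else cfg


def ensemble_band_center(ensemble: Sequence[EnsembleMember], band: str,
                         e_l_invcm: float) -> float:
    """Resonance-weighted mean band center at excitation energy E_L.

    Member weights are ``w_i ∝ weight_i · Γ² / ((E_L − E_abs,i)² + Γ²)``
    (Lorentzian resonance profile).  If every resonance factor
    underflows, population weights are used instead."""
    if not ensemble:
        raise ConfigurationError("empty ensemble")
    w = np.array([m.weight * m.gamma_invcm**2 /
                  ((e_l_invcm - m.e_abs_invcm) ** 2 + m.gamma_invcm**2)
                  for m in ensemble])
    if w.sum() <= 0 or not np.isfinite(w.sum()):
        w = np.array([m.weight for m in ensemble], dtype=float)
    centers = np.array([m.centers[band] for m in ensemble], dtype=float)
    return float((w * centers).sum() / w.sum())


def band_centers_at(config: SimConfig, excitation_nm: float) -> dict[str, float]:
    """Noiseless ground-truth pigment band centers at one excitation."""
    e_l = nm_to_invcm(excitation_nm)
    out = {}
    for band, shape in config.pigment_bands.items():
        if config.dispersion_model == "none":
            c = shape.center
        elif config.dispersion_model == "linear":
            s = config.linear_slopes.get(band, 0.0)
            c = shape.center + s * (e_l - config.reference_energy_invcm)
        else:
            c = ensemble_band_center(config.ensemble, band, e_l)
        out[band] = c
    return out


def _lorentz(w: np.ndarray, center: float, height: float, fwhm: float) -> np.ndarray:
    g = fwhm / 2.0
    return height * g**2 / ((w - center) ** 2 + g**2)


def simulate_spectrum(
    config: SimConfig, excitation_nm: float | None = None,
    rng: np.random.Generator | None = None, replicate_id: str = "r1",
) -> tuple[Spectrum, dict]:
    """One synthetic trace plus its ground-truth record.

    Identical (config, seed) → bit-identical output.  The truth record
    carries the noiseless pigment centers actually used (pre-jitter),
    the keratin centers, and the generator settings that matter
    downstream."""
    if rng is None:
        rng = np.random.default_rng(config.seed)
    w = config.axis()
    y = np.zeros_like(w)

    exc = excitation_nm if excitation_nm is not None else 532.0
    pigment_centers = band_centers_at(config, exc)
    for band, shape in config.pigment_bands.items():
        if shape.height <= 0:
            continue
        center = pigment_centers[band]
        if config.center_jitter_sd > 0:
            center = center + rng.normal(0.0, config.center_jitter_sd)
        y += _lorentz(w, center, shape.height, shape.fwhm)
        if config.overtones:
            oc = 2.0 * center
            if w[0] <= oc <= w[-1]:
                y += _lorentz(w, oc, shape.height * config.overtone_rel_height,
                              1.5 * shape.fwhm)
    for shape in config.keratin_bands.values():
        if shape.height > 0:
            y += _lorentz(w, shape.center, shape.height, shape.fwhm)

    if config.emission_amplitude > 0:
        sigma = config.emission_fwhm / 2.3548200450309493
        y += config.emission_amplitude * np.exp(
            -0.5 * ((w - config.emission_center) / sigma) ** 2)
    if config.baseline_coeffs:
        x = (w - w.mean()) / (np.ptp(w) / 2.0)
        y += np.polynomial.polynomial.polyval(x, np.asarray(config.baseline_coeffs))
    if config.noise_sd > 0:
        y = y + rng.normal(0.0, config.noise_sd, w.size)

    spec = Spectrum(w, y, excitation_nm=excitation_nm,
                    region_label=config.region_label,
                    replicate_id=replicate_id, source="synthetic")
    truth = {
        "excitation_nm": excitation_nm,
        "pigment_centers": pigment_centers,
        "keratin_centers": {b: s.center for b, s in config.keratin_bands.items()
                            if s.height > 0},
        "dispersion_model": config.dispersion_model,
    }
    return spec, truth


def simulate_series(
    config: SimConfig,
    excitations: Sequence[float] = PAPER_EXCITATIONS_NM,
    n_replicates: int = 3,
    seed: int | None = None,
) -> tuple[ExcitationSeries, dict]:
    """Replicate-averaged excitation series plus ground truth.

    Replicates at each excitation get independent noise and center
    jitter, then are averaged pointwise (the raw-replicate averaging of
    the series workflow).  Truth carries per-excitation noiseless
    centers per band and, via :func:`true_dispersion`, the exact
    dispersion rate they imply."""
    excitations = [float(x) for x in excitations]
    if len(excitations) < 3:
        raise ConfigurationError("need >= 3 excitations for a series")
    if len(set(excitations)) != len(excitations):
        raise ValidationError("duplicate excitation wavelengths")
    rng = np.random.default_rng(config.seed if seed is None else seed)

    entries: dict[float, Spectrum] = {}
    centers: dict[str, dict[float, float]] = {b: {} for b in config.pigment_bands}
    for nm in sorted(excitations):
        reps = []
        for k in range(n_replicates):
            spec, truth = simulate_spectrum(config, nm, rng=rng,
                                            replicate_id=f"r{k + 1}")
            reps.append(spec)
        mean = np.mean([s.intensities for s in reps], axis=0)
        entries[nm] = Spectrum(reps[0].wavenumbers.copy(), mean,
                               excitation_nm=nm, region_label=config.region_label,
                               replicate_id=f"mean(n={n_replicates})",
                               source="synthetic")
        for band in centers:
            centers[band][nm] = truth["pigment_centers"][band]

    truth = {
        "centers": centers,
        "dispersion_model": config.dispersion_model,
        "linear_slopes": dict(config.linear_slopes),
        "reference_energy_invcm": config.reference_energy_invcm,
        "D_true_cm": true_dispersion(centers),
    }
    return ExcitationSeries(region_label=config.region_label, entries=entries), truth


def true_dispersion(centers: Mapping[str, Mapping[float, float]],
                    exclusions: Sequence[float] = ()) -> float:
    """Exact dispersion rate (cm) implied by noiseless band centers.

    Builds the product-rule values from the true centers (reference =
    lowest excitation energy among included wavelengths) and returns
    the OLS slope against E_L in cm⁻¹."""
    excl = {float(x) for x in exclusions}
    some_band = next(iter(centers.values()))
    nm = np.array(sorted((x for x in some_band if
                          not any(abs(x - e) < 1e-6 for e in excl)),
                         reverse=True))
    if nm.size < 3:
        raise ValidationError("need >= 3 included excitations for true_dispersion")
    e = nm_to_invcm(nm)
    prod = np.ones(nm.size)
    for band_centers in centers.values():
        c = np.array([band_centers[x] for x in nm])
        prod *= (c / c[0]) ** 2
    slope = np.polyfit(e, prod, 1)[0]
    return float(slope)


HUE_MEANS_STEP_DEFAULT = 4.0


def simulate_hue_panel(
    n_per_hue: int = 7,
    trend: float = HUE_MEANS_STEP_DEFAULT,
    noise_sd: float = 2.0,
    seed: int = 0,
    counts: Mapping[str, int] | None = None,
    base_cc: float = 1128.0,
    base_cc2: float = 1518.0,
):
    """Hue panel: band positions drawn around hue-ordered means.

    Means rise by ``trend`` cm⁻¹ per hue step from magenta (lowest) to
    yellow (highest); draws are Gaussian with ``noise_sd`` and clipped
    to the band windows.  Returns a list of
    :class:`~ramanfd.dispersion.HueRecord`."""
    from .dispersion import HUE_ORDER, HueRecord
    from .peakfit import BAND_WINDOWS

    if counts is None:
        counts = {h: int(n_per_hue) for h in HUE_ORDER}
    if any(v < 1 for v in counts.values()):
        raise ConfigurationError("need >= 1 record per requested hue")
    for k, (base, band) in enumerate(((base_cc, "cc"), (base_cc2, "cc2"))):
        lo, hi = BAND_WINDOWS[band]
        top = base + trend * (len(HUE_ORDER) - 1)
        if not (lo <= base <= hi and lo <= top <= hi):
            raise ConfigurationError(
                f"hue means for {band} leave window ({lo}, {hi})")
    rng = np.random.default_rng(seed)
    records = []
    i = 0
    for step, hue in enumerate(HUE_ORDER):
        for _ in range(counts.get(hue, 0)):
            cc = base_cc + trend * step + (rng.normal(0, noise_sd) if noise_sd else 0.0)
            cc2 = base_cc2 + trend * step + (rng.normal(0, noise_sd) if noise_sd else 0.0)
            cc = float(np.clip(cc, *BAND_WINDOWS["cc"]))
            cc2 = float(np.clip(cc2, *BAND_WINDOWS["cc2"]))
            records.append(HueRecord(f"sim{i:03d}", hue, cc, cc2))
            i += 1
    return records


def simulate_hypermap(
    n_rows: int = 16,
    n_cols: int = 16,
    mask: np.ndarray | None = None,
    inside: SimConfig | None = None,
    outside: SimConfig | None = None,
    excitation_nm: float = 532.0,
    pixel_size_um: float = 30.0,
    seed: int = 0,
) -> tuple[HyperMap, np.ndarray]:
    """Pixel grid with a pigmented (or emissive) region on a keratin
    background.  ``mask`` is a boolean (n_rows, n_cols) array marking
    the ``inside`` region; default is a centered disc of radius
    min(n)/4.  Returns (HyperMap, mask)."""
    if n_rows < 2 or n_cols < 2:
        raise ConfigurationError("hypermap needs at least a 2x2 grid")
    if mask is None:
        r = np.arange(n_rows)[:, None] - (n_rows - 1) / 2.0
        c = np.arange(n_cols)[None, :] - (n_cols - 1) / 2.0
        mask = (r**2 + c**2) <= (min(n_rows, n_cols) / 4.0) ** 2
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != (n_rows, n_cols):
        raise ValidationError(f"mask shape {mask.shape} != ({n_rows}, {n_cols})")
    inside = inside if inside is not None else red_like_config()
    outside = outside if outside is not None else keratin_only_config()
    if inside.grid != outside.grid:
        raise ConfigurationError("inside and outside configs must share a grid")

    rng = np.random.default_rng(seed)
    axis = inside.axis()
    data = np.empty((n_rows, n_cols, axis.size))
    for i in range(n_rows):
        for j in range(n_cols):
            cfg = inside if mask[i, j] else outside
            spec, _ = simulate_spectrum(cfg, excitation_nm, rng=rng,
                                        replicate_id=f"px({i},{j})")
            data[i, j] = spec.intensities
    return HyperMap(n_rows, n_cols, pixel_size_um, axis, data,
                    excitation_nm=excitation_nm), mask


def write_series_fixture(
    outdir: str | os.PathLike,
    config: SimConfig | None = None,
    excitations: Sequence[float] = PAPER_EXCITATIONS_NM,
    n_replicates: int = 3,
    seed: int = 0,
) -> str:
    """Emit per-replicate spectrum files plus a manifest; returns the
    manifest path.  The manifest feeds :func:`ramanfd.spectra_io.read_series`."""
    config = config if config is not None else red_like_config()
    os.makedirs(outdir, exist_ok=True)
    rng = np.random.default_rng(seed)
    rows = ["path,excitation_nm,region_label,replicate_id"]
    for nm in sorted(float(x) for x in excitations):
        for k in range(n_replicates):
            spec, _ = simulate_spectrum(config, nm, rng=rng, replicate_id=f"r{k + 1}")
            fname = f"exc{nm:g}_r{k + 1}.csv"
            write_spectrum(spec, os.path.join(outdir, fname))
            rows.append(f"{fname},{nm:g},{config.region_label},r{k + 1}")
    manifest = os.path.join(outdir, "manifest.csv")
    with open(manifest, "w", encoding="utf-8") as fh:
        fh.write("\n".join(rows) + "\n")
    return manifest
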