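"""Band localization and excitation-series peak tracking.

The two pigment bands of the conjugated polyene backbone — the C−C
stretch near 1130–1145 cm⁻¹ and the C=C stretch near 1525–1550 cm⁻¹ —
are located either by parabolic refinement of the grid maximum or by a
Lorentzian least-squares fit.  β-keratin matrix bands (1006, 1240,
1450, 1670 cm⁻¹) are detected the same way in ±20 cm⁻¹ windows.
Tracking a band across an excitation series yields the per-excitation
center trajectory referenced to the lowest excitation energy, the raw
material of the dispersion analysis.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.optimize import curve_fit

from .errors import InsufficientDataError, RangeError, ValidationError
from .spectra_io import ExcitationSeries, Spectrum
from .units import nm_to_invcm, invcm_to_eV

__all__ = [
    "Peak",
    "BandTrack",
    "BAND_WINDOWS",
    "KERATIN_CENTERS",
    "find_band",
    "detect_psittacofulvin",
    "keratin_bands",
    "track_band",
]

#: Default search windows (cm⁻¹) for the pigment doublet — ±50 cm⁻¹
#: around the nominal 1140 / 1540 cm⁻¹ band positions, matching the
#: sum-filter windows used for hyperspectral maps.
BAND_WINDOWS: dict[str, tuple[float, float]] = {
    "cc": (1090.0, 1190.0),
    "cc2": (1490.0, 1590.0),
}

#: Nominal β-keratin band centers (cm⁻¹): phenylalanine ring breathing,
#: amide, CH₂ deformation, amide.
KERATIN_CENTERS: tuple[float, ...] = (1006.0, 1240.0, 1450.0, 1670.0)


@dataclass
class Peak:
    """A fitted band: center/height/width plus quality diagnostics."""

    band: str
    center: float
    height: float
    fwhm: float
    window: tuple[float, float]
    snr: float
    method: str
    flags: list[str] = field(default_factory=list)

    @property
    def on_edge(self) -> bool:
        return "edge" in self.flags


@dataclass
class BandTrack:
    """Per-excitation trajectory of one band across a series.

    Points are ordered by ascending excitation energy; the reference
    ν̃0R is the center measured at the lowest excitation energy
    included (longest wavelength).
    """

    band: str
    excitation_nm: np.ndarray          # included excitations, nm
    energy_invcm: np.ndarray           # E_L in cm⁻¹ (ascending)
    energy_eV: np.ndarray
    centers: np.ndarray                # ν̃nR in cm⁻¹, aligned with energies
    ref_center: float                  # ν̃0R
    ref_excitation_nm: float
    window: tuple[float, float]
    excluded: list[tuple[float, str]] = field(default_factory=list)
    peaks: list[Peak] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.centers.size != self.energy_invcm.size:
            raise ValidationError("track arrays misaligned")
        excluded_nm = {nm for nm, _ in self.excluded}
        if excluded_nm & set(np.round(self.excitation_nm, 9)):
            raise ValidationError("excitation both included and excluded")
        lo, hi = self.window
        if np.any((self.centers < lo) | (self.centers > hi)):
            raise ValidationError("tracked center outside band window")

    @property
    def max_shift(self) -> float:
        """Range of the band center across included excitations (cm⁻¹)."""
        return float(np.ptp(self.centers))

    def __len__(self) -> int:
        return self.centers.size


def _lorentzian(x, amp, x0, gamma, c0, c1):
    return amp * gamma**2 / ((x - x0) ** 2 + gamma**2) + c0 + c1 * (x - x0)


def _robust_noise(residuals: np.ndarray) -> float:
    mad = np.median(np.abs(residuals - np.median(residuals)))
    return 1.4826 * mad


def _window_noise(w: np.ndarray, y: np.ndarray, center: float, fwhm: float) -> float:
    """Noise level of a band window: robust spread of the residuals
    after a window-wide quadratic detrend, excluding the peak core.

    Points within ±fwhm of the candidate peak are excluded; a quadratic
    fitted to the remaining (off-peak) points absorbs slow background
    and band tails, so what remains is the window's noise-like
    variation even when smoothing has correlated it.
    """
    radius = min(fwhm, (w[-1] - w[0]) / 4.0)
    keep = np.abs(w - center) > radius
    if keep.sum() < 8:
        keep = np.ones(w.size, dtype=bool)
    wk, yk = w[keep], y[keep]
    resid = yk - np.polyval(np.polyfit(wk, yk, 2), wk)
    return _robust_noise(resid)


def _fwhm_from_grid(w: np.ndarray, y: np.ndarray, center: float, height: float,
                    floor: float) -> float:
    """Half-maximum crossings by linear interpolation within the window."""
    half = floor + height / 2.0
    above = y >= half
    if not above.any():
        return float(w[1] - w[0])
    idx = np.flatnonzero(above)
    left = w[idx[0]]
    if idx[0] > 0:
        w0, w1, y0, y1 = w[idx[0] - 1], w[idx[0]], y[idx[0] - 1], y[idx[0]]
        left = w0 + (half - y0) / (y1 - y0) * (w1 - w0) if y1 != y0 else w0
    right = w[idx[-1]]
    if idx[-1] < y.size - 1:
        w0, w1, y0, y1 = w[idx[-1]], w[idx[-1] + 1], y[idx[-1]], y[idx[-1] + 1]
        right = w0 + (half - y0) / (y1 - y0) * (w1 - w0) if y1 != y0 else w1
    return max(float(right - left), 1e-9)


def find_band(spec: Spectrum, window: tuple[float, float],
              method: str = "argmax_parabolic", band: str = "") -> Peak:
    """Locate the strongest band inside ``window``.

    ``argmax_parabolic`` refines the grid maximum with a parabola
    through it and its two neighbours; ``lorentzian_ls`` fits a
    Lorentzian plus a linear offset, initialized at the grid maximum,
    and falls back to the parabolic estimate (with a ``fallback`` flag)
    if the fit does not converge.  A maximum on the window edge is
    returned unrefined with an ``edge`` flag.  Ties on the grid maximum
    resolve to the lower wavenumber.
    """
    lo, hi = window
    mask = (spec.wavenumbers >= lo) & (spec.wavenumbers <= hi)
    if mask.sum() < 5:
        raise RangeError(f"window ({lo}, {hi}) holds fewer than 5 points")
    w = spec.wavenumbers[mask]
    y = spec.intensities[mask]
    i = int(np.argmax(y))  # first (= lowest wavenumber) on ties
    # height is measured above the window median: a robust floor that a
    # lone band barely moves, while min(y) would ride noise extremes and
    # inflate the SNR of empty windows
    floor = float(np.median(y))
    flags: list[str] = []

    if i == 0 or i == y.size - 1:
        height = max(float(y[i]) - floor, 0.0)
        fwhm = _fwhm_from_grid(w, y, float(w[i]), height, floor)
        noise = _window_noise(w, y, float(w[i]), fwhm)
        return Peak(band, float(w[i]), max(height, 1e-300), fwhm, window,
                    height / noise if noise > 0 else np.inf,
                    method, ["edge"])

    if method == "lorentzian_ls":
        fwhm0 = _fwhm_from_grid(w, y, float(w[i]), float(y[i]) - floor, floor)
        p0 = [float(y[i]) - floor, float(w[i]), max(fwhm0 / 2.0, (w[1] - w[0]) / 2.0),
              floor, 0.0]
        try:
            popt, _ = curve_fit(
                _lorentzian, w, y, p0=p0,
                bounds=([0.0, lo, 1e-6, -np.inf, -np.inf],
                        [np.inf, hi, hi - lo, np.inf, np.inf]),
                maxfev=10000)
            amp, x0, gamma = popt[0], popt[1], popt[2]
            noise = _window_noise(w, y, float(x0), float(2 * gamma))
            snr = amp / noise if noise > 0 else np.inf
            return Peak(band, float(x0), float(amp), float(2 * gamma), window,
                        float(snr), "lorentzian_ls", flags)
        except (RuntimeError, ValueError):
            flags.append("fallback")
            method = "argmax_parabolic"

    # parabola through (i-1, i, i+1); general abscissae via quadratic fit
    x3, y3 = w[i - 1:i + 2], y[i - 1:i + 2]
    a, b, c = np.polyfit(x3, y3, 2)
    if a < 0:
        center = -b / (2 * a)
        peak_val = np.polyval([a, b, c], center)
    else:  # flat/degenerate triple: keep the grid point
        center, peak_val = float(w[i]), float(y[i])
        flags.append("degenerate_vertex")
    height = max(float(peak_val) - floor, 1e-300)
    fwhm = _fwhm_from_grid(w, y, float(center), height, floor)
    noise = _window_noise(w, y, float(center), fwhm)
    snr = height / noise if noise > 0 else np.inf
    return Peak(band, float(center), height, fwhm, window, float(snr),
                "argmax_parabolic", flags)


def keratin_bands(spec: Spectrum, min_snr: float = 5.0, halfwidth: float = 20.0,
                  method: str = "argmax_parabolic") -> list[Peak]:
    """Detect β-keratin matrix bands in ±``halfwidth`` windows around the
    nominal centers; only interior maxima with snr ≥ ``min_snr`` are
    returned."""
    out = []
    for c in KERATIN_CENTERS:
        window = (c - halfwidth, c + halfwidth)
        if window[0] < spec.wavenumbers[0] or window[1] > spec.wavenumbers[-1]:
            continue
        try:
            pk = find_band(spec, window, method=method, band=f"keratin_{int(c)}")
        except RangeError:
            continue
        if not pk.on_edge and pk.snr >= min_snr:
            out.append(pk)
    return out


def detect_psittacofulvin(
    spec: Spectrum, min_snr: float = 5.0, method: str = "argmax_parabolic",
    windows: Mapping[str, tuple[float, float]] = BAND_WINDOWS,
) -> tuple[bool, list[Peak]]:
    """Decide whether the pigment doublet is present.

    ``present`` is true iff both the C−C and C=C bands are found as
    interior maxima with snr ≥ ``min_snr``.  The peak list carries the
    pigment peaks (when present) plus any β-keratin bands detected.
    """
    pigment = [find_band(spec, windows[b], method=method, band=b)
               for b in ("cc", "cc2")]
    present = all(not p.on_edge and p.snr >= min_snr for p in pigment)
    peaks = (pigment if present else []) + keratin_bands(spec, min_snr, method=method)
    return present, peaks


def track_band(
    series: ExcitationSeries,
    band: str = "cc2",
    window: tuple[float, float] | None = None,
    exclusions: Sequence[float] | Mapping[float, str] = (),
    method: str = "argmax_parabolic",
) -> BandTrack:
    """Fit one band at every included excitation of a series.

    ``exclusions`` is a list of excitation wavelengths (nm) or a mapping
    nm → reason ("user", "pre-resonant", "spurious", ...).  The
    reference ν̃0R is the center at the included excitation with the
    lowest excitation energy.  Fewer than 3 included excitations raise
    :class:`InsufficientDataError`.
    """
    if window is None:
        if band not in BAND_WINDOWS:
            raise ValidationError(f"no default window for band {band!r}")
        window = BAND_WINDOWS[band]
    if isinstance(exclusions, Mapping):
        reasons = {float(k): str(v) for k, v in exclusions.items()}
    else:
        reasons = {float(nm): "user" for nm in exclusions}

    included_nm, excluded = [], []
    for nm in series.excitations:
        match = [x for x in reasons if abs(x - nm) < 1e-6]
        if match:
            excluded.append((nm, reasons[match[0]]))
        else:
            included_nm.append(nm)
    if len(included_nm) < 3:
        raise InsufficientDataError(
            f"only {len(included_nm)} excitations included; need >= 3")

    # ascending excitation energy = descending wavelength
    included_nm.sort(reverse=True)
    peaks = [find_band(series.entries[nm], window, method=method, band=band)
             for nm in included_nm]
    centers = np.array([p.center for p in peaks])
    nm_arr = np.array(included_nm)
    e_invcm = nm_to_invcm(nm_arr)
    return BandTrack(
        band=band,
        excitation_nm=nm_arr,
        energy_invcm=e_invcm,
        energy_eV=invcm_to_eV(e_invcm),
        centers=centers,
        ref_center=float(centers[0]),
        ref_excitation_nm=float(nm_arr[0]),
        window=window,
        excluded=excluded,
        peaks=peaks,
    )
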