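"""Spectral preprocessing chain for feather Raman spectra.

The default chain reproduces the survey workflow: crop to the
900–1800 cm⁻¹ fingerprint region, Savitzky–Golay smoothing, baseline
correction, 0–1 intensity normalization, replicate averaging.  The
order is configurable; for excitation-series work raw replicates are
averaged before normalization (band *positions* are unaffected either
way, only relative intensities).
"""

from __future__ import annotations

from dataclasses import replace
from typing import Sequence

import numpy as np
from scipy import sparse
from scipy.signal import savgol_filter
from scipy.sparse.linalg import spsolve

from .errors import DegenerateInputError, RangeError, ValidationError
from .spectra_io import Spectrum

__all__ = [
    "crop",
    "smooth_savgol",
    "baseline_correct",
    "asls_baseline",
    "polynomial_baseline",
    "normalize01",
    "average_replicates",
    "preprocess_spectrum",
]


def crop(spec: Spectrum, lo: float = 900.0, hi: float = 1800.0) -> Spectrum:
    """Keep only points with ``lo <= wavenumber <= hi`` (closed interval)."""
    if not lo < hi:
        raise ValidationError(f"crop bounds out of order: {lo} >= {hi}")
    mask = (spec.wavenumbers >= lo) & (spec.wavenumbers <= hi)
    if mask.sum() < 2:
        raise RangeError(f"crop [{lo}, {hi}] leaves fewer than 2 points")
    out = replace(spec, wavenumbers=spec.wavenumbers[mask],
                  intensities=spec.intensities[mask])
    out.flags = list(spec.flags)
    return out


def _check_uniform(w: np.ndarray) -> None:
    d = np.diff(w)
    if d.size and not np.allclose(d, d[0], rtol=1e-6, atol=1e-9 * abs(d[0])):
        raise ValidationError(
            "smoothing requires a uniform wavenumber grid; resample first")


def smooth_savgol(spec: Spectrum, window_pts: int = 11, polyorder: int = 3) -> Spectrum:
    """Savitzky–Golay smoothing (edges: polynomial fit on the truncated
    window, i.e. scipy's ``mode='interp'``)."""
    if window_pts % 2 == 0 or window_pts <= polyorder:
        raise ValidationError("window_pts must be odd and > polyorder")
    if len(spec) < window_pts:
        raise ValidationError("spectrum shorter than the smoothing window")
    _check_uniform(spec.wavenumbers)
    y = savgol_filter(spec.intensities, window_pts, polyorder, mode="interp")
    return spec.with_intensities(y)


def asls_baseline(y: np.ndarray, lam: float = 1e5, p: float = 0.01,
                  max_iter: int = 50, tol: float = 1e-6) -> tuple[np.ndarray, bool]:
    """Asymmetric least-squares baseline (Eilers–Boelens).

    Minimizes ``sum w_i (y_i - z_i)^2 + lam * sum (Δ²z)^2`` with
    asymmetric weights ``w_i = p`` above the baseline and ``1 - p``
    below, iterated to a fixed point.  Returns (baseline, converged).
    """
    y = np.asarray(y, dtype=float)
    n = y.size
    D = sparse.diags([1.0, -2.0, 1.0], [0, 1, 2], shape=(n - 2, n))
    DtD = lam * (D.T @ D)
    w = np.ones(n)
    z = y.copy()
    for _ in range(max_iter):
        W = sparse.diags(w)
        z_new = spsolve((W + DtD).tocsc(), w * y)
        w_new = np.where(y > z_new, p, 1.0 - p)
        done = np.array_equal(w_new, w) or (
            np.linalg.norm(z_new - z) <= tol * max(np.linalg.norm(z), 1e-30))
        z, w = z_new, w_new
        if done:
            return z, True
    return z, False


def polynomial_baseline(w: np.ndarray, y: np.ndarray, order: int = 3,
                        max_iter: int = 50, tol: float = 1e-8) -> tuple[np.ndarray, bool]:
    """Iterative polynomial baseline: fit, clip the signal above the fit,
    refit (modified-polyfit scheme).  Exact for spectra that *are*
    polynomials of the given order."""
    x = (w - w.mean()) / max(np.ptp(w) / 2.0, 1.0)  # conditioning
    target = np.asarray(y, dtype=float).copy()
    z = np.zeros_like(target)
    for _ in range(max_iter):
        coef = np.polynomial.polynomial.polyfit(x, target, order)
        z_new = np.polynomial.polynomial.polyval(x, coef)
        if np.max(np.abs(z_new - z)) <= tol * max(np.max(np.abs(y)), 1e-30):
            return z_new, True
        z = z_new
        target = np.minimum(target, z)
    return z, False


def baseline_correct(spec: Spectrum, method: str = "asls",
                     return_baseline: bool = False, **params):
    """Subtract a slowly varying background estimate.

    ``method='asls'`` (default, params: lam, p, max_iter, tol) or
    ``method='polynomial'`` (params: order, max_iter, tol).  If the
    iteration cap is hit before the tolerance, the corrected spectrum is
    returned with a ``baseline_not_converged`` flag rather than raising.
    """
    if method == "asls":
        base, converged = asls_baseline(spec.intensities, **params)
    elif method == "polynomial":
        base, converged = polynomial_baseline(spec.wavenumbers, spec.intensities, **params)
    else:
        raise ValidationError(f"unknown baseline method {method!r}")
    flags = () if converged else ("baseline_not_converged",)
    out = spec.with_intensities(spec.intensities - base, extra_flags=flags)
    if return_baseline:
        return out, base
    return out


def normalize01(spec: Spectrum) -> Spectrum:
    """Min-max scale intensities onto [0, 1] exactly."""
    y = spec.intensities
    lo, hi = y.min(), y.max()
    if hi == lo:
        raise DegenerateInputError("cannot normalize a constant spectrum")
    return spec.with_intensities((y - lo) / (hi - lo))


def average_replicates(specs: Sequence[Spectrum]) -> Spectrum:
    """Pointwise arithmetic mean of replicate spectra on a common grid."""
    specs = list(specs)
    if not specs:
        raise ValidationError("no spectra to average")
    ref = specs[0]
    excs = {s.excitation_nm for s in specs}
    if len(excs) > 1:
        raise ValidationError(f"mixed excitation wavelengths in replicates: {sorted(excs, key=str)}")
    regions = {s.region_label for s in specs if s.region_label}
    if len(regions) > 1:
        raise ValidationError(f"mixed region labels in replicates: {sorted(regions)}")
    for s in specs[1:]:
        if s.wavenumbers.size != ref.wavenumbers.size or not np.allclose(
                s.wavenumbers, ref.wavenumbers):
            raise ValidationError("replicates are not on a common grid; resample first")
    mean = np.mean([s.intensities for s in specs], axis=0)
    out = replace(ref, intensities=mean, replicate_id=f"mean(n={len(specs)})")
    out.flags = sorted({f for s in specs for f in s.flags})
    return out


def preprocess_spectrum(
    spec: Spectrum,
    lo: float = 900.0,
    hi: float = 1800.0,
    savgol_window: int = 11,
    savgol_order: int = 3,
    baseline_method: str = "asls",
    baseline_params: dict | None = None,
    normalize: bool = True,
) -> Spectrum:
    """Default single-spectrum chain: crop → smooth → baseline → normalize."""
    out = crop(spec, lo, hi)
    out = smooth_savgol(out, savgol_window, savgol_order)
    out = baseline_correct(out, method=baseline_method, **(baseline_params or {}))
    if normalize:
        out = normalize01(out)
    return out
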