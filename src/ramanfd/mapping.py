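"""Band-sum hyperspectral mapping.

A band map sums raw intensities per pixel inside a closed ±50 cm⁻¹
window around a band center (1140 cm⁻¹ for the C−C stretch, 1540 cm⁻¹
for C=C); no baseline or emission correction is applied, so emissive
pixels appear bright in both windows.  The emission index estimates the
per-pixel background level from peak-free reference windows and flags
emissive regions.
"""

from __future__ import annotations

import numpy as np

from .errors import RangeError
from .spectra_io import HyperMap

__all__ = ["band_intensity_map", "emission_index_map"]

#: Default peak-free reference windows (cm⁻¹) for background estimation:
#: below the phenylalanine band and above the amide region.
EMISSION_REFERENCE_WINDOWS: tuple[tuple[float, float], ...] = (
    (900.0, 980.0), (1700.0, 1800.0))


def _window_mask(axis: np.ndarray, lo: float, hi: float) -> np.ndarray:
    mask = (axis >= lo) & (axis <= hi)
    if not mask.any():
        raise RangeError(
            f"window [{lo:g}, {hi:g}] cm^-1 outside axis "
            f"[{axis[0]:g}, {axis[-1]:g}]")
    return mask


def band_intensity_map(hmap: HyperMap, center: float, halfwidth: float = 50.0) -> np.ndarray:
    """Per-pixel sum of raw intensities at grid points within
    ``center ± halfwidth`` (closed interval).  Returns an
    (n_rows, n_cols) image in arbitrary units."""
    mask = _window_mask(hmap.wavenumbers, center - halfwidth, center + halfwidth)
    return hmap.data[:, :, mask].sum(axis=2)


def emission_index_map(
    hmap: HyperMap,
    reference_windows: tuple[tuple[float, float], ...] = EMISSION_REFERENCE_WINDOWS,
) -> np.ndarray:
    """Per-pixel background level: median intensity over the peak-free
    reference windows.  High values flag emissive pixels (broad
    fluorescence underlying the Raman bands)."""
    axis = hmap.wavenumbers
    if np.ptp(axis) < 400.0:
        raise RangeError("emission index needs an axis spanning >= 400 cm^-1")
    mask = np.zeros(axis.size, dtype=bool)
    for lo, hi in reference_windows:
        mask |= _window_mask(axis, lo, hi)
    return np.median(hmap.data[:, :, mask], axis=2)
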