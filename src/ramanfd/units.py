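"""Unit bridges between excitation wavelength, wavenumber and energy."""

from __future__ import annotations

import numpy as np

__all__ = ["CM_PER_EV", "nm_to_invcm", "invcm_to_nm", "invcm_to_eV", "eV_to_invcm"]

#: Wavenumbers per electron-volt (1 eV = 8065.544 cm⁻¹).
CM_PER_EV: float = 8065.544


def nm_to_invcm(wavelength_nm):
    """Photon energy in cm⁻¹ for a vacuum wavelength in nm (1e7 / λ)."""
    wl = np.asarray(wavelength_nm, dtype=float)
    if np.any(wl <= 0):
        raise ValueError("wavelength must be positive")
    out = 1e7 / wl
    return float(out) if np.isscalar(wavelength_nm) else out


def invcm_to_nm(x_invcm):
    x = np.asarray(x_invcm, dtype=float)
    if np.any(x <= 0):
        raise ValueError("wavenumber must be positive")
    out = 1e7 / x
    return float(out) if np.isscalar(x_invcm) else out


def invcm_to_eV(x_invcm):
    x = np.asarray(x_invcm, dtype=float)
    out = x / CM_PER_EV
    return float(out) if np.isscalar(x_invcm) else out


def eV_to_invcm(x_eV):
    x = np.asarray(x_eV, dtype=float)
    out = x * CM_PER_EV
    return float(out) if np.isscalar(x_eV) else out
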