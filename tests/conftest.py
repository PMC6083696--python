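import numpy as np
import pytest

from ramanfd.spectra_io import Spectrum


def lorentzian(w, center, height, fwhm):
    g = fwhm / 2.0
    return height * g * g / ((w - center) ** 2 + g * g)


@pytest.fixture
def fingerprint_axis():
    """Uniform 1 cm^-1 grid over the 900-1800 cm^-1 fingerprint region."""
    return np.arange(900.0, 1801.0, 1.0)


@pytest.fixture
def doublet_spectrum(fingerprint_axis):
    """Noiseless pigment doublet (C-C at 1135, C=C at 1528)."""
    w = fingerprint_axis
    y = lorentzian(w, 1135.0, 1.0, 12.0) + lorentzian(w, 1528.0, 1.2, 14.0)
    return Spectrum(w, y, excitation_nm=532.0, region_label="red", replicate_id="r1")
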