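import numpy as np
import pytest

from brams import (AnalysisConfig, Modality, Spectrum, SpectralMap,
                   brillouin_axis, raman_axis)


@pytest.fixture
def config():
    return AnalysisConfig()


@pytest.fixture
def pipeline_config():
    """Extraction settings used for synthetic spectra with a constant
    Brillouin background."""
    return AnalysisConfig(subtract_background=True)


def lorentzian(axis, center, fwhm, area=1.0):
    gamma = fwhm / 2.0
    return area * (gamma / np.pi) / ((axis - center) ** 2 + gamma ** 2)


@pytest.fixture
def brillouin_spectrum_builder():
    """Build a noiseless Brillouin spectrum from (center, fwhm, area) peaks."""

    def build(peaks, background=0.0, axis=None):
        axis = brillouin_axis() if axis is None else np.asarray(axis, float)
        intensity = np.full_like(axis, float(background))
        for center, fwhm, area in peaks:
            intensity = intensity + lorentzian(axis, center, fwhm, area)
        return Spectrum(axis, intensity, Modality.BRILLOUIN)

    return build


@pytest.fixture
def raman_spectrum_builder():
    """Build a noiseless Raman spectrum from (center, fwhm, height) bands
    plus an optional polynomial baseline given as coefficients in the raw
    wavenumber (low order, e.g. 1e-4·x)."""

    def build(bands, baseline_coeffs=(), axis=None):
        axis = raman_axis() if axis is None else np.asarray(axis, float)
        intensity = np.zeros_like(axis)
        for center, fwhm, height in bands:
            gamma = fwhm / 2.0
            intensity += height * gamma ** 2 / ((axis - center) ** 2 + gamma ** 2)
        baseline = np.zeros_like(axis)
        for k, coeff in enumerate(baseline_coeffs):
            baseline += coeff * (axis / 1000.0) ** k
        return Spectrum(axis, intensity + np.clip(baseline, 0, None),
                        Modality.RAMAN)

    return build


def tiny_map(rows=2, cols=2, raman_missing=()):
    """Small paired map with distinct per-pixel peaks for IO tests."""
    b_axis = np.linspace(4.0, 32.0, 57)
    r_axis = np.linspace(800.0, 1800.0, 101)
    bgrid = np.full((rows, cols), None, dtype=object)
    rgrid = np.full((rows, cols), None, dtype=object)
    for r in range(rows):
        for c in range(cols):
            k = r * cols + c + 1
            bgrid[r, c] = Spectrum(b_axis, np.abs(np.sin(k * b_axis)) + k,
                                   Modality.BRILLOUIN)
            if (r, c) not in raman_missing:
                rgrid[r, c] = Spectrum(r_axis, np.abs(np.cos(k * r_axis)) + k,
                                       Modality.RAMAN)
    return SpectralMap(bgrid, rgrid, step=3.0, origin=(0.0, 0.0))
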