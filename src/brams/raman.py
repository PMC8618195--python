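"""Raman chemical markers for bone tissue.

The pipeline follows standard bone-quality Raman practice: remove the
fluorescence background with an iterative-clipping polynomial fit, normalize
to the CH₂ wagging band at 1445 cm⁻¹, then compute three markers per pixel:

* mineral-to-matrix ratio — peak intensity of ν₁PO₄³⁻ (965 cm⁻¹) over
  proline (860 cm⁻¹), a proxy for collagen-bundle mineralization degree;
* CH₂-CH₃ band first moment (2800–3100 cm⁻¹) — lipid-to-protein balance;
  shifts toward 2872 cm⁻¹ (CH₂, lipids) when lipids dominate over the CH₃
  protein stretch at 2935 cm⁻¹;
* heme–amide band first moment (1500–1720 cm⁻¹) — lower values mark
  hemoglobin (1580 cm⁻¹) against amide I / unsaturated fatty acids near
  1660 cm⁻¹, i.e. red-marrow prevalence.

"Peak intensity" is the window maximum (half-width 8 cm⁻¹ by default), which
makes the ratio robust to small calibration shifts and scale-invariant.
An optional mineral-crystallinity estimate (FWHM of the 965 cm⁻¹ band) is
provided but excluded from the default feature set.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np

from .brillouin import spectral_moment
from .exceptions import EmptyBandError, NormalizationError
from .types import AnalysisConfig, Modality, Spectrum

__all__ = [
    "RamanFeatures",
    "BAND_CATALOGUE",
    "remove_baseline",
    "normalize_to_reference",
    "peak_intensity",
    "mineralization_ratio",
    "band_first_moment",
    "crystallinity_fwhm",
    "extract_raman_features",
]

#: Typical Raman bands of bone tissue: (wavenumber or range cm⁻¹, assignment).
BAND_CATALOGUE: tuple[tuple[float | tuple[float, float], str], ...] = (
    (860.0, "proline (ring breathing)"),
    (870.0, "hydroxyproline (ring breathing)"),
    (965.0, "nu1 PO4^3- (P-O symmetric stretch)"),
    (1003.0, "phenylalanine (aromatic ring breathing)"),
    (1030.0, "nu3 PO4^3- (P-O asymmetric stretch)"),
    (1068.0, "nu1 CO3^2- (C-O in-plane stretch)"),
    ((1125.0, 1160.0), "C-CH3 carotenoids"),
    (1170.0, "hemoglobin"),
    (1242.0, "amide III (C-N-H stretch)"),
    (1298.0, "fatty acids (CH2-CH3 twist/wag)"),
    (1445.0, "CH2 wagging (lipids + collagen)"),
    (1580.0, "hemoglobin"),
    ((1655.0, 1675.0), "amide I (C=O stretch)"),
    (1745.0, "esters (C=O)"),
    (2872.0, "CH2 stretch, lipids"),
    (2935.0, "CH3 stretch, proteins"),
    ((3150.0, 3500.0), "OH stretching"),
)


@dataclass(frozen=True)
class RamanFeatures:
    """Per-pixel chemical markers; NaN marks a missing feature."""

    mineral_to_matrix: float  # dimensionless I(965)/I(860)
    ch_moment: float          # cm⁻¹, within [2800, 3100]
    heme_moment: float        # cm⁻¹, within [1500, 1720]
    normalized: Optional[Spectrum]  # baseline-removed, 1445-normalized

    def as_dict(self) -> dict[str, float]:
        return {
            "mineral_to_matrix": self.mineral_to_matrix,
            "ch_moment": self.ch_moment,
            "heme_moment": self.heme_moment,
        }


def _fit_baseline(axis: np.ndarray, intensity: np.ndarray,
                  order: int, iterations: int,
                  rtol: float = 1e-6) -> np.ndarray:
    """Iterative-clipping polynomial baseline (modified polyfit).

    Fit a polynomial of the given order, replace intensities above the fit
    by the fit, repeat until the fit changes by less than ``rtol`` of the
    data range or the iteration cap is reached.  The axis is mapped to
    [-1, 1] internally (Chebyshev-style conditioning), so any monotone
    cm⁻¹ grid is acceptable.
    """
    work = intensity.astype(float).copy()
    scale = float(np.max(np.abs(intensity))) or 1.0
    span = axis[-1] - axis[0]
    t = 2.0 * (axis - axis[0]) / span - 1.0
    vander = np.polynomial.polynomial.polyvander(t, order)
    q, r = np.linalg.qr(vander)  # fixed design matrix: factorize once
    fit = np.zeros_like(work)
    for _ in range(iterations):
        new_fit = vander @ np.linalg.solve(r, q.T @ work)
        if not np.all(np.isfinite(new_fit)):
            raise ValueError(
                "polynomial baseline fit diverged; rescale the axis or "
                "lower the order"
            )
        delta = float(np.max(np.abs(new_fit - fit)))
        fit = new_fit
        work = np.minimum(work, fit)
        if delta < rtol * scale:
            break
    return fit


def remove_baseline(spectrum: Spectrum, order: int = 5,
                    iterations: int = 200) -> Spectrum:
    """Subtract an iteratively clipped polynomial fluorescence baseline.

    Residual intensities are clipped at 0 (Eq.-style moment weights must be
    non-negative); the axis is unchanged.
    """
    if order < 1:
        raise ValueError("baseline order must be >= 1")
    if len(spectrum) <= order + 1:
        raise ValueError(
            f"need more than order+1={order + 1} channels, got {len(spectrum)}"
        )
    fit = _fit_baseline(spectrum.axis, spectrum.intensity, order, iterations)
    corrected = np.clip(spectrum.intensity - fit, 0.0, None)
    return Spectrum(axis=spectrum.axis, intensity=corrected,
                    modality=spectrum.modality, position=spectrum.position)


def _window_mask(axis: np.ndarray, center: float, half_width: float) -> np.ndarray:
    return (axis >= center - half_width) & (axis <= center + half_width)


def normalize_to_reference(spectrum: Spectrum, ref_wavenumber: float = 1445.0,
                           window: float = 10.0) -> Spectrum:
    """Divide by the maximum intensity within ref_wavenumber ± window.

    The reference-window maximum becomes exactly 1.  Raises
    :class:`NormalizationError` when the window holds no positive signal
    (callers translate this into a per-pixel missing-feature flag).
    """
    mask = _window_mask(spectrum.axis, ref_wavenumber, window)
    if not mask.any():
        raise NormalizationError(
            f"no channels within {ref_wavenumber} ± {window} cm⁻¹"
        )
    ref = float(spectrum.intensity[mask].max())
    if ref <= 0:
        raise NormalizationError(
            f"non-positive reference intensity at {ref_wavenumber} cm⁻¹"
        )
    return Spectrum(axis=spectrum.axis, intensity=spectrum.intensity / ref,
                    modality=spectrum.modality, position=spectrum.position)


def peak_intensity(spectrum: Spectrum, center: float,
                   window: float = 8.0) -> float:
    """Maximum intensity within center ± window (cm⁻¹)."""
    mask = _window_mask(spectrum.axis, center, window)
    if not mask.any():
        raise EmptyBandError(
            f"no channels within {center} ± {window} cm⁻¹"
        )
    return float(spectrum.intensity[mask].max())


def mineralization_ratio(spectrum: Spectrum,
                         config: Optional[AnalysisConfig] = None) -> float:
    """Mineral-to-matrix ratio I(965)/I(860); NaN when proline is absent."""
    config = config or AnalysisConfig()
    mineral = peak_intensity(spectrum, config.mineral_peak, config.peak_window)
    matrix = peak_intensity(spectrum, config.proline_peak, config.peak_window)
    if matrix <= 0:
        return math.nan
    return mineral / matrix


def band_first_moment(spectrum: Spectrum, band: tuple[float, float]) -> float:
    """First spectral moment Σ Iᵢνᵢ / Σ Iᵢ over a wavenumber band.

    Same contract (and implementation) as the Brillouin band moment, on the
    Raman axis; NaN flags an empty band.
    """
    return spectral_moment(spectrum, band)


def crystallinity_fwhm(spectrum: Spectrum, center: float = 965.0,
                       window: float = 25.0) -> float:
    """FWHM of the ν₁PO₄³⁻ band by linear half-maximum crossing (optional
    marker; narrower linewidth = higher hydroxyapatite crystallinity).

    Returns NaN when the band apex is non-positive or a half-maximum
    crossing lies outside the window.
    """
    mask = _window_mask(spectrum.axis, center, window)
    if mask.sum() < 3:
        return math.nan
    x = spectrum.axis[mask]
    y = spectrum.intensity[mask]
    apex = int(np.argmax(y))
    top = y[apex]
    if top <= 0:
        return math.nan
    half = top / 2.0

    def _cross(idx_range, reverse: bool) -> float:
        seq = idx_range[::-1] if reverse else idx_range
        prev = apex
        for i in seq:
            if y[i] < half:
                # linear interpolation between channel i and the previous one
                x0, x1 = x[i], x[prev]
                y0, y1 = y[i], y[prev]
                if y1 == y0:
                    return x0
                return x0 + (half - y0) * (x1 - x0) / (y1 - y0)
            prev = i
        return math.nan

    left = _cross(np.arange(0, apex), reverse=True)
    right = _cross(np.arange(apex + 1, y.size), reverse=False)
    if math.isnan(left) or math.isnan(right):
        return math.nan
    return right - left


def extract_raman_features(
    spectrum: Spectrum,
    config: Optional[AnalysisConfig] = None,
) -> RamanFeatures:
    """Full per-pixel Raman pipeline: baseline → normalize → three markers.

    A failed normalization (no CH₂ signal) flags every marker NaN and
    returns ``normalized=None``; the pixel is retained.
    """
    config = config or AnalysisConfig()
    if spectrum.modality is not Modality.RAMAN:
        raise ValueError("expected a Raman spectrum")
    flat = remove_baseline(spectrum, config.baseline_order, config.baseline_iters)
    try:
        norm = normalize_to_reference(flat, config.ref_wavenumber, config.ref_window)
    except NormalizationError:
        return RamanFeatures(math.nan, math.nan, math.nan, None)
    ratio = mineralization_ratio(norm, config)
    ch = band_first_moment(norm, config.ch_band)
    heme = band_first_moment(norm, config.heme_band)
    return RamanFeatures(ratio, ch, heme, norm)
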