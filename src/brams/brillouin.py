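"""Two-phase Brillouin mechanics.

A bone Brillouin spectrum carries two well-separated inelastic peaks in the
same scattering volume: P_SOFT (4–13 GHz, the disordered extracellular
matrix / marrow phase) and P_HARD (13–32 GHz, mineralized collagen bundles).
This module turns one such spectrum into per-pixel mechanical features:

* band spectral moments — the intensity-weighted mean frequency
  ν̄ = Σ Iᵢνᵢ / Σ Iᵢ over each band, a fit-free band-center estimator;
* integrated band intensities and their normalization into relative volume
  fractions I_SOFT + I_HARD = 100 % (the per-pixel normalization cancels the
  rough-surface filling factor; a scattering-efficiency weight converts
  photometric intensity to volume);
* the longitudinal elastic modulus M = ν² λ² κ / 4 per phase, with
  κ = ρ/n² carried as one combined constant (default 1.29 g/cm³ for bone,
  λ = 532 nm);
* the composition-weighted Voigt average
  M_AVERAGED = (I_SOFT·M_SOFT + I_HARD·M_HARD)/(I_SOFT + I_HARD).

Missing signal in a band yields NaN features (never 0), so downstream ROI
statistics can mask them.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np

from .types import AnalysisConfig, Modality, Spectrum

__all__ = [
    "BrillouinFeatures",
    "spectral_moment",
    "band_intensity",
    "relative_fractions",
    "longitudinal_modulus",
    "voigt_average",
    "extract_brillouin_features",
]


@dataclass(frozen=True)
class BrillouinFeatures:
    """Per-pixel mechanical features; NaN marks a missing band."""

    nu_soft: float   # GHz
    nu_hard: float   # GHz
    I_soft: float    # % of scattering volume
    I_hard: float    # %
    M_soft: float    # GPa
    M_hard: float    # GPa
    M_avg: float     # GPa

    def as_dict(self) -> dict[str, float]:
        return {
            "nu_soft": self.nu_soft, "nu_hard": self.nu_hard,
            "I_soft": self.I_soft, "I_hard": self.I_hard,
            "M_soft": self.M_soft, "M_hard": self.M_hard,
            "M_avg": self.M_avg,
        }


def _band_mask(axis: np.ndarray, band: tuple[float, float],
               include_lo: bool = True) -> np.ndarray:
    lo, hi = band
    if not lo < hi:
        raise ValueError(f"band must satisfy lo < hi, got ({lo}, {hi})")
    left = axis >= lo if include_lo else axis > lo
    return left & (axis <= hi)


def spectral_moment(spectrum: Spectrum, band: tuple[float, float],
                    include_lo: bool = True) -> float:
    """Intensity-weighted mean channel position over ``band`` (inclusive).

    Returns NaN when the band holds no positive intensity — a flagged
    empty-band result, distinct from 0.
    """
    mask = _band_mask(spectrum.axis, band, include_lo)
    inten = spectrum.intensity[mask]
    total = inten.sum()
    if total <= 0:
        return math.nan
    return float(np.dot(inten, spectrum.axis[mask]) / total)


def band_intensity(spectrum: Spectrum, band: tuple[float, float],
                   include_lo: bool = True) -> float:
    """Trapezoidal integral of intensity over ``band``; 0 flags an empty band."""
    mask = _band_mask(spectrum.axis, band, include_lo)
    if mask.sum() < 2:
        return 0.0
    return float(np.trapezoid(spectrum.intensity[mask], spectrum.axis[mask]))


def relative_fractions(A_soft: float, A_hard: float,
                       efficiency_ratio: float = 1.0) -> tuple[float, float]:
    """Convert band areas to relative volume percentages (I_soft, I_hard).

    The soft band's photometric area is divided by the soft-vs-hard
    scattering-efficiency ratio before the two are normalized to 100 %;
    the normalization absorbs the per-pixel filling factor.  Both areas
    zero → (NaN, NaN), a missing-feature flag.
    """
    if efficiency_ratio <= 0:
        raise ValueError("efficiency_ratio must be > 0")
    if A_soft < 0 or A_hard < 0:
        raise ValueError("band areas must be non-negative")
    w_soft = A_soft / efficiency_ratio
    total = w_soft + A_hard
    if total == 0:
        return (math.nan, math.nan)
    I_soft = 100.0 * w_soft / total
    return (I_soft, 100.0 - I_soft)


# unit factors: ν GHz→s⁻¹ (1e9), λ nm→m (1e-9), κ g/cm³→kg/m³ (1e3), Pa→GPa (1e-9)
_MODULUS_SCALE = (1e9 ** 2) * (1e-9 ** 2) * 1e3 * 1e-9 / 4.0


def longitudinal_modulus(nu: float, lambda_laser: float = 532.0,
                         kappa: float = 1.29) -> float:
    """Longitudinal elastic modulus M = ν²λ²κ/4 in GPa.

    Parameters
    ----------
    nu:
        Brillouin frequency shift in GHz.
    lambda_laser:
        Laser wavelength in nm.
    kappa:
        ρ/n² in g/cm³ (mass density over squared refractive index).

    Exactly quadratic in ν; NaN propagates (missing band → missing modulus).
    """
    if not (math.isfinite(lambda_laser) and math.isfinite(kappa)):
        raise ValueError("non-finite optical constants")
    if lambda_laser <= 0 or kappa <= 0:
        raise ValueError("lambda_laser and kappa must be > 0")
    if math.isnan(nu):
        return math.nan
    if not math.isfinite(nu) or nu < 0:
        raise ValueError(f"invalid frequency shift {nu}")
    return nu * nu * lambda_laser * lambda_laser * kappa * _MODULUS_SCALE


def voigt_average(M_soft: float, M_hard: float,
                  I_soft: float, I_hard: float) -> float:
    """Composition-weighted (Voigt) average modulus.

    (I_soft·M_soft + I_hard·M_hard)/(I_soft + I_hard); invariant under a
    common rescaling of the two fractions and bounded by [min, max] of the
    two moduli.  A phase with zero fraction may carry a NaN modulus without
    poisoning the average; both fractions zero → NaN.
    """
    if math.isnan(I_soft) or math.isnan(I_hard):
        return math.nan
    if I_soft < 0 or I_hard < 0:
        raise ValueError("fractions must be non-negative")
    total = I_soft + I_hard
    if total == 0:
        return math.nan
    acc = 0.0
    for frac, mod in ((I_soft, M_soft), (I_hard, M_hard)):
        if frac > 0:
            if math.isnan(mod):
                return math.nan
            acc += frac * mod
    return acc / total


def _constant_background(spectrum: Spectrum, config: AnalysisConfig) -> float:
    """Median intensity of channels outside both analysis bands."""
    in_soft = _band_mask(spectrum.axis, config.soft_range)
    in_hard = _band_mask(spectrum.axis, config.hard_range)
    outside = ~(in_soft | in_hard)
    if not outside.any():
        return 0.0
    return float(np.median(spectrum.intensity[outside]))


def extract_brillouin_features(
    spectrum: Spectrum,
    config: Optional[AnalysisConfig] = None,
) -> BrillouinFeatures:
    """Full per-pixel Brillouin feature extraction.

    Band moments and areas → relative fractions → per-phase moduli → Voigt
    average.  When the soft and hard bands share an edge (the default
    contiguous split at 13 GHz) the shared channel is assigned to the soft
    band.  With ``config.subtract_background`` the median off-band intensity
    is removed (clipped at 0) before any moment or area.
    """
    config = config or AnalysisConfig()
    if spectrum.modality is not Modality.BRILLOUIN:
        raise ValueError("expected a Brillouin spectrum")
    work = spectrum
    if config.subtract_background:
        bg = _constant_background(spectrum, config)
        if bg > 0:
            work = Spectrum(
                axis=spectrum.axis,
                intensity=np.clip(spectrum.intensity - bg, 0.0, None),
                modality=spectrum.modality,
                position=spectrum.position,
            )
    contiguous = config.hard_range[0] == config.soft_range[1]
    hard_inc_lo = not contiguous  # shared 13 GHz edge belongs to the soft band

    nu_soft = spectral_moment(work, config.soft_range)
    nu_hard = spectral_moment(work, config.hard_range, include_lo=hard_inc_lo)
    A_soft = band_intensity(work, config.soft_range)
    A_hard = band_intensity(work, config.hard_range, include_lo=hard_inc_lo)
    if math.isnan(nu_soft):
        A_soft = 0.0
    if math.isnan(nu_hard):
        A_hard = 0.0
    I_soft, I_hard = relative_fractions(A_soft, A_hard, config.efficiency_ratio)

    M_soft = longitudinal_modulus(nu_soft, config.lambda_laser, config.kappa)
    M_hard = longitudinal_modulus(nu_hard, config.lambda_laser, config.kappa)
    M_avg = voigt_average(M_soft, M_hard, I_soft, I_hard)
    return BrillouinFeatures(nu_soft, nu_hard, I_soft, I_hard,
                             M_soft, M_hard, M_avg)
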