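"""Core containers: single spectra, spatial maps of spectra, and the analysis
configuration.

A :class:`Spectrum` is one acquisition channel axis (GHz for Brillouin,
cm⁻¹ for Raman) with per-channel intensities.  A :class:`SpectralMap` is a
rectangular x-y lattice of pixels, each holding a Brillouin and/or a Raman
spectrum, with the grid step in µm.  :class:`AnalysisConfig` collects every
tunable of the analysis pipeline — band limits, optical constants, baseline
and normalization settings — with defaults matching the measurement protocol
the package models.
"""

from __future__ import annotations

from dataclasses import dataclass, fields, replace
from enum import Enum
from pathlib import Path
from typing import Optional

import numpy as np
import yaml

from .exceptions import MapFormatError, SpectrumFormatError

__all__ = ["Modality", "Spectrum", "SpectralMap", "AnalysisConfig"]

# physically admissible axis windows per modality
_AXIS_LIMITS = {"brillouin": (0.0, 50.0), "raman": (100.0, 4100.0)}


class Modality(str, Enum):
    """Which spectrometer produced a spectrum."""

    BRILLOUIN = "brillouin"
    RAMAN = "raman"


@dataclass(frozen=True)
class Spectrum:
    """One spectrum: strictly increasing axis, non-negative intensities.

    Parameters
    ----------
    axis:
        Channel positions, strictly increasing.  GHz for Brillouin,
        cm⁻¹ (wavenumber) for Raman.
    intensity:
        Counts per channel, same length as ``axis``, all ``>= 0``.
    modality:
        ``Modality.BRILLOUIN`` or ``Modality.RAMAN``.
    position:
        Optional (x, y) stage position in µm.
    """

    axis: np.ndarray
    intensity: np.ndarray
    modality: Modality
    position: Optional[tuple[float, float]] = None

    def __post_init__(self) -> None:
        axis = np.asarray(self.axis, dtype=float)
        intensity = np.asarray(self.intensity, dtype=float)
        object.__setattr__(self, "axis", axis)
        object.__setattr__(self, "intensity", intensity)
        object.__setattr__(self, "modality", Modality(self.modality))
        if axis.ndim != 1 or intensity.ndim != 1:
            raise SpectrumFormatError("axis and intensity must be 1-D")
        if axis.shape != intensity.shape:
            raise SpectrumFormatError(
                f"axis has {axis.size} channels but intensity has {intensity.size}"
            )
        if axis.size == 0:
            raise SpectrumFormatError("empty spectrum")
        if not np.all(np.diff(axis) > 0):
            raise SpectrumFormatError("axis must be strictly increasing")
        if np.any(intensity < 0):
            bad = int(np.argmax(intensity < 0))
            raise SpectrumFormatError(
                f"negative intensity {intensity[bad]} at channel {bad} "
                f"(axis value {axis[bad]})"
            )
        lo, hi = _AXIS_LIMITS[self.modality.value]
        if axis[0] < lo or axis[-1] > hi:
            raise SpectrumFormatError(
                f"{self.modality.value} axis [{axis[0]}, {axis[-1]}] outside "
                f"admissible window [{lo}, {hi}]"
            )

    def __len__(self) -> int:
        return self.axis.size

    def scaled(self, factor: float) -> "Spectrum":
        """Return a copy with intensities multiplied by ``factor`` (> 0)."""
        if factor <= 0:
            raise ValueError("scale factor must be positive")
        return replace(self, intensity=self.intensity * factor)


@dataclass
class SpectralMap:
    """Rectangular lattice of paired Brillouin/Raman spectra.

    ``brillouin`` and ``raman`` are (rows, cols) object arrays whose cells
    hold a :class:`Spectrum` or ``None`` (modality absent at that pixel).
    Within one map every present spectrum of a modality shares an identical
    axis.  Pixel (i, j) sits at ``origin + (j*step, i*step)`` µm (x along
    columns, y along rows).
    """

    brillouin: np.ndarray
    raman: np.ndarray
    step: float = 3.0
    origin: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self) -> None:
        self.brillouin = np.asarray(self.brillouin, dtype=object)
        self.raman = np.asarray(self.raman, dtype=object)
        if self.brillouin.ndim != 2 or self.raman.ndim != 2:
            raise MapFormatError("map grids must be 2-D")
        if self.brillouin.shape != self.raman.shape:
            raise MapFormatError(
                f"modality grids disagree in shape: {self.brillouin.shape} "
                f"vs {self.raman.shape}"
            )
        if self.step <= 0:
            raise MapFormatError("grid step must be > 0")
        for name, grid in (("brillouin", self.brillouin), ("raman", self.raman)):
            ref = None
            for spec in grid.flat:
                if spec is None:
                    continue
                if ref is None:
                    ref = spec.axis
                elif spec.axis.shape != ref.shape or not np.array_equal(spec.axis, ref):
                    raise MapFormatError(
                        f"inconsistent {name} axes within one map"
                    )

    @property
    def shape(self) -> tuple[int, int]:
        return self.brillouin.shape

    def axis_of(self, modality: Modality | str) -> Optional[np.ndarray]:
        """Shared axis of a modality, or None if entirely absent."""
        grid = self.brillouin if Modality(modality) is Modality.BRILLOUIN else self.raman
        for spec in grid.flat:
            if spec is not None:
                return spec.axis
        return None

    def pixel_position(self, row: int, col: int) -> tuple[float, float]:
        """(x, y) µm of a pixel via origin + index·step."""
        x0, y0 = self.origin
        return (x0 + col * self.step, y0 + row * self.step)


@dataclass
class AnalysisConfig:
    """All tunables of the chemo-mechanical pipeline.

    Brillouin side: the two-phase split of the spectrum into a soft band
    (default 4–13 GHz, disordered ECM / marrow) and a hard band (13–32 GHz,
    mineralized collagen), the laser wavelength λ and the combined optical
    constant κ = ρ/n² used by the modulus conversion M = ν²λ²κ/4, and the
    soft-vs-hard scattering-efficiency weight used when photometric band
    areas are converted to volume fractions.

    Raman side: iterative polynomial-baseline parameters, the CH₂ reference
    band at 1445 cm⁻¹ used for normalization, the marker windows (mineral
    ν₁PO₄³⁻ 965, proline 860, CH₂-CH₃ 2800–3100, heme–amide 1500–1720) and
    the 800–1780 cm⁻¹ fingerprint window used for PCA.
    """

    # Brillouin bands (GHz); contiguous split at 13 GHz, shared edge goes soft
    soft_range: tuple[float, float] = (4.0, 13.0)
    hard_range: tuple[float, float] = (13.0, 32.0)
    lambda_laser: float = 532.0        # nm
    kappa: float = 1.29                # ρ/n² in g/cm³
    efficiency_ratio: float = 1.0      # soft-vs-hard scattering efficiency
    subtract_background: bool = False  # constant background (median off-band)

    # Raman preprocessing
    baseline_order: int = 5
    baseline_iters: int = 200
    ref_wavenumber: float = 1445.0     # cm⁻¹, CH₂ wagging
    ref_window: float = 10.0           # cm⁻¹ half-width

    # Raman marker windows (cm⁻¹)
    fingerprint_range: tuple[float, float] = (800.0, 1780.0)
    ch_band: tuple[float, float] = (2800.0, 3100.0)
    heme_band: tuple[float, float] = (1500.0, 1720.0)
    mineral_peak: float = 965.0
    proline_peak: float = 860.0
    peak_window: float = 8.0           # cm⁻¹ half-width

    def __post_init__(self) -> None:
        for name in ("soft_range", "hard_range", "fingerprint_range",
                     "ch_band", "heme_band"):
            lo, hi = getattr(self, name)
            if not lo < hi:
                raise ValueError(f"{name} must satisfy lo < hi, got ({lo}, {hi})")
            setattr(self, name, (float(lo), float(hi)))
        for name in ("lambda_laser", "kappa", "efficiency_ratio",
                     "ref_window", "peak_window"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.baseline_order < 1 or self.baseline_iters < 1:
            raise ValueError("baseline_order and baseline_iters must be >= 1")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AnalysisConfig":
        """Load a config from a YAML mapping; absent keys keep defaults."""
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key, val in data.items():
            if isinstance(val, list):
                data[key] = tuple(val)
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        data = {f.name: getattr(self, f.name) for f in fields(self)}
        data = {k: (list(v) if isinstance(v, tuple) else v) for k, v in data.items()}
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=False)
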