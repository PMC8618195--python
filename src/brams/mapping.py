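"""Feature maps, ROI statistics and ROI comparisons.

Per-pixel Brillouin and Raman features are assembled into 2-D arrays with a
missing-value mask, summarized over rectangular regions of interest
(mean, SD, SEM = SD/√n, quartiles, histogram), and compared between ROIs
as signed percent changes of the means — the arithmetic used to contrast
frozen vs PFA-fixed tissue and diaphyseal vs epiphyseal anatomy.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Iterable, Optional

import numpy as np
import pandas as pd

from .brillouin import extract_brillouin_features
from .raman import extract_raman_features
from .types import AnalysisConfig, SpectralMap

__all__ = [
    "FeatureMap", "ROI", "ROISummary",
    "map_features", "roi_statistics", "percent_change", "compare_rois",
]

BRILLOUIN_FEATURES = ("nu_soft", "nu_hard", "I_soft", "I_hard",
                      "M_soft", "M_hard", "M_avg")
RAMAN_FEATURES = ("mineral_to_matrix", "ch_moment", "heme_moment")
ALL_FEATURES = BRILLOUIN_FEATURES + RAMAN_FEATURES


@dataclass
class FeatureMap:
    """One 2-D array per feature (NaN = missing) plus grid metadata."""

    features: dict[str, np.ndarray]
    step: float = 3.0
    origin: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self) -> None:
        shapes = {v.shape for v in self.features.values()}
        if len(shapes) > 1:
            raise ValueError(f"feature arrays disagree in shape: {sorted(shapes)}")

    @property
    def shape(self) -> tuple[int, int]:
        return next(iter(self.features.values())).shape

    def __getitem__(self, name: str) -> np.ndarray:
        return self.features[name]


@dataclass(frozen=True)
class ROI:
    """Axis-aligned rectangle in pixel indices, lo-inclusive, hi-exclusive."""

    id: str
    row_lo: int
    row_hi: int
    col_lo: int
    col_hi: int

    def __post_init__(self) -> None:
        if self.row_lo >= self.row_hi or self.col_lo >= self.col_hi:
            raise ValueError(f"ROI {self.id!r} is empty: {self}")

    def slice(self) -> tuple[slice, slice]:
        return (slice(self.row_lo, self.row_hi), slice(self.col_lo, self.col_hi))


@dataclass
class ROISummary:
    """Per-feature descriptive statistics over the unmasked ROI pixels."""

    roi_id: str
    stats: dict[str, dict]  # feature -> {n, mean, sd, sem, quartiles, histogram}

    def mean(self, feature: str) -> float:
        return self.stats[feature]["mean"]

    def sem(self, feature: str) -> float:
        return self.stats[feature]["sem"]


def map_features(smap: SpectralMap,
                 config: Optional[AnalysisConfig] = None) -> FeatureMap:
    """Run both per-pixel extractions over a map; flags become NaN cells.

    Pixels missing one modality keep the other's features; a map with no
    usable pixel at all is an error.
    """
    config = config or AnalysisConfig()
    rows, cols = smap.shape
    out = {name: np.full((rows, cols), np.nan) for name in ALL_FEATURES}
    usable = 0
    for r in range(rows):
        for c in range(cols):
            bspec = smap.brillouin[r, c]
            rspec = smap.raman[r, c]
            if bspec is not None:
                feats = extract_brillouin_features(bspec, config).as_dict()
                for name, val in feats.items():
                    out[name][r, c] = val
                usable += 1
            if rspec is not None:
                feats = extract_raman_features(rspec, config).as_dict()
                for name, val in feats.items():
                    out[name][r, c] = val
                usable += 1
    if usable == 0:
        raise ValueError("map has no usable pixels")
    return FeatureMap(out, step=smap.step, origin=smap.origin)


def roi_statistics(fmap: FeatureMap, roi: ROI, bins: int = 30,
                   features: Optional[Iterable[str]] = None) -> ROISummary:
    """Mean/SD/SEM/quartiles/histogram per feature over unmasked ROI pixels.

    SD uses the n−1 (sample) normalization and SEM = SD/√n; a single pixel
    reports SD = SEM = 0.  Fully masked features are omitted with a warning.
    Histograms use ``bins`` equal-width bins over the ROI's observed range.
    """
    rows, cols = fmap.shape
    if roi.row_lo >= rows or roi.col_lo >= cols or roi.row_hi <= 0 or roi.col_hi <= 0:
        raise ValueError(f"ROI {roi.id!r} does not intersect the {rows}x{cols} grid")
    names = list(features) if features is not None else list(fmap.features)
    stats: dict[str, dict] = {}
    for name in names:
        block = fmap[name][roi.slice()]
        vals = block[~np.isnan(block)]
        n = vals.size
        if n == 0:
            warnings.warn(f"ROI {roi.id!r}: feature {name!r} fully masked; omitted")
            continue
        sd = float(np.std(vals, ddof=1)) if n > 1 else 0.0
        edges = np.histogram_bin_edges(vals, bins=bins)
        counts, edges = np.histogram(vals, bins=edges)
        stats[name] = {
            "n": int(n),
            "mean": float(np.mean(vals)),
            "sd": sd,
            "sem": sd / math.sqrt(n),
            "quartiles": tuple(float(q) for q in
                               np.percentile(vals, (25, 50, 75))),
            "histogram": (edges, counts),
        }
    return ROISummary(roi.id, stats)


def percent_change(reference_mean: float, comparison_mean: float) -> float:
    """Signed percent change 100·(comparison − reference)/reference."""
    if reference_mean == 0:
        raise ZeroDivisionError("reference mean is zero")
    if math.isnan(reference_mean) or math.isnan(comparison_mean):
        raise ValueError("percent change of a missing mean")
    return 100.0 * (comparison_mean - reference_mean) / reference_mean


def percent_change_rounded(reference_mean: float, comparison_mean: float) -> int:
    """Magnitude of the percent change rounded to the nearest integer
    (the convention used when quoting 'about N %' changes)."""
    return round(abs(percent_change(reference_mean, comparison_mean)))


def compare_rois(summary_a: ROISummary, summary_b: ROISummary,
                 features: Iterable[str]) -> pd.DataFrame:
    """Tabulate mean ± SEM of both ROIs and the a→b percent change.

    Rows follow the requested feature order; a feature missing from either
    summary is omitted with a warning.
    """
    rows = []
    for name in features:
        if name not in summary_a.stats or name not in summary_b.stats:
            warnings.warn(f"feature {name!r} missing from a summary; row omitted")
            continue
        mean_a, mean_b = summary_a.mean(name), summary_b.mean(name)
        rows.append({
            "feature": name,
            f"mean_{summary_a.roi_id}": mean_a,
            f"sem_{summary_a.roi_id}": summary_a.sem(name),
            f"mean_{summary_b.roi_id}": mean_b,
            f"sem_{summary_b.roi_id}": summary_b.sem(name),
            "percent_change": percent_change(mean_a, mean_b),
            "percent_change_rounded": percent_change_rounded(mean_a, mean_b),
        })
    return pd.DataFrame(rows)
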