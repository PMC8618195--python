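"""PCA of fingerprint-region Raman spectra for ROI classification.

Preprocessed (baseline-removed, 1445-normalized) spectra restricted to the
800–1780 cm⁻¹ fingerprint window form an observation × wavenumber matrix.
A deterministic SVD of the column-centered matrix yields loadings
(component weight vectors over wavenumber), scores (observation
coordinates) and explained/cumulative variance.  The sign of each
component is fixed so that its largest-magnitude loading weight is
positive, making loadings reproducible across runs and platforms.
Group separation along a component is quantified as a standardized mean
separation (between-group mean gap over pooled within-group SD).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .mapping import ROI
from .raman import extract_raman_features
from .types import AnalysisConfig, SpectralMap

__all__ = ["SpectralMatrix", "PCAResult", "build_matrix", "run_pca",
           "group_separation"]

logger = logging.getLogger(__name__)


@dataclass
class SpectralMatrix:
    """Observations × wavenumber-channel matrix with (roi, x, y) row labels."""

    data: np.ndarray             # (n_obs, n_channels)
    wavenumbers: np.ndarray      # strictly increasing, cm⁻¹
    labels: pd.MultiIndex        # levels: roi, x, y

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, float)
        self.wavenumbers = np.asarray(self.wavenumbers, float)
        if self.data.ndim != 2:
            raise ValueError("data must be 2-D")
        if self.data.shape[1] != self.wavenumbers.size:
            raise ValueError("column count does not match wavenumbers")
        if not np.all(np.diff(self.wavenumbers) > 0):
            raise ValueError("wavenumbers must be strictly increasing")
        if np.isnan(self.data).any():
            raise ValueError("spectral matrix must have no missing cells")
        if len(self.labels) != self.data.shape[0]:
            raise ValueError("row labels do not match observation count")

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.data, index=self.labels,
                            columns=self.wavenumbers)


@dataclass
class PCAResult:
    """Deterministic PCA decomposition of a spectral matrix."""

    loadings: np.ndarray                 # (k, n_channels), orthonormal rows
    scores: np.ndarray                   # (n_obs, k)
    explained_variance_pct: np.ndarray   # (k,), of the total variance
    cumulative_variance_pct: np.ndarray  # (k,), running sum
    mean_spectrum: np.ndarray            # column means removed before SVD
    wavenumbers: np.ndarray
    labels: pd.MultiIndex

    @property
    def n_components(self) -> int:
        return self.loadings.shape[0]


def build_matrix(
    smap: SpectralMap,
    rois: Optional[Sequence[ROI]] = None,
    config: Optional[AnalysisConfig] = None,
) -> SpectralMatrix:
    """Preprocess every usable Raman pixel and crop to the fingerprint window.

    Pixels whose Raman spectrum is absent or fails normalization are dropped
    and logged.  Rows are labeled ``(roi id, x, y)``; with no ROIs the whole
    grid is one ROI ``"all"``.  Fewer than two usable rows is an error.
    """
    config = config or AnalysisConfig()
    rows_, cols_ = smap.shape
    if rois is None:
        rois = [ROI("all", 0, rows_, 0, cols_)]
    lo, hi = config.fingerprint_range
    data_rows: list[np.ndarray] = []
    labels: list[tuple[str, int, int]] = []
    crop = None
    wavenumbers = None
    for roi in rois:
        for r in range(max(roi.row_lo, 0), min(roi.row_hi, rows_)):
            for c in range(max(roi.col_lo, 0), min(roi.col_hi, cols_)):
                spec = smap.raman[r, c]
                if spec is None:
                    logger.info("pixel (%d, %d): Raman absent, dropped", c, r)
                    continue
                feats = extract_raman_features(spec, config)
                if feats.normalized is None:
                    logger.info("pixel (%d, %d): normalization failed, dropped",
                                c, r)
                    continue
                if crop is None:
                    axis = feats.normalized.axis
                    crop = (axis >= lo) & (axis <= hi)  # inclusive limits
                    wavenumbers = axis[crop]
                data_rows.append(feats.normalized.intensity[crop])
                labels.append((roi.id, c, r))
    if len(data_rows) < 2:
        raise ValueError(f"need >= 2 usable Raman pixels, got {len(data_rows)}")
    index = pd.MultiIndex.from_tuples(labels, names=["roi", "x", "y"])
    return SpectralMatrix(np.vstack(data_rows), wavenumbers, index)


def run_pca(matrix: SpectralMatrix, n_components: int) -> PCAResult:
    """Column-mean centering (no scaling) followed by SVD.

    Requesting more components than the matrix rank returns the available
    ones with a warning.  Explained variance percentages are relative to
    the total column variance of the centered matrix, so retaining all
    components sums to 100.
    """
    n_obs, n_chan = matrix.shape
    max_k = min(n_obs - 1, n_chan)
    if n_components < 1 or n_components > max_k:
        raise ValueError(
            f"n_components must be in [1, min(rows-1, cols)] = [1, {max_k}]"
        )
    mean = matrix.data.mean(axis=0)
    centered = matrix.data - mean
    u, s, vt = np.linalg.svd(centered, full_matrices=False)
    # effective rank: discard numerically null directions
    tol = s.max(initial=0.0) * max(n_obs, n_chan) * np.finfo(float).eps
    rank = int((s > tol).sum())
    k = n_components
    if rank < n_components:
        warnings.warn(
            f"matrix rank {rank} < requested {n_components} components; "
            f"returning {max(rank, 1)}"
        )
        k = max(rank, 1)
    # deterministic sign: largest-|weight| channel of each loading positive
    for j in range(k):
        idx = int(np.argmax(np.abs(vt[j])))
        if vt[j, idx] < 0:
            vt[j] = -vt[j]
            u[:, j] = -u[:, j]
    scores = u[:, :k] * s[:k]
    total_var = float((s ** 2).sum())
    if total_var == 0:
        explained = np.zeros(k)
    else:
        explained = 100.0 * (s[:k] ** 2) / total_var
    return PCAResult(
        loadings=vt[:k].copy(),
        scores=scores,
        explained_variance_pct=explained,
        cumulative_variance_pct=np.cumsum(explained),
        mean_spectrum=mean,
        wavenumbers=matrix.wavenumbers,
        labels=matrix.labels,
    )


def group_separation(result: PCAResult,
                     labels: Optional[Iterable[str]] = None,
                     threshold: float = 2.0) -> pd.DataFrame:
    """Standardized separation of labeled groups along each component.

    For each component: group score means, the pooled within-group SD, and
    for each group its one-vs-rest standardized separation
    ``|mean_g − mean_rest| / pooled SD``.  A component "divides" a group
    from the rest when that separation exceeds ``threshold``.  Returns one
    row per (component, group) with columns ``component, group, group_mean,
    pooled_sd, separation, divides``.
    """
    if labels is None:
        labels = result.labels.get_level_values("roi")
    labels = np.asarray(list(labels))
    if labels.size != result.scores.shape[0]:
        raise ValueError("labels do not match observations")
    groups = np.unique(labels)
    if groups.size < 2:
        raise ValueError("need at least two groups")
    rows = []
    for j in range(result.n_components):
        comp = result.scores[:, j]
        # pooled within-group SD (n−1 weights)
        num = 0.0
        den = 0
        for g in groups:
            vals = comp[labels == g]
            if vals.size > 1:
                num += (vals.size - 1) * np.var(vals, ddof=1)
                den += vals.size - 1
        pooled = float(np.sqrt(num / den)) if den > 0 else 0.0
        for g in groups:
            in_g = comp[labels == g]
            rest = comp[labels != g]
            gap = abs(float(in_g.mean()) - float(rest.mean()))
            sep = gap / pooled if pooled > 0 else (np.inf if gap > 0 else 0.0)
            rows.append({
                "component": j + 1,
                "group": g,
                "group_mean": float(in_g.mean()),
                "pooled_sd": pooled,
                "separation": sep,
                "divides": sep > threshold,
            })
    return pd.DataFrame(rows)
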