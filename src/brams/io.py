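"""Reading and writing spectra, maps and feature tables.

Two on-disk dialects are supported for maps, both plain text:

* **long format** — one delimited table (TAB default, comma accepted) with
  columns ``x  y  modality  axis_value  intensity``, one row per channel,
  plus a YAML sidecar ``<file>.meta.yaml`` holding ``step`` and ``origin``;
* **directory layout** — an ``index.tsv`` table with columns
  ``x  y  brillouin_file  raman_file`` (empty cell = modality absent),
  per-pixel two-column spectrum files, and a ``meta.yaml`` sidecar.

``x``/``y`` are 0-based pixel indices (column, row); µm positions follow
from ``origin + index·step``.  Single spectra are two-column text
(axis, intensity) with optional ``#``-prefixed header lines carrying
modality and stage position.  Numbers are written with 6 significant
digits.
"""

from __future__ import annotations

import csv
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from .exceptions import MapFormatError, SpectrumFormatError
from .types import Modality, Spectrum, SpectralMap

__all__ = [
    "read_spectrum", "write_spectrum",
    "read_map", "write_map",
    "write_features_table", "read_features_table",
    "read_rois", "write_rois",
]

_FMT = "%.6g"

#: column order of the per-pixel feature table
FEATURE_COLUMNS = [
    "nu_soft", "nu_hard", "I_soft", "I_hard", "M_soft", "M_hard", "M_avg",
    "mineral_to_matrix", "ch_moment", "heme_moment",
]


def read_spectrum(path: str | Path, modality: Optional[str] = None) -> Spectrum:
    """Read a two-column (axis, intensity) text spectrum.

    ``#``-prefixed header lines may declare ``modality:`` and
    ``position: x y``; an explicit ``modality`` argument overrides the
    header.  Raises :class:`SpectrumFormatError` on a non-monotone axis or
    a negative intensity, naming the offending line.
    """
    path = Path(path)
    header_modality: Optional[str] = None
    position: Optional[tuple[float, float]] = None
    axis: list[float] = []
    intensity: list[float] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith("#"):
                body = line.lstrip("#").strip()
                if body.lower().startswith("modality:"):
                    header_modality = body.split(":", 1)[1].strip().lower()
                elif body.lower().startswith("position:"):
                    parts = body.split(":", 1)[1].replace(",", " ").split()
                    position = (float(parts[0]), float(parts[1]))
                continue
            parts = line.replace(",", " ").split()
            if len(parts) < 2:
                raise SpectrumFormatError(
                    f"{path}:{lineno}: expected two columns, got {line!r}"
                )
            try:
                a, i = float(parts[0]), float(parts[1])
            except ValueError as exc:
                raise SpectrumFormatError(f"{path}:{lineno}: {exc}") from exc
            if axis and a <= axis[-1]:
                raise SpectrumFormatError(
                    f"{path}:{lineno}: axis not strictly increasing "
                    f"({a} after {axis[-1]})"
                )
            if i < 0:
                raise SpectrumFormatError(
                    f"{path}:{lineno}: negative intensity {i}"
                )
            axis.append(a)
            intensity.append(i)
    mod = modality or header_modality
    if mod is None:
        raise SpectrumFormatError(f"{path}: modality neither in header nor given")
    try:
        return Spectrum(np.array(axis), np.array(intensity), Modality(mod),
                        position=position)
    except SpectrumFormatError as exc:
        raise SpectrumFormatError(f"{path}: {exc}") from exc


def write_spectrum(spectrum: Spectrum, path: str | Path) -> None:
    """Write a spectrum as two-column text with a '#' metadata header."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(f"# modality: {spectrum.modality.value}\n")
        if spectrum.position is not None:
            fh.write(f"# position: {_FMT % spectrum.position[0]} "
                     f"{_FMT % spectrum.position[1]}\n")
        for a, i in zip(spectrum.axis, spectrum.intensity):
            fh.write(f"{_FMT % a}\t{_FMT % i}\n")


def _read_sidecar(path: Path) -> dict:
    if not path.exists():
        return {}
    with open(path) as fh:
        return yaml.safe_load(fh) or {}


def _write_sidecar(path: Path, step: float, origin: tuple[float, float]) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump({"step": float(step), "origin": [float(origin[0]),
                                                        float(origin[1])]}, fh)


def _grid_from_pixels(pixels: dict[tuple[int, int], dict], what: str
                      ) -> tuple[np.ndarray, np.ndarray]:
    """Assemble rectangular modality grids from a pixel dict; validate."""
    if not pixels:
        raise MapFormatError(f"{what}: no pixels found")
    xs = sorted({p[0] for p in pixels})
    ys = sorted({p[1] for p in pixels})
    if xs != list(range(xs[0], xs[0] + len(xs))) or \
       ys != list(range(ys[0], ys[0] + len(ys))):
        raise MapFormatError(f"{what}: pixel indices are not a dense grid")
    missing = [(x, y) for y in ys for x in xs if (x, y) not in pixels]
    if missing:
        raise MapFormatError(
            f"{what}: grid is ragged, missing pixels at (x, y) = {missing[:8]}"
        )
    shape = (len(ys), len(xs))
    bgrid = np.full(shape, None, dtype=object)
    rgrid = np.full(shape, None, dtype=object)
    for (x, y), rec in pixels.items():
        r, c = y - ys[0], x - xs[0]
        bgrid[r, c] = rec.get("brillouin")
        rgrid[r, c] = rec.get("raman")
    return bgrid, rgrid


def read_map(path: str | Path) -> SpectralMap:
    """Read a SpectralMap from either on-disk dialect.

    A directory → directory layout (``index.tsv`` + spectrum files +
    ``meta.yaml``); a file → long-format table with a ``.meta.yaml``
    sidecar.  Missing modality at a pixel is recorded as absent, not zero.
    """
    path = Path(path)
    if path.is_dir():
        return _read_map_dir(path)
    return _read_map_long(path)


def _read_map_long(path: Path) -> SpectralMap:
    meta = _read_sidecar(path.with_name(path.name + ".meta.yaml"))
    df = pd.read_csv(path, sep=None, engine="python", comment="#")
    required = {"x", "y", "modality", "axis_value", "intensity"}
    if not required.issubset(df.columns):
        raise MapFormatError(
            f"{path}: long format needs columns {sorted(required)}, "
            f"got {list(df.columns)}"
        )
    pixels: dict[tuple[int, int], dict] = {}
    for (x, y, mod), group in df.groupby(["x", "y", "modality"], sort=True):
        group = group.sort_values("axis_value")
        try:
            spec = Spectrum(group["axis_value"].to_numpy(float),
                            group["intensity"].to_numpy(float),
                            Modality(str(mod)))
        except (SpectrumFormatError, ValueError) as exc:
            raise MapFormatError(f"{path}: pixel ({x}, {y}) {mod}: {exc}") from exc
        pixels.setdefault((int(x), int(y)), {})[str(mod)] = spec
    bgrid, rgrid = _grid_from_pixels(pixels, str(path))
    try:
        return SpectralMap(bgrid, rgrid,
                           step=float(meta.get("step", 3.0)),
                           origin=tuple(meta.get("origin", (0.0, 0.0))))
    except MapFormatError as exc:
        raise MapFormatError(f"{path}: {exc}") from exc


def _read_map_dir(path: Path) -> SpectralMap:
    index = path / "index.tsv"
    if not index.exists():
        raise MapFormatError(f"{path}: directory layout requires index.tsv")
    meta = _read_sidecar(path / "meta.yaml")
    df = pd.read_csv(index, sep="\t", comment="#",
                     dtype={"brillouin_file": str, "raman_file": str})
    required = {"x", "y", "brillouin_file", "raman_file"}
    if not required.issubset(df.columns):
        raise MapFormatError(f"{index}: needs columns {sorted(required)}")
    pixels: dict[tuple[int, int], dict] = {}
    for row in df.itertuples(index=False):
        rec: dict = {}
        for mod, fname in (("brillouin", row.brillouin_file),
                           ("raman", row.raman_file)):
            if isinstance(fname, str) and fname.strip():
                rec[mod] = read_spectrum(path / fname.strip(), mod)
        pixels[(int(row.x), int(row.y))] = rec
    bgrid, rgrid = _grid_from_pixels(pixels, str(path))
    try:
        return SpectralMap(bgrid, rgrid,
                           step=float(meta.get("step", 3.0)),
                           origin=tuple(meta.get("origin", (0.0, 0.0))))
    except MapFormatError as exc:
        raise MapFormatError(f"{path}: {exc}") from exc


def write_map(smap: SpectralMap, path: str | Path, layout: str = "long",
              delimiter: str = "\t") -> None:
    """Write a SpectralMap in the requested dialect ('long' or 'dir')."""
    path = Path(path)
    if layout == "long":
        _write_map_long(smap, path, delimiter)
    elif layout == "dir":
        _write_map_dir(smap, path)
    else:
        raise ValueError(f"unknown layout {layout!r}")


def _write_map_long(smap: SpectralMap, path: Path, delimiter: str) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter=delimiter)
        writer.writerow(["x", "y", "modality", "axis_value", "intensity"])
        rows, cols = smap.shape
        for r in range(rows):
            for c in range(cols):
                for mod, grid in (("brillouin", smap.brillouin),
                                  ("raman", smap.raman)):
                    spec = grid[r, c]
                    if spec is None:
                        continue
                    for a, i in zip(spec.axis, spec.intensity):
                        writer.writerow([c, r, mod, _FMT % a, _FMT % i])
    _write_sidecar(path.with_name(path.name + ".meta.yaml"),
                   smap.step, smap.origin)


def _write_map_dir(smap: SpectralMap, path: Path) -> None:
    path.mkdir(parents=True, exist_ok=True)
    rows_out = []
    rows, cols = smap.shape
    for r in range(rows):
        for c in range(cols):
            rec = {"x": c, "y": r, "brillouin_file": "", "raman_file": ""}
            for mod, grid in (("brillouin", smap.brillouin),
                              ("raman", smap.raman)):
                spec = grid[r, c]
                if spec is not None:
                    fname = f"{mod}_x{c:03d}_y{r:03d}.txt"
                    write_spectrum(spec, path / fname)
                    rec[f"{mod}_file"] = fname
            rows_out.append(rec)
    pd.DataFrame(rows_out).to_csv(path / "index.tsv", sep="\t", index=False)
    _write_sidecar(path / "meta.yaml", smap.step, smap.origin)


def write_features_table(feature_maps: dict[str, np.ndarray],
                         path: str | Path, delimiter: str = "\t") -> None:
    """Write per-pixel features as one delimited row per pixel.

    ``feature_maps`` maps feature name → 2-D array (NaN = missing).  All
    arrays must share one shape; NaN cells are written empty, not as zeros.
    """
    shapes = {np.asarray(v).shape for v in feature_maps.values()}
    if len(shapes) != 1:
        raise ValueError(f"feature maps disagree in shape: {sorted(shapes)}")
    shape = shapes.pop()
    names = [n for n in FEATURE_COLUMNS if n in feature_maps]
    names += [n for n in feature_maps if n not in FEATURE_COLUMNS]
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter=delimiter)
        writer.writerow(["x", "y"] + names)
        for r in range(shape[0]):
            for c in range(shape[1]):
                row: list = [c, r]
                for name in names:
                    val = float(np.asarray(feature_maps[name])[r, c])
                    row.append("" if np.isnan(val) else _FMT % val)
                writer.writerow(row)


def read_features_table(path: str | Path) -> dict[str, np.ndarray]:
    """Read a feature table back into feature name → 2-D array (NaN missing)."""
    df = pd.read_csv(path, sep=None, engine="python", comment="#")
    if not {"x", "y"}.issubset(df.columns):
        raise MapFormatError(f"{path}: feature table needs x and y columns")
    rows = int(df["y"].max()) + 1
    cols = int(df["x"].max()) + 1
    out: dict[str, np.ndarray] = {}
    for name in df.columns:
        if name in ("x", "y"):
            continue
        arr = np.full((rows, cols), np.nan)
        arr[df["y"].to_numpy(int), df["x"].to_numpy(int)] = \
            pd.to_numeric(df[name], errors="coerce").to_numpy(float)
        out[name] = arr
    return out


def read_rois(path: str | Path) -> list:
    """Read ROI rectangles from a delimited file with columns
    id, row_lo, row_hi, col_lo, col_hi (hi-exclusive)."""
    from .mapping import ROI

    df = pd.read_csv(path, sep=None, engine="python", comment="#")
    required = {"id", "row_lo", "row_hi", "col_lo", "col_hi"}
    if not required.issubset(df.columns):
        raise MapFormatError(f"{path}: ROI file needs columns {sorted(required)}")
    return [ROI(str(r.id), int(r.row_lo), int(r.row_hi),
                int(r.col_lo), int(r.col_hi))
            for r in df.itertuples(index=False)]


def write_rois(rois: list, path: str | Path, delimiter: str = "\t") -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter=delimiter)
        writer.writerow(["id", "row_lo", "row_hi", "col_lo", "col_hi"])
        for roi in rois:
            writer.writerow([roi.id, roi.row_lo, roi.row_hi,
                             roi.col_lo, roi.col_hi])
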