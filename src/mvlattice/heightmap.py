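"""Calibrated AFM height maps and their on-disk representations.

A :class:`HeightMap` is the universal currency of the pipeline: a
rectangular grid of surface heights in nanometres together with an
isotropic lateral calibration (nm per pixel).  Row 0 is the top of the
scan and the column index increases rightward; pixel indices are
0-based, and physical coordinates are ``index * pixel_size``.

Calibration travels in a small YAML/JSON sidecar file next to the image
(keys ``pixel_size_nm`` and ``z_units``) for both supported formats:
single-channel float32 TIFF and whitespace-separated ASCII grids.
Vendor AFM formats are deliberately not parsed.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Iterable, Optional, Tuple

import numpy as np
import pandas as pd
import tifffile
import yaml

__all__ = [
    "HeightMap",
    "ResultRecord",
    "CalibrationError",
    "FormatError",
    "read_heightmap",
    "write_heightmap",
    "crop_roi",
    "write_result_records",
    "read_result_records",
]

#: exact header of the per-image results table
RESULT_COLUMNS = ["lattice_type", "lattice_constant_um", "image_id", "counts_per_roi_um2"]

MIN_GRID = 16


class CalibrationError(ValueError):
    """Missing or invalid lateral/height calibration."""


class FormatError(ValueError):
    """Malformed image data (non-rectangular, non-numeric, wrong dtype)."""


@dataclasses.dataclass(frozen=True)
class HeightMap:
    """A calibrated 2D topography grid.

    Parameters
    ----------
    heights : ndarray, shape (rows, cols)
        Surface height in nm.  Must be finite everywhere.
    pixel_size : float
        Isotropic lateral calibration in nm/px, > 0.
    note : str, optional
        Free-form provenance (scan mode, scan angle, ...).
    """

    heights: np.ndarray
    pixel_size: float
    note: str = ""

    def __post_init__(self) -> None:
        arr = np.asarray(self.heights, dtype=float)
        if arr.ndim != 2:
            raise FormatError(f"heights must be 2D, got ndim={arr.ndim}")
        if arr.shape[0] < MIN_GRID or arr.shape[1] < MIN_GRID:
            raise FormatError(
                f"grid must be at least {MIN_GRID}x{MIN_GRID}, got {arr.shape}"
            )
        if not np.all(np.isfinite(arr)):
            raise FormatError("height values must all be finite")
        if not (self.pixel_size > 0):
            raise CalibrationError(f"pixel_size must be > 0, got {self.pixel_size}")
        object.__setattr__(self, "heights", arr)

    # -- geometry ---------------------------------------------------------
    @property
    def shape(self) -> Tuple[int, int]:
        return self.heights.shape

    @property
    def field_size_nm(self) -> Tuple[float, float]:
        """(height, width) of the scanned field in nm."""
        r, c = self.heights.shape
        return (r * self.pixel_size, c * self.pixel_size)

    @property
    def area_um2(self) -> float:
        """Scan area in square micrometres."""
        h, w = self.field_size_nm
        return h * w * 1e-6

    def with_heights(self, heights: np.ndarray) -> "HeightMap":
        """Same calibration and provenance, new height grid."""
        return HeightMap(heights, self.pixel_size, self.note)

    def allclose(self, other: "HeightMap", atol: float = 1e-9) -> bool:
        return (
            self.heights.shape == other.heights.shape
            and np.isclose(self.pixel_size, other.pixel_size)
            and np.allclose(self.heights, other.heights, atol=atol)
        )


@dataclasses.dataclass(frozen=True)
class ResultRecord:
    """One row of the per-image results table.

    Mirrors the four raw-data columns: lattice class label, lattice
    constant in μm, image identifier, and microvillus count per ROI
    area in μm⁻².
    """

    lattice_type: str
    lattice_constant_um: float
    image_id: str
    counts_per_roi_um2: float


# ---------------------------------------------------------------------------
# sidecar handling
# ---------------------------------------------------------------------------

def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".meta.yaml")


def _write_sidecar(path: Path, pixel_size: float, note: str) -> None:
    meta = {"pixel_size_nm": float(pixel_size), "z_units": "nm"}
    if note:
        meta["note"] = note
    _sidecar_path(path).write_text(yaml.safe_dump(meta), encoding="utf-8")


def _read_sidecar(path: Path) -> dict:
    sidecar = _sidecar_path(path)
    if not sidecar.exists():
        # accept .json sidecars too
        alt = path.with_suffix(path.suffix + ".meta.json")
        if alt.exists():
            return json.loads(alt.read_text(encoding="utf-8"))
        raise CalibrationError(f"no calibration sidecar found for {path}")
    meta = yaml.safe_load(sidecar.read_text(encoding="utf-8"))
    if not isinstance(meta, dict) or "pixel_size_nm" not in meta:
        raise CalibrationError(f"sidecar {sidecar} lacks pixel_size_nm")
    px = meta["pixel_size_nm"]
    if isinstance(px, (list, tuple)):
        # anisotropic calibration is rejected rather than resampled
        if len(set(float(v) for v in px)) != 1:
            raise CalibrationError(f"anisotropic pixel size {px} not supported")
        meta["pixel_size_nm"] = float(px[0])
    if meta.get("z_units", "nm") != "nm":
        raise CalibrationError(f"unsupported z_units {meta.get('z_units')!r}")
    return meta


# ---------------------------------------------------------------------------
# read / write
# ---------------------------------------------------------------------------

def _infer_format(path: Path, format: Optional[str]) -> str:
    if format is not None:
        if format not in ("tiff", "ascii_grid"):
            raise ValueError(f"unknown format {format!r}")
        return format
    if path.suffix.lower() in (".tif", ".tiff"):
        return "tiff"
    return "ascii_grid"


def read_heightmap(path, format: Optional[str] = None) -> HeightMap:
    """Read a calibrated height map from TIFF or ASCII grid.

    The lateral calibration is taken from the sidecar metadata file
    (``<name>.meta.yaml``); a missing sidecar raises
    :class:`CalibrationError`.
    """
    path = Path(path)
    fmt = _infer_format(path, format)
    meta = _read_sidecar(path)
    if fmt == "tiff":
        arr = tifffile.imread(path)
        arr = np.asarray(arr, dtype=float)
    else:
        try:
            arr = np.loadtxt(path, dtype=float, ndmin=2)
        except ValueError as exc:
            raise FormatError(f"cannot parse ASCII grid {path}: {exc}") from exc
    return HeightMap(arr, float(meta["pixel_size_nm"]), note=str(meta.get("note", "")))


def write_heightmap(hm: HeightMap, path, format: Optional[str] = None) -> None:
    """Write a height map plus its calibration sidecar.

    ASCII grids are lossless (``%.17g``, one row per scan line); TIFF is
    written as single-channel 32-bit float.
    """
    path = Path(path)
    fmt = _infer_format(path, format)
    try:
        if fmt == "tiff":
            tifffile.imwrite(path, hm.heights.astype(np.float32))
        else:
            np.savetxt(path, hm.heights, fmt="%.17g")
        _write_sidecar(path, hm.pixel_size, hm.note)
    except OSError as exc:
        raise IOError(f"cannot write height map to {path}: {exc}") from exc


def crop_roi(hm: HeightMap, rect: Tuple[int, int, int, int]) -> HeightMap:
    """Crop a rectangular ROI given as ``(row0, col0, n_rows, n_cols)``.

    The ROI must lie within the grid and be at least 16x16 px.  The ROI
    area in μm² is available as ``crop_roi(...).area_um2``.
    """
    r0, c0, nr, nc = (int(v) for v in rect)
    rows, cols = hm.shape
    if nr < MIN_GRID or nc < MIN_GRID:
        raise IndexError(f"ROI {nr}x{nc} smaller than {MIN_GRID}x{MIN_GRID}")
    if r0 < 0 or c0 < 0 or r0 + nr > rows or c0 + nc > cols:
        raise IndexError(f"ROI {rect} exceeds grid {hm.shape}")
    return hm.with_heights(hm.heights[r0 : r0 + nr, c0 : c0 + nc].copy())


# ---------------------------------------------------------------------------
# results table
# ---------------------------------------------------------------------------

def write_result_records(records: Iterable[ResultRecord], path) -> None:
    """Write the per-image results CSV with the canonical four columns."""
    df = pd.DataFrame(
        [
            (r.lattice_type, r.lattice_constant_um, r.image_id, r.counts_per_roi_um2)
            for r in records
        ],
        columns=RESULT_COLUMNS,
    )
    df.to_csv(path, index=False)


def read_result_records(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    if list(df.columns) != RESULT_COLUMNS:
        raise FormatError(f"unexpected results header {list(df.columns)}")
    return df
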