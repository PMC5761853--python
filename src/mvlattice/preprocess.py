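"""Scan-artifact correction applied before any quantitative analysis.

AFM raster scans carry instrument artifacts that must be removed before
object detection or spectral analysis: per-scan-line height offsets
(each line has its own z reference), an overall sample tilt, and
"scars" — short bursts of bad feedback confined to a few consecutive
scan lines.  The correction chain is, in order:

1. row alignment — remove per-line offsets.  Two estimators are
   provided: :func:`align_rows_median` (subtract the median of each
   scan line) and :func:`align_rows_diffmedian` (offsets accumulated
   from the median of row-to-row differences).  The default chain uses
   the difference-median form: on surfaces densely covered by relief,
   per-line medians track the structure itself and imprint a
   lattice-phase stripe pattern, while the difference median is blind
   to any structure that varies slowly from line to line;
2. :func:`level_plane`       — subtract the least-squares best-fit plane;
3. :func:`remove_scars`      — detect and interpolate over narrow
   row-aligned deviant segments (default geometry: at most 4 px wide,
   at least 16 px long).

The Hann taper (:func:`hann_window`) is not part of the chain; it is
applied only inside the spectral analysis, immediately before the FFT.
"""

from __future__ import annotations

import dataclasses
from typing import List, Sequence, Tuple

import numpy as np

from .heightmap import HeightMap

__all__ = [
    "PreprocessParams",
    "align_rows_median",
    "align_rows_diffmedian",
    "level_plane",
    "remove_scars",
    "hann_window",
    "preprocess",
]


@dataclasses.dataclass(frozen=True)
class PreprocessParams:
    """Tunables of the correction chain.

    scar_max_width : int
        Maximum scar thickness in scan lines (px).  Default 4.
    scar_min_length : int
        Minimum scar extent along the fast axis (px).  Default 16.
    scar_threshold : float
        Height-deviation threshold in multiples of the robust scatter
        (median absolute deviation) of the row-difference field.
    steps : tuple of str
        Ordered chain; subset of {"align_rows_diff", "align_rows",
        "level_plane", "remove_scars"}.
    """

    scar_max_width: int = 4
    scar_min_length: int = 16
    scar_threshold: float = 5.0
    steps: Tuple[str, ...] = ("align_rows_diff", "level_plane", "remove_scars")

    def __post_init__(self) -> None:
        if self.scar_max_width < 1 or self.scar_min_length < 1:
            raise ValueError("scar geometry parameters must be >= 1 px")
        unknown = set(self.steps) - {"align_rows_diff", "align_rows",
                                     "level_plane", "remove_scars"}
        if unknown:
            raise ValueError(f"unknown preprocessing steps {sorted(unknown)}")


def align_rows_median(hm: HeightMap) -> HeightMap:
    """Subtract the median of each scan line; every output row has median 0."""
    z = hm.heights
    return hm.with_heights(z - np.median(z, axis=1, keepdims=True))


def align_rows_diffmedian(hm: HeightMap) -> HeightMap:
    """Remove per-line offsets estimated from row-to-row differences.

    The offset increment of line ``i`` is the median over columns of
    ``z[i] - z[i-1]``; the cumulative increments are subtracted (line 0
    is the reference).  Unlike plain per-line medians this estimator
    does not respond to relief that extends over several lines, so
    dense periodic structure passes through unchanged.
    """
    z = hm.heights
    d = np.median(np.diff(z, axis=0), axis=1)
    offsets = np.concatenate([[0.0], np.cumsum(d)])
    return hm.with_heights(z - offsets[:, None])


def level_plane(hm: HeightMap) -> HeightMap:
    """Subtract the least-squares best-fit plane z = a·x + b·y + c."""
    z = hm.heights
    rows, cols = z.shape
    yy, xx = np.mgrid[0:rows, 0:cols]
    A = np.column_stack([xx.ravel(), yy.ravel(), np.ones(z.size)])
    coef, *_ = np.linalg.lstsq(A, z.ravel(), rcond=None)
    plane = (A @ coef).reshape(z.shape)
    return hm.with_heights(z - plane)


def _runs(row: np.ndarray):
    """Start/stop pairs of True runs in a boolean row."""
    edges = np.flatnonzero(
        np.diff(np.concatenate(([0], row.view(np.int8), [0])))
    )
    return zip(edges[::2], edges[1::2])


def _scar_mask(z: np.ndarray, params: PreprocessParams) -> np.ndarray:
    """Boolean mask of scar pixels.

    A scar is a band of ``w <= scar_max_width`` consecutive scan lines
    that is offset by a roughly constant amount from the rows
    immediately outside the band.  For every candidate width the band
    is compared against the mean of its two bracketing rows; columns
    where *all* band rows deviate with the same sign by more than
    ``scar_threshold`` robust-sigma (MAD of the lag-1 row differences)
    are grouped into runs.  A run is accepted only if it is at least
    ``scar_min_length`` px long and its deviation is near-constant
    along the run (offset-like, not relief-like): the run's deviation
    scatter must stay below half its mean magnitude.  Genuine surface
    relief — even steep microvillus rims — varies along a row and is
    left alone.
    """
    rows, cols = z.shape
    row_diff = np.diff(z, axis=0)
    mad = np.median(np.abs(row_diff - np.median(row_diff)))
    sigma = 1.4826 * mad
    if sigma <= 0:
        sigma = np.finfo(float).tiny
    thresh = params.scar_threshold * sigma

    mask = np.zeros_like(z, dtype=bool)
    for w in range(1, params.scar_max_width + 1):
        # bands touching the image border have no clean reference on one
        # side; interpolating them is ill-posed, so they are left alone
        for i in range(1, rows - w):
            above = z[i - 1]
            below = z[i + w]
            ref = 0.5 * (above + below)
            # the references themselves must agree; otherwise one of
            # them lies inside a wider scar (or on steep relief)
            refs_ok = np.abs(above - below) < thresh
            dev = z[i : i + w] - ref  # (w, cols)
            pos = (dev > thresh).all(axis=0) & refs_ok
            neg = (dev < -thresh).all(axis=0) & refs_ok
            m = dev.mean(axis=0)
            for cand in (pos, neg):
                for start, stop in _runs(cand):
                    if stop - start < params.scar_min_length:
                        continue
                    seg = m[start:stop]
                    if np.std(seg) <= 0.5 * np.mean(np.abs(seg)):
                        mask[i : i + w, start:stop] = True
    return mask


def remove_scars(hm: HeightMap, params: PreprocessParams | None = None) -> HeightMap:
    """Replace scar pixels by linear interpolation from clean rows.

    Pixels outside the detected scar mask are returned bit-identical.
    """
    if params is None:
        params = PreprocessParams()
    z = hm.heights
    mask = _scar_mask(z, params)
    if not mask.any():
        return hm.with_heights(z.copy())
    out = z.copy()
    rows = z.shape[0]
    for j in np.flatnonzero(mask.any(axis=0)):
        col_mask = mask[:, j]
        bad = np.flatnonzero(col_mask)
        good = np.flatnonzero(~col_mask)
        if good.size == 0:
            continue
        out[bad, j] = np.interp(bad, good, z[good, j])
    return hm.with_heights(out)


def hann_window(hm: HeightMap) -> HeightMap:
    """Apply the separable 2D Hann taper; borders go to zero."""
    rows, cols = hm.shape
    wr = np.hanning(rows)
    wc = np.hanning(cols)
    return hm.with_heights(hm.heights * np.outer(wr, wc))


_STEPS = {
    "align_rows": lambda hm, p: align_rows_median(hm),
    "align_rows_diff": lambda hm, p: align_rows_diffmedian(hm),
    "level_plane": lambda hm, p: level_plane(hm),
    "remove_scars": remove_scars,
}


def preprocess(hm: HeightMap, params: PreprocessParams | None = None) -> HeightMap:
    """Run the full correction chain in its canonical order."""
    if params is None:
        params = PreprocessParams()
    for name in params.steps:
        hm = _STEPS[name](hm, params)
    return hm
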