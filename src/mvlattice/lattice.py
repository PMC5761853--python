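"""Bravais-lattice analysis of microvillar fields.

The lattice type and lattice constant of a microvillar carpet are read
from the 2D power spectrum of the (preprocessed, Hann-windowed) height
map: the ring of first-order peaks is the first Brillouin zone of the
tip lattice.  Two linearly independent first-order peaks ``b1, b2``
(cycles/nm) determine the real-space primitive vectors through

    a_i · b_j = δ_ij        (no 2π — all frequencies are cycles/nm)

and the pair (|a1|, |a2|, θ) is classified into one of the five planar
Bravais classes with configurable length/angle tolerances.  A
complementary real-space check counts, for each detected microvillus,
the neighbors reachable by a nearest-neighbor lattice translation
(coordination 6 on hexagonal fields, 4 on rhombic ones).

:class:`LatticeModel` packages the chain in a fit-style interface::

    res = LatticeModel(hm).fit()
    res.lattice_constant_nm, res.bravais_class
    print(res.summary())
"""

from __future__ import annotations

import dataclasses
import warnings
from typing import List, Optional, Sequence, Tuple

import networkx as nx
import numpy as np
from scipy import ndimage, spatial

from .heightmap import HeightMap
from .preprocess import PreprocessParams, hann_window, preprocess

__all__ = [
    "SpectralPeak",
    "PowerSpectrum",
    "LatticeFit",
    "NeighborGraph",
    "DegenerateBasisError",
    "power_spectrum",
    "find_lattice_peaks",
    "reciprocal_to_real",
    "classify_bravais",
    "neighbor_links",
    "LatticeModel",
    "LatticeResults",
]

BRAVAIS_CLASSES = ("hexagonal", "rhombic", "square", "rectangular", "oblique", "none")


class DegenerateBasisError(ValueError):
    """Reciprocal peaks too close to collinear to invert."""


@dataclasses.dataclass(frozen=True)
class SpectralPeak:
    """One reciprocal-space peak (the +k representative of a ±k pair)."""

    kx: float  # cycles/nm
    ky: float  # cycles/nm
    magnitude: float
    halfwidth: float  # half-width of the quadratic peak fit, cycles/nm
    first_order: bool = True

    @property
    def k(self) -> np.ndarray:
        return np.array([self.kx, self.ky])

    @property
    def radius(self) -> float:
        return float(np.hypot(self.kx, self.ky))


@dataclasses.dataclass(frozen=True)
class PowerSpectrum:
    """Zero-frequency-centred FFT magnitude with calibrated axes."""

    magnitude: np.ndarray
    freq_row: np.ndarray  # cycles/nm along rows (y)
    freq_col: np.ndarray  # cycles/nm along cols (x)

    @property
    def bin_width(self) -> float:
        return float(self.freq_col[1] - self.freq_col[0])


@dataclasses.dataclass(frozen=True)
class LatticeFit:
    """Classified real-space lattice of one field."""

    a1: np.ndarray  # nm
    a2: np.ndarray  # nm
    bravais_class: str
    lattice_constant_nm: float
    lattice_constant_sd_nm: float
    theta_deg: float
    peaks: Tuple[SpectralPeak, ...] = ()

    @property
    def lengths(self) -> Tuple[float, float]:
        return float(np.linalg.norm(self.a1)), float(np.linalg.norm(self.a2))

    def nearest_neighbor_translations(self) -> List[np.ndarray]:
        """Lattice translations to nearest neighbors (one per ± pair).

        ``a1`` and ``a2`` always; on a hexagonal lattice the third
        equivalent direction ``a1 - a2`` as well.
        """
        ts = [np.asarray(self.a1, float), np.asarray(self.a2, float)]
        if self.bravais_class == "hexagonal":
            ts.append(ts[0] - ts[1])
        return ts


@dataclasses.dataclass
class NeighborGraph:
    """Symmetry-axis nearest-neighbor links between detections."""

    graph: nx.Graph
    interior: np.ndarray  # bool per node
    link_counts: np.ndarray  # int per node

    @property
    def interior_link_counts(self) -> np.ndarray:
        return self.link_counts[self.interior]


# ---------------------------------------------------------------------------
# spectrum
# ---------------------------------------------------------------------------

def power_spectrum(hm: HeightMap, window: bool = True) -> PowerSpectrum:
    """Magnitude of the 2D DFT of the Hann-windowed height map.

    Non-square inputs are centre-cropped to a square with a warning;
    axes are in cycles/nm.  The mean is removed before windowing so the
    DC bin does not swamp the display scale.
    """
    z = hm.heights
    rows, cols = z.shape
    if rows != cols:
        warnings.warn("non-square height map: using centred square crop",
                      stacklevel=2)
        n = min(rows, cols)
        r0 = (rows - n) // 2
        c0 = (cols - n) // 2
        z = z[r0 : r0 + n, c0 : c0 + n]
    z = z - z.mean()
    if window:
        w = np.hanning(z.shape[0])
        z = z * np.outer(w, w)
    mag = np.abs(np.fft.fftshift(np.fft.fft2(z)))
    freq = np.fft.fftshift(np.fft.fftfreq(z.shape[0], d=hm.pixel_size))
    return PowerSpectrum(magnitude=mag, freq_row=freq.copy(), freq_col=freq)


# ---------------------------------------------------------------------------
# peak finding
# ---------------------------------------------------------------------------

def _quad_subpixel_1d(fm: float, f0: float, fp: float) -> Tuple[float, float]:
    """(offset, halfwidth) of the parabola through three samples."""
    denom = 2.0 * (2.0 * f0 - fm - fp)
    if denom <= 0:
        return 0.0, 0.5
    off = float(np.clip((fp - fm) / denom, -0.5, 0.5))
    # parabola f0 - c2 (x-off)^2 with c2 = denom/4; half max at
    # sqrt(f0 / (2 c2)) bins from the apex
    c2 = denom / 4.0
    hw = float(np.sqrt(max(f0, 0.0) / (2.0 * c2))) if c2 > 0 else 0.5
    return off, min(hw, 3.0)


def find_lattice_peaks(
    spec: PowerSpectrum,
    annulus: Tuple[float, float] = (0.002, 0.012),
    threshold_factor: float = 10.0,
    profile_line: Optional[Tuple[np.ndarray, np.ndarray]] = None,
) -> List[SpectralPeak]:
    """Sub-pixel reciprocal peaks inside a frequency annulus.

    Local maxima of the magnitude inside ``annulus`` (cycles/nm,
    DC region excluded) that exceed ``threshold_factor`` times the
    annulus median are refined to sub-pixel position by separable
    quadratic fits over their 3x3 neighbourhood, merged with their
    centro-symmetric partners (the returned representative has
    ``ky > 0``, or ``ky == 0`` and ``kx > 0``), and ranked by
    magnitude.  An empty list means no periodic structure above
    background.

    ``profile_line`` — optional pair of endpoint frequency vectors; when
    given, only peaks within one frequency bin of the segment are kept
    (the manual profile-line mode).
    """
    mag = spec.magnitude
    ky, kx = np.meshgrid(spec.freq_row, spec.freq_col, indexing="ij")
    kr = np.hypot(kx, ky)
    lo, hi = annulus
    if lo <= 0:
        raise ValueError("annulus must exclude the DC region (lo > 0)")
    mask = (kr >= lo) & (kr <= hi)
    if not mask.any():
        return []
    background = float(np.median(mag[mask]))
    threshold = threshold_factor * background

    local_max = mag == ndimage.maximum_filter(mag, size=3, mode="nearest")
    cand = np.argwhere(local_max & mask & (mag >= threshold))

    bin_w = spec.bin_width
    peaks: List[SpectralPeak] = []
    for r, c in cand:
        if r <= 0 or c <= 0 or r >= mag.shape[0] - 1 or c >= mag.shape[1] - 1:
            continue
        dr, hw_r = _quad_subpixel_1d(mag[r - 1, c], mag[r, c], mag[r + 1, c])
        dc, hw_c = _quad_subpixel_1d(mag[r, c - 1], mag[r, c], mag[r, c + 1])
        pky = spec.freq_row[r] + dr * bin_w
        pkx = spec.freq_col[c] + dc * bin_w
        hw = 0.5 * (hw_r + hw_c) * bin_w
        # canonical representative of the ±k pair
        if pky < 0 or (pky == 0 and pkx < 0):
            pkx, pky = -pkx, -pky
        peaks.append(SpectralPeak(kx=pkx, ky=pky, magnitude=float(mag[r, c]),
                                  halfwidth=hw))

    # merge duplicates (a peak and its mirrored partner land together)
    merged: List[SpectralPeak] = []
    for p in sorted(peaks, key=lambda p: -p.magnitude):
        if all(np.hypot(p.kx - q.kx, p.ky - q.ky) > bin_w for q in merged):
            merged.append(p)

    if profile_line is not None:
        p0 = np.asarray(profile_line[0], float)
        p1 = np.asarray(profile_line[1], float)
        seg = p1 - p0
        L2 = float(seg @ seg)

        def seg_dist(k: np.ndarray) -> float:
            ds = []
            for kk in (k, -k):
                t = float(np.clip((kk - p0) @ seg / L2, 0.0, 1.0)) if L2 > 0 else 0.0
                ds.append(float(np.linalg.norm(kk - (p0 + t * seg))))
            return min(ds)

        merged = [p for p in merged if seg_dist(p.k) <= bin_w]
    return merged


def first_order_peak_snr(hm: HeightMap,
                         annulus: Tuple[float, float] = (0.002, 0.012)
                         ) -> float:
    """Strongest annulus peak relative to the annulus median background.

    The ratio the peak threshold (``threshold_factor``) is compared
    against; a field whose SNR falls below the threshold yields no
    lattice fit.
    """
    spec = power_spectrum(hm)
    mag = spec.magnitude
    ky, kx = np.meshgrid(spec.freq_row, spec.freq_col, indexing="ij")
    kr = np.hypot(kx, ky)
    mask = (kr >= annulus[0]) & (kr <= annulus[1])
    if not mask.any():
        return 0.0
    bg = float(np.median(mag[mask]))
    return float(mag[mask].max() / bg) if bg > 0 else 0.0


def first_order_peaks(peaks: Sequence[SpectralPeak],
                      rel_magnitude: float = 0.25,
                      ring_tolerance: float = 1.25) -> List[SpectralPeak]:
    """Keep the peaks on the first-order ring (the first Brillouin zone).

    The strongest peak is taken as a lattice fundamental and its radius
    defines the ring; among peaks at least ``rel_magnitude`` of the
    strongest, those whose radius differs from the ring by more than a
    factor ``ring_tolerance`` are dropped — harmonics and combination
    peaks lie farther out, disorder-induced low-frequency clutter
    farther in.
    """
    if not peaks:
        return []
    r0 = max(peaks, key=lambda p: p.magnitude).radius
    strong = [p for p in peaks if p.magnitude >= rel_magnitude * peaks[0].magnitude]
    kept = [dataclasses.replace(
                p, first_order=r0 / ring_tolerance <= p.radius <= ring_tolerance * r0)
            for p in strong]
    return [p for p in kept if p.first_order]


# ---------------------------------------------------------------------------
# basis inversion and classification
# ---------------------------------------------------------------------------

def reciprocal_to_real(p1: SpectralPeak, p2: SpectralPeak,
                       max_condition: float = 50.0
                       ) -> Tuple[np.ndarray, np.ndarray]:
    """Invert two reciprocal peaks to the real-space primitive vectors.

    Solves ``a_i · b_j = δ_ij``, i.e. ``A = (Bᵀ)⁻¹`` for the 2x2
    matrices with basis vectors as rows.  Near-collinear peaks raise
    :class:`DegenerateBasisError`.
    """
    B = np.array([[p1.kx, p1.ky], [p2.kx, p2.ky]], dtype=float)
    if np.linalg.cond(B) > max_condition:
        raise DegenerateBasisError(
            f"reciprocal peaks nearly collinear (cond={np.linalg.cond(B):.3g})"
        )
    A = np.linalg.inv(B.T)
    return A[0], A[1]


def classify_bravais(a1: np.ndarray, a2: np.ndarray,
                     length_tolerance: float = 0.10,
                     angle_tolerance_deg: float = 8.0,
                     peaks: Sequence[SpectralPeak] = ()) -> LatticeFit:
    """Classify a real-space basis into a planar Bravais class.

    The included angle is normalised to (0°, 90°]; classification is
    invariant to swapping or sign-flipping the basis vectors.  Equal
    lengths (within the relative tolerance) and θ ≈ 60° → hexagonal;
    θ ≈ 90° → square; otherwise rhombic.  Unequal lengths with
    θ ≈ 90° → rectangular; anything else → oblique.
    """
    a1 = np.asarray(a1, float)
    a2 = np.asarray(a2, float)
    l1, l2 = np.linalg.norm(a1), np.linalg.norm(a2)
    if l1 == 0 or l2 == 0:
        raise DegenerateBasisError("zero-length basis vector")
    cosang = np.clip(abs(a1 @ a2) / (l1 * l2), 0.0, 1.0)
    theta = float(np.degrees(np.arccos(cosang)))  # folded into (0, 90]
    equal = abs(l1 - l2) / max(l1, l2) <= length_tolerance
    near60 = abs(theta - 60.0) <= angle_tolerance_deg
    near90 = abs(theta - 90.0) <= angle_tolerance_deg
    if equal and near60:
        cls = "hexagonal"
    elif equal and near90:
        cls = "square"
    elif equal:
        cls = "rhombic"
    elif near90:
        cls = "rectangular"
    else:
        cls = "oblique"
    constant = float(0.5 * (l1 + l2))
    # propagate the sub-pixel peak half-widths through |a| = 1/(|b| sin φ)
    sd = 0.0
    if peaks:
        rel = np.mean([p.halfwidth / p.radius for p in peaks if p.radius > 0])
        sd = float(constant * rel)
    return LatticeFit(a1=a1, a2=a2, bravais_class=cls,
                      lattice_constant_nm=constant,
                      lattice_constant_sd_nm=sd, theta_deg=theta,
                      peaks=tuple(peaks))


def fit_lattice(
    hm: HeightMap,
    annulus: Tuple[float, float] = (0.002, 0.012),
    threshold_factor: float = 10.0,
    length_tolerance: float = 0.10,
    angle_tolerance_deg: float = 8.0,
    min_pair_angle_deg: float = 20.0,
) -> LatticeFit:
    """Spectrum → peaks → basis → class, on an already preprocessed map.

    Uses the two strongest non-collinear first-order peaks.  When fewer
    than two usable peaks exist the fit has class ``"none"`` and a NaN
    lattice constant.
    """
    spec = power_spectrum(hm)
    peaks = find_lattice_peaks(spec, annulus=annulus,
                               threshold_factor=threshold_factor)
    ring = first_order_peaks(peaks)
    chosen: List[SpectralPeak] = []
    for p in ring:
        if not chosen:
            chosen.append(p)
            continue
        q = chosen[0]
        cosang = abs(p.k @ q.k) / (p.radius * q.radius)
        ang = np.degrees(np.arccos(np.clip(cosang, 0.0, 1.0)))
        if ang >= min_pair_angle_deg:
            chosen.append(p)
            break
    if len(chosen) < 2:
        return LatticeFit(a1=np.zeros(2), a2=np.zeros(2), bravais_class="none",
                          lattice_constant_nm=float("nan"),
                          lattice_constant_sd_nm=float("nan"),
                          theta_deg=float("nan"), peaks=tuple(ring))
    a1, a2 = reciprocal_to_real(chosen[0], chosen[1])
    return classify_bravais(a1, a2, length_tolerance, angle_tolerance_deg,
                            peaks=tuple(chosen))


# ---------------------------------------------------------------------------
# real-space neighbor links
# ---------------------------------------------------------------------------

def neighbor_links(positions_nm: np.ndarray, fit: LatticeFit,
                   tolerance: float = 0.2,
                   field_nm: Optional[Tuple[float, float]] = None
                   ) -> NeighborGraph:
    """Link detections separated by a nearest-neighbor lattice translation.

    An edge joins two tips whose displacement matches ±a1, ±a2 (and
    ±(a1−a2) on hexagonal fields) within ``tolerance`` × |translation|.
    Nodes closer to the field border than the largest translation are
    marked non-interior; their truncated coordination should not enter
    population statistics.
    """
    if fit.bravais_class == "none":
        raise ValueError("cannot build neighbor links without a classified lattice")
    pts = np.asarray(positions_nm, float)
    ts = fit.nearest_neighbor_translations()
    tmax = max(np.linalg.norm(t) for t in ts)
    cutoff = tmax * (1.0 + tolerance)

    g = nx.Graph()
    g.add_nodes_from(range(len(pts)))
    if len(pts) >= 2:
        tree = spatial.cKDTree(pts)
        for i, j in tree.query_pairs(cutoff):
            d = pts[j] - pts[i]
            for t in ts:
                if (np.linalg.norm(d - t) <= tolerance * np.linalg.norm(t)
                        or np.linalg.norm(d + t) <= tolerance * np.linalg.norm(t)):
                    g.add_edge(i, j)
                    break

    if field_nm is None and len(pts):
        mins = pts.min(axis=0)
        maxs = pts.max(axis=0)
    elif field_nm is not None:
        mins = np.zeros(2)
        maxs = np.asarray(field_nm, float)
    else:
        mins = maxs = np.zeros(2)
    margin = cutoff
    interior = np.array(
        [bool(np.all(p - mins >= margin) and np.all(maxs - p >= margin))
         for p in pts]
    )
    counts = np.array([g.degree(i) for i in range(len(pts))], dtype=int)
    return NeighborGraph(graph=g, interior=interior, link_counts=counts)


# ---------------------------------------------------------------------------
# fit-style wrapper
# ---------------------------------------------------------------------------

class LatticeModel:
    """Bravais-lattice model of a microvillar height map.

    Parameters
    ----------
    hm : HeightMap
        Raw or preprocessed topography.
    preprocess : bool
        Apply the standard correction chain before the spectral
        analysis (default True).
    annulus, threshold_factor, length_tolerance, angle_tolerance_deg :
        forwarded to the spectral fit.
    """

    def __init__(self, hm: HeightMap, preprocess: bool = True,
                 preprocess_params: PreprocessParams | None = None,
                 annulus: Tuple[float, float] = (0.002, 0.012),
                 threshold_factor: float = 10.0,
                 length_tolerance: float = 0.10,
                 angle_tolerance_deg: float = 8.0):
        self.hm = hm
        self.preprocess = preprocess
        self.preprocess_params = preprocess_params
        self.annulus = annulus
        self.threshold_factor = threshold_factor
        self.length_tolerance = length_tolerance
        self.angle_tolerance_deg = angle_tolerance_deg

    def fit(self) -> "LatticeResults":
        hm = self.hm
        if self.preprocess:
            hm = preprocess(hm, self.preprocess_params)
        fit = fit_lattice(hm, annulus=self.annulus,
                          threshold_factor=self.threshold_factor,
                          length_tolerance=self.length_tolerance,
                          angle_tolerance_deg=self.angle_tolerance_deg)
        return LatticeResults(self, hm, fit)


class LatticeResults:
    """Fitted lattice: estimates, uncertainty, and real-space checks."""

    def __init__(self, model: LatticeModel, preprocessed: HeightMap,
                 fit: LatticeFit):
        self.model = model
        self.preprocessed = preprocessed
        self.fit = fit

    @property
    def bravais_class(self) -> str:
        return self.fit.bravais_class

    @property
    def lattice_constant_nm(self) -> float:
        return self.fit.lattice_constant_nm

    @property
    def lattice_constant_sd_nm(self) -> float:
        return self.fit.lattice_constant_sd_nm

    @property
    def theta_deg(self) -> float:
        return self.fit.theta_deg

    def neighbor_links(self, positions_nm: np.ndarray,
                       tolerance: float = 0.2) -> NeighborGraph:
        h, w = self.preprocessed.field_size_nm
        return neighbor_links(positions_nm, self.fit, tolerance=tolerance,
                              field_nm=(w, h))

    def summary(self) -> str:
        f = self.fit
        l1, l2 = (f.lengths if f.bravais_class != "none" else (float("nan"),) * 2)
        lines = [
            "Microvillar lattice fit",
            "=" * 31,
            f"Bravais class        {f.bravais_class}",
            f"|a1|                 {l1:8.1f} nm",
            f"|a2|                 {l2:8.1f} nm",
            f"included angle       {f.theta_deg:8.1f} deg",
            f"lattice constant     {f.lattice_constant_nm:8.1f} "
            f"+/- {f.lattice_constant_sd_nm:.1f} nm",
            f"first-order peaks    {len(f.peaks):8d}",
        ]
        return "\n".join(lines)
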