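"""Synthetic AFM topographies of microvillated cell surfaces.

The generator emulates what an AFM sees when scanning the apical brush
border of an epithelial monolayer: a quasi-periodic field of finger-like
protrusions (microvilli) whose tips form a 2D point lattice.  Each image
comes with exact ground truth (tip positions, lattice parameters, true
density), which is what makes the generator usable as a benchmark for
the detection and lattice-analysis modules.

The forward model has four stages:

1. **positions** — a Bravais lattice (hexagonal, rhombic, square,
   rectangular, oblique), a clustered Matérn-like process, or complete
   spatial randomness; positional jitter and random vacancies model
   biological disorder;
2. **surface** — each microvillus is rendered as a hemispherically
   capped pillar ("spherical_cap") or a Gaussian bump; overlapping
   profiles combine by pointwise maximum, as an AFM tip would report;
3. **tip convolution** — grayscale dilation with an inverted spherical
   tip of radius ``R_tip``, the standard geometric model of finite-tip
   broadening;
4. **scan artifacts** — sample tilt, per-scan-line offsets, scars, and
   i.i.d. pixel noise, all seeded.

All randomness flows through explicit integer seeds; there is no hidden
global state.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import List, Optional, Sequence, Tuple

import numpy as np
import yaml
from scipy import ndimage

from .heightmap import HeightMap, write_heightmap

__all__ = [
    "LatticeSpec",
    "MicrovillusShape",
    "TipSpec",
    "ScanArtifactSpec",
    "SyntheticGroundTruth",
    "ideal_density_per_um2",
    "generate_positions",
    "render_surface",
    "tip_dilate",
    "add_artifacts",
    "generate_field",
    "generate_dataset",
]

LATTICE_CLASSES = (
    "hexagonal",
    "rhombic",
    "square",
    "rectangular",
    "oblique",
    "clustered",
    "random",
)


@dataclasses.dataclass(frozen=True)
class LatticeSpec:
    """Geometry of the generating point process.

    lattice_class : str
        One of hexagonal / rhombic / square / rectangular / oblique /
        clustered / random.
    a, b : float
        Primitive-vector lengths in nm (``b`` defaults to ``a``; it is
        only independent for rectangular/oblique).
    theta_deg : float
        Included angle between primitive vectors, degrees in (0, 180).
    jitter_nm : float
        Isotropic Gaussian positional jitter, 1 SD per axis.
    vacancy : float
        I.i.d. probability in [0, 1) that a lattice site is empty.
    rotation_deg : float or None
        Lattice orientation relative to the scan axes; ``None`` draws a
        uniform random orientation per field.
    cluster_mean_size, cluster_spacing_nm : parameters of the clustered
        (Matérn-like parent/daughter) class.
    """

    lattice_class: str = "hexagonal"
    a: float = 169.0
    b: Optional[float] = None
    theta_deg: Optional[float] = None
    jitter_nm: float = 5.0
    vacancy: float = 0.0
    rotation_deg: Optional[float] = None
    cluster_mean_size: float = 6.0
    cluster_spacing_nm: float = 120.0

    def __post_init__(self) -> None:
        if self.lattice_class not in LATTICE_CLASSES:
            raise ValueError(f"unknown lattice class {self.lattice_class!r}")
        if not self.a > 0:
            raise ValueError("lattice constant a must be > 0")
        if self.jitter_nm < 0:
            raise ValueError("jitter must be >= 0")
        if not (0 <= self.vacancy < 1):
            raise ValueError("vacancy fraction must lie in [0, 1)")
        b, theta = self._resolve_geometry()
        if not (0 < theta < 180):
            raise ValueError(f"theta must lie in (0, 180), got {theta}")
        # rhombic with theta = 60 or 90 is permitted at generation time:
        # it degenerates (site-for-site) to hexagonal / square

    def _resolve_geometry(self) -> Tuple[float, float]:
        """Effective (b, theta) after class constraints."""
        cls = self.lattice_class
        if cls == "hexagonal":
            return self.a, 60.0
        if cls == "square":
            return self.a, 90.0
        if cls == "rhombic":
            theta = 80.0 if self.theta_deg is None else float(self.theta_deg)
            return self.a, theta
        if cls == "rectangular":
            b = self.a if self.b is None else float(self.b)
            return b, 90.0
        b = self.a if self.b is None else float(self.b)
        theta = 80.0 if self.theta_deg is None else float(self.theta_deg)
        return b, theta

    @property
    def basis(self) -> np.ndarray:
        """Primitive vectors as rows, in nm, before field rotation."""
        b, theta = self._resolve_geometry()
        t = np.deg2rad(theta)
        return np.array([[self.a, 0.0], [b * np.cos(t), b * np.sin(t)]])


@dataclasses.dataclass(frozen=True)
class MicrovillusShape:
    """Rendered profile of a single microvillus.

    ``spherical_cap`` is a pillar of apex height ``h_mv`` topped by a
    hemisphere of radius ``R_mv`` (the standard cylinder-with-rounded-
    tip idealisation of a microvillus); ``gaussian_bump`` is an
    isotropic Gaussian of amplitude ``h_mv`` and sigma ``R_mv``.
    """

    kind: str = "spherical_cap"
    R_mv: float = 50.0
    h_mv: float = 100.0

    def __post_init__(self) -> None:
        if self.kind not in ("spherical_cap", "gaussian_bump"):
            raise ValueError(f"unknown profile kind {self.kind!r}")
        if not (self.R_mv > 0 and self.h_mv > 0):
            raise ValueError("R_mv and h_mv must be > 0")

    def profile(self, rho: np.ndarray) -> np.ndarray:
        """Height at lateral distance ``rho`` (nm) from the tip."""
        rho = np.asarray(rho, dtype=float)
        if self.kind == "gaussian_bump":
            return self.h_mv * np.exp(-0.5 * (rho / self.R_mv) ** 2)
        h = np.zeros_like(rho)
        inside = rho <= self.R_mv
        cap = self.h_mv - self.R_mv + np.sqrt(
            np.clip(self.R_mv**2 - rho[inside] ** 2, 0.0, None)
        )
        h[inside] = np.clip(cap, 0.0, None)
        return h

    @property
    def support_radius(self) -> float:
        """Lateral extent beyond which the profile is (numerically) zero."""
        if self.kind == "gaussian_bump":
            return 5.0 * self.R_mv
        return self.R_mv


@dataclasses.dataclass(frozen=True)
class TipSpec:
    """Geometric AFM tip: a sphere of radius ``R_tip`` nm (0 = ideal tip)."""

    R_tip: float = 30.0

    def __post_init__(self) -> None:
        if self.R_tip < 0:
            raise ValueError("R_tip must be >= 0")


@dataclasses.dataclass(frozen=True)
class ScanArtifactSpec:
    """Instrument artifacts added after tip convolution.

    Defaults keep scars within the geometry the preprocessing defaults
    can remove (width <= 4 px, length >= 16 px).
    """

    row_offset_sd_nm: float = 1.0
    tilt_nm_per_px: Tuple[float, float] = (0.0, 0.0)
    pixel_noise_sd_nm: float = 1.0
    scar_count: int = 0
    scar_width_px: int = 2
    scar_length_px: int = 30
    scar_amplitude_nm: float = 40.0

    def __post_init__(self) -> None:
        if self.row_offset_sd_nm < 0 or self.pixel_noise_sd_nm < 0:
            raise ValueError("artifact SDs must be >= 0")
        if self.scar_count < 0:
            raise ValueError("scar_count must be >= 0")


@dataclasses.dataclass(frozen=True)
class SyntheticGroundTruth:
    """Everything the generator knows about one simulated field."""

    positions_nm: np.ndarray  # (n, 2) array of (x, y) tip coordinates
    lattice: LatticeSpec
    shape: MicrovillusShape
    tip: TipSpec
    artifacts: Optional[ScanArtifactSpec]
    field_nm: Tuple[float, float]
    seed: int
    rotation_deg: float = 0.0

    @property
    def density_per_um2(self) -> float:
        w, h = self.field_nm
        return len(self.positions_nm) / (w * h * 1e-6)


def ideal_density_per_um2(spec: LatticeSpec) -> float:
    """Closed-form site density of the ideal (vacancy-free) lattice.

    One site per primitive cell: hexagonal 2/(sqrt(3) a²), otherwise
    1/(a b sin θ), in μm⁻².
    """
    basis = spec.basis
    cell_area_nm2 = abs(basis[0, 0] * basis[1, 1] - basis[0, 1] * basis[1, 0])
    return 1e6 / cell_area_nm2


# ---------------------------------------------------------------------------
# stage 1: positions
# ---------------------------------------------------------------------------

def _lattice_points(basis: np.ndarray, field: Tuple[float, float], origin: np.ndarray,
                    rot: float) -> np.ndarray:
    """All lattice points n·a1 + m·a2 (rotated, shifted) inside the field."""
    w, h = field
    c, s = np.cos(rot), np.sin(rot)
    R = np.array([[c, -s], [s, c]])
    rb = basis @ R.T
    # index range large enough to cover the field from any origin
    diag = np.hypot(w, h)
    amin = min(np.linalg.norm(rb[0]), np.linalg.norm(rb[1]))
    nmax = int(np.ceil(diag / amin)) + 2
    n, m = np.mgrid[-nmax : nmax + 1, -nmax : nmax + 1]
    pts = n.ravel()[:, None] * rb[0] + m.ravel()[:, None] * rb[1] + origin
    keep = (pts[:, 0] >= 0) & (pts[:, 0] < w) & (pts[:, 1] >= 0) & (pts[:, 1] < h)
    return pts[keep]


def _clustered_points(spec: LatticeSpec, field: Tuple[float, float],
                      rng: np.random.Generator) -> np.ndarray:
    """Matérn-like parent/daughter process (qualitative use only)."""
    w, h = field
    area_um2 = w * h * 1e-6
    n_parents = max(1, rng.poisson(2.0 * area_um2))
    parents = rng.uniform([0, 0], [w, h], size=(n_parents, 2))
    pts = []
    for p in parents:
        k = max(1, rng.poisson(spec.cluster_mean_size))
        ang = rng.uniform(0, 2 * np.pi, k)
        rad = spec.cluster_spacing_nm * np.sqrt(rng.uniform(0, 1, k))
        pts.append(p + np.column_stack([rad * np.cos(ang), rad * np.sin(ang)]))
    pts = np.concatenate(pts)
    keep = (pts[:, 0] >= 0) & (pts[:, 0] < w) & (pts[:, 1] >= 0) & (pts[:, 1] < h)
    return pts[keep]


def generate_positions(
    spec: LatticeSpec,
    field_nm: Tuple[float, float],
    seed: int,
    shape: MicrovillusShape | None = None,
    tip: TipSpec | None = None,
    artifacts: ScanArtifactSpec | None = None,
) -> SyntheticGroundTruth:
    """Draw microvillus tip positions for one field.

    ``field_nm`` is (width, height) in nm and must be at least 3 lattice
    constants on each side for periodic classes.  The same spec and seed
    always reproduce the same point set.
    """
    w, h = float(field_nm[0]), float(field_nm[1])
    if spec.lattice_class not in ("clustered", "random") and min(w, h) < 3 * spec.a:
        raise ValueError(f"field {field_nm} smaller than 3 lattice constants")
    rng = np.random.default_rng(seed)
    rotation = 0.0
    if spec.lattice_class == "random":
        density = ideal_density_per_um2(spec) * (1 - spec.vacancy)
        n = rng.poisson(density * w * h * 1e-6)
        pts = rng.uniform([0, 0], [w, h], size=(n, 2))
    elif spec.lattice_class == "clustered":
        pts = _clustered_points(spec, (w, h), rng)
    else:
        if spec.rotation_deg is None:
            rotation = float(rng.uniform(0.0, 60.0))
        else:
            rotation = float(spec.rotation_deg)
        origin = rng.uniform([0, 0], [w, h])
        pts = _lattice_points(spec.basis, (w, h), origin, np.deg2rad(rotation))
        if spec.vacancy > 0:
            pts = pts[rng.uniform(size=len(pts)) >= spec.vacancy]
        if spec.jitter_nm > 0:
            pts = pts + rng.normal(0.0, spec.jitter_nm, size=pts.shape)
            keep = (
                (pts[:, 0] >= 0) & (pts[:, 0] < w) & (pts[:, 1] >= 0) & (pts[:, 1] < h)
            )
            pts = pts[keep]
    return SyntheticGroundTruth(
        positions_nm=pts,
        lattice=spec,
        shape=shape or MicrovillusShape(),
        tip=tip or TipSpec(),
        artifacts=artifacts,
        field_nm=(w, h),
        seed=int(seed),
        rotation_deg=rotation,
    )


# ---------------------------------------------------------------------------
# stage 2: surface rendering
# ---------------------------------------------------------------------------

def render_surface(
    positions_nm: np.ndarray,
    shape: MicrovillusShape,
    pixel_size: float,
    field_nm: Tuple[float, float],
) -> HeightMap:
    """Render tip positions into a height map.

    ``height(x) = max_p profile(|x - p|)`` over all microvilli ``p``;
    the background is 0.  The pointwise max mirrors how an AFM probe
    reports the upper envelope of overlapping structures.
    """
    if pixel_size <= 0:
        raise ValueError("pixel_size must be > 0")
    w, h = field_nm
    cols = int(round(w / pixel_size))
    rows = int(round(h / pixel_size))
    z = np.zeros((rows, cols))
    sup = shape.support_radius
    rpix = int(np.ceil(sup / pixel_size)) + 1
    for x, y in np.asarray(positions_nm, dtype=float):
        cc = x / pixel_size
        rr = y / pixel_size
        c0, c1 = int(np.floor(cc)) - rpix, int(np.ceil(cc)) + rpix + 1
        r0, r1 = int(np.floor(rr)) - rpix, int(np.ceil(rr)) + rpix + 1
        c0, c1 = max(c0, 0), min(c1, cols)
        r0, r1 = max(r0, 0), min(r1, rows)
        if c0 >= c1 or r0 >= r1:
            continue
        jj, ii = np.meshgrid(np.arange(c0, c1), np.arange(r0, r1))
        rho = pixel_size * np.hypot(jj - cc, ii - rr)
        np.maximum(z[r0:r1, c0:c1], shape.profile(rho), out=z[r0:r1, c0:c1])
    return HeightMap(z, pixel_size, note="synthetic")


# ---------------------------------------------------------------------------
# stage 3: tip convolution
# ---------------------------------------------------------------------------

def tip_structure(tip: TipSpec, pixel_size: float) -> np.ndarray:
    """Non-flat structuring element of the spherical tip.

    ``t(u) = -(R_tip - sqrt(R_tip² - |u|²))`` on the disc |u| <= R_tip,
    sampled at pixel centres; a large negative value outside the disc
    excludes those offsets from the max.
    """
    r_px = int(np.floor(tip.R_tip / pixel_size))
    if r_px < 1:
        return np.zeros((1, 1))
    u = np.arange(-r_px, r_px + 1) * pixel_size
    uu, vv = np.meshgrid(u, u)
    d2 = uu**2 + vv**2
    t = np.full(d2.shape, -1e12)
    inside = d2 <= tip.R_tip**2
    t[inside] = -(tip.R_tip - np.sqrt(tip.R_tip**2 - d2[inside]))
    return t


def tip_dilate(hm: HeightMap, tip: TipSpec) -> HeightMap:
    """Geometric tip convolution as grayscale dilation.

    ``out(x) = max_{|u| <= R_tip} [in(x-u) + t(u)]`` with the inverted
    lower tip hemisphere ``t``.  The output is >= the input everywhere;
    ``R_tip = 0`` is the identity.
    """
    t = tip_structure(tip, hm.pixel_size)
    if t.shape == (1, 1):
        return hm.with_heights(hm.heights.copy())
    out = ndimage.grey_dilation(hm.heights, structure=t, mode="nearest")
    return hm.with_heights(out)


# ---------------------------------------------------------------------------
# stage 4: scan artifacts
# ---------------------------------------------------------------------------

def add_artifacts(hm: HeightMap, art: ScanArtifactSpec, seed: int) -> HeightMap:
    """Add tilt, per-row offsets, scars and pixel noise (in that order)."""
    rng = np.random.default_rng(seed)
    z = hm.heights.copy()
    rows, cols = z.shape
    a, b = art.tilt_nm_per_px
    if a != 0.0 or b != 0.0:
        yy, xx = np.mgrid[0:rows, 0:cols]
        z += a * xx + b * yy
    if art.row_offset_sd_nm > 0:
        z += rng.normal(0.0, art.row_offset_sd_nm, size=(rows, 1))
    for _ in range(art.scar_count):
        r = int(rng.integers(0, max(1, rows - art.scar_width_px)))
        c = int(rng.integers(0, max(1, cols - art.scar_length_px)))
        z[r : r + art.scar_width_px, c : c + art.scar_length_px] += art.scar_amplitude_nm
    if art.pixel_noise_sd_nm > 0:
        z += rng.normal(0.0, art.pixel_noise_sd_nm, size=z.shape)
    return hm.with_heights(z)


# ---------------------------------------------------------------------------
# full forward model
# ---------------------------------------------------------------------------

def generate_field(
    spec: LatticeSpec,
    field_nm: Tuple[float, float] = (2500.0, 2500.0),
    pixel_size: float = 7.0,
    seed: int = 0,
    shape: MicrovillusShape | None = None,
    tip: TipSpec | None = None,
    artifacts: ScanArtifactSpec | None = ScanArtifactSpec(),
) -> Tuple[HeightMap, SyntheticGroundTruth]:
    """Run all four stages and return (image, ground truth).

    Defaults reflect a high-resolution contact-mode scan: 7 nm/px over
    a 2.5 × 2.5 μm field with a 30 nm tip.
    """
    shape = shape or MicrovillusShape()
    tip = tip or TipSpec()
    gt = generate_positions(spec, field_nm, seed, shape=shape, tip=tip,
                            artifacts=artifacts)
    hm = render_surface(gt.positions_nm, shape, pixel_size, field_nm)
    hm = tip_dilate(hm, tip)
    if artifacts is not None:
        hm = add_artifacts(hm, artifacts, seed=seed + 1_000_003)
    return hm, gt


# ---------------------------------------------------------------------------
# dataset persistence
# ---------------------------------------------------------------------------

def _spec_to_dict(obj) -> dict:
    return dataclasses.asdict(obj) if obj is not None else None


def generate_dataset(config: dict, out_dir) -> List[Tuple[Path, Path]]:
    """Generate a batch of fields and persist images + ground truth.

    ``config`` mirrors the YAML simulation schema::

        seed: 7
        n_images: 3
        field_nm: [2500, 2500]
        pixel_size_nm: 7.0
        format: tiff            # or ascii_grid
        lattice: {lattice_class: hexagonal, a: 169.0, ...}
        shape:   {kind: spherical_cap, R_mv: 50.0, h_mv: 100.0}
        tip:     {R_tip: 30.0}
        artifacts: {row_offset_sd_nm: 1.0, ...}

    Writes one image (+ calibration sidecar) and one ground-truth CSV
    per field, plus a single config snapshot, and returns the list of
    (image_path, truth_path) pairs.  Deterministic under the seed.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seed = int(config.get("seed", 0))
    n_images = int(config.get("n_images", 1))
    field = tuple(config.get("field_nm", (2500.0, 2500.0)))
    px = float(config.get("pixel_size_nm", 7.0))
    fmt = config.get("format", "tiff")
    ext = ".tif" if fmt == "tiff" else ".txt"
    spec = LatticeSpec(**config.get("lattice", {}))
    shape = MicrovillusShape(**config.get("shape", {}))
    tip = TipSpec(**config.get("tip", {}))
    art_cfg = config.get("artifacts", {})
    artifacts = None if art_cfg is None else ScanArtifactSpec(**art_cfg)

    (out / "config.yaml").write_text(yaml.safe_dump(config), encoding="utf-8")
    pairs: List[Tuple[Path, Path]] = []
    for i in range(n_images):
        hm, gt = generate_field(
            spec, field, px, seed=seed + i, shape=shape, tip=tip, artifacts=artifacts
        )
        img_path = out / f"image_{i:03d}{ext}"
        write_heightmap(hm, img_path, format=fmt)
        truth_path = out / f"image_{i:03d}.truth.csv"
        header = json.dumps(
            {
                "lattice": _spec_to_dict(spec),
                "shape": _spec_to_dict(shape),
                "tip": _spec_to_dict(tip),
                "artifacts": _spec_to_dict(artifacts),
                "field_nm": list(gt.field_nm),
                "seed": gt.seed,
                "rotation_deg": gt.rotation_deg,
                "density_per_um2": gt.density_per_um2,
            }
        )
        with open(truth_path, "w", encoding="utf-8") as fh:
            fh.write(f"# {header}\n")
            fh.write("x_nm,y_nm\n")
            for x, y in gt.positions_nm:
                fh.write(f"{x:.6f},{y:.6f}\n")
        pairs.append((img_path, truth_path))
    return pairs


def read_ground_truth(path) -> Tuple[np.ndarray, dict]:
    """Read a ground-truth CSV back into (positions, metadata dict)."""
    path = Path(path)
    with open(path, encoding="utf-8") as fh:
        first = fh.readline()
    meta = json.loads(first.lstrip("# ").strip()) if first.startswith("#") else {}
    pts = np.loadtxt(path, delimiter=",", skiprows=2, ndmin=2)
    if pts.size == 0:
        pts = np.empty((0, 2))
    return pts, meta
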