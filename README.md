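# mvlattice

Quantification of microvillar surface lattices in AFM height maps.

Differentiated transport epithelia (and epithelial cell lines such as
Caco-2) cover their apical surface with a dense carpet of microvilli —
the brush border. Atomic force microscopy resolves the individual
microvilli as bumps in a calibrated height map, and their tip positions
turn out to be crystallographically ordered: densely packed regions
form a 2D **hexagonal** lattice, while regions at sub-maximal density
arrange on a **rhombic** lattice (equal primitive vectors, included
angle away from 60° and 90°). `mvlattice` is a pipeline for measuring
that order:

1. **Preprocessing** — per-scan-line offset alignment, least-squares
   plane leveling, and detection/interpolation of scan "scars"
   (deviant bands ≤ 4 px wide and ≥ 16 px long).
2. **Detection** — deterministic microvillus localisation (Gaussian
   smoothing → prominence-filtered local maxima → sub-pixel quadratic
   refinement) with per-object morphometrics: tip height, local
   deviational volume (LDV), and the radius-bound pair
   (*r*<sub>min</sub>, *r*<sub>max</sub>) measured on the angularly
   averaged radial profile *h*(ρ) — the inflection point
   (*h*″ = 0) and the maximum of the curvature
   κ = |*h*″| / (1 + *h*′²)<sup>3/2</sup>. The finite AFM tip makes the
   true radius unobservable; the pair brackets it.
3. **Lattice analysis** — Hann-windowed 2D power spectrum; sub-pixel
   first-order peak detection; inversion of two reciprocal peaks
   **b**₁, **b**₂ to the real-space basis via
   **a**ᵢ·**b**ⱼ = δᵢⱼ; Bravais classification of
   (|**a**₁|, |**a**₂|, θ); and a real-space check counting
   nearest-neighbor tip links (coordination 6 on hexagonal, 4 on
   rhombic fields).
4. **Morphometry** — densities, population statistics, and the derived
   arithmetic: mean diameter from the doubled radius bounds and the
   smallest intermicrovillar surface-to-surface distance
   (lattice constant − diameter), with SDs propagated in quadrature and
   everything rounded by a significant-figure convention (SD to one
   significant figure, central value half-up to the SD's decimal
   place).
5. **Synthetic AFM generator** — because raw scans of this kind are
   rarely shared, the package ships a forward model with exact ground
   truth: Bravais/clustered/random point processes with jitter and
   vacancies, microvilli rendered as hemispherically capped pillars,
   geometric tip convolution (grayscale dilation with an inverted
   spherical tip), and seeded scan artifacts (tilt, row offsets, scars,
   pixel noise).

The lattice estimator is exposed statsmodels-style:

```python
import mvlattice as mv

hm, truth = mv.generate_field(mv.LatticeSpec("hexagonal", a=169.0), seed=3)
res = mv.LatticeModel(hm).fit()
print(res.summary())
```

```
Microvillar lattice fit
===============================
Bravais class        hexagonal
|a1|                    169.9 nm
|a2|                    170.3 nm
included angle           59.3 deg
lattice constant        170.1 +/- 10.6 nm
first-order peaks           2
```

## Worked example

The shipped demo config simulates three hexagonal brush-border fields
(lattice constant 169 nm, 13 % vacancies, 5 nm jitter, 30 nm tip,
7 nm/px, 2.5 × 2.5 μm) and analyzes them end to end:

```bash
mvlattice full --config configs/demo.yaml --out run_demo --seed 7
```

`run_demo/results.csv` (one row per image, the pipeline's canonical
four columns):

```
lattice_type,lattice_constant_um,image_id,counts_per_roi_um2
hexagonal,0.16854027943934086,image_000,35.06804882817473
hexagonal,0.16887234340199322,image_001,35.22817690501571
hexagonal,0.16841183545104269,image_002,36.02881728922061
```

`run_demo/summary.csv` (cross-image mean ± SD per lattice class):

```
lattice_type,n_images,density_mean,density_sd,constant_nm_mean,constant_nm_sd
hexagonal,3,35.44168100747035,0.5147397500279527,168.6081527641256,0.23763834788426727
```

All three fields are classified hexagonal; the recovered lattice
constant (168.6 ± 0.2 nm) matches the generating 169 nm, and the
detected density (35.4 ± 0.5 μm⁻²) matches the ground-truth site
density of an ideal 169 nm hexagonal lattice (40.4 μm⁻²) thinned by
13 % vacancies (≈ 35.2 μm⁻²). Each run directory also contains
per-image detection tables, a structured log, and the exact config
snapshot; reruns with the same config and seed are bit-identical.

Height maps are float32 TIFF or plain-text grids, each with a small
YAML sidecar carrying the calibration (`pixel_size_nm`, `z_units`).

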