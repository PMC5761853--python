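# Methods

This note records the models, conventions, and design choices behind
`mvlattice`, and what the synthetic benchmark does and does not show
about real AFM data.

## The measurement problem

An AFM height map of a brush border is a calibrated grid *z*(x, y) in
nm, sampled isotropically (nm/px). Three instrument effects stand
between the raw scan and the biology: every scan line carries its own
height offset, the whole field is tilted, and occasional feedback
glitches produce "scars" — bands a few lines thick that are offset from
their surroundings. On top of that, the finite tip radius broadens
every feature (tip convolution), which makes the true microvillar
radius unobservable and motivates the radius-bound model below.

## Preprocessing chain

Order: row alignment → plane leveling → scar removal. The Hann taper is
applied only inside the spectral analysis.

**Row alignment.** Two estimators are provided. `align_rows_median`
subtracts each line's median (every output row has median exactly 0).
On surfaces densely covered by relief, however, per-line medians track
the structure itself: on a periodic bump field, lines through crest
rows have systematically higher medians than lines between them, and
subtracting them imprints a lattice-phase stripe pattern strong enough
to suppress real maxima (we measured apex losses of ~60 nm on default
synthetic fields). The default chain therefore uses
`align_rows_diffmedian`: the offset increment of line *i* is the median
over columns of *z*[i] − *z*[i−1], and the cumulative increments are
subtracted. This estimator responds only to jumps coherent along a
whole line, is exact for pure per-line offsets, and passes periodic
relief through unchanged. Its one weakness — a slow random-walk drift
when line-to-line differences are noise-dominated — is low-frequency
and absorbed by the plane fit and the spectral annulus.

**Plane leveling** subtracts the least-squares plane; idempotent by
construction.

**Scar removal.** The admissible geometry is fixed (width ≤ 4 px,
length ≥ 16 px); the detection rule is ours. For every candidate width
*w* ≤ 4 and start line, the band of *w* lines is compared with the mean
of the two lines bracketing it. A column is a candidate when all band
lines deviate from the reference with the same sign by more than 5× the
robust sigma (1.4826 × MAD of the lag-1 line differences), and the two
reference lines agree with each other within the same threshold (a
reference that disagrees is itself inside a wider scar, or on steep
relief). Candidate columns are grouped into runs; a run is accepted as
a scar only if it is ≥ 16 px long and its deviation is offset-like
rather than relief-like (scatter along the run ≤ half its mean
magnitude — a microvillus rim crossing the band produces a strongly
varying deviation and is left alone). Accepted pixels are replaced by
linear interpolation along columns from the nearest clean lines; all
other pixels are returned bit-identical. Bands touching the image
border have no clean reference on one side and are deliberately left
alone.

## Synthetic AFM forward model

The generator stands in for raw scans and defines the benchmark
conditions. Defaults describe a high-resolution contact-mode scan of a
differentiated brush border:

| parameter | default | rationale |
|---|---|---|
| field | 2.5 × 2.5 μm | typical high-resolution scan window |
| pixel size | 7 nm/px | high-resolution contact-mode sampling; AC-mode (2.6 nm/px) available by config |
| lattice constant | 169 nm (hexagonal), 185 nm (rhombic, θ = 80°) | class-typical spacings of microvillar lattices |
| jitter σ | 5 nm/axis | biological positional disorder ~3 % of the spacing |
| microvillus | capped pillar, R = 50 nm, h = 100 nm | tip radius chosen between the radius bounds that the detector reports (18–63 nm); the apparent diameter after tip dilation lands in the 36–130 nm bound window |
| tip radius | 30 nm | standard soft-cantilever tip |
| row offset / pixel noise | 1 nm / 1 nm SD | z-noise of a well-tuned instrument in fluid |
| scars | off by default; when enabled, ≤ 4 px × ≥ 30 px, +40 nm | within the geometry the preprocessing removes |

The rhombic angle is a modelling choice: rhombic lattices are defined
by equal primitive vectors with θ ∉ {60°, 90°}, and θ = 80° produces a
clearly non-hexagonal, non-square pattern whose site density at 2 %
vacancies is ≈ 29 μm⁻², the density regime where rhombic order is
observed. Each field gets a random lattice orientation and origin
unless pinned, so spectral estimates are exercised off the FFT grid
axes.

Rendering takes the pointwise **maximum** of the per-microvillus
profiles (an AFM probe reports the upper envelope). The
`spherical_cap` profile is a pillar of apex height *h* topped by a
hemisphere of radius *R* — the standard cylinder-with-rounded-tip
idealisation; `gaussian_bump` is provided for analytic checks. Tip
convolution is grayscale dilation with the inverted lower hemisphere
t(u) = −(R_tip − √(R_tip² − |u|²)), the exact geometric contact model
for a spherical tip; near an apex it reproduces the sphere-on-sphere
closed form (dilated radius R + R_tip), which the tests verify against
a brute-force max-over-footprint oracle.

**What the generator does not emulate:** cell-body curvature and
cell–cell junction ridges, cantilever dynamics and feedback transients,
tip wear/asymmetry, and the coupling between scan speed, scan size and
noise. Consequences are noted where they matter (resolution property
below). Passing benchmarks on this model shows the *analysis* is
correct under realistic geometry and artifacts, not that any particular
biological sample is well described by it.

## Detection and radius bounds

Detection: Gaussian smoothing (default 14 nm — about half the tip
radius; dilated apexes are nearly flat, so smaller scales make
sub-pixel localisation needlessly noise-sensitive), local maxima with a
minimum separation (default 80 nm, safely below both lattice
constants), prominence over the local median background (default
20 nm), then separable 3-point quadratic refinement. On default
synthetic fields, matched recall and precision against ground truth
exceed 0.95 at a 30 nm matching radius; residual misses concentrate at
tips within ~80 nm of the field border, where caps are truncated.

Radial profiles average bilinear-interpolated heights over 24 rays at
2 nm steps out to 150 nm. The profile is lightly smoothed (Gaussian,
2 steps) before differencing; *r*<sub>min</sub> is the first
significant zero crossing of *h*″ (sub-sample by linear interpolation),
*r*<sub>max</sub> the curvature maximum beyond it. Two guards keep the
estimator honest on degenerate profiles: a significance floor of 1 %
of max |*h*″| (numerically flat profiles such as linear ramps report
"no inflection" instead of rounding noise), and exclusion of four
smoothing lengths at each end of the profile, where the smoothing
kernel's own boundary curvature lives. Angular averaging (rather than
single scan-line profiles) is a choice; it roughly halves profile noise
at the cost of mixing in anisotropic neighbours.

LDV sums height above the local baseline (median on the annulus
[r_max, 1.5 r_max]) over the tip disc. Objects whose annulus leaves the
image are flagged `edge` and excluded from shape statistics. Density,
by contrast, counts **all** detected tips (n / ROI area): excluding
edge objects while dividing by the full area would bias density down by
~10 % at these field sizes, which is larger than the seed-to-seed
scatter of the estimate.

## Spectral lattice estimation

The power spectrum is |FFT| of the mean-subtracted, Hann-windowed
square map, with axes in cycles/nm (no 2π anywhere; the inversion is
**a**ᵢ·**b**ⱼ = δᵢⱼ, i.e. A = (Bᵀ)⁻¹ for 2×2 row-vector matrices).
Peaks are local maxima inside a frequency annulus (default
0.002–0.012 cycles/nm, i.e. periods 83–500 nm) exceeding 10× the
annulus median, refined to sub-pixel by separable quadratic fits and
merged with their centro-symmetric partners. The first-order ring is
anchored at the *strongest* peak's radius (±25 %): harmonics and
combination peaks lie farther out, and — importantly on vacancy-
disordered fields — diffuse low-frequency clutter lies farther in and
can rival genuine peaks in magnitude. The basis is the two strongest
non-collinear ring peaks; on hexagonal fields any two of the three
first-order pairs give the same lattice (property-tested). The manual
profile-line mode restricts peaks to a user-drawn reciprocal-space
segment.

Classification normalises θ into (0°, 90°] and is invariant to swapping
or sign-flipping the basis: equal lengths (10 % tolerance) with
θ within 8° of 60° → hexagonal, of 90° → square, otherwise rhombic;
unequal lengths with θ ≈ 90° → rectangular, else oblique. The
tolerances separate 60° from observed rhombic angles while absorbing
jitter-induced scatter, and are exposed in config. The per-image
lattice-constant uncertainty is the quadratic peak half-width
propagated through the inversion (δa/a = δ|b|/|b|); cross-image SDs
are computed by the pipeline layer.

Nearest-neighbor links connect detections whose displacement matches
±**a**₁, ±**a**₂ (hexagonal: also ±(**a**₁−**a**₂)) within 20 %.
Interior nodes (further than one link length + tolerance from the
border) carry coordination 6 on hexagonal and 4 on rhombic fields; on
rhombic lattices |**a**₁−**a**₂| = 2a·sin(θ/2) ≈ 1.29a lies outside
the matching band, which is why only four links survive.

**Resolution property.** Coarsening the sampling weakens the spectral
contrast of the lattice (measured SNR at 18–22 nm/px is clearly below
7 nm/px), and the detector warns above 15 nm/px. A strict monotone SNR
decline that crosses the peak-detection threshold just beyond 15 nm/px
is *not* reproduced by pure resampling: at these spacings even
22 nm/px leaves the period well sampled, and the diffuse background
scales with the signal. In real instruments the cutoff arises from
noise growing with scan speed/size — physics outside this forward
model, so the suite asserts the coarse-vs-fine degradation and the
warning behaviour, not an absolute cutoff.

## Error propagation and rounding

All derived quantities use one convention, chosen because it is the
only simple rule consistent with the full chain of printed-style
values (36, 130, 80, 90, 110 from bounds 18 ± 2 and 63 ± 5 and
constants 169 and 185): the SD is rounded to **one significant
figure**, and the central value is rounded **half-up** to the same
decimal place (105 → 110 at the tens digit; banker's rounding would
give 100). The diameter is the midpoint of the doubled, individually
rounded bounds; its SD is reported as the larger of half the bound
range and the quadrature of the bound SDs — an explicit convention,
since no standard propagation rule reproduces a unique value for a
quantity defined by an interval. The smallest intermicrovillar
distance is constant − diameter with quadrature SDs; negative values
are allowed but flagged.

Statistical comparison between lattice classes is a plain two-sample
Student's t on per-image densities; nothing more is implied.

## Benchmark problem sizes

The test suite and the acceptance script simulate 2.5 × 2.5 μm fields
at 7 nm/px (357² px): 10 seeds per class for lattice-constant
recovery, 4–6 seeds per class for density recovery, one field per
class for coordination counts. These sizes put the sampling error of
each mean well below the tolerances being checked while keeping a full
run in tens of seconds on one CPU.

## Known limitations

- The detector is a transparent stand-in for proprietary
  trained-classifier detection; it assumes bump-like, convex objects
  and will not separate merged microvilli closer than the minimum
  separation.
- Scar detection assumes scars are offset-like along their run; a scar
  crossing strong relief diagonally would be missed (and a genuinely
  line-aligned biological structure of exactly scar geometry would be
  removed).
- The rhombic/oblique boundary is tolerance-defined; lattices with
  θ within 8° of 60° or 90° are absorbed into the symmetric classes.
- Density recovery inherits detector edge behaviour; fields smaller
  than ~10 lattice constants make edge effects dominant.
- The clustered point process is qualitative only; no quantitative
  claims are attached to it.
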