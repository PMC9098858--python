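# Methods

This note documents the models, conventions, numerical choices and known
limitations behind `lsfmrecon`. It is written for someone who wants to
trust (or challenge) the pipeline's numbers, not just run it.

## Coordinate conventions and acquisition geometry

The sample frame is `(Z, Y, X)`: Z is slab depth (0 at the illuminated
face), Y the transversal axis along which tile rows are laid out, X the
stage-motion axis. Raw tiles live on the objective-frame lattice
`(k, v, u)`: k counts frames along the stage sweep, v is the camera row
(mapping to Y), u the camera column, which the 45° objective tilt shears
into both Z and X. The forward map is the affine

    Z = u · p_u · sin θ
    Y = y₀ + v · p_v
    X = x₀ + s · (k · Δ + u · p_u · cos θ)

with pixel pitch `p = (0.55, 0.55) µm`, frame spacing `Δ = 3.3 µm`, tilt
`θ = 45°` and `s = ±1` the row's stage direction (alternating when the
snake pattern is enabled). Increasing u maps to increasing Z; the
simulator and reslicer share this sign convention through one code path
(`geometry.lattice_to_sample_affine`), which is what makes the round-trip
tests meaningful. Reverse-swept rows are handled by the sign inside the
affine rather than by flipping arrays afterwards; every resliced tile
comes out in the common +X orientation.

Reslicing composes this map with the `1/out_voxel` scaling in a single
4×4 matrix, so resampling and downsampling happen in one interpolation
pass. `out_voxel = p_u · downsample`; the default downsample 6 gives
`0.55 × 6 = 3.3 µm`, equal to the frame spacing, hence an exactly
isotropic output grid. 0.55 µm is used as the canonical raw pitch
throughout. Frame spacing is interpreted as the step along the stage (X)
axis.

## Phantom model

The synthetic slab emulates a cleared, antibody-stained cortex slice:

- **Staining compartment**: spherical somata (default radius 5 µm,
  amplitude 10 000 counts), tubular dendrites (radius 1 µm, rendered as
  soft-edged capsules along persistent random-walk polylines), and an
  optional homogeneous "neuropil" stain. All staining is modulated by the
  depth-penetration profile
  `D(z) = exp(−z/λ) + exp(−(T−z)/λ) + A·[g(z−z_r) + g(T−z−z_r)]`,
  i.e. exponential decay of antibody concentration from each face of a
  slab of thickness T (default 500 µm, λ = 150 µm) plus an optional
  Gaussian rim peak at depth z_r (default 50 µm) modeling superficial
  probe accumulation.
- **Autofluorescence compartment**: a uniform background plus punctate
  lipofuscin-like Gaussians (σ = 1 µm), not modulated by depth. Punctum
  density and amplitude are free parameters — no quantitative
  autofluorescence spectrum is asserted.
- **Edges**: objects have erf-smoothed edges (default σ = 2 µm) so the
  phantom is approximately band-limited at the 3.3 µm reconstruction
  scale; interpolation-error bounds in the tests assume this smoothness.

The acquisition simulator samples the phantom by trilinear interpolation
at the inverse image of the reslice affine (zero outside the slab),
multiplies by a per-tile illumination profile over the transversal camera
axis v (sinusoid or polynomial descriptor), applies Poisson shot noise
with gain g (counts = g·Poisson(I/g), so Var ≈ g·mean) and Gaussian read
noise, and casts to uint16. Per-row stage origins receive an optional
uniform jitter; the true origins and pairwise offsets are recorded in the
ground-truth record, which is what offset-recovery tests compare against.
Identical `(spec, geometry, seed)` triples reproduce bit-identical tiles
(per-row generators are spawned from one seed sequence).

What the phantom does **not** model: the optical PSF, light scattering and
absorption, refractive-index inhomogeneity, stripe artifacts, chromatic
shifts, or realistic lipofuscin spectra. Passing tests therefore certify
the *geometry and statistics* of the reconstruction chain, not robustness
to every optical artifact of real tissue.

## Reslicing

Output voxels are computed by inverting the single affine and trilinearly
interpolating the tile (nearest-neighbour optional). Coordinates within
1e-6 of the lattice boundary are snapped onto it (scipy's constant-mode
interpolation would otherwise zero them); voxels outside the lattice's
convex hull are zero and flagged in a validity mask. An anti-alias
Gaussian (σ = 0.5·downsample raw px on the two camera axes, never on the
frame axis, never for nearest-neighbour) precedes the resampling; it is
the one deliberate deviation from pure single-pass resampling and is
switchable off. A brute-force per-voxel resampler in the test suite pins
the implementation: bit-identical for nearest, ≤1e-6 relative for
trilinear.

One stated property of nearest-neighbour reslicing deserves a caveat: a
single bright voxel cannot in general map to *exactly one* output voxel,
because the tilted u axis advances Z in sub-voxel steps (`p·sinθ <
p·downsample`) for any tilt in (0°, 90°); depending on phase it lights up
0 or ≥2 output voxels. The test asserts the exact brute-force prediction
instead of a count of one.

## Stitching

Offsets between Y-adjacent resliced tiles are estimated on the nominal
overlap region (rejected below 8 voxels per axis): phase correlation
proposes an integer shift, clamped to the search radius (default
(2, 5, 5) voxels), and a ±1 exhaustive local search maximizes normalized
cross-correlation, whose peak value (clipped to [0, 1]) is the acceptance
score. Offsets are integer-voxel only — at 3.3 µm isotropic scale
subvoxel refinement would not move any downstream metric. Scores below
0.3 fall back to the nominal layout offset (uncorrelated noise pairs stay
below 0.1 in the empirical null over 100 seeds, so 0.3 separates cleanly).
Global positions solve an anchored least-squares problem on the
displacement graph, per connected component, in correction space relative
to the nominal layout; orphan tiles keep nominal positions. Fusion uses
linear-ramp weights along Y (each tile weighted by its distance to the
nearer Y edge, normalized to sum to 1 wherever any tile is valid), which
keeps seams continuous for the flat-field stage; a voxelwise `max` blend
is available for visualization.

## Flat-field homogenization

Per wavelength, the Y illumination profile is the mean over all non-Y
axes, smoothed by a centered moving average with reflective boundaries
(default window 5% of the Y extent, odd-rounded; a window spanning the
whole axis degenerates to the global mean), clamped below at 1e-3 of its
mean, and divided out as `out = in · mean(P)/P(y)`. The model is
multiplicative, matching how laser-power variation enters fluorescence
images. The correction preserves the global mean to <0.5% and is
idempotent to <0.5% RMS at the default smoothing. It is computed on the
fused volume (or its maximum-intensity projection) rather than per tile.

## Quantification

- **AF ROI statistics**: rectangular ROIs (default 20 ROIs of
  20 × 500 µm²) placed by seeded rejection sampling, non-overlapping,
  inside an optional region mask; per-ROI means with group mean ± SD. The
  seed is recorded in the report.
- **Mann–Whitney**: U from midrank sums. For n₁+n₂ ≤ 12 without ties the
  two-sided p is exact by full enumeration of rank assignments; otherwise
  the tie-corrected normal approximation with continuity correction
  (scipy). Identical constant samples return p = 1. Significance stars at
  α ∈ {0.05, 0.01, 0.001, 0.0001}, no multiple-testing correction (by
  design — fidelity to the source workflow; add your own correction when
  testing many hypotheses). Note the exact-vs-asymptotic agreement at
  n₁ = n₂ = 6 is 0.0155 worst-case (mid-range p); in the p < 0.1 tail it
  is < 0.006.
- **Depth profiles**: per-z mean ± SD over the union of ROI columns,
  optionally restricted by a validity mask; z oriented from the
  illuminated face. Penetration depth λ is fitted by bounded nonlinear
  least squares to `a·[exp(−z/λ) + exp(−(T−z)/λ)] + c` (both faces), a
  single-face variant, or a rim-augmented model. Recovery bias at the
  500 µm / λ = 150 µm / SNR 5 condition is ≈0.1% over 20 seeds.
- **S/B and SNR**: S/B is the ratio of ROI means. SNR is defined as
  `(µ_signal − µ_background)/σ_background` with the background statistic
  pooled globally over the background ROIs — the field never states a
  single convention, so this contrast-to-noise form is adopted and
  documented here.
- **SSIM**: uniform 8×8 sliding window over fully-contained patches,
  `C1 = (0.01·L)²`, `C2 = (0.03·L)²`, L from the input dtype (65535 for
  16-bit) unless overridden. `deformation_index` adds the preprocessing
  contract for small neuron crops: ×4 bilinear upscale when a side is
  below 256 px. Even-window SSIM is not available in scikit-image, which
  is why the core is implemented here; skimage serves as an odd-window
  cross-check in the tests.
- **Tortuosity**: polyline arc length over endpoint distance; undefined
  (error) for coincident endpoints.
- **Signal retention**: `100·(1 − S/B_t1 / S/B_t0)` per channel.
- **Shrinkage**: mask area ratio after/before in physical µm², so masks
  at different resolutions compare correctly.

## Pipeline, determinism, problem sizes

`run_pipeline` executes simulate → reslice → stitch → flatfield →
quantify from one strictly-validated config (unknown keys rejected);
stage failures abort with the stage name. Each stage logs parameters and
a content hash (SHA-256 of the output quantized at 1e-6 of its peak, so
digests are stable against sub-tolerance floating-point drift) to a
JSON-lines run log; a rerun with the same config reproduces identical
hashes.

The desk-scale defaults stand in for the production geometry: 256 × 128 px
field of view (production: 2048 × 2048), two tile rows at 20% overlap, a
50 µm slab with λ = 15 µm (the 500 µm / λ ≈ 150 µm condition scaled
proportionally), phantom rendered at ~1 µm voxels. A 256-px transversal
FOV is the smallest that leaves ≥8 resliced voxels of overlap at
downsample 6 (128 px would leave only ~4, below the registration
minimum). The pipeline's penetration-λ summary is computed on the slab
footprint only, excluding z planes with <50% valid coverage and one plane
at each face (resampling mixes zero padding into face planes); with the
default sparse-soma phantom this summary still scatters strongly across
seeds — sparse 10 000-count somata on 13 z samples dominate the profile —
whereas a uniform-stain phantom recovers λ through the full pipeline to
<1%.

JPEG2000 tile I/O is lossless by default (verified bit-identical round
trips for 16-bit frames); lossy compression exists only behind an
explicit ratio parameter and is never used by the quantification path.

## Known limitations

- No non-rigid alignment between consecutive slabs; no X-adjacent
  registration within a row (rows are treated as contiguous sweeps).
- No destriping, PSF deconvolution, or chromatic-shift correction.
- The 405 nm inner-filter attenuation is out of scope; flat-field
  correction addresses only the transversal illumination profile.
- Phantom realism is geometric/statistical, not optical (see above);
  absolute autofluorescence levels are free parameters.
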