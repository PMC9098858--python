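# lsfmrecon

Volumetric reconstruction and tissue-quality quantification for oblique
light-sheet fluorescence microscopy (LSFM) of cleared, immunostained human
brain slabs.

Large cleared slices (≈500 µm thick, centimeters across) are imaged by an
inverted light-sheet microscope whose objectives are tilted 45° to the
sample holder: the camera records stacks in a sheared *objective reference
frame* (pixel pitch 0.55 × 0.55 µm, stage step 3.3 µm per frame) while the
stage translates the sample in a snake-like pattern of overlapping tile
rows. Turning those raw tiles into an analysis-ready volume — and judging
the quality of the clearing and staining — requires a chain of
computations that this package implements as a tested, reusable library:

1. **phantom** — a synthetic slab generator (somata, dendrites,
   lipofuscin-like puncta, depth-dependent antibody penetration,
   illumination inhomogeneity, Poisson–Gaussian camera noise) plus a
   forward model of the tilted, tiled acquisition. Every stage downstream
   is testable against its ground truth without any real data.
2. **reslice** — one affine resampling per tile that converts the tilted
   lattice `(frame k, row v, col u)` to the sample frame `(Z, Y, X)` and
   applies the downsampling factor in the same matrix:
   `Z = u·p·sinθ`, `Y = v·p`, `X = x₀ + s·(k·Δ + u·p·cosθ)`
   with pitch `p = 0.55 µm`, stage step `Δ = 3.3 µm`, tilt `θ = 45°` and
   row direction `s = ±1`. With downsample 6 the output grid is exactly
   isotropic at **3.3 µm**.
3. **stitch** — phase-correlation offset estimation between Y-adjacent
   resliced tiles, least-squares global placement on the displacement
   graph, and linear-ramp fusion.
4. **flatfield** — per-wavelength illumination homogenization: average the
   volume along X, smooth the resulting Y profile, divide it out.
5. **quantify** — autofluorescence ROI statistics with Mann–Whitney
   rank-sum tests, antibody depth-penetration profiles and exponential-λ
   fits, S/B, SNR = (µ_signal − µ_background)/σ_background, the SSIM
   structural-deformation index, dendrite tortuosity (arc/chord),
   multi-round signal retention, and clearing shrinkage ratios.
6. **io / CLI** — TIFF / lossless JPEG2000 / zarr tile I/O with YAML
   layout sidecars, a strictly validated pipeline config, JSON-lines run
   logs with content hashes, and the `lsfmrecon` command.

## Worked example

Simulate a two-row acquisition of a uniformly stained 50 µm slab with a
15 µm penetration depth and a 30% illumination gradient, then reconstruct
and quantify it end to end:

```yaml
# demo.yaml
seed: 4
phantom:
  n_somata: 0
  n_dendrites: 0
  n_puncta: 0
  neuropil_amp: 1000.0
  illum_amplitude: 0.3
```

```sh
lsfmrecon run --config demo.yaml --outdir out/
```

prints

```json
{
 "penetration_lambda_um": 14.994293747657478,
 "af_mean": 207.5694209123782,
 "phantom": "50db7e9a7e873ac303bc9d66ac40ef56a504ca4fdcd99f88e14d2ffd43760859",
 "tiles": "b1160318db309b143b133a4ec8e1b371cbf5d8e651854508a18b58bd7ba07c91",
 "resliced": "cae9ea36379c08fe7480a3e6abea88df702098d36d166875b712346dbf09ee77",
 "fused": "5a970902f4e17cdb513f435af843a44b1a07e0395ff2804d66cac09e2db80e1e",
 "corrected": "81922b14211ddc5a0bd19c2ba2e9c2869b44d09dac945a8d6f2d84fcc347e4bf"
}
```

The fitted penetration depth (14.99 µm) recovers the generating value
(15 µm) to 0.04% after the full simulate → reslice → stitch → flatfield
chain; `af_mean` is the mean intensity over randomly placed
autofluorescence ROIs; the hashes are quantized content digests that make
reruns verifiable (`out/run_log.jsonl` records per-stage parameters and
timings, `out/offsets.csv` the estimated tile displacement — here
`(0, 32, -16)` voxels with correlation score 0.84).

Each stage is also exposed separately (`lsfmrecon simulate | reslice |
stitch | flatfield | quantify`) and as plain library calls:

```python
from lsfmrecon import ResliceParams, voxel_pitch_um
voxel_pitch_um(ResliceParams())   # array([3.3, 3.3, 3.3]) µm
```

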