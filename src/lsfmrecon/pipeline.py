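"""Pipeline driver: simulate/ingest → reslice → stitch → flatfield → quantify.

Configuration is a strictly validated schema (unknown keys rejected) that
serializes round-trip through YAML; every stage logs its parameters and the
content hash of its output to a JSON-lines run log, so a rerun with the same
config and seeds reproduces identical hashes.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Optional

import numpy as np
import yaml
from pydantic import BaseModel, ConfigDict

from . import io as lio
from .flatfield import apply_correction, compute_profile, default_window
from .geometry import AcquisitionGeometry
from .phantom import PhantomSpec, PhantomTruth, make_phantom, simulate_acquisition
from .quantify import ROI, QuantReport, af_roi_stats, depth_profile, fit_penetration_depth
from .reslice import ResliceParams, apply_reslice
from .stitch import PairOffset, TileLayout, estimate_pairwise_offset, fuse, globally_place
from .volume import SampleVolume, content_hash

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline"]

log = logging.getLogger("lsfmrecon")


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class PhantomBlock(_Strict):
    slab_size_um: tuple[float, float, float] = (50.0, 240.0, 110.0)
    voxel_um: float = 1.0
    n_somata: int = 12
    soma_radius_um: float = 5.0
    n_dendrites: int = 3
    dendrite_radius_um: float = 1.0
    dendrite_length_um: float = 50.0
    n_puncta: int = 15
    # desk-scale default: the 50 µm slab stand-in scales the 500 µm slab's
    # ~150 µm penetration depth proportionally
    penetration_depth_um: float = 15.0
    rim_peak_amp: float = 0.0
    rim_peak_depth_um: float = 50.0
    rim_peak_sigma_um: float = 15.0
    soma_amp: float = 10000.0
    dendrite_amp: float = 6000.0
    puncta_amp: float = 3000.0
    # homogeneous neuropil stain makes the depth-penetration profile
    # identifiable on a sparse desk-scale phantom
    neuropil_amp: float = 800.0
    background: float = 300.0
    edge_sigma_um: float = 2.0
    illum_amplitude: float = 0.0
    illum_cycles: float = 1.0
    noise_gain: float = 0.0
    read_noise_sd: float = 0.0

    def to_spec(self, seed: int) -> PhantomSpec:
        d = self.model_dump()
        amp = d.pop("illum_amplitude")
        cyc = d.pop("illum_cycles")
        return PhantomSpec(
            illum_profile={"kind": "sinusoid", "amplitude": amp, "cycles": cyc, "phase": 0.0},
            seed=seed,
            **d,
        )


class GeometryBlock(_Strict):
    pixel_pitch_um: tuple[float, float] = (0.55, 0.55)
    frame_spacing_um: float = 3.3
    tilt_deg: float = 45.0
    fov_px: tuple[int, int] = (256, 128)
    tile_overlap_frac: float = 0.2
    n_rows: int = 2
    snake: bool = True
    stage_jitter_um: float = 0.0

    def to_geometry(self) -> AcquisitionGeometry:
        d = self.model_dump()
        d["pixel_pitch_um"] = tuple(d["pixel_pitch_um"])
        d["fov_px"] = tuple(d["fov_px"])
        return AcquisitionGeometry(**d)


class ResliceBlock(_Strict):
    downsample: int = 6
    interpolation: Literal["nearest", "trilinear"] = "trilinear"
    antialias: bool = True


class StitchBlock(_Strict):
    enabled: bool = True
    search_radius_vox: tuple[int, int, int] = (2, 5, 5)
    score_threshold: float = 0.3
    blend: Literal["ramp", "max"] = "ramp"


class FlatfieldBlock(_Strict):
    enabled: bool = True
    window_frac: float = 0.05
    on: Literal["volume", "mip"] = "volume"


class QuantifyBlock(_Strict):
    af_rois: int = 10
    af_roi_size_um: tuple[float, float] = (20.0, 100.0)
    # ROIs large relative to the footprint average over sparse somata,
    # mirroring 200 × 700 µm² ROIs on full-size slabs; sizes exceeding the
    # footprint are clamped to it
    depth_rois: int = 3
    depth_roi_size_um: tuple[float, float] = (300.0, 350.0)
    seed: int = 0


class IOBlock(_Strict):
    outdir: Optional[str] = None
    tile_format: Literal["tiff", "jp2", "zarr"] = "tiff"
    volume_format: Literal["tiff", "zarr"] = "tiff"
    lossy_ratio: Optional[float] = None


class PipelineConfig(_Strict):
    seed: int = 0
    channel_nm: Optional[int] = 638
    phantom: PhantomBlock = PhantomBlock()
    geometry: GeometryBlock = GeometryBlock()
    reslice: ResliceBlock = ResliceBlock()
    stitch: StitchBlock = StitchBlock()
    flatfield: FlatfieldBlock = FlatfieldBlock()
    quantify: QuantifyBlock = QuantifyBlock()
    io: IOBlock = IOBlock()

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        return cls.model_validate(yaml.safe_load(Path(path).read_text()) or {})

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(json.loads(self.model_dump_json()), sort_keys=False))


@dataclass
class PipelineResult:
    volume: SampleVolume
    truth: PhantomTruth
    offsets: list[PairOffset]
    reports: dict[str, QuantReport]
    quantities: dict[str, float]
    hashes: dict[str, str] = field(default_factory=dict)


def _log_stage(run_log: list[dict], stage: str, t0: float, **info) -> None:
    entry = {"stage": stage, "elapsed_s": round(time.time() - t0, 3), **info}
    log.info("stage %s: %s", stage, info)
    run_log.append(entry)


def run_pipeline(config: PipelineConfig, outdir: str | Path | None = None) -> PipelineResult:
    """Execute all stages on a simulated acquisition and collect reports.

    Stage errors propagate wrapped with the stage name. When ``outdir`` (or
    ``config.io.outdir``) is set, tiles, the fused volume, reports, the run
    log and the resolved config are written there.
    """
    out = Path(outdir or config.io.outdir) if (outdir or config.io.outdir) else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)
    run_log: list[dict] = []
    hashes: dict[str, str] = {}

    # -- simulate ----------------------------------------------------------
    spec = config.phantom.to_spec(config.seed)
    geom = config.geometry.to_geometry()
    t0 = time.time()
    try:
        vol, truth = make_phantom(spec)
        tiles = simulate_acquisition(vol, truth, geom, seed=config.seed + 1,
                                     channel_nm=config.channel_nm)
    except Exception as err:
        raise RuntimeError(f"pipeline stage 'simulate' failed: {err}") from err
    hashes["phantom"] = content_hash(vol)
    hashes["tiles"] = content_hash(np.concatenate([t.voxels.ravel() for t in tiles]))
    _log_stage(run_log, "simulate", t0, n_tiles=len(tiles), hash=hashes["tiles"],
               spec_seed=spec.seed)
    if out is not None:
        lio.write_tiles(tiles, out / "tiles", geom, config.io.tile_format, config.io.lossy_ratio)
        lio.write_truth(out / "truth.json", truth)

    # -- reslice -----------------------------------------------------------
    t0 = time.time()
    params = ResliceParams(
        geom=geom,
        downsample=config.reslice.downsample,
        interpolation=config.reslice.interpolation,
        antialias=config.reslice.antialias,
    )
    try:
        resliced = [apply_reslice(t, params) for t in tiles]
    except Exception as err:
        raise RuntimeError(f"pipeline stage 'reslice' failed: {err}") from err
    hashes["resliced"] = content_hash(np.concatenate([r.data.ravel() for r in resliced]))
    _log_stage(run_log, "reslice", t0, out_voxel_um=params.out_voxel_um, hash=hashes["resliced"])

    # -- stitch ------------------------------------------------------------
    t0 = time.time()
    offsets: list[PairOffset] = []
    try:
        if config.stitch.enabled and len(resliced) > 1:
            nominal = np.asarray(
                [np.asarray(r.origin_um) / r.voxel_um for r in resliced]
            )
            # nominal placement from the layout's nominal (jitter-free) origins
            nominal_layout = np.asarray(
                [
                    (np.asarray(r.origin_um)
                     + (np.asarray(n) - np.asarray(o)))
                    / r.voxel_um
                    for r, n, o in zip(resliced, truth.nominal_origins_um, truth.tile_origins_um)
                ]
            )
            layout = TileLayout(
                grid_indices=tuple(t.grid_index for t in tiles),
                nominal_positions_vox=nominal_layout,
                voxel_um=resliced[0].voxel_um,
                pairs=tuple((i, i + 1) for i in range(len(resliced) - 1)),
            )
            for i, j in layout.pairs:
                off = estimate_pairwise_offset(
                    resliced[i],
                    resliced[j],
                    nominal_vox=nominal_layout[j] - nominal_layout[i],
                    search_radius_vox=config.stitch.search_radius_vox,
                    score_threshold=config.stitch.score_threshold,
                    pair=(i, j),
                )
                offsets.append(off)
            positions = globally_place(layout, offsets)
            fused = fuse(resliced, positions, blend=config.stitch.blend)
        else:
            fused = resliced[0]
    except Exception as err:
        raise RuntimeError(f"pipeline stage 'stitch' failed: {err}") from err
    hashes["fused"] = content_hash(fused.data)
    _log_stage(run_log, "stitch", t0, n_offsets=len(offsets), hash=hashes["fused"])

    # -- flatfield ---------------------------------------------------------
    t0 = time.time()
    try:
        if config.flatfield.enabled:
            target = (
                fused.data.max(axis=0) if config.flatfield.on == "mip" else fused.data
            )
            window = default_window(fused.shape[1], config.flatfield.window_frac)
            profile = compute_profile(target, window, channel_nm=fused.channel_nm)
            corrected_data = apply_correction(fused.data, profile, channel_nm=fused.channel_nm)
            corrected = SampleVolume(
                data=corrected_data,
                voxel_um=fused.voxel_um,
                origin_um=fused.origin_um,
                channel_nm=fused.channel_nm,
                valid=fused.valid,
            )
        else:
            profile = None
            corrected = fused
    except Exception as err:
        raise RuntimeError(f"pipeline stage 'flatfield' failed: {err}") from err
    hashes["corrected"] = content_hash(corrected.data)
    _log_stage(run_log, "flatfield", t0, enabled=config.flatfield.enabled,
               hash=hashes["corrected"])

    # -- quantify ----------------------------------------------------------
    t0 = time.time()
    q = config.quantify
    reports: dict[str, QuantReport] = {}
    quantities: dict[str, float] = {}
    try:
        reports["af"] = af_roi_stats(
            corrected.data,
            n_rois=q.af_rois,
            roi_size_um=q.af_roi_size_um,
            voxel_um=corrected.voxel_um,
            seed=q.seed,
        )
        rng = np.random.default_rng(q.seed)
        vx = corrected.voxel_um
        dy = max(int(round(q.depth_roi_size_um[0] / vx)), 1)
        dx = max(int(round(q.depth_roi_size_um[1] / vx)), 1)
        # restrict to the slab footprint: the fused bounding box extends past
        # the tissue (tilt shear in X, padding in Y/Z), where columns are
        # zero-padded and would flatten the depth profile
        org = np.asarray(corrected.origin_um)
        lo = np.maximum(np.ceil((0.0 - org) / vx).astype(int), 0)
        hi = np.minimum(
            np.floor((np.asarray(spec.slab_size_um) - org) / vx).astype(int) + 1,
            corrected.shape,
        )
        valid_frac = corrected.valid_mask().mean(axis=(1, 2))
        nz = hi[0]
        while nz > 2 and valid_frac[nz - 1] < 0.5:
            nz -= 1
        ny, nx = hi[1] - lo[1], hi[2] - lo[2]
        dy, dx = min(dy, ny), min(dx, nx)
        rois = []
        for i in range(q.depth_rois):
            y0 = lo[1] + int(rng.integers(0, max(ny - dy, 0) + 1))
            x0 = lo[2] + int(rng.integers(0, max(nx - dx, 0) + 1))
            rois.append(ROI(label=f"depth_{i}", origin=(y0, x0), size=(dy, dx)))
        # drop the outermost plane at each face: resampling mixes in
        # out-of-slab zeros there, depressing the profile ends
        prof = depth_profile(
            corrected.data[1 : nz - 1],
            rois,
            corrected.voxel_um,
            valid=corrected.valid_mask()[1 : nz - 1],
        )
        prof.z_um = prof.z_um + corrected.voxel_um
        quantities["penetration_lambda_um"] = fit_penetration_depth(
            prof, thickness_um=spec.slab_size_um[0]
        )["lambda_um"]
        quantities["af_mean"] = float(reports["af"].summary()["mean"].iloc[0])
    except Exception as err:
        raise RuntimeError(f"pipeline stage 'quantify' failed: {err}") from err
    _log_stage(run_log, "quantify", t0, **{k: round(v, 3) for k, v in quantities.items()})

    if out is not None:
        lio.write_volume(out / ("fused." + ("tiff" if config.io.volume_format == "tiff" else "zarr")),
                         corrected, config.io.volume_format)
        for name, rep in reports.items():
            rep.to_csv(out / f"report_{name}.csv")
        if offsets:
            import pandas as pd

            pd.DataFrame(
                [
                    {
                        "pair": f"{o.pair[0]}-{o.pair[1]}",
                        "dz": int(o.displacement_vox[0]),
                        "dy": int(o.displacement_vox[1]),
                        "dx": int(o.displacement_vox[2]),
                        "score": o.score,
                        "accepted": o.accepted,
                    }
                    for o in offsets
                ]
            ).to_csv(out / "offsets.csv", index=False)
        (out / "run_log.jsonl").write_text(
            "\n".join(json.dumps(e) for e in run_log) + "\n"
        )
        config.to_yaml(out / "config.yaml")
        (out / "hashes.json").write_text(json.dumps(hashes, indent=1))

    return PipelineResult(
        volume=corrected,
        truth=truth,
        offsets=offsets,
        reports=reports,
        quantities=quantities,
        hashes=hashes,
    )
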