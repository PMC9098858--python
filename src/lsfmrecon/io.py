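"""Tile and volume I/O: multi-page TIFF, lossless/lossy JPEG2000, zarr, layout sidecars.

Raw tiles are written one file (or, for JPEG2000, one per-frame directory)
per tile together with a ``layout.yaml`` sidecar holding the acquisition
geometry and per-tile grid indices / stage origins, and optionally a
``truth.json`` ground-truth record for simulated data.
"""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path

import numpy as np
import tifffile
import yaml
from PIL import Image

from .geometry import AcquisitionGeometry
from .phantom import PhantomSpec, PhantomTruth, RawTile
from .volume import SampleVolume

__all__ = [
    "write_tiles",
    "read_tiles",
    "write_layout",
    "read_layout",
    "write_truth",
    "read_truth",
    "write_volume",
    "read_volume",
]


def _tile_stem(tile: RawTile) -> str:
    r, c = tile.grid_index
    return f"tile_r{r:02d}_c{c:02d}"


def _write_jp2_stack(arr: np.ndarray, folder: Path, lossy_ratio: float | None) -> None:
    folder.mkdir(parents=True, exist_ok=True)
    for k in range(arr.shape[0]):
        im = Image.fromarray(arr[k])
        path = folder / f"frame_{k:04d}.jp2"
        if lossy_ratio is None:
            im.save(path, irreversible=False)
        else:
            im.save(path, irreversible=True, quality_mode="rates", quality_layers=[lossy_ratio])


def _read_jp2_stack(folder: Path) -> np.ndarray:
    frames = sorted(folder.glob("frame_*.jp2"))
    if not frames:
        raise FileNotFoundError(f"no JPEG2000 frames in {folder}")
    return np.stack([np.asarray(Image.open(f)) for f in frames]).astype(np.uint16)


def write_tiles(
    tiles: list[RawTile],
    outdir: str | Path,
    geom: AcquisitionGeometry,
    tile_format: str = "tiff",
    lossy_ratio: float | None = None,
) -> Path:
    """Write tiles plus ``layout.yaml``; returns the layout path.

    ``tile_format``: ``tiff`` (multi-page, BigTIFF when needed), ``jp2``
    (one JPEG2000 per frame, lossless unless ``lossy_ratio`` is given) or
    ``zarr``. Lossy compression is never applied unless explicitly requested.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    entries = []
    for tile in tiles:
        stem = _tile_stem(tile)
        if tile_format == "tiff":
            fname = f"{stem}.tiff"
            tifffile.imwrite(outdir / fname, tile.voxels, bigtiff=tile.voxels.nbytes > 2**31)
        elif tile_format == "jp2":
            fname = stem
            _write_jp2_stack(tile.voxels, outdir / stem, lossy_ratio)
        elif tile_format == "zarr":
            fname = f"{stem}.zarr"
            import zarr

            zarr.save_array(str(outdir / fname), tile.voxels)
        else:
            raise ValueError(f"unknown tile format {tile_format!r}")
        entries.append(
            {
                "grid_index": list(tile.grid_index),
                "stage_origin_um": [float(v) for v in tile.stage_origin_um],
                "row_sign": tile.row_sign,
                "channel_nm": tile.channel_nm,
                "file": fname,
            }
        )
    layout_path = outdir / "layout.yaml"
    write_layout(layout_path, geom, entries, tile_format)
    return layout_path


def write_layout(path: str | Path, geom: AcquisitionGeometry, entries: list[dict],
                 tile_format: str) -> None:
    doc = {"geometry": asdict(geom), "tile_format": tile_format, "tiles": entries}
    # tuples -> lists for clean YAML
    doc["geometry"]["pixel_pitch_um"] = list(geom.pixel_pitch_um)
    doc["geometry"]["fov_px"] = list(geom.fov_px)
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))


def read_layout(path: str | Path) -> tuple[AcquisitionGeometry, list[dict], str]:
    doc = yaml.safe_load(Path(path).read_text())
    g = doc["geometry"]
    geom = AcquisitionGeometry(
        pixel_pitch_um=tuple(g["pixel_pitch_um"]),
        frame_spacing_um=g["frame_spacing_um"],
        tilt_deg=g["tilt_deg"],
        fov_px=tuple(g["fov_px"]),
        tile_overlap_frac=g["tile_overlap_frac"],
        n_rows=g["n_rows"],
        snake=g["snake"],
        stage_jitter_um=g.get("stage_jitter_um", 0.0),
    )
    entries = doc["tiles"]
    seen = set()
    for e in entries:
        gi = tuple(e["grid_index"])
        if gi in seen:
            raise ValueError(f"duplicate grid index {gi} in layout")
        seen.add(gi)
    return geom, entries, doc.get("tile_format", "tiff")


def read_tiles(path: str | Path) -> tuple[list[RawTile], AcquisitionGeometry]:
    """Read tiles described by a ``layout.yaml`` (or its directory)."""
    path = Path(path)
    layout_path = path / "layout.yaml" if path.is_dir() else path
    geom, entries, fmt = read_layout(layout_path)
    base = layout_path.parent
    tiles = []
    for e in entries:
        src = base / e["file"]
        gi = tuple(e["grid_index"])
        try:
            if fmt == "tiff":
                vox = tifffile.imread(src).astype(np.uint16)
            elif fmt == "jp2":
                vox = _read_jp2_stack(src)
            elif fmt == "zarr":
                import zarr

                vox = np.asarray(zarr.load(str(src))).astype(np.uint16)
            else:
                raise ValueError(f"unknown tile format {fmt!r}")
        except FileNotFoundError as err:
            raise FileNotFoundError(f"missing tile at grid index {gi}: {err}") from err
        tiles.append(
            RawTile(
                voxels=vox,
                grid_index=gi,
                stage_origin_um=tuple(e["stage_origin_um"]),
                row_sign=e.get("row_sign", 1),
                channel_nm=e.get("channel_nm"),
            )
        )
    return tiles, geom


def write_truth(path: str | Path, truth: PhantomTruth) -> None:
    Path(path).write_text(json.dumps(truth.to_dict(), indent=1))


def read_truth(path: str | Path) -> PhantomTruth:
    doc = json.loads(Path(path).read_text())
    spec_doc = dict(doc["spec"])
    for key in ("slab_size_um",):
        spec_doc[key] = tuple(spec_doc[key])
    spec = PhantomSpec(**spec_doc)
    return PhantomTruth(
        spec=spec,
        soma_centers_um=np.asarray(doc["soma_centers_um"], dtype=float).reshape(-1, 3),
        dendrite_polylines_um=[np.asarray(p, dtype=float) for p in doc["dendrite_polylines_um"]],
        dendrite_tortuosity=list(doc["dendrite_tortuosity"]),
        puncta_um=np.asarray(doc["puncta_um"], dtype=float).reshape(-1, 3),
        tile_origins_um=[tuple(o) for o in doc["tile_origins_um"]],
        nominal_origins_um=[tuple(o) for o in doc["nominal_origins_um"]],
        pair_offsets_um=[tuple(o) for o in doc["pair_offsets_um"]],
        illum_samples=None
        if doc["illum_samples"] is None
        else np.asarray(doc["illum_samples"], dtype=float),
    )


def write_volume(path: str | Path, vol: SampleVolume, fmt: str = "tiff") -> Path:
    """Write a sample-frame volume as multi-page (Big)TIFF or a zarr array."""
    path = Path(path)
    if fmt == "tiff":
        data = vol.data
        if data.dtype.kind == "f":
            data = data.astype(np.float32)
        tifffile.imwrite(
            path,
            data,
            bigtiff=data.nbytes > 2**31,
            metadata={"voxel_um": vol.voxel_um, "origin_um": list(vol.origin_um)},
        )
    elif fmt == "zarr":
        import zarr

        zarr.save_array(str(path), vol.data)
    else:
        raise ValueError(f"unknown volume format {fmt!r}")
    return path


def read_volume(path: str | Path, voxel_um: float = 3.3) -> SampleVolume:
    path = Path(path)
    if path.suffix in (".tif", ".tiff"):
        data = tifffile.imread(path)
    else:
        import zarr

        data = np.asarray(zarr.load(str(path)))
    return SampleVolume(data=data, voxel_um=voxel_um)
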