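"""Synthetic slab phantoms and simulated oblique tiled acquisition.

The phantom emulates a 500 µm-thick cleared human-cortex slice imaged by an
inverted light-sheet microscope: spherical somata and tubular dendrites
carrying an immunostaining signal, punctate lipofuscin-like autofluorescence,
a depth-dependent antibody penetration profile (bright rim near each face
plus an exponential decay into the interior), multiplicative illumination
variation along the transversal camera axis, Poisson–Gaussian camera noise,
and sampling on the 45°-tilted objective-frame lattice.

Every generated tile is exactly reproducible from ``(PhantomSpec,
AcquisitionGeometry, seed)``; the :class:`PhantomTruth` record carries the
ground truth (object coordinates, true tile origins and pairwise offsets,
illumination samples, penetration parameters) that downstream recovery tests
compare against.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np
from scipy.ndimage import map_coordinates
from scipy.special import erfc

from .geometry import AcquisitionGeometry, lattice_to_sample_affine

__all__ = [
    "PhantomSpec",
    "PhantomTruth",
    "RawTile",
    "make_phantom",
    "simulate_acquisition",
    "depth_modulation",
    "illumination_profile",
]


@dataclass(frozen=True)
class PhantomSpec:
    """Parameters of one synthetic slab.

    Lengths in µm, intensities in camera counts. ``slab_size_um`` is ordered
    (Z thickness, Y, X); the 500 µm default Z matches the thickest slice the
    clearing protocol labels homogeneously.
    """

    slab_size_um: tuple[float, float, float] = (500.0, 1000.0, 1000.0)
    voxel_um: float = 1.0
    n_somata: int = 30
    soma_radius_um: float = 5.0
    n_dendrites: int = 5
    dendrite_radius_um: float = 1.0
    dendrite_length_um: float = 80.0
    n_puncta: int = 50
    penetration_depth_um: float = 150.0
    rim_peak_amp: float = 0.5
    rim_peak_depth_um: float = 50.0
    rim_peak_sigma_um: float = 15.0
    soma_amp: float = 10000.0
    dendrite_amp: float = 6000.0
    puncta_amp: float = 3000.0
    neuropil_amp: float = 0.0
    background: float = 300.0
    edge_sigma_um: float = 2.0
    illum_profile: dict = field(
        default_factory=lambda: {"kind": "sinusoid", "amplitude": 0.0, "cycles": 1.0, "phase": 0.0}
    )
    noise_gain: float = 0.0  # photons-per-count; 0 disables shot noise
    read_noise_sd: float = 0.0  # counts
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.slab_size_um) <= 0 or self.voxel_um <= 0:
            raise ValueError("slab extents and voxel size must be positive")
        for name in ("soma_radius_um", "dendrite_radius_um", "penetration_depth_um",
                     "rim_peak_depth_um", "rim_peak_sigma_um", "dendrite_length_um"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        if self.rim_peak_amp < 0 or self.background < 0 or self.neuropil_amp < 0:
            raise ValueError("amplitudes must be nonnegative")
        if min(self.n_somata, self.n_dendrites, self.n_puncta) < 0:
            raise ValueError("object counts must be nonnegative")
        if self.n_somata > 0 and min(self.slab_size_um) < 2 * self.soma_radius_um:
            raise ValueError("slab smaller than one soma diameter")
        if self.noise_gain < 0 or self.read_noise_sd < 0:
            raise ValueError("noise parameters must be nonnegative")


@dataclass
class PhantomTruth:
    """Ground truth of a phantom plus (after simulation) of its acquisition."""

    spec: PhantomSpec
    soma_centers_um: np.ndarray  # (n, 3) in (z, y, x)
    dendrite_polylines_um: list[np.ndarray]  # each (m, 3)
    dendrite_tortuosity: list[float]
    puncta_um: np.ndarray  # (n, 3)
    # populated by simulate_acquisition:
    tile_origins_um: list[tuple[float, float, float]] = field(default_factory=list)
    nominal_origins_um: list[tuple[float, float, float]] = field(default_factory=list)
    pair_offsets_um: list[tuple[float, float, float]] = field(default_factory=list)
    illum_samples: np.ndarray | None = None

    def to_dict(self) -> dict:
        return {
            "spec": asdict(self.spec),
            "soma_centers_um": self.soma_centers_um.tolist(),
            "dendrite_polylines_um": [p.tolist() for p in self.dendrite_polylines_um],
            "dendrite_tortuosity": list(self.dendrite_tortuosity),
            "puncta_um": self.puncta_um.tolist(),
            "tile_origins_um": [list(o) for o in self.tile_origins_um],
            "nominal_origins_um": [list(o) for o in self.nominal_origins_um],
            "pair_offsets_um": [list(o) for o in self.pair_offsets_um],
            "illum_samples": None if self.illum_samples is None else self.illum_samples.tolist(),
        }


@dataclass
class RawTile:
    """One acquired 3D stack in the objective reference frame, axes (k, v, u)."""

    voxels: np.ndarray  # uint16
    grid_index: tuple[int, int]
    stage_origin_um: tuple[float, float, float]  # (z0, y0, x0), true origin
    row_sign: int = 1
    channel_nm: int | None = None

    def __post_init__(self) -> None:
        if self.voxels.ndim != 3:
            raise ValueError("tile voxels must be 3D (frame, v, u)")
        if self.voxels.dtype != np.uint16:
            raise ValueError("tile voxels must be uint16")


# ---------------------------------------------------------------------------
# phantom rendering


def depth_modulation(z_um: np.ndarray, spec: PhantomSpec) -> np.ndarray:
    """Staining depth profile D(z) across a slab of thickness Z.

    ``D(z) = exp(-z/λ) + exp(-(Z-z)/λ) + A·[g(z - z_r) + g(Z - z - z_r)]``
    where g is a Gaussian bump of width ``rim_peak_sigma_um``: antibodies
    accumulate in a rim near each face and decay exponentially inward.
    """
    lam = spec.penetration_depth_um
    thickness = spec.slab_size_um[0]
    z = np.asarray(z_um, dtype=float)
    d = np.exp(-z / lam) + np.exp(-(thickness - z) / lam)
    if spec.rim_peak_amp > 0:
        s2 = 2.0 * spec.rim_peak_sigma_um**2
        d = d + spec.rim_peak_amp * (
            np.exp(-((z - spec.rim_peak_depth_um) ** 2) / s2)
            + np.exp(-((thickness - z - spec.rim_peak_depth_um) ** 2) / s2)
        )
    return d


def _soft_ball(shape, center_vox, radius_vox, sigma_vox):
    """Unit-amplitude sphere with an erf-smoothed edge, on a local grid."""
    lo = np.maximum(np.floor(center_vox - radius_vox - 4 * sigma_vox).astype(int), 0)
    hi = np.minimum(np.ceil(center_vox + radius_vox + 4 * sigma_vox).astype(int) + 1, shape)
    if np.any(hi <= lo):
        return None, None, None
    grids = np.meshgrid(*[np.arange(a, b) for a, b in zip(lo, hi)], indexing="ij")
    d = np.sqrt(sum((g - c) ** 2 for g, c in zip(grids, center_vox)))
    f = 0.5 * erfc((d - radius_vox) / (math.sqrt(2.0) * sigma_vox))
    return lo, hi, f


def _render_capsule(out, p0, p1, radius_vox, sigma_vox, amp):
    """max-composite a soft-edged cylinder segment into ``out`` (voxel coords)."""
    margin = radius_vox + 4 * sigma_vox
    lo = np.maximum(np.floor(np.minimum(p0, p1) - margin).astype(int), 0)
    hi = np.minimum(np.ceil(np.maximum(p0, p1) + margin).astype(int) + 1, out.shape)
    if np.any(hi <= lo):
        return
    grids = np.meshgrid(*[np.arange(a, b) for a, b in zip(lo, hi)], indexing="ij")
    p = np.stack([g.astype(float) for g in grids], axis=-1)
    ab = p1 - p0
    denom = float(ab @ ab)
    if denom == 0:
        t = np.zeros(p.shape[:-1])
    else:
        t = np.clip(((p - p0) @ ab) / denom, 0.0, 1.0)
    closest = p0 + t[..., None] * ab
    d = np.linalg.norm(p - closest, axis=-1)
    f = amp * 0.5 * erfc((d - radius_vox) / (math.sqrt(2.0) * sigma_vox))
    region = tuple(slice(a, b) for a, b in zip(lo, hi))
    np.maximum(out[region], f, out=out[region])


def _polyline_tortuosity(points: np.ndarray) -> float:
    seg = np.diff(points, axis=0)
    arc = float(np.sum(np.linalg.norm(seg, axis=1)))
    chord = float(np.linalg.norm(points[-1] - points[0]))
    return arc / chord


def make_phantom(spec: PhantomSpec) -> tuple[np.ndarray, PhantomTruth]:
    """Render a sample-frame intensity volume (Z, Y, X) and its ground truth.

    The staining compartment (somata, dendrites, optional homogeneous
    neuropil) is modulated by the depth-penetration profile
    :func:`depth_modulation`; the autofluorescence compartment (uniform
    background plus lipofuscin-like puncta) is not.
    """
    rng = np.random.default_rng(spec.seed)
    shape = tuple(int(round(s / spec.voxel_um)) + 1 for s in spec.slab_size_um)
    vx = spec.voxel_um
    sigma_vox = spec.edge_sigma_um / vx

    # stain is composited in absolute counts (max of overlapping structures)
    stain = np.full(shape, spec.neuropil_amp, dtype=np.float64)
    margin = spec.soma_radius_um + 2 * spec.edge_sigma_um
    extents = np.asarray(spec.slab_size_um)

    centers = np.empty((spec.n_somata, 3))
    for i in range(spec.n_somata):
        centers[i] = rng.uniform(np.minimum(margin, extents / 2), np.maximum(extents - margin, extents / 2))
        lo, hi, f = _soft_ball(shape, centers[i] / vx, spec.soma_radius_um / vx, sigma_vox)
        if lo is not None:
            region = tuple(slice(a, b) for a, b in zip(lo, hi))
            np.maximum(stain[region], spec.soma_amp * f, out=stain[region])

    polylines: list[np.ndarray] = []
    torts: list[float] = []
    step = 2.0  # µm between polyline nodes
    for _ in range(spec.n_dendrites):
        n_steps = max(int(spec.dendrite_length_um / step), 2)
        start = rng.uniform(margin, np.maximum(extents - margin, margin + 1e-6))
        direction = rng.normal(size=3)
        direction /= np.linalg.norm(direction)
        pts = [start]
        for _ in range(n_steps):
            direction = direction + 0.25 * rng.normal(size=3)
            direction /= np.linalg.norm(direction)
            nxt = np.clip(pts[-1] + step * direction, 0.0, extents)
            pts.append(nxt)
        pts = np.asarray(pts)
        polylines.append(pts)
        torts.append(_polyline_tortuosity(pts))
        for a, b in zip(pts[:-1], pts[1:]):
            _render_capsule(stain, a / vx, b / vx, spec.dendrite_radius_um / vx, sigma_vox, spec.dendrite_amp)

    z_um = np.arange(shape[0]) * vx
    vol = stain * depth_modulation(z_um, spec)[:, None, None]

    puncta = np.empty((spec.n_puncta, 3))
    sigma_p = 1.0  # µm, punctum width
    for i in range(spec.n_puncta):
        puncta[i] = rng.uniform(0, extents)
        lo, hi, f = _soft_ball(shape, puncta[i] / vx, sigma_p / vx, max(sigma_p / vx, 0.8))
        if lo is not None:
            region = tuple(slice(a, b) for a, b in zip(lo, hi))
            vol[region] += spec.puncta_amp * f

    vol += spec.background
    truth = PhantomTruth(
        spec=spec,
        soma_centers_um=centers,
        dendrite_polylines_um=polylines,
        dendrite_tortuosity=torts,
        puncta_um=puncta,
    )
    return vol.astype(np.float32), truth


# ---------------------------------------------------------------------------
# acquisition simulation


def illumination_profile(descriptor: dict, n_v: int) -> np.ndarray:
    """Evaluate a multiplicative illumination profile over the v (transversal) axis.

    ``{"kind": "sinusoid", "amplitude": a, "cycles": c, "phase": p}`` gives
    ``1 + a·sin(2π(c·t + p))`` on t ∈ [0, 1];
    ``{"kind": "polynomial", "coeffs": [...]}`` evaluates the polynomial in t.
    """
    t = np.linspace(0.0, 1.0, n_v)
    kind = descriptor.get("kind", "sinusoid")
    if kind == "sinusoid":
        a = float(descriptor.get("amplitude", 0.0))
        c = float(descriptor.get("cycles", 1.0))
        p = float(descriptor.get("phase", 0.0))
        prof = 1.0 + a * np.sin(2.0 * math.pi * (c * t + p))
    elif kind == "polynomial":
        prof = np.polynomial.polynomial.polyval(t, np.asarray(descriptor["coeffs"], dtype=float))
    else:
        raise ValueError(f"unknown illumination profile kind: {kind!r}")
    if np.any(prof <= 0):
        raise ValueError("illumination profile must be strictly positive")
    return prof


def simulate_acquisition(
    volume: np.ndarray,
    truth: PhantomTruth,
    geom: AcquisitionGeometry,
    seed: int,
    channel_nm: int | None = None,
) -> list[RawTile]:
    """Sample a phantom on the tilted objective-frame lattice, tile by tile.

    Forward model per tile: trilinear interpolation of the sample-frame
    volume at the lattice's affine image (zero outside the slab), multiplied
    by the illumination profile along v, Poisson shot noise at the spec's
    gain plus Gaussian read noise, cast to uint16. True per-row stage
    origins (nominal + jitter) and pairwise row offsets are recorded in
    ``truth``.
    """
    spec = truth.spec
    vx = spec.voxel_um
    extents = np.asarray(spec.slab_size_um)
    y_covered = geom.nominal_row_origin_um(geom.n_rows - 1, extents[2])[1] + geom.tile_y_extent_um
    if y_covered + 1e-6 < extents[1]:
        raise ValueError(
            f"geometry covers Y up to {y_covered:.1f} µm but slab extends to {extents[1]:.1f} µm"
        )
    overlap_vox = geom.tile_overlap_frac * geom.tile_y_extent_um / geom.pixel_pitch_um[0]
    if geom.n_rows > 1 and overlap_vox < 8:
        raise ValueError("tile overlap smaller than 8 shared voxels")

    n_v, n_u = geom.fov_px
    n_k = geom.n_frames(extents[2])
    illum = illumination_profile(spec.illum_profile, n_v)
    truth.illum_samples = illum

    ss = np.random.SeedSequence(seed)
    children = ss.spawn(geom.n_rows)

    kk, vv, uu = np.meshgrid(
        np.arange(n_k), np.arange(n_v), np.arange(n_u), indexing="ij"
    )
    lattice = np.stack(
        [kk.ravel(), vv.ravel(), uu.ravel(), np.ones(kk.size)], axis=0
    ).astype(float)

    tiles: list[RawTile] = []
    truth.tile_origins_um = []
    truth.nominal_origins_um = []
    truth.pair_offsets_um = []
    for row in range(geom.n_rows):
        rng = np.random.default_rng(children[row])
        nominal = geom.nominal_row_origin_um(row, extents[2])
        if geom.stage_jitter_um > 0:
            jitter = rng.uniform(-geom.stage_jitter_um, geom.stage_jitter_um, size=2)
        else:
            jitter = np.zeros(2)
        origin = (nominal[0], nominal[1] + jitter[0], nominal[2] + jitter[1])
        affine = lattice_to_sample_affine(geom, geom.row_sign(row), origin)
        phys = affine @ lattice  # (4, N) -> rows z, y, x, 1
        coords = phys[:3] / vx
        sampled = map_coordinates(
            volume.astype(np.float32), coords, order=1, mode="constant", cval=0.0
        ).reshape(n_k, n_v, n_u)
        sampled *= illum[None, :, None]
        if spec.noise_gain > 0:
            sampled = spec.noise_gain * rng.poisson(sampled / spec.noise_gain).astype(np.float64)
        if spec.read_noise_sd > 0:
            sampled = sampled + rng.normal(0.0, spec.read_noise_sd, size=sampled.shape)
        vox = np.clip(np.rint(sampled), 0, 65535).astype(np.uint16)
        tiles.append(
            RawTile(
                voxels=vox,
                grid_index=(row, 0),
                stage_origin_um=origin,
                row_sign=geom.row_sign(row),
                channel_nm=channel_nm,
            )
        )
        truth.tile_origins_um.append(origin)
        truth.nominal_origins_um.append(nominal)
    for a, b in zip(truth.tile_origins_um[:-1], truth.tile_origins_um[1:]):
        truth.pair_offsets_um.append(tuple(np.subtract(b, a)))
    return tiles
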