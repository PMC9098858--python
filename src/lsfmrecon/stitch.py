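"""Pairwise offset estimation, global placement and fusion of resliced tiles.

Adjacent tile rows overlap along the transversal Y axis. Offsets are
estimated on the nominal overlap region by phase correlation refined with an
integer-shift local search maximizing normalized cross-correlation; global
positions minimize the squared residuals of accepted pairwise constraints
(anchored least squares on the displacement graph); fusion blends overlaps
with linear ramp weights so seams stay continuous for the downstream
flat-field stage.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.sparse.csgraph import connected_components
from skimage.registration import phase_cross_correlation

from .volume import SampleVolume

__all__ = [
    "TileLayout",
    "PairOffset",
    "estimate_pairwise_offset",
    "globally_place",
    "fuse",
]

MIN_OVERLAP_VOX = 8


@dataclass(frozen=True)
class TileLayout:
    """Nominal placement of resliced tiles: grid indices, positions (voxels), adjacency."""

    grid_indices: tuple[tuple[int, int], ...]
    nominal_positions_vox: np.ndarray  # (n, 3) float, (z, y, x)
    voxel_um: float
    pairs: tuple[tuple[int, int], ...] = ()  # indices of Y-adjacent overlapping tiles

    def __post_init__(self) -> None:
        if len(set(self.grid_indices)) != len(self.grid_indices):
            raise ValueError("duplicate grid indices in layout")
        if len(self.grid_indices) != len(self.nominal_positions_vox):
            raise ValueError("positions and grid indices disagree in length")


@dataclass
class PairOffset:
    """Estimated displacement of tile b relative to tile a, in voxels."""

    pair: tuple[int, int]
    displacement_vox: np.ndarray  # (3,) int
    score: float  # peak normalized cross-correlation, clipped to [0, 1]
    accepted: bool


def _ncc(a: np.ndarray, b: np.ndarray) -> float:
    a = a.astype(np.float64).ravel()
    b = b.astype(np.float64).ravel()
    a -= a.mean()
    b -= b.mean()
    denom = np.sqrt((a @ a) * (b @ b))
    if denom == 0:
        return 0.0
    return float((a @ b) / denom)


def _overlap_views(shape_a, shape_b, disp):
    """Index slices of the overlap of two boxes when b sits at ``disp`` in a's frame."""
    lo = np.maximum(disp, 0)
    hi = np.minimum(np.asarray(shape_a), np.asarray(disp) + np.asarray(shape_b))
    if np.any(hi - lo < 1):
        return None, None
    sl_a = tuple(slice(int(l), int(h)) for l, h in zip(lo, hi))
    sl_b = tuple(slice(int(l - d), int(h - d)) for l, h, d in zip(lo, hi, disp))
    return sl_a, sl_b


def estimate_pairwise_offset(
    a: SampleVolume,
    b: SampleVolume,
    nominal_vox: np.ndarray,
    search_radius_vox: np.ndarray = (2, 5, 5),
    score_threshold: float = 0.3,
    pair: tuple[int, int] = (-1, -1),
) -> PairOffset:
    """Estimate the integer-voxel displacement of ``b`` relative to ``a``.

    ``nominal_vox`` is the layout's expected displacement. Phase correlation
    on the nominal overlap proposes a candidate within ``search_radius_vox``;
    an exhaustive ±1 local search around it picks the shift maximizing
    normalized cross-correlation, which also provides the acceptance score.
    """
    nominal = np.rint(np.asarray(nominal_vox, dtype=float)).astype(int)
    radius = np.asarray(search_radius_vox, dtype=int)
    sl_a, sl_b = _overlap_views(a.shape, b.shape, nominal)
    if sl_a is None or any(s.stop - s.start < MIN_OVERLAP_VOX for s in sl_a):
        raise ValueError(
            f"nominal overlap smaller than {MIN_OVERLAP_VOX} voxels in some axis"
        )
    ov_a = a.data[sl_a].astype(np.float64)
    ov_b = b.data[sl_b].astype(np.float64)

    shift, _, _ = phase_cross_correlation(ov_a, ov_b, upsample_factor=1, normalization="phase")
    # moving (ov_b) shifted by +shift aligns to ov_a, i.e. b actually sits at
    # nominal + shift in a's frame.
    delta0 = np.clip(np.rint(shift).astype(int), -radius, radius)

    best_delta, best_score = None, -np.inf
    for dz in (-1, 0, 1):
        for dy in (-1, 0, 1):
            for dx in (-1, 0, 1):
                delta = np.clip(delta0 + np.array([dz, dy, dx]), -radius, radius)
                disp = nominal + delta
                va, vb = _overlap_views(a.shape, b.shape, disp)
                if va is None or any(s.stop - s.start < MIN_OVERLAP_VOX for s in va):
                    continue
                score = _ncc(a.data[va], b.data[vb])
                if score > best_score:
                    best_score, best_delta = score, delta.copy()
    if best_delta is None:
        return PairOffset(pair=pair, displacement_vox=nominal, score=0.0, accepted=False)
    score = float(np.clip(best_score, 0.0, 1.0))
    return PairOffset(
        pair=pair,
        displacement_vox=nominal + best_delta,
        score=score,
        accepted=score >= score_threshold,
    )


def globally_place(layout: TileLayout, offsets: list[PairOffset]) -> np.ndarray:
    """Absolute tile positions (voxels) from pairwise constraints.

    Positions minimize the sum of squared residuals of accepted pairwise
    displacements, solved per axis on the displacement graph with the first
    tile of each connected component anchored at its nominal position;
    tiles with no accepted constraint keep their nominal position.
    """
    n = len(layout.grid_indices)
    nominal = np.asarray(layout.nominal_positions_vox, dtype=float)
    accepted = [o for o in offsets if o.accepted]
    if not accepted:
        return nominal.copy()

    adj = np.zeros((n, n), dtype=bool)
    for o in accepted:
        i, j = o.pair
        adj[i, j] = adj[j, i] = True
    n_comp, labels = connected_components(adj, directed=False)

    positions = nominal.copy()
    # solve in correction space: c_j - c_i = disp_ij - (nom_j - nom_i)
    rows = []
    rhs = []
    for o in accepted:
        i, j = o.pair
        r = np.zeros(n)
        r[i], r[j] = -1.0, 1.0
        rows.append(r)
        rhs.append(np.asarray(o.displacement_vox, dtype=float) - (nominal[j] - nominal[i]))
    # anchor one tile per connected component (and every isolated tile)
    for comp in range(n_comp):
        members = np.flatnonzero(labels == comp)
        anchor = members[0]
        r = np.zeros(n)
        r[anchor] = 1.0
        rows.append(r)
        rhs.append(np.zeros(3))
    a_mat = np.asarray(rows)
    b_mat = np.asarray(rhs)
    corr, *_ = np.linalg.lstsq(a_mat, b_mat, rcond=None)
    return nominal + corr


def pairwise_residual(positions: np.ndarray, offsets: list[PairOffset]) -> float:
    """Sum of squared residuals of accepted pairwise constraints at given positions."""
    total = 0.0
    for o in offsets:
        if not o.accepted:
            continue
        i, j = o.pair
        r = (positions[j] - positions[i]) - np.asarray(o.displacement_vox, dtype=float)
        total += float(r @ r)
    return total


def fuse(tiles: list[SampleVolume], positions_vox: np.ndarray, blend: str = "ramp") -> SampleVolume:
    """Blend placed tiles into one volume.

    With ``blend="ramp"`` (default) each tile's weight is its distance to
    the nearer transversal (Y) edge, so in a two-tile overlap the normalized
    weights ramp linearly from one tile to the other; weights are divided by
    their sum wherever at least one tile is valid. ``blend="max"`` takes the
    voxelwise maximum instead.
    """
    if not tiles:
        raise ValueError("no tiles to fuse")
    if blend not in ("ramp", "max"):
        raise ValueError("blend must be 'ramp' or 'max'")
    pos = np.rint(np.asarray(positions_vox, dtype=float)).astype(int)
    pos = pos - pos.min(axis=0)
    shapes = np.asarray([t.shape for t in tiles])
    out_shape = tuple((pos + shapes).max(axis=0))

    acc = np.zeros(out_shape, dtype=np.float64)
    wsum = np.zeros(out_shape, dtype=np.float64)
    for tile, p in zip(tiles, pos):
        nz, ny, nx = tile.shape
        y = np.arange(ny, dtype=np.float64)
        ramp = np.minimum(y + 1.0, ny - y)  # distance to nearer Y edge
        w = np.broadcast_to(ramp[None, :, None], tile.shape) * tile.valid_mask()
        region = tuple(slice(p[i], p[i] + tile.shape[i]) for i in range(3))
        if blend == "max":
            np.maximum(acc[region], tile.data * tile.valid_mask(), out=acc[region])
            wsum[region] += w
        else:
            acc[region] += w * tile.data.astype(np.float64)
            wsum[region] += w
    if blend == "max":
        fused = acc
    else:
        with np.errstate(invalid="ignore", divide="ignore"):
            fused = np.where(wsum > 0, acc / np.where(wsum > 0, wsum, 1.0), 0.0)

    ref = tiles[0]
    min_shift = np.rint(np.asarray(positions_vox, dtype=float)).astype(int).min(axis=0)
    origin = np.asarray(ref.origin_um) + (min_shift - np.rint(positions_vox[0])) * ref.voxel_um
    data = fused.astype(ref.data.dtype) if ref.data.dtype.kind == "f" else np.clip(
        np.rint(fused), 0, np.iinfo(ref.data.dtype).max
    ).astype(ref.data.dtype)
    return SampleVolume(
        data=data,
        voxel_um=ref.voxel_um,
        origin_um=tuple(origin),
        channel_nm=ref.channel_nm,
        valid=wsum > 0,
    )
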