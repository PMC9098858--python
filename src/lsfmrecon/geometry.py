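"""Acquisition geometry for oblique (45°-tilted) light-sheet imaging.

Coordinate conventions
----------------------
Sample frame (physical, µm): axes ordered ``(Z, Y, X)``.

* ``Z`` — slab thickness (depth from the illuminated face),
* ``Y`` — transversal axis, along which tile rows are laid out,
* ``X`` — stage-motion axis (the sample translates horizontally).

Objective-frame lattice (integer indices): ``(k, v, u)``.

* ``k`` — frame number along the stage sweep,
* ``v`` — camera row; maps to the transversal axis Y,
* ``u`` — camera column; the detection axis is tilted, so ``u`` mixes into
  both depth Z and stage axis X.

The forward map lattice → sample-frame µm is the single affine

    Z = u · p_u · sin(tilt)
    Y = y0 + v · p_v
    X = x0 + s · (k · Δ + u · p_u · cos(tilt))

with ``p_v, p_u`` the camera pixel pitch, ``Δ`` the stage step per frame and
``s = ±1`` the stage direction of the row (alternating in a snake-like
acquisition pattern).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = ["AcquisitionGeometry", "lattice_to_sample_affine"]


@dataclass(frozen=True)
class AcquisitionGeometry:
    """Camera / stage parameters of one tiled acquisition.

    Defaults correspond to the production instrument: 0.55 µm pixel pitch,
    3.3 µm stage step per frame, objectives tilted 45° to the holder plane,
    2048 × 2048 px field of view. Tests use a scaled-down ``fov_px``.
    """

    pixel_pitch_um: tuple[float, float] = (0.55, 0.55)  # (v, u)
    frame_spacing_um: float = 3.3
    tilt_deg: float = 45.0
    fov_px: tuple[int, int] = (2048, 2048)  # (v, u)
    tile_overlap_frac: float = 0.2
    n_rows: int = 1
    snake: bool = True
    #: uniform ±jitter (µm) applied to each row's true stage origin by the
    #: simulator; nominal layout positions do not include it.
    stage_jitter_um: float = 0.0

    def __post_init__(self) -> None:
        pv, pu = self.pixel_pitch_um
        if pv <= 0 or pu <= 0 or self.frame_spacing_um <= 0:
            raise ValueError("pixel pitch and frame spacing must be positive")
        if not 0.0 < self.tilt_deg < 90.0:
            raise ValueError(f"tilt must be strictly inside (0, 90) deg, got {self.tilt_deg}")
        if not 0.05 <= self.tile_overlap_frac <= 0.5:
            raise ValueError("tile_overlap_frac must lie in [0.05, 0.5]")
        if self.fov_px[0] < 2 or self.fov_px[1] < 2:
            raise ValueError("fov_px must be at least 2 px per axis")
        if self.n_rows < 1:
            raise ValueError("n_rows must be >= 1")
        if self.stage_jitter_um < 0:
            raise ValueError("stage_jitter_um must be >= 0")

    # -- derived quantities ------------------------------------------------

    @property
    def tilt_rad(self) -> float:
        return math.radians(self.tilt_deg)

    @property
    def tile_y_extent_um(self) -> float:
        """Transversal width of one tile in the sample frame."""
        return self.fov_px[0] * self.pixel_pitch_um[0]

    @property
    def row_pitch_um(self) -> float:
        """Nominal Y spacing between adjacent tile rows."""
        return (1.0 - self.tile_overlap_frac) * self.tile_y_extent_um

    @property
    def depth_extent_um(self) -> float:
        """Depth (Z) range swept by the tilted detection axis."""
        return (self.fov_px[1] - 1) * self.pixel_pitch_um[1] * math.sin(self.tilt_rad)

    @property
    def shear_extent_um(self) -> float:
        """X range contributed by the tilted u axis within one frame."""
        return (self.fov_px[1] - 1) * self.pixel_pitch_um[1] * math.cos(self.tilt_rad)

    def row_sign(self, row: int) -> int:
        """Stage direction of a row: +1 on even rows, −1 on odd when snaking."""
        return -1 if (self.snake and row % 2 == 1) else 1

    def nominal_row_origin_um(self, row: int, x_extent_um: float) -> tuple[float, float, float]:
        """Nominal stage origin ``(z0, y0, x0)`` of a row covering ``[0, x_extent_um]``.

        The origin is chosen so the sheared u axis never leaves the target X
        range unsampled: forward rows start at ``−shear``, reverse rows at
        ``x_extent + shear``.
        """
        y0 = row * self.row_pitch_um
        if self.row_sign(row) > 0:
            x0 = -self.shear_extent_um
        else:
            x0 = x_extent_um + self.shear_extent_um
        return (0.0, y0, x0)

    def row_for_origin(self, origin_um: tuple[float, float, float]) -> int:
        """Inverse of the grid-index → stage-position map (bijectivity contract)."""
        row = round(origin_um[1] / self.row_pitch_um)
        if abs(row * self.row_pitch_um - origin_um[1]) > 1e-6:
            raise ValueError(f"origin {origin_um} is not on the nominal row lattice")
        return row

    def n_frames(self, x_extent_um: float) -> int:
        """Frames needed for one row to cover ``[0, x_extent_um]`` incl. shear."""
        span = x_extent_um + 2.0 * self.shear_extent_um
        return int(math.ceil(span / self.frame_spacing_um)) + 1


def lattice_to_sample_affine(
    geom: AcquisitionGeometry,
    row_sign: int,
    stage_origin_um: tuple[float, float, float],
) -> np.ndarray:
    """4×4 homogeneous affine mapping lattice ``(k, v, u)`` to sample-frame µm ``(z, y, x)``.

    This single matrix is the contract between the acquisition simulator
    (which samples the phantom on its inverse image) and the reslicer (which
    resamples tiles through it); both always agree on the tilt sign
    convention: increasing u maps to increasing Z.
    """
    if row_sign not in (-1, 1):
        raise ValueError("row_sign must be ±1")
    pv, pu = geom.pixel_pitch_um
    th = geom.tilt_rad
    z0, y0, x0 = stage_origin_um
    a = np.zeros((4, 4), dtype=float)
    # rows: z, y, x; cols: k, v, u, 1
    a[0, 2] = pu * math.sin(th)
    a[0, 3] = z0
    a[1, 1] = pv
    a[1, 3] = y0
    a[2, 0] = row_sign * geom.frame_spacing_um
    a[2, 2] = row_sign * pu * math.cos(th)
    a[2, 3] = x0
    a[3, 3] = 1.0
    return a
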