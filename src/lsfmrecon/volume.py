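"""Sample-frame volumes: the common container handed between pipeline stages."""

from __future__ import annotations

import hashlib
from dataclasses import dataclass

import numpy as np

__all__ = ["SampleVolume", "content_hash"]


@dataclass
class SampleVolume:
    """A 3D array in the sample reference frame with isotropic voxels.

    Axes are ordered ``(Z, Y, X)``; ``origin_um`` locates voxel (0, 0, 0)
    in sample-frame physical coordinates. ``valid`` flags voxels that were
    inside the support of the source data (resampling fills the rest with 0).
    """

    data: np.ndarray
    voxel_um: float
    origin_um: tuple[float, float, float] = (0.0, 0.0, 0.0)
    channel_nm: int | None = None
    valid: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.data.ndim != 3:
            raise ValueError("SampleVolume data must be 3D (Z, Y, X)")
        if self.voxel_um <= 0:
            raise ValueError("voxel size must be positive")
        if self.valid is not None and self.valid.shape != self.data.shape:
            raise ValueError("valid mask shape must match data shape")

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    def valid_mask(self) -> np.ndarray:
        if self.valid is None:
            return np.ones(self.data.shape, dtype=bool)
        return self.valid.astype(bool)

    def extent_um(self) -> np.ndarray:
        """Physical size along (Z, Y, X)."""
        return (np.asarray(self.data.shape) - 1) * self.voxel_um


def content_hash(arr: np.ndarray, rel_tol: float = 1e-6) -> str:
    """SHA-256 of an array quantized at ``rel_tol`` of its peak magnitude.

    Quantizing before hashing makes the digest stable across platforms
    whose floating-point rounding differs below the stated tolerance.
    """
    a = np.asarray(arr)
    if a.dtype.kind in "ui":
        payload = np.ascontiguousarray(a).tobytes()
    else:
        peak = float(np.max(np.abs(a))) if a.size else 0.0
        scale = peak * rel_tol if peak > 0 else 1.0
        payload = np.ascontiguousarray(np.round(a / scale).astype(np.int64)).tobytes()
    h = hashlib.sha256()
    h.update(str(a.shape).encode())
    h.update(payload)
    return h.hexdigest()
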