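"""Illumination intensity homogenization (flat-field correction).

Laser-power variation across the light sheet shows up as a multiplicative
intensity gradient along the transversal Y axis of the stitched volume. Per
wavelength, the observed intensity is averaged along X (and Z for 3D input)
to build a smoothed Y profile that serves as the flat-field reference; the
volume is divided by the normalized profile to even out the illumination.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import uniform_filter1d

__all__ = ["IlluminationProfile", "compute_profile", "apply_correction", "default_window"]


@dataclass
class IlluminationProfile:
    """Smoothed per-channel Y intensity profile used as flat-field reference."""

    values: np.ndarray  # strictly positive, length = Y extent
    window: int
    mean: float
    channel_nm: int | None = None

    def normalized(self) -> np.ndarray:
        return self.values / self.mean


def default_window(n_y: int, frac: float = 0.05) -> int:
    """Odd-rounded smoothing window covering ``frac`` of the Y extent."""
    w = max(int(round(frac * n_y)), 1)
    return w if w % 2 == 1 else w + 1


def compute_profile(
    volume: np.ndarray, window: int, channel_nm: int | None = None
) -> IlluminationProfile:
    """Y illumination profile of a volume (Z, Y, X) or of its MIP (Y, X).

    The raw profile is the mean over every non-Y axis, smoothed by a
    centered moving average with reflective boundaries and clamped below at
    1e-3 of its mean so later division is safe.
    """
    vol = np.asarray(volume, dtype=np.float64)
    if vol.ndim not in (2, 3):
        raise ValueError("expected a 2D MIP (Y, X) or 3D volume (Z, Y, X)")
    if window < 1 or window % 2 == 0:
        raise ValueError("window must be odd and >= 1")
    y_axis = vol.ndim - 2
    reduce_axes = tuple(ax for ax in range(vol.ndim) if ax != y_axis)
    raw = vol.mean(axis=reduce_axes)
    if not np.any(raw > 0):
        raise ValueError("profile undefined for an all-zero volume")
    if window >= len(raw):
        smoothed = np.full_like(raw, raw.mean())
    elif window > 1:
        smoothed = uniform_filter1d(raw, size=window, mode="reflect")
    else:
        smoothed = raw
    eps = 1e-3 * float(raw.mean())
    smoothed = np.maximum(smoothed, eps)
    return IlluminationProfile(
        values=smoothed, window=window, mean=float(smoothed.mean()), channel_nm=channel_nm
    )


def apply_correction(volume: np.ndarray, profile: IlluminationProfile,
                     channel_nm: int | None = None) -> np.ndarray:
    """Divide out the illumination profile: ``out = in · mean(P) / P(y)``.

    The dtype is preserved (with clipping to the integer range for integer
    input); each channel must be corrected only by its own profile, so a
    channel label mismatch is an error.
    """
    if channel_nm is not None and profile.channel_nm is not None and channel_nm != profile.channel_nm:
        raise ValueError(
            f"channel mismatch: volume is {channel_nm} nm, profile is {profile.channel_nm} nm"
        )
    vol = np.asarray(volume)
    y_axis = vol.ndim - 2
    if vol.shape[y_axis] != len(profile.values):
        raise ValueError("profile length does not match volume Y extent")
    shape = [1] * vol.ndim
    shape[y_axis] = len(profile.values)
    gain = (profile.mean / profile.values).reshape(shape)
    out = vol.astype(np.float64) * gain
    if vol.dtype.kind in "ui":
        info = np.iinfo(vol.dtype)
        return np.clip(np.rint(out), info.min, info.max).astype(vol.dtype)
    return out.astype(vol.dtype)
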