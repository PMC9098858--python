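"""Shared fixtures: small phantoms and simulated acquisitions."""

from __future__ import annotations

import numpy as np
import pytest
from scipy.ndimage import binary_erosion, map_coordinates

from lsfmrecon import (
    AcquisitionGeometry,
    PhantomSpec,
    ResliceParams,
    apply_reslice,
    make_phantom,
    simulate_acquisition,
)


@pytest.fixture(scope="session")
def two_row_sim():
    """Noise-free two-row snake acquisition of a textured slab phantom."""
    spec = PhantomSpec(
        slab_size_um=(45.0, 240.0, 100.0),
        voxel_um=1.1,
        n_somata=30,
        n_dendrites=3,
        dendrite_length_um=40.0,
        n_puncta=80,
        penetration_depth_um=150.0,
        rim_peak_amp=0.0,
        background=300.0,
        seed=11,
    )
    vol, truth = make_phantom(spec)
    geom = AcquisitionGeometry(fov_px=(256, 128), n_rows=2, tile_overlap_frac=0.2)
    tiles = simulate_acquisition(vol, truth, geom, seed=101)
    return spec, vol, truth, geom, tiles


@pytest.fixture(scope="session")
def resliced_pair(two_row_sim):
    spec, vol, truth, geom, tiles = two_row_sim
    params = ResliceParams(geom=geom)
    return [apply_reslice(t, params) for t in tiles]


def phantom_oracle(vol, spec, sample_volume, erode=2):
    """Sample the phantom on a resliced volume's grid; returns (oracle, interior mask)."""
    shape = sample_volume.shape
    gz, gy, gx = np.meshgrid(*[np.arange(s) for s in shape], indexing="ij")
    phys = (
        np.stack([gz, gy, gx]).reshape(3, -1) * sample_volume.voxel_um
        + np.asarray(sample_volume.origin_um)[:, None]
    )
    oracle = map_coordinates(
        vol.astype(np.float64), phys / spec.voxel_um, order=1, mode="constant", cval=0.0
    ).reshape(shape)
    interior = binary_erosion(sample_volume.valid_mask(), iterations=erode)
    inside = np.all(
        (phys >= 0) & (phys <= np.asarray(spec.slab_size_um)[:, None]), axis=0
    ).reshape(shape)
    return oracle, interior & inside
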