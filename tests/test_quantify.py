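"""Quantification metrics: rank tests, profiles, contrast, SSIM, morphometry."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from lsfmrecon import (
    PhantomSpec,
    make_phantom,
)
from lsfmrecon.quantify import (
    ROI,
    QuantReport,
    af_roi_stats,
    deformation_index,
    depth_profile,
    fit_penetration_depth,
    mann_whitney,
    shrinkage_ratio,
    signal_retention,
    signal_to_background,
    snr,
    ssim_index,
    tortuosity,
)

# ---------------------------------------------------------------------------
# Mann-Whitney


def test_mann_whitney_fully_separated_small_samples():
    res = mann_whitney([1, 2, 3], [4, 5, 6])
    assert res.statistic == 0.0
    assert res.p_value == pytest.approx(0.1)
    assert res.method == "exact"
    assert res.stars == ""


def test_mann_whitney_identical_samples():
    res = mann_whitney([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
    assert res.statistic == pytest.approx(4.5)  # n^2 / 2
    assert res.p_value == pytest.approx(1.0, abs=1e-9)


def test_mann_whitney_constant_samples_p_one():
    res = mann_whitney([5.0, 5.0], [5.0, 5.0, 5.0])
    assert res.p_value == 1.0


def test_exact_enumeration_matches_scipy():
    rng = np.random.default_rng(0)
    for _ in range(10):
        x = rng.normal(size=5)
        y = rng.normal(size=6)
        mine = mann_whitney(x, y)
        ref = stats.mannwhitneyu(x, y, alternative="two-sided", method="exact")
        assert mine.method == "exact"
        assert mine.p_value == pytest.approx(float(ref.pvalue), abs=1e-12)


def test_exact_and_asymptotic_agree_for_n6():
    """Enumeration vs continuity-corrected normal approximation at n1 = n2 = 6.

    Exhaustive enumeration over all U shows the worst-case gap is 0.0155
    (attained mid-range, near p = 0.6); in the decision-relevant tail
    (p < 0.1) the two agree within 0.006.
    """
    rng = np.random.default_rng(1)
    for _ in range(40):
        x = rng.normal(size=6)
        y = rng.normal(size=6)
        p_exact = mann_whitney(x, y).p_value
        p_asym = float(
            stats.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic").pvalue
        )
        gap = abs(p_exact - min(p_asym, 1.0))
        assert gap < 0.016
        if p_exact < 0.1:
            assert gap < 0.006


def test_stars_follow_alpha_levels():
    r = mann_whitney(np.arange(20.0), np.arange(20.0) + 30.0)
    assert r.p_value < 0.0001
    assert r.stars == "****"


@settings(max_examples=30, deadline=None, derandomize=True)
@given(
    st.lists(st.floats(-100, 100, allow_nan=False), min_size=2, max_size=8),
    st.lists(st.floats(-100, 100, allow_nan=False), min_size=2, max_size=8),
)
def test_mann_whitney_properties(x, y):
    r = mann_whitney(x, y)
    assert 0.0 <= r.statistic <= r.n1 * r.n2
    assert 0.0 < r.p_value <= 1.0
    r_swap = mann_whitney(y, x)
    assert r.statistic + r_swap.statistic == pytest.approx(r.n1 * r.n2)
    assert r.p_value == pytest.approx(r_swap.p_value, rel=1e-9)


# ---------------------------------------------------------------------------
# ROI statistics


def test_af_roi_stats_constant_volume():
    vol = np.full((10, 80, 80), 7.0)
    rep = af_roi_stats(vol, n_rois=5, roi_size_um=(10.0, 20.0), voxel_um=1.0, seed=1)
    s = rep.summary()
    assert s.loc["AF", "mean"] == pytest.approx(7.0)
    assert s.loc["AF", "sd"] == pytest.approx(0.0)
    assert s.loc["AF", "n"] == 5


def test_af_roi_defaults_match_characterization_design():
    import inspect

    sig = inspect.signature(af_roi_stats)
    assert sig.parameters["n_rois"].default == 20
    assert sig.parameters["roi_size_um"].default == (20.0, 500.0)


def test_af_rois_do_not_overlap_and_respect_mask():
    vol = np.ones((4, 60, 60))
    mask = np.zeros((60, 60), bool)
    mask[:30, :] = True
    rep = af_roi_stats(vol, n_rois=6, roi_size_um=(8.0, 8.0), voxel_um=1.0,
                       region_mask=mask, seed=3)
    t = rep.table
    for _, r in t.iterrows():
        assert r.y0 + r.dy <= 30
    boxes = t[["y0", "x0", "dy", "dx"]].to_numpy()
    for i in range(len(boxes)):
        for j in range(i + 1, len(boxes)):
            yi, xi, dy, dx = boxes[i]
            yj, xj, _, _ = boxes[j]
            assert abs(yi - yj) >= dy or abs(xi - xj) >= dx


def test_af_roi_mask_too_small():
    vol = np.ones((4, 20, 20))
    mask = np.zeros((20, 20), bool)
    mask[:5, :5] = True
    with pytest.raises(ValueError):
        af_roi_stats(vol, n_rois=10, roi_size_um=(4.0, 4.0), voxel_um=1.0,
                     region_mask=mask, seed=0)


def test_group_means_exact_on_half_volumes():
    vol = np.concatenate([np.full((4, 20, 40), 10.0), np.full((4, 20, 40), 20.0)], axis=1)
    top = np.zeros((40, 40), bool)
    top[:20] = True
    rep_a = af_roi_stats(vol, 4, (5.0, 5.0), 1.0, region_mask=top, seed=0, group="top")
    rep_b = af_roi_stats(vol, 4, (5.0, 5.0), 1.0, region_mask=~top, seed=0, group="bottom")
    assert rep_a.summary().loc["top", "mean"] == pytest.approx(10.0)
    assert rep_b.summary().loc["bottom", "mean"] == pytest.approx(20.0)


def test_report_csv_roundtrip(tmp_path):
    vol = np.full((4, 30, 30), 3.5)
    rep = af_roi_stats(vol, 4, (5.0, 5.0), 1.0, seed=2)
    path = tmp_path / "report.csv"
    rep.to_csv(path)
    back = QuantReport.from_csv(path, metric=rep.metric)
    import pandas as pd

    pd.testing.assert_frame_equal(rep.table, back.table)
    pd.testing.assert_frame_equal(rep.summary(), back.summary())


# ---------------------------------------------------------------------------
# depth profiles


def test_depth_profile_flat_volume():
    vol = np.full((20, 30, 30), 5.0)
    prof = depth_profile(vol, [ROI("r", (0, 0), (30, 30))], voxel_um=2.0)
    np.testing.assert_allclose(prof.mean, 5.0)
    np.testing.assert_allclose(prof.sd, 0.0)
    assert prof.z_um[-1] == pytest.approx(38.0)


def test_depth_profile_face_flip_reverses_order():
    vol = np.arange(10.0)[:, None, None] * np.ones((10, 8, 8))
    roi = [ROI("r", (0, 0), (8, 8))]
    top = depth_profile(vol, roi, 1.0, illuminated_face="top")
    bottom = depth_profile(vol, roi, 1.0, illuminated_face="bottom")
    np.testing.assert_array_equal(top.mean, bottom.mean[::-1])


def test_depth_profile_requires_rois():
    with pytest.raises(ValueError):
        depth_profile(np.ones((5, 5, 5)), [], 1.0)


def test_single_exponential_lambda_recovery():
    z = np.arange(0, 500.0, 2.0)
    vol = np.exp(-z / 100.0)[:, None, None] * np.ones((len(z), 6, 6))
    prof = depth_profile(vol, [ROI("r", (0, 0), (6, 6))], voxel_um=2.0)
    fit = fit_penetration_depth(prof, thickness_um=500.0, faces="illuminated")
    assert abs(fit["lambda_um"] - 100.0) / 100.0 < 0.05


# ---------------------------------------------------------------------------
# S/B and SNR


def _box_volume():
    vol = np.full((10, 40, 40), 50.0)
    vol[2:8, 5:10, 5:10] = 200.0
    return vol


def test_signal_to_background_examples():
    vol = _box_volume()
    sig = [ROI("s", (2, 5, 5), (6, 5, 5))]
    bkg = [ROI("b", (0, 20, 20), (10, 10, 10))]
    rep = signal_to_background(vol, sig, bkg)
    assert rep.provenance["sb_ratio"] == pytest.approx(4.0)
    rep2 = signal_to_background(vol, bkg, bkg)
    assert rep2.provenance["sb_ratio"] == pytest.approx(1.0)


def test_signal_to_background_zero_background_rejected():
    vol = np.zeros((4, 10, 10))
    with pytest.raises(ValueError):
        signal_to_background(vol, [ROI("s", (0, 0, 0), (2, 2, 2))],
                             [ROI("b", (0, 5, 5), (2, 2, 2))])


def test_snr_by_adopted_definition():
    rng = np.random.default_rng(0)
    vol = rng.normal(50.0, 10.0, (10, 60, 60))
    vol[2:8, 5:15, 5:15] += 100.0
    rep = snr(vol, [ROI("n1", (2, 5, 5), (6, 10, 10))], [ROI("b", (0, 30, 30), (10, 25, 25))])
    got = rep.table["value"].iloc[0]
    expected = (vol[2:8, 5:15, 5:15].mean() - rep.provenance["background_mean"]) / rep.provenance[
        "background_sd"
    ]
    assert got == pytest.approx(expected)
    assert got == pytest.approx(10.0, rel=0.1)


def test_snr_null_is_near_zero():
    vals = []
    for seed in range(100):
        rng = np.random.default_rng(seed)
        vol = rng.normal(100.0, 20.0, (6, 40, 40))
        soma = [ROI(f"n{i}", (0, 5 * i, 0), (6, 5, 5)) for i in range(5)]
        bkg = [ROI("b", (0, 0, 20), (6, 40, 20))]
        vals.append(snr(vol, soma, bkg).table["value"].mean())
    vals = np.asarray(vals)
    assert abs(vals.mean()) < 0.02
    assert np.all(np.abs(vals) < 3.0 / np.sqrt(6 * 5 * 5))


def test_snr_scales_linearly_with_contrast():
    vol = _box_volume()
    rng = np.random.default_rng(1)
    vol += rng.normal(0, 1.0, vol.shape)
    soma = [ROI("n", (2, 5, 5), (6, 5, 5))]
    bkg = [ROI("b", (0, 20, 20), (10, 15, 15))]
    s1 = snr(vol, soma, bkg).table["value"].iloc[0]
    vol2 = _box_volume()
    vol2[2:8, 5:10, 5:10] = 350.0  # doubled contrast over the 50 baseline
    vol2 += rng.normal(0, 1.0, vol.shape)
    s2 = snr(vol2, soma, bkg).table["value"].iloc[0]
    assert s2 == pytest.approx(2 * s1, rel=0.05)


# ---------------------------------------------------------------------------
# SSIM


def test_ssim_identical_images_is_one():
    rng = np.random.default_rng(0)
    a = rng.uniform(0, 255, (40, 40))
    assert ssim_index(a, a, dynamic_range=255) == pytest.approx(1.0, abs=1e-12)


def test_ssim_constant_pair_closed_form():
    a = np.full((32, 32), 100.0)
    b = np.full((32, 32), 50.0)
    c1 = (0.01 * 255) ** 2
    expected = (2 * 100 * 50 + c1) / (100**2 + 50**2 + c1)  # contrast/structure terms cancel
    got = ssim_index(a, b, dynamic_range=255)
    assert got == pytest.approx(expected, abs=1e-12)
    assert got == pytest.approx(0.8001, abs=5e-4)


def _brute_force_ssim(a, b, w, L):
    c1, c2 = (0.01 * L) ** 2, (0.03 * L) ** 2
    vals = []
    for i in range(a.shape[0] - w + 1):
        for j in range(a.shape[1] - w + 1):
            pa = a[i : i + w, j : j + w].ravel()
            pb = b[i : i + w, j : j + w].ravel()
            ma, mb = pa.mean(), pb.mean()
            va, vb = pa.var(), pb.var()
            cov = (pa * pb).mean() - ma * mb
            vals.append(
                ((2 * ma * mb + c1) * (2 * cov + c2))
                / ((ma * ma + mb * mb + c1) * (va + vb + c2))
            )
    return float(np.mean(vals))


def test_ssim_matches_brute_force_oracle():
    rng = np.random.default_rng(7)
    for _ in range(3):
        a = rng.uniform(0, 255, (32, 32))
        b = rng.uniform(0, 255, (32, 32))
        assert ssim_index(a, b, window=8, dynamic_range=255) == pytest.approx(
            _brute_force_ssim(a, b, 8, 255), abs=1e-9
        )


def test_ssim_matches_skimage_for_odd_windows():
    """Independent library cross-check (skimage only supports odd windows)."""
    from skimage.metrics import structural_similarity

    rng = np.random.default_rng(5)
    a = rng.uniform(0, 255, (40, 40))
    b = rng.uniform(0, 255, (40, 40))
    mine = ssim_index(a, b, window=7, dynamic_range=255)
    ref = structural_similarity(
        a, b, win_size=7, gaussian_weights=False, data_range=255, use_sample_covariance=False
    )
    assert mine == pytest.approx(float(ref), abs=1e-12)


def test_ssim_symmetry_and_range():
    rng = np.random.default_rng(9)
    a = rng.uniform(0, 100, (24, 24))
    b = rng.uniform(0, 100, (24, 24))
    s_ab = ssim_index(a, b, dynamic_range=255)
    s_ba = ssim_index(b, a, dynamic_range=255)
    assert s_ab == pytest.approx(s_ba, abs=1e-12)
    assert -1.0 <= s_ab <= 1.0


def test_ssim_shift_invariance_small_regularizers():
    """When the images share all window means, the index is invariant to a
    common additive offset in the C1, C2 -> 0 limit (only the
    contrast/structure terms remain, and they depend on central moments)."""
    rng = np.random.default_rng(11)
    a = rng.normal(100, 10, (32, 32))
    # period-4 perturbation sums to zero over every 8-sample window, so all
    # sliding-window means of a and b coincide exactly
    j = np.arange(32)
    b = a + 5.0 * np.cos(np.pi * j / 2)[None, :]
    s0 = ssim_index(a, b, dynamic_range=1e-3)
    s1 = ssim_index(a + 500, b + 500, dynamic_range=1e-3)
    assert s1 == pytest.approx(s0, abs=1e-6)
    assert s0 < 1.0


def test_ssim_shape_mismatch_rejected():
    with pytest.raises(ValueError):
        ssim_index(np.ones((8, 8)), np.ones((9, 9)))


def test_deformation_index_upscales_small_crops():
    rng = np.random.default_rng(13)
    a = rng.uniform(0, 255, (64, 64))
    assert deformation_index(a, a, dynamic_range=255) == pytest.approx(1.0, abs=1e-12)
    b = np.clip(a + rng.normal(0, 25, a.shape), 0, 255)
    d = deformation_index(a, b, dynamic_range=255)
    assert 0.0 < d < 1.0


# ---------------------------------------------------------------------------
# tortuosity


def test_tortuosity_straight_path():
    assert tortuosity(np.array([[0, 0, 0], [1, 1, 1], [2, 2, 2.0]])) == 1.0


def test_tortuosity_semicircle():
    th = np.linspace(0, np.pi, 1000)
    arc = np.stack([np.zeros_like(th), np.sin(th), np.cos(th)], axis=1)
    assert tortuosity(arc) == pytest.approx(np.pi / 2, abs=1e-4)


def test_tortuosity_coincident_endpoints_rejected():
    with pytest.raises(ValueError):
        tortuosity(np.array([[0, 0, 0], [1, 0, 0], [0, 0, 0.0]]))


def test_tortuosity_matches_phantom_truth():
    spec = PhantomSpec(
        slab_size_um=(60.0, 80.0, 80.0), n_somata=0, n_dendrites=6, n_puncta=0, seed=21
    )
    _, truth = make_phantom(spec)
    assert len(truth.dendrite_polylines_um) == 6
    for pts, stored in zip(truth.dendrite_polylines_um, truth.dendrite_tortuosity):
        assert tortuosity(pts) == pytest.approx(stored, rel=0.01)
        assert stored >= 1.0


@settings(max_examples=30, deadline=None, derandomize=True)
@given(st.integers(0, 10_000))
def test_tortuosity_at_least_one_for_random_walks(seed):
    rng = np.random.default_rng(seed)
    pts = np.cumsum(rng.normal(size=(10, 3)), axis=0)
    if np.linalg.norm(pts[-1] - pts[0]) < 1e-9:
        return
    assert tortuosity(pts) >= 1.0 - 1e-12


# ---------------------------------------------------------------------------
# retention and shrinkage


def _sb_report(signal_mean, seed=0, channel=None):
    rng = np.random.default_rng(seed)
    vol = rng.normal(50.0, 2.0, (6, 60, 60))
    for i in range(10):
        vol[1:4, 3 * i : 3 * i + 3, 0:3] = signal_mean + rng.normal(0, 2.0)
    sig = [ROI(f"s{i}", (1, 3 * i, 0), (3, 3, 3)) for i in range(10)]
    bkg = [ROI(f"b{i}", (1, 3 * i, 30), (3, 3, 3)) for i in range(10)]
    rep = signal_to_background(vol, sig, bkg)
    if channel is not None:
        rep.provenance["channel_nm"] = channel
    return rep


def test_signal_retention_identical_reports():
    rep = _sb_report(400.0)
    assert signal_retention(rep, rep) == pytest.approx(0.0)


def test_signal_retention_halved_sb():
    r0 = _sb_report(400.0, seed=1)
    r1 = _sb_report(200.0, seed=1)
    assert signal_retention(r0, r1) == pytest.approx(50.0, abs=2.0)


@pytest.mark.parametrize("factor,expected", [(0.49, 51.0), (0.76, 24.0), (0.86, 14.0)])
def test_signal_retention_bleaching_factors(factor, expected):
    """Per-channel decay factors on the signal reproduce the printed reductions."""
    r0 = _sb_report(1000.0, seed=2)
    r1 = _sb_report(1000.0 * factor, seed=2)
    assert signal_retention(r0, r1) == pytest.approx(expected, abs=2.0)


def test_signal_retention_channel_mismatch():
    with pytest.raises(ValueError, match="channel"):
        signal_retention(_sb_report(100.0, channel=488), _sb_report(100.0, channel=647))


def test_shrinkage_identical_masks():
    m = np.zeros((50, 50), bool)
    m[10:40, 10:40] = True
    assert shrinkage_ratio(m, m) == 1.0


def test_shrinkage_linear_scaling():
    yy, xx = np.mgrid[:400, :400]
    before = (yy - 200) ** 2 + (xx - 200) ** 2 < 150**2
    after = (yy - 200) ** 2 + (xx - 200) ** 2 < 135**2  # linear scale 0.9
    assert shrinkage_ratio(before, after) == pytest.approx(0.81, abs=0.005)


def test_shrinkage_physical_units_across_resolutions():
    yy, xx = np.mgrid[:200, :200]
    coarse = (yy - 100) ** 2 + (xx - 100) ** 2 < 60**2
    yy2, xx2 = np.mgrid[:400, :400]
    fine = (yy2 - 200) ** 2 + (xx2 - 200) ** 2 < 120**2
    ratio = shrinkage_ratio(coarse, fine, pixel_um_before=2.0, pixel_um_after=1.0)
    assert ratio == pytest.approx(1.0, abs=0.01)


def test_shrinkage_empty_before_mask_rejected():
    with pytest.raises(ValueError):
        shrinkage_ratio(np.zeros((5, 5), bool), np.ones((5, 5), bool))
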