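"""Feature extraction: GLCM/LBP oracles, stain channels, stats, geometry."""

import math

import numpy as np
import pytest
from skimage.draw import polygon as draw_polygon

from lbcquant import (
    GLCMParams,
    SlideCase,
    geometry_features,
    glcm_features,
    glcm_features_normalized,
    intensity_stats,
    lbp_features,
    resample_roi,
    stain_channels,
)
from lbcquant.detect import ClusterAnnotation
from lbcquant.features import GLCM_FEATURE_NAMES

from conftest import oracle_glcm_features, oracle_lbp_codes


def _ann(poly, cluster_id="c0"):
    poly = np.asarray(poly, dtype=float)
    return ClusterAnnotation(cluster_id, poly, 0.0, 0.0)


# ----------------------------------------------------------------------- GLCM


def test_glcm_constant_patch_degeneracies():
    patch = np.full((5, 5), 100.0)
    f = glcm_features(patch)
    assert f["contrast"] == 0.0
    assert f["energy"] == 1.0
    assert f["entropy"] == 0.0
    assert f["homogeneity"] == 1.0
    assert f["correlation"] == 0.0  # zero marginal SD convention


def test_glcm_two_level_hand_example():
    """2x2 checker columns at 2 gray levels, horizontal offset only:
    p = {(0,1): 1/2, (1,0): 1/2} by direct pair enumeration."""
    patch = np.array([[0.0, 255.0], [0.0, 255.0]])
    params = GLCMParams(levels=2, distance=1, angles=((0, 1),))
    f = glcm_features(patch, None, params)
    assert f["contrast"] == pytest.approx(1.0)
    assert f["energy"] == pytest.approx(0.5)
    assert f["entropy"] == pytest.approx(1.0)
    assert f["homogeneity"] == pytest.approx(0.5)


def test_glcm_matches_bruteforce_oracle(rng):
    params = GLCMParams(levels=8, distance=1)
    for _ in range(25):
        patch = rng.integers(0, 256, size=(8, 8)).astype(float)
        mask = rng.random((8, 8)) < 0.8
        got = glcm_features(patch, mask, params)
        exp = oracle_glcm_features(patch, mask, levels=8)
        if exp is None:
            assert all(np.isnan(v) for v in got.values())
            continue
        for name in GLCM_FEATURE_NAMES:
            assert got[name] == pytest.approx(exp[name], abs=1e-10), name


def test_glcm_no_valid_pair_is_missing():
    mask = np.zeros((4, 4), dtype=bool)
    mask[0, 0] = True  # a single masked pixel has no co-occurring partner
    f = glcm_features(np.ones((4, 4)) * 50, mask)
    assert all(np.isnan(v) for v in f.values())


def test_normalized_identity_on_full_range_patch(rng):
    patch = rng.integers(0, 256, size=(8, 8)).astype(float)
    patch[0, 0], patch[-1, -1] = 0.0, 255.0
    raw = glcm_features(patch)
    norm = glcm_features_normalized(patch)
    for name in GLCM_FEATURE_NAMES:
        assert norm[f"normalized_{name}"] == pytest.approx(raw[name], abs=1e-12)


@pytest.mark.parametrize("a,b", [(2.0, 10.0), (0.5, -20.0), (4.0, 37.0)])
def test_normalized_affine_invariance(rng, a, b):
    """normalized_* features are invariant to v -> a*v + b (a > 0);
    power-of-two gains keep the min-max rescale bitwise quantization-safe."""
    for _ in range(10):
        patch = rng.integers(0, 200, size=(8, 8)).astype(float)
        base = glcm_features_normalized(patch)
        mapped = glcm_features_normalized(a * patch + b)
        for name in GLCM_FEATURE_NAMES:
            assert mapped[f"normalized_{name}"] == pytest.approx(
                base[f"normalized_{name}"], abs=1e-9
            )


def test_normalized_constant_patch_degenerates_like_raw():
    patch = np.full((4, 4), 77.0)
    f = glcm_features_normalized(patch)
    assert f["normalized_contrast"] == 0.0
    assert f["normalized_energy"] == 1.0


# ------------------------------------------------------------------------ LBP


def test_lbp_constant_patch():
    f = lbp_features(np.full((5, 5), 42.0))
    assert f["lbp_mean"] == 255.0
    assert f["lbp_sd"] == 0.0
    assert f["lbp_entropy"] == 0.0


def test_lbp_strict_center_maximum():
    patch = np.full((3, 3), 99.0)
    patch[1, 1] = 100.0
    f = lbp_features(patch)
    assert f["lbp_mean"] == 0.0


def test_lbp_matches_bruteforce_oracle(rng):
    for _ in range(25):
        patch = rng.integers(0, 256, size=(6, 6)).astype(float)
        mask = rng.random((6, 6)) < 0.85
        got = lbp_features(patch, mask)
        codes = oracle_lbp_codes(patch, mask)
        if not codes:
            assert math.isnan(got["lbp_mean"])
            continue
        assert got["lbp_mean"] == pytest.approx(np.mean(codes))
        expected_sd = np.std(codes, ddof=1) if len(codes) > 1 else 0.0
        assert got["lbp_sd"] == pytest.approx(expected_sd)
        hist = np.bincount(codes, minlength=256) / len(codes)
        nz = hist[hist > 0]
        assert got["lbp_entropy"] == pytest.approx(-(nz * np.log2(nz)).sum())


# -------------------------------------------------------------- stain channels


def test_stain_channels_white_pixel():
    ch = stain_channels(np.array([[[255.0, 255.0, 255.0]]]))
    assert ch["od_sum"][0, 0] == pytest.approx(0.0, abs=1e-5)
    assert ch["hematoxylin"][0, 0] == pytest.approx(0.0, abs=1e-5)
    assert ch["residual"][0, 0] == pytest.approx(0.0, abs=1e-5)
    assert ch["saturation"][0, 0] == 0.0
    assert ch["brightness"][0, 0] == 1.0


def test_stain_channels_pure_red_hexcone():
    ch = stain_channels(np.array([[[255.0, 0.0, 0.0]]]))
    assert ch["hue"][0, 0] == 0.0
    assert ch["saturation"][0, 0] == 1.0
    assert ch["brightness"][0, 0] == 1.0


def test_hue_wraps_near_red():
    a = stain_channels(np.array([[[255.0, 0.0, 0.0]]]))["hue"][0, 0]
    b = stain_channels(np.array([[[255.0, 1.0, 1.0]]]))["hue"][0, 0]
    assert min(abs(a - b), 1 - abs(a - b)) < 0.01


def test_residual_zero_for_pixel_parallel_to_stain_vector():
    h = np.array([0.651, 0.701, 0.290])
    h = h / np.linalg.norm(h)
    od = 0.5 * h
    rgb = 255.0 * 10.0 ** (-od) - 1e-6 * 255.0
    ch = stain_channels(rgb.reshape(1, 1, 3))
    assert ch["residual"][0, 0] == pytest.approx(0.0, abs=1e-9)
    assert ch["hematoxylin"][0, 0] == pytest.approx(0.5, abs=1e-9)


# ------------------------------------------------------------- intensity stats


def test_intensity_stats_single_value():
    s = intensity_stats(np.array([5.0]))
    assert s == {"mean": 5.0, "sd": 0.0, "min": 5.0, "max": 5.0, "median": 5.0}


def test_intensity_stats_hand_example():
    s = intensity_stats(np.array([1.0, 2.0, 3.0, 4.0]))
    assert s["mean"] == 2.5
    assert s["sd"] == pytest.approx(math.sqrt(5.0 / 3.0))
    assert s["median"] == 2.5


def test_intensity_stats_ordering(rng):
    for _ in range(20):
        v = rng.normal(size=rng.integers(1, 30))
        s = intensity_stats(v)
        assert s["min"] <= s["median"] <= s["max"]
        assert s["min"] <= s["mean"] <= s["max"]


# --------------------------------------------------------------------- geometry


def test_geometry_square():
    ann = _ann([[0, 0], [10, 0], [10, 10], [0, 10]])
    g = geometry_features(ann, mpp=0.5)
    assert g["area_um2"] == pytest.approx(25.0)
    assert g["length_um"] == pytest.approx(20.0)


def test_geometry_similarity_scaling(rng):
    poly = rng.random((6, 2)) * 50
    hull_poly = poly[np.argsort(np.arctan2(*(poly - poly.mean(0)).T[::-1]))]
    g1 = geometry_features(_ann(hull_poly), 1.0)
    g2 = geometry_features(_ann(hull_poly * 3.0), 1.0)
    assert g2["area_um2"] == pytest.approx(9 * g1["area_um2"])
    assert g2["length_um"] == pytest.approx(3 * g1["length_um"])


def test_geometry_rejects_degenerate_polygon():
    with pytest.raises(ValueError):
        geometry_features(_ann([[0, 0], [1, 1]]), 1.0)


def test_shoelace_matches_raster_area(rng):
    """Shoelace area of a random convex polygon agrees with its pixel
    rasterization within 5%."""
    pts = rng.random((12, 2)) * 80 + 10
    center = pts.mean(axis=0)
    hull = pts[np.argsort(np.arctan2(*(pts - center).T[::-1]))]
    g = geometry_features(_ann(hull), 1.0)
    rr, cc = draw_polygon(hull[:, 1], hull[:, 0], shape=(120, 120))
    assert abs(g["area_um2"] - rr.size) / rr.size < 0.05


# ------------------------------------------------------------------ ROI patches


def _case_with_gradient(mpp):
    img = np.zeros((120, 120, 3), dtype=np.uint8)
    img[..., 0] = np.linspace(0, 255, 120, dtype=np.uint8)[None, :]
    return SlideCase("g", img, mpp, "normal", False)


def test_resample_identity_at_target_mpp():
    case = _case_with_gradient(2.0)
    ann = _ann([[10, 10], [60, 10], [60, 60], [10, 60]])
    patch, mask = resample_roi(case, ann, target_mpp=2.0)
    assert patch.shape[:2] == (50, 50)
    np.testing.assert_allclose(patch, case.image[10:60, 10:60].astype(float))


def test_resample_quarter_scale():
    case = _case_with_gradient(0.5)
    ann = _ann([[0, 0], [100, 0], [100, 100], [0, 100]])
    patch, _ = resample_roi(case, ann, target_mpp=2.0)
    assert patch.shape[:2] == (25, 25)


def test_resample_degenerate_polygon_forces_center_pixel():
    case = _case_with_gradient(2.0)
    ann = _ann([[5.0, 5.0], [5.2, 5.0], [5.2, 5.2]])
    _, mask = resample_roi(case, ann, target_mpp=2.0)
    assert mask.sum() >= 1


def test_resample_out_of_bounds_raises():
    case = _case_with_gradient(1.0)
    ann = _ann([[100, 100], [200, 100], [200, 200]])
    with pytest.raises(ValueError):
        resample_roi(case, ann)
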