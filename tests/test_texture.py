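import numpy as np
import pytest
from scipy import stats

from hippotex.texture import (RoiVolume, DiscretizedRoi, trim_extremes,
                              znormalize, discretize, volume_mm3,
                              first_order_features, compute_glcm,
                              glcm_features, compute_glrlm, glrlm_features,
                              extract_features, extract_all, GLRLM_DIRECTIONS)
from conftest import brute_glcm, brute_runs


# ---------------------------------------------------------------------------
# preprocessing
# ---------------------------------------------------------------------------

def test_trim_removes_only_planted_extreme():
    rng = np.random.default_rng(0)
    vals = rng.normal(0, 1, 1000)
    mu, sd = vals.mean(), vals.std()
    vals[500] = mu + 5 * sd
    roi = RoiVolume(vals.reshape(10, 10, 10), np.ones((10, 10, 10), bool))
    # oracle: recompute the rule directly
    mu2, sd2 = vals.mean(), vals.std()
    expected_removed = int((np.abs(vals - mu2) > 3 * sd2).sum())
    out, n = trim_extremes(roi)
    assert n == expected_removed
    assert not out.mask.reshape(-1)[500]


def test_trim_no_extremes_leaves_mask():
    # uniform values are bounded well inside mu +/- 3 sd
    rng = np.random.default_rng(2)
    roi = RoiVolume(rng.uniform(0, 1, (6, 6, 6)), np.ones((6, 6, 6), bool))
    out, n = trim_extremes(roi)
    assert n == 0
    np.testing.assert_array_equal(out.mask, roi.mask)


def test_trim_constant_roi_unchanged():
    roi = RoiVolume(np.full((4, 4, 4), 3.0), np.ones((4, 4, 4), bool))
    out, n = trim_extremes(roi)
    assert n == 0


def test_znormalize_moments(random_roi):
    out = znormalize(random_roi)
    assert out.values.mean() == pytest.approx(0.0, abs=1e-10)
    assert out.values.std() == pytest.approx(1.0, abs=1e-10)


def test_znormalize_shift_scale_invariance(random_roi):
    base = znormalize(random_roi).values
    shifted = RoiVolume(random_roi.intensities + 7.0, random_roi.mask)
    scaled = RoiVolume(random_roi.intensities * 3.5, random_roi.mask)
    np.testing.assert_allclose(znormalize(shifted).values, base, atol=1e-10)
    np.testing.assert_allclose(znormalize(scaled).values, base, atol=1e-10)


def test_znormalize_degenerate_errors():
    roi = RoiVolume(np.full((3, 3, 3), 1.0), np.ones((3, 3, 3), bool))
    with pytest.raises(ValueError, match="degenerate"):
        znormalize(roi)


def test_discretize_closed_form_uniform_grid():
    vals = np.linspace(0.0, 1.0, 64).reshape(4, 4, 4)
    roi = RoiVolume(vals, np.ones((4, 4, 4), bool))
    d = discretize(roi, g_levels=32)
    expected = np.clip(np.ceil(32 * vals.ravel()), 1, 32)
    np.testing.assert_array_equal(d.levels.ravel(), expected)


def test_discretize_two_level():
    vals = np.full((3, 3, 3), 1.0)
    vals[0, 0, 0] = 1.001
    roi = RoiVolume(vals, np.ones((3, 3, 3), bool))
    d = discretize(roi, 32)
    occupied = np.unique(d.levels)
    np.testing.assert_array_equal(occupied, [1, 32])


def test_discretize_histogram_matches_explicit_edges(random_roi):
    g = 16
    d = discretize(random_roi, g)
    v = random_roi.values
    edges = np.linspace(v.min(), v.max(), g + 1)
    counts = np.histogram(v, bins=edges)[0]
    ours = np.bincount(d.levels[d.mask], minlength=g + 1)[1:]
    np.testing.assert_array_equal(ours, counts)


def test_discretize_zero_range_errors():
    roi = RoiVolume(np.zeros((3, 3, 3)), np.ones((3, 3, 3), bool))
    with pytest.raises(ValueError):
        discretize(roi)


# ---------------------------------------------------------------------------
# first-order
# ---------------------------------------------------------------------------

def test_first_order_on_znormalized(random_roi):
    f = first_order_features(znormalize(random_roi))
    assert f["fo_mean"] == pytest.approx(0.0, abs=1e-10)
    assert f["fo_sd"] == pytest.approx(1.0, abs=1e-10)


def test_first_order_constant_entropy_zero():
    roi = RoiVolume(np.full((3, 3, 3), 2.0), np.ones((3, 3, 3), bool))
    f = first_order_features(roi)
    assert f["fo_entropy"] == 0.0
    assert f["fo_range"] == 0.0


def test_first_order_moment_formula_oracle():
    rng = np.random.default_rng(8)
    v = rng.normal(3, 2, 100)
    roi = RoiVolume(v.reshape(4, 5, 5), np.ones((4, 5, 5), bool))
    f = first_order_features(roi)
    m = v - v.mean()
    skew = (m**3).mean() / (m**2).mean() ** 1.5
    kurt = (m**4).mean() / (m**2).mean() ** 2
    assert f["fo_skewness"] == pytest.approx(skew, abs=1e-10)
    assert f["fo_kurtosis"] == pytest.approx(kurt, abs=1e-10)
    assert f["fo_energy"] == pytest.approx((v**2).sum(), rel=1e-12)


# ---------------------------------------------------------------------------
# GLCM
# ---------------------------------------------------------------------------

def _random_droi(seed, shape=(3, 3, 3), g=4):
    rng = np.random.default_rng(seed)
    mask = rng.random(shape) > 0.2
    if not mask.any():
        mask[0, 0, 0] = True
    levels = np.zeros(shape, dtype=np.int32)
    levels[mask] = rng.integers(1, g + 1, mask.sum())
    return DiscretizedRoi(levels, mask, g)


@pytest.mark.parametrize("seed", range(5))
def test_glcm_equals_bruteforce(seed):
    d = _random_droi(seed)
    ours = compute_glcm(d)
    ref = brute_glcm(d.levels, d.mask, d.g)
    np.testing.assert_allclose(ours, ref, rtol=1e-12, atol=1e-14)


def test_glcm_symmetric_and_sums_to_one(textured_roi):
    d = discretize(znormalize(textured_roi), 8)
    m = compute_glcm(d)
    assert m.sum() == pytest.approx(1.0, abs=1e-12)
    np.testing.assert_allclose(m, m.T, atol=1e-14)


def test_glcm_constant_roi_single_entry():
    levels = np.full((4, 4, 4), 3, dtype=np.int32)
    d = DiscretizedRoi(levels, np.ones((4, 4, 4), bool), 4)
    m = compute_glcm(d)
    assert m[2, 2] == pytest.approx(1.0)
    assert m.sum() == pytest.approx(1.0)


def test_glcm_features_closed_forms():
    diag = np.diag([0.25, 0.25, 0.25, 0.25])
    f = glcm_features(diag)
    assert f["glcm_contrast"] == 0.0
    uniform = np.full((4, 4), 1 / 16)
    f = glcm_features(uniform)
    assert f["glcm_entropy"] == pytest.approx(4.0, abs=1e-12)


def test_glcm_features_formula_oracle():
    rng = np.random.default_rng(1)
    m = rng.random((4, 4))
    m = (m + m.T)
    m /= m.sum()
    f = glcm_features(m)
    g = 4
    tot_c = tot_d = tot_h = tot_e = tot_ac = 0.0
    for i in range(g):
        for j in range(g):
            p = m[i, j]
            tot_c += p * (i - j) ** 2
            tot_d += p * abs(i - j)
            tot_h += p / (1 + abs(i - j))
            tot_ac += p * (i + 1) * (j + 1)
            if p > 0:
                tot_e -= p * np.log2(p)
    assert f["glcm_contrast"] == pytest.approx(tot_c, abs=1e-12)
    assert f["glcm_dissimilarity"] == pytest.approx(tot_d, abs=1e-12)
    assert f["glcm_homogeneity"] == pytest.approx(tot_h, abs=1e-12)
    assert f["glcm_entropy"] == pytest.approx(tot_e, abs=1e-12)
    assert f["glcm_autocorrelation"] == pytest.approx(tot_ac, abs=1e-12)


# ---------------------------------------------------------------------------
# GLRLM
# ---------------------------------------------------------------------------

def test_glrlm_single_line_one_run():
    levels = np.ones((1, 1, 8), dtype=np.int32)
    mask = np.ones((1, 1, 8), bool)
    mats = compute_glrlm(DiscretizedRoi(levels, mask, 2))
    axial = mats[(0, 0, 1)]
    assert axial.shape[1] == 8
    assert axial[0, 7] == 1 and axial.sum() == 1
    # perpendicular directions see 8 runs of length 1
    assert mats[(1, 0, 0)].sum() == 8


def test_glrlm_alternating_line_sre_one():
    levels = np.array([[[1, 2, 1, 2, 1, 2, 1, 2]]], dtype=np.int32)
    mask = np.ones((1, 1, 8), bool)
    mats = compute_glrlm(DiscretizedRoi(levels, mask, 2))
    feats = glrlm_features({(0, 0, 1): mats[(0, 0, 1)]}, 8)
    assert feats["glrlm_sre"] == pytest.approx(1.0)
    assert feats["glrlm_rp"] == pytest.approx(1.0)


@pytest.mark.parametrize("seed", range(4))
def test_glrlm_equals_bruteforce(seed):
    d = _random_droi(seed + 50, shape=(4, 4, 4), g=4)
    mats = compute_glrlm(d)
    for direction in GLRLM_DIRECTIONS:
        ref = brute_runs(d.levels, d.mask, d.g, np.array(direction))
        ours = mats[direction]
        assert ours.shape == ref.shape
        np.testing.assert_array_equal(ours, ref)


# ---------------------------------------------------------------------------
# full extraction
# ---------------------------------------------------------------------------

def test_extract_all_identical_hemispheres_equals_single(textured_roi):
    pair = extract_all(textured_roi, textured_roi)
    single = extract_features(textured_roi)
    for k in single.index:
        assert pair[k] == pytest.approx(single[k], rel=1e-12)


def test_extract_all_left_right_symmetric(textured_roi, random_roi):
    a = extract_all(textured_roi, random_roi)
    b = extract_all(random_roi, textured_roi)
    np.testing.assert_allclose(a.to_numpy(), b.to_numpy(), rtol=1e-12)


def test_extract_all_missing_hemisphere_policy(textured_roi):
    with pytest.raises(ValueError, match="hemisphere"):
        extract_all(textured_roi, None)
    vec = extract_all(textured_roi, None, allow_single=True)
    assert vec["single_hemisphere"] == 1.0


def test_volume_uses_true_voxel_volume():
    mask = np.zeros((6, 6, 6), bool)
    mask[1:5, 1:5, 1:5] = True
    roi = RoiVolume(np.random.default_rng(0).normal(size=(6, 6, 6)), mask,
                    spacing=(0.5, 1.0, 2.0))
    assert volume_mm3(roi) == pytest.approx(64 * 0.5 * 1.0 * 2.0)


def test_features_invariant_to_affine_rescale(textured_roi):
    f1 = extract_features(textured_roi)
    rescaled = RoiVolume(textured_roi.intensities * 2.5 - 40.0,
                         textured_roi.mask, textured_roi.spacing)
    f2 = extract_features(rescaled)
    np.testing.assert_allclose(f1.to_numpy(), f2.to_numpy(), rtol=1e-9,
                               atol=1e-9)


def test_extraction_deterministic(textured_roi):
    f1 = extract_features(textured_roi)
    f2 = extract_features(textured_roi)
    assert f1.equals(f2)


def test_too_small_roi_rejected():
    roi = RoiVolume(np.random.default_rng(0).normal(size=(3, 3, 3)),
                    np.pad(np.ones((2, 2, 2), bool), (0, 1)))
    with pytest.raises(ValueError, match="too small"):
        extract_features(roi)
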