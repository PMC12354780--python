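"""Preprocessing: normalization, grayscale, denoising, augmentation, splits."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from uigo import prep
from uigo.phantom_forge import PhantomSpec, forge_sample


# -- min-max / grayscale / z-score --------------------------------------------

def test_min_max_normalize_examples():
    out = prep.min_max_normalize(np.array([[2.0, 6.0, 10.0]]))
    assert np.allclose(out, [[0.0, 0.5, 1.0]])
    assert np.all(prep.min_max_normalize(np.full((4, 4), 5.0)) == 0.0)


def test_min_max_normalize_attains_unit_range_and_is_idempotent(rng):
    img = rng.normal(size=(8, 8))
    out = prep.min_max_normalize(img)
    assert out.min() == 0.0 and out.max() == 1.0
    assert np.allclose(prep.min_max_normalize(out), out)


def test_to_grey_luma_coefficients():
    ones = np.ones((2, 2))
    zeros = np.zeros((2, 2))
    assert np.allclose(prep.to_grey(np.stack([ones, ones, ones], 2)), 1.0)
    assert np.allclose(prep.to_grey(np.stack([ones, zeros, zeros], 2)), 0.299)
    assert np.allclose(prep.to_grey(np.stack([zeros, ones, zeros], 2)), 0.587)
    assert np.allclose(prep.to_grey(np.stack([zeros, zeros, ones], 2)), 0.114)
    with pytest.raises(ValueError, match="3"):
        prep.to_grey(np.zeros((4, 4, 2)))


def test_zscore_standardizes_and_handles_degenerate_input(rng):
    img = rng.normal(loc=3.0, scale=2.0, size=(16, 16))
    out = prep.zscore(img)
    assert abs(out.mean()) < 1e-9 and abs(out.std() - 1.0) < 1e-9
    assert np.allclose(prep.zscore(np.array([[0.0, 2.0]])), [[-1.0, 1.0]])
    assert np.all(prep.zscore(np.full((3, 3), 4.0)) == 0.0)


# -- bilateral / gaussian ------------------------------------------------------

def brute_force_bilateral(img, p):
    """Double-loop oracle over all window pixel pairs, reflect padding."""
    rad = p.radius()
    padded = np.pad(img, rad, mode="reflect")
    out = np.zeros_like(img)
    for y in range(img.shape[0]):
        for x in range(img.shape[1]):
            acc = norm = 0.0
            for dy in range(-rad, rad + 1):
                for dx in range(-rad, rad + 1):
                    v = padded[y + rad + dy, x + rad + dx]
                    w = (np.exp(-(dy ** 2 + dx ** 2) / (2 * p.sigma_s ** 2))
                         * np.exp(-(v - img[y, x]) ** 2 / (2 * p.sigma_r ** 2)))
                    acc += w * v
                    norm += w
            out[y, x] = acc / norm
    return out


def test_bilateral_constant_image_is_fixed_point():
    img = np.full((8, 8), 0.3)
    out = prep.bilateral(img, prep.BilateralParams(1.0, 0.1))
    assert np.allclose(out, img)


def test_bilateral_matches_brute_force_oracle(rng):
    img = rng.random((16, 16))
    p = prep.BilateralParams(sigma_s=1.2, sigma_r=0.15)
    assert np.max(np.abs(prep.bilateral(img, p) - brute_force_bilateral(img, p))) < 1e-6


def test_bilateral_wide_range_kernel_reduces_to_gaussian_blur(rng):
    img = rng.random((12, 12))
    p = prep.BilateralParams(sigma_s=1.5, sigma_r=1e6)
    blurred = prep.gaussian_blur(img, 1.5)
    assert np.max(np.abs(prep.bilateral(img, p) - blurred)) < 1e-6


def test_bilateral_output_is_convex_combination_of_window(rng):
    img = rng.random((10, 10))
    p = prep.BilateralParams(sigma_s=1.0, sigma_r=0.2)
    out = prep.bilateral(img, p)
    rad = p.radius()
    padded = np.pad(img, rad, mode="reflect")
    for y in range(10):
        for x in range(10):
            window = padded[y:y + 2 * rad + 1, x:x + 2 * rad + 1]
            assert window.min() - 1e-12 <= out[y, x] <= window.max() + 1e-12


def test_bilateral_rejects_bad_sigmas():
    with pytest.raises(ValueError, match="sigma"):
        prep.bilateral(np.zeros((4, 4)), prep.BilateralParams(sigma_s=-1.0, sigma_r=0.1))


def test_gaussian_blur_impulse_peak_and_mass_conservation():
    img = np.zeros((9, 9))
    img[4, 4] = 1.0
    out = prep.gaussian_blur(img, 1.0)
    # closed-form peak of the normalized discrete kernel over radius 2
    offsets = np.arange(-2, 3)
    k1 = np.exp(-offsets ** 2 / 2.0)
    k1 /= k1.sum()
    assert out[4, 4] == pytest.approx(k1[2] ** 2, abs=1e-6)
    assert out.sum() == pytest.approx(1.0, abs=1e-6)
    assert np.allclose(prep.gaussian_blur(np.full((5, 5), 2.0), 1.0), 2.0)
    with pytest.raises(ValueError, match="sigma"):
        prep.gaussian_blur(img, 0.0)


# -- augmentation --------------------------------------------------------------

@pytest.fixture()
def tumor_sample():
    return forge_sample(PhantomSpec(n_tumors=(1, 2), seed=21))


def test_rotation_by_180_twice_is_identity(tumor_sample):
    plan = prep.AugmentationPlan()
    img1, msk1 = prep.rotate_sample(tumor_sample, 180.0, plan)
    once = type(tumor_sample)(image=img1, label_map=msk1)
    img2, msk2 = prep.rotate_sample(once, 180.0, plan)
    assert np.array_equal(msk2, tumor_sample.label_map)
    assert np.allclose(img2, tumor_sample.image)


def test_flips_preserve_class_pixel_counts(tumor_sample):
    flipped = tumor_sample.label_map[:, ::-1]
    for cls in (0, 1, 2):
        assert (flipped == cls).sum() == (tumor_sample.label_map == cls).sum()


def test_oblique_rotation_changes_counts_by_less_than_5pct_of_liver(tumor_sample):
    plan = prep.AugmentationPlan()
    _, msk = prep.rotate_sample(tumor_sample, 80.0, plan)
    liver_area = (tumor_sample.label_map >= 1).sum()
    for cls in (1, 2):
        before = (tumor_sample.label_map == cls).sum()
        after = (msk == cls).sum()
        assert abs(int(after) - int(before)) < 0.05 * liver_area


def test_augment_applies_identical_geometry_to_image_and_mask(tumor_sample):
    plan = prep.AugmentationPlan(rotations=(90.0,), hflip=True, vflip=False,
                                 apply_probability=1.0)
    variants = prep.augment(tumor_sample, plan, seed=0)
    rot = variants[0]
    assert np.array_equal(rot.label_map, np.rot90(tumor_sample.label_map))
    assert np.allclose(rot.image, np.rot90(tumor_sample.image))
    assert all(set(np.unique(v.label_map)) <= {0, 1, 2} for v in variants)


def test_augment_rejects_unlisted_rotation(tumor_sample):
    plan = prep.AugmentationPlan(rotations=(90.0,))
    with pytest.raises(ValueError, match="rotation"):
        prep.rotate_sample(tumor_sample, 45.0, plan)


# -- splits --------------------------------------------------------------------

@pytest.mark.parametrize("n,expected", [
    (201, (141, 40, 20)),
    (6407, (4485, 1281, 641)),
    (2658, (1860, 532, 266)),
    (2187, (1531, 437, 219)),
    (10, (7, 2, 1)),
])
def test_split_counts_reproduce_published_70_20_10_rows(n, expected):
    assert prep.split_counts(n) == expected


@settings(max_examples=200, deadline=None)
@given(st.integers(min_value=3, max_value=10 ** 6))
def test_split_counts_conserve_n(n):
    assert sum(prep.split_counts(n)) == n


def test_split_ratios_validation():
    with pytest.raises(ValueError):
        prep.SplitRatios(0.5, 0.5, 0.2)
    with pytest.raises(ValueError):
        prep.SplitRatios(1.0, 0.0, 0.0)


def test_assign_splits_partition_and_determinism(phantom_manifest):
    m = phantom_manifest
    assert set(m["split"]) == {"train", "val", "test"}
    n_train, n_val, n_test = prep.split_counts(len(m))
    assert (m["split"] == "train").sum() == n_train
    assert (m["split"] == "val").sum() == n_val
    assert (m["split"] == "test").sum() == n_test
    again = prep.assign_splits(m.drop(columns="split").assign(split=""), seed=42)
    assert list(again["split"]) == list(m["split"])
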