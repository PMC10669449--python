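"""Phantom generation and augmentation: determinism, geometry, splits."""

import numpy as np
import pytest

from dafdnet.metrics import dice
from dafdnet.phantom import (AugmentSpec, PhantomSpec, augment, generate_phantom,
                             make_dataset, transform_like)

FIXED_GEOM = dict(roi_center=(32.0, 34.0), roi_axes=(20.0, 12.0), roi_angle=0.2,
                  crack_orientation=1.1, background_scale=8.0)


def test_same_seed_is_bit_identical():
    a = generate_phantom(PhantomSpec(image_size=64, seed=11))
    b = generate_phantom(PhantomSpec(image_size=64, seed=11))
    np.testing.assert_array_equal(a.image, b.image)
    np.testing.assert_array_equal(a.roi_mask, b.roi_mask)
    np.testing.assert_array_equal(a.fracture_mask, b.fracture_mask)
    assert a.meta == b.meta


def test_different_seeds_differ():
    a = generate_phantom(PhantomSpec(image_size=64, seed=1))
    b = generate_phantom(PhantomSpec(image_size=64, seed=2))
    assert not np.array_equal(a.image, b.image)


def test_zero_contrast_leaves_image_untouched_but_mask_present():
    import dataclasses
    base = PhantomSpec(image_size=64, seed=3, noise_sd=0.0, **FIXED_GEOM)
    invisible = generate_phantom(dataclasses.replace(base, crack_contrast=0.0))
    visible = generate_phantom(dataclasses.replace(base, crack_contrast=0.2))
    assert invisible.fracture_mask.any()
    np.testing.assert_array_equal(invisible.fracture_mask, visible.fracture_mask)
    # the two renders differ only where the crack was drawn (soft support)
    diff = np.abs(invisible.image - visible.image) > 1e-6
    from scipy.ndimage import binary_dilation
    support = binary_dilation(visible.fracture_mask, structure=np.ones((3, 3)),
                              iterations=3)
    assert diff.any() and not (diff & ~support).any()


def test_roi_brighter_than_background(phantom64):
    spec = PhantomSpec(image_size=64, seed=7)
    inside = phantom64.image[phantom64.roi_mask].mean()
    outside = phantom64.image[~phantom64.roi_mask].mean()
    assert inside - outside >= spec.brightness_margin


def test_crack_confined_to_roi(phantom64):
    assert phantom64.fracture_mask.any()
    assert not (phantom64.fracture_mask & ~phantom64.roi_mask).any()


@pytest.mark.parametrize("bad", [
    dict(crack_width=4),
    dict(crack_contrast=0.7),
    dict(image_size=8),
    dict(noise_sd=-0.1),
])
def test_invalid_specs_rejected(bad):
    with pytest.raises(ValueError):
        generate_phantom(PhantomSpec(**bad))


class TestAugment:
    def test_variant_count(self, phantom64):
        assert len(augment(phantom64, AugmentSpec(n_variants=5, seed=0))) == 5

    def test_identity_transform_preserves_record(self, phantom64):
        spec = AugmentSpec(rotation_range=(0.0, 0.0), scale_factor=1.0,
                           n_variants=2, seed=0)
        for v in augment(phantom64, spec):
            np.testing.assert_allclose(v.image, phantom64.image, atol=1e-5)
            np.testing.assert_array_equal(v.roi_mask, phantom64.roi_mask)
            np.testing.assert_array_equal(v.fracture_mask, phantom64.fracture_mask)

    def test_sampled_angles_stay_in_range(self):
        spec = AugmentSpec(seed=42)
        angles = spec.sample_angles(10_000)
        assert angles.min() >= -15.0 and angles.max() <= 15.0

    def test_inverse_transform_recovers_fracture_mask(self, phantom64):
        spec = AugmentSpec(n_variants=4, seed=9)
        for v in augment(phantom64, spec):
            back = transform_like(v.fracture_mask, -v.meta["augment_angle"],
                                  1.0 / v.meta["augment_scale"], binary=True)
            assert dice(back, phantom64.fracture_mask) >= 0.8

    def test_same_transform_applied_to_image_and_masks(self, phantom64):
        v = augment(phantom64, AugmentSpec(n_variants=1, seed=4))[0]
        expected = transform_like(phantom64.roi_mask,
                                  v.meta["augment_angle"], v.meta["augment_scale"],
                                  binary=True)
        np.testing.assert_array_equal(v.roi_mask, expected)


class TestMakeDataset:
    def test_counts_and_leakage(self):
        train, test = make_dataset(12, 0.5, image_size=48, n_variants=3, seed=0)
        assert len(train) == 18 and len(test) == 18
        assert {r.meta["base_id"] for r in train}.isdisjoint(
            {r.meta["base_id"] for r in test})

    def test_minimal_split(self):
        train, test = make_dataset(2, 0.5, image_size=48, n_variants=1, seed=0)
        assert len(train) == 1 and len(test) == 1

    def test_reproducible(self):
        a_train, _ = make_dataset(4, 0.5, image_size=48, n_variants=2, seed=3)
        b_train, _ = make_dataset(4, 0.5, image_size=48, n_variants=2, seed=3)
        for a, b in zip(a_train, b_train):
            np.testing.assert_array_equal(a.image, b.image)
            assert a.meta == b.meta

    def test_degenerate_split_rejected(self):
        with pytest.raises(ValueError):
            make_dataset(4, 0.01, image_size=48, n_variants=1, seed=0)
        with pytest.raises(ValueError):
            make_dataset(1, 0.5, image_size=48, n_variants=1, seed=0)
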