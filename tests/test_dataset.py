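"""Thick-slice stacking, splitting, resizing and augmentation."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from xpctseg import (AnnotatedPair, AugmentationParams, augment, resize_pair,
                     split_dataset, stack_thick_slices, unstack_mask)


class TestThickSliceStacking:
    def test_pointwise_maximum_composite(self):
        vol = np.array([[[1, 5], [3, 2]], [[4, 0], [1, 6]]], dtype=float)
        stacks = stack_thick_slices(vol, k=2)
        assert len(stacks) == 1
        np.testing.assert_array_equal(stacks[0].smax, [[4, 5], [3, 6]])
        assert stacks[0].z_start == 0

    def test_constant_volume_composite_is_constant(self):
        stacks = stack_thick_slices(np.full((10, 4, 4), 2.5), k=10)
        np.testing.assert_array_equal(stacks[0].smax, 2.5)

    def test_4000_slices_make_400_stacks(self):
        stacks = stack_thick_slices(np.zeros((4000, 4, 4), dtype=np.float32), k=10)
        assert len(stacks) == 400
        assert [s.z_start for s in stacks[:3]] == [0, 10, 20]

    def test_trailing_remainder_dropped(self):
        assert len(stack_thick_slices(np.zeros((25, 2, 2)), k=10)) == 2

    @given(st.integers(2, 5), st.integers(1, 4))
    @settings(max_examples=20, deadline=None)
    def test_composite_dominates_constituents(self, depth_mult, k):
        rng = np.random.default_rng(depth_mult * 10 + k)
        vol = rng.normal(size=(depth_mult * k, 6, 6))
        for stack in stack_thick_slices(vol, k=k):
            assert stack.smax.shape == stack.slices[0].shape  # dim invariant
            assert np.all(stack.smax[None] >= stack.slices)

    def test_unstack_replicates_mask(self):
        stacks = stack_thick_slices(np.zeros((10, 4, 4)), k=10)
        mask = np.arange(16).reshape(4, 4) % 6
        out = unstack_mask(stacks[0], mask)
        assert len(out) == 10
        for m in out:
            np.testing.assert_array_equal(m, mask)

    def test_unstack_restack_recovers_thick_mask(self):
        stacks = stack_thick_slices(np.zeros((10, 4, 4)), k=10)
        mask = (np.arange(16).reshape(4, 4) % 2).astype(np.uint8)
        replicated = np.stack(unstack_mask(stacks[0], mask))
        restacked = stack_thick_slices(replicated, k=10)
        np.testing.assert_array_equal(restacked[0].smax, mask)

    def test_errors(self):
        with pytest.raises(ValueError):
            stack_thick_slices(np.zeros((10, 4, 4)), k=0)
        with pytest.raises(ValueError):
            stack_thick_slices(np.zeros((5, 4, 4)), k=10)
        stacks = stack_thick_slices(np.zeros((10, 4, 4)), k=10)
        with pytest.raises(ValueError):
            unstack_mask(stacks[0], np.zeros((5, 5)))


def _pairs(n, shape=(4, 4)):
    return [AnnotatedPair(np.zeros(shape, dtype=np.float32),
                          np.zeros(shape, dtype=np.uint8)) for _ in range(n)]


class TestSplit:
    def test_300_pairs_split_240_30_30(self):
        train, val, test = split_dataset(_pairs(300), (0.8, 0.1, 0.1), seed=5)
        assert (len(train), len(val), len(test)) == (240, 30, 30)

    def test_all_train_when_fraction_one(self):
        train, val, test = split_dataset(_pairs(10), (1.0, 0.0, 0.0), seed=0)
        assert (len(train), len(val), len(test)) == (10, 0, 0)

    def test_same_seed_same_partition(self):
        pairs = _pairs(50)
        a = split_dataset(pairs, seed=3)
        b = split_dataset(pairs, seed=3)
        for sa, sb in zip(a, b):
            assert [id(p) for p in sa] == [id(p) for p in sb]

    def test_partition_is_disjoint_and_exhaustive(self):
        pairs = _pairs(47)
        train, val, test = split_dataset(pairs, seed=1)
        ids = [id(p) for s in (train, val, test) for p in s]
        assert sorted(ids) == sorted(id(p) for p in pairs)
        assert {p.split_tag for p in train} == {"train"}
        assert {p.split_tag for p in test} == {"test"}

    def test_errors(self):
        with pytest.raises(ValueError):
            split_dataset(_pairs(2))
        with pytest.raises(ValueError):
            split_dataset(_pairs(10), (0.5, 0.2, 0.2))


class TestResize:
    def test_full_frame_resizes_to_half(self):
        pair = AnnotatedPair(np.zeros((1460, 1460), dtype=np.float32),
                             np.zeros((1460, 1460), dtype=np.uint8))
        out = resize_pair(pair, 0.5)
        assert out.image.shape == (730, 730)
        assert out.mask.shape == (730, 730)

    def test_scale_one_is_identity(self):
        rng = np.random.default_rng(0)
        pair = AnnotatedPair(rng.normal(size=(8, 8)).astype(np.float32),
                             rng.integers(0, 6, (8, 8)).astype(np.uint8))
        out = resize_pair(pair, 1.0)
        np.testing.assert_array_equal(out.image, pair.image)
        np.testing.assert_array_equal(out.mask, pair.mask)

    def test_mask_label_set_preserved(self):
        mask = np.zeros((32, 32), dtype=np.uint8)
        mask[8:24, 8:24] = 1
        pair = AnnotatedPair(mask.astype(np.float32), mask)
        out = resize_pair(pair, 0.5)
        assert set(np.unique(out.mask)) <= {0, 1}
        assert out.mask.dtype == np.uint8


class TestAugment:
    def _pair(self):
        rng = np.random.default_rng(4)
        image = rng.normal(size=(16, 16)).astype(np.float32)
        mask = np.zeros((16, 16), dtype=np.uint8)
        mask[2:9, 3:12] = 3
        return AnnotatedPair(image, mask)

    def test_identity_when_disabled(self):
        pair = self._pair()
        params = AugmentationParams(mirror=False, rotation_range=0.0,
                                    noise_sigma=0.0)
        out = augment(pair, params)
        np.testing.assert_array_equal(out.image, pair.image)
        np.testing.assert_array_equal(out.mask, pair.mask)

    def test_noise_only_leaves_mask_bit_exact(self):
        pair = self._pair()
        params = AugmentationParams(mirror=False, rotation_range=0.0,
                                    noise_sigma=0.01, seed=2)
        out = augment(pair, params)
        np.testing.assert_array_equal(out.mask, pair.mask)
        assert not np.array_equal(out.image, pair.image)

    def test_geometry_applied_consistently_to_image_and_mask(self):
        """A forced mirror keeps image/mask overlay alignment exact."""
        pair = self._pair()
        pair.image[pair.mask == 3] += 10.0
        params = AugmentationParams(mirror=True, rotation_range=0.0,
                                    noise_sigma=0.0, seed=0)
        rng = np.random.default_rng(2)  # seed chosen to trigger both mirrors
        out = augment(pair, params, rng)
        assert not np.array_equal(out.mask, pair.mask)
        np.testing.assert_array_equal(out.image > 5.0, out.mask == 3)

    def test_rotation_adds_no_new_labels(self):
        pair = self._pair()
        params = AugmentationParams(mirror=False, rotation_range=90.0,
                                    noise_sigma=0.0, seed=8)
        out = augment(pair, params)
        assert set(np.unique(out.mask)) <= {0, 3}

    def test_reproducible_from_seed(self):
        pair = self._pair()
        params = AugmentationParams(seed=9)
        a = augment(pair, params)
        b = augment(pair, params)
        np.testing.assert_array_equal(a.image, b.image)
        np.testing.assert_array_equal(a.mask, b.mask)
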