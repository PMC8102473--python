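"""Pre-processing chain: cropping, resizing, flipping, normalization."""

import dataclasses

import numpy as np
import pytest

from mcvbmd.core import ContourAnnotation
from mcvbmd.errors import (DegenerateDataError, LeakageError, MetadataError,
                           VOIRangeError)
from mcvbmd.io import mask_to_contour
from mcvbmd.phantom import generate_phantom
from mcvbmd.preprocess import (NormalizationStats, compute_norm_stats,
                               extract_annotated_region, flip_if_left,
                               normalize, resize_case)


def square_annotation(voi, size=8, offset=4):
    poly = np.array([[offset, offset], [offset, offset + size],
                     [offset + size, offset + size], [offset + size, offset]],
                    dtype=float)
    return ContourAnnotation({z: [poly] for z in range(*voi)}, *voi)


class TestExtractAnnotatedRegion:
    def test_voi_cropping_bookkeeping(self, small_case):
        volume, mask = small_case
        ann = mask_to_contour(mask)
        vol, msk, record = extract_annotated_region(volume, ann)
        lo, hi = mask.annotated_range
        assert vol.shape[2] == msk.shape[2] == hi - lo
        assert record.annotated_range == (lo, hi)
        assert record.original_shape == volume.shape
        assert np.array_equal(vol, volume.intensities[:, :, lo:hi])

    def test_full_voi_is_identity(self, small_case):
        volume, mask = small_case
        full = dataclasses.replace(mask, annotated_range=(0, volume.shape[2]))
        ann = mask_to_contour(full)
        vol, msk, _ = extract_annotated_region(volume, ann)
        assert np.array_equal(vol, volume.intensities)
        assert np.array_equal(msk, full.values)

    def test_voi_out_of_range_raises(self, small_case):
        volume, _ = small_case
        ann = square_annotation((24, 40))
        with pytest.raises(VOIRangeError):
            extract_annotated_region(volume, ann)


class TestResize:
    def test_constant_volume_stays_constant(self):
        vol = np.full((32, 32, 8), 7.25, np.float32)
        mask = np.ones((32, 32, 8), np.uint8)
        out_v, out_m = resize_case(vol, mask, (16, 16, 16))
        assert out_v.shape == (16, 16, 16)
        assert np.allclose(out_v, 7.25, atol=1e-5)
        assert np.array_equal(out_m, np.ones((16, 16, 16), np.uint8))

    def test_disk_mask_area_preserved_on_downscale(self):
        rr, cc = np.meshgrid(np.arange(64), np.arange(64), indexing="ij")
        disk = ((rr - 32) ** 2 + (cc - 32) ** 2 <= 20**2)
        mask = np.repeat(disk[:, :, None], 4, axis=2).astype(np.uint8)
        _, out = resize_case(mask.astype(np.float32), mask, (32, 32, 4))
        in_area = disk.sum() / 64**2
        out_area = out[:, :, 2].sum() / 32**2
        assert abs(out_area - in_area) / in_area < 0.05
        assert set(np.unique(out)) <= {0, 1}

    def test_resize_factors_recorded(self, small_case):
        from mcvbmd.preprocess import PreprocessRecord
        record = PreprocessRecord((64, 64, 32), (8, 24))
        vol = np.zeros((64, 64, 16), np.float32)
        resize_case(vol, vol.astype(np.uint8), (32, 32, 16), record)
        assert record.resize_factors == (0.5, 0.5, 1.0)


class TestFlip:
    def test_right_hand_is_identity(self, rng):
        vol = rng.normal(size=(8, 8, 4)).astype(np.float32)
        mask = (rng.random((8, 8, 4)) > 0.5).astype(np.uint8)
        out_v, out_m, flipped = flip_if_left(vol, mask, "right")
        assert not flipped
        assert np.array_equal(out_v, vol) and np.array_equal(out_m, mask)

    def test_flip_twice_is_identity(self, rng):
        vol = rng.normal(size=(8, 8, 4)).astype(np.float32)
        mask = (rng.random((8, 8, 4)) > 0.5).astype(np.uint8)
        v1, m1, _ = flip_if_left(vol, mask, "left")
        v2, m2, _ = flip_if_left(v1, m1, "left")
        assert np.array_equal(v2, vol) and np.array_equal(m2, mask)

    def test_left_twin_matches_flipped_right(self, small_spec):
        right_vol, right_mask = generate_phantom(small_spec)
        left_spec = dataclasses.replace(small_spec, laterality="left")
        left_vol, left_mask = generate_phantom(left_spec)
        v, m, flipped = flip_if_left(left_vol.intensities, left_mask.values,
                                     "left")
        assert flipped
        assert np.array_equal(v, right_vol.intensities)
        assert np.array_equal(m, right_mask.values)

    def test_unknown_laterality_raises(self):
        with pytest.raises(MetadataError):
            flip_if_left(np.zeros((2, 2, 2)), np.zeros((2, 2, 2)), "ambidextrous")


class TestNormalization:
    def test_binary_data_hand_arithmetic(self):
        data = np.array([[[0.0, 2.0]]], dtype=np.float32)
        stats = compute_norm_stats([data])
        assert stats.mean == 1.0 and stats.variance == 1.0
        assert np.array_equal(normalize(data, stats),
                              np.array([[[-1.0, 1.0]]], np.float32))

    def test_self_normalization_zero_mean_unit_variance(self, rng):
        vol = rng.normal(5.0, 3.0, size=(16, 16, 8)).astype(np.float32)
        stats = compute_norm_stats([vol])
        out = normalize(vol, stats)
        assert abs(out.mean()) < 1e-5
        assert abs(out.var() - 1.0) < 1e-4

    def test_constant_shift_closed_form(self, rng):
        vol = rng.normal(size=(8, 8, 4)).astype(np.float32)
        stats = NormalizationStats(mean=0.0, variance=4.0)
        shifted = normalize(vol + 3.0, stats)
        assert np.allclose(shifted, normalize(vol, stats) + 1.5, atol=1e-5)

    def test_zero_variance_raises(self):
        with pytest.raises(DegenerateDataError):
            compute_norm_stats([np.full((4, 4, 4), 2.0)])

    def test_stats_from_multiple_volumes_pool_all_voxels(self, rng):
        a = rng.normal(size=(4, 4, 4))
        b = rng.normal(size=(6, 6, 6))
        stats = compute_norm_stats([a, b])
        pooled = np.concatenate([a.ravel(), b.ravel()])
        assert stats.mean == pytest.approx(pooled.mean())
        assert stats.variance == pytest.approx(pooled.var())


def test_leakage_guard_rejects_non_training_stats(rng):
    from mcvbmd.models import ModelConfig2D, build_unet2d
    from mcvbmd.train import SplitResult, TrainConfig, train_model

    cases = {f"c{i}": (rng.normal(size=(32, 32, 2)).astype(np.float32),
                       (rng.random((32, 32, 2)) > 0.5).astype(np.uint8))
             for i in range(3)}
    split = SplitResult(("c0",), ("c1",), ("c2",))
    stats = NormalizationStats(0.0, 1.0, provenance="cohort",
                               case_ids=("c0", "c1"))  # c1 is validation!
    cfg = TrainConfig(architecture="2d", epochs=0)
    with pytest.raises(LeakageError):
        train_model(lambda s: build_unet2d(
            ModelConfig2D(width_multiplier=0.05, encoder_blocks=(1, 1, 1, 1)),
            seed=s), cases, split, cfg, stats=stats)
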