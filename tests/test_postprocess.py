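"""Post-processing: hole filling, flip-back, grid restoration contracts."""

import dataclasses

import numpy as np
import pytest
from scipy import ndimage

from mcvbmd.errors import VOIRangeError
from mcvbmd.io import mask_to_contour
from mcvbmd.models import dsc_binary
from mcvbmd.phantom import generate_phantom
from mcvbmd.postprocess import (fill_holes, flip_back, postprocess_prediction,
                                restore_dropped_slices,
                                restore_full_resolution)
from mcvbmd.preprocess import (PreprocessRecord, extract_annotated_region,
                               flip_if_left, preprocess_case, resize_case)


def border_flood_fill_oracle(mask2d):
    """Reference solidification: background connected to the border stays
    background, every other background pixel becomes foreground."""
    bg = ~mask2d.astype(bool)
    labels, n = ndimage.label(bg)
    border_labels = set(labels[0, :]) | set(labels[-1, :]) \
        | set(labels[:, 0]) | set(labels[:, -1])
    border_labels.discard(0)
    keep_bg = np.isin(labels, sorted(border_labels))
    return ~(bg & keep_bg)


def disk_with_hole(shape=(40, 40), center=(20, 20), radius=15, hole=3):
    rr, cc = np.meshgrid(np.arange(shape[0]), np.arange(shape[1]), indexing="ij")
    disk = (rr - center[0]) ** 2 + (cc - center[1]) ** 2 <= radius**2
    disk[center[0] - hole // 2: center[0] + hole - hole // 2,
         center[1] - hole // 2: center[1] + hole - hole // 2] = False
    return disk


class TestFlipBack:
    def test_identity_when_not_flipped(self, rng):
        mask = (rng.random((8, 8, 4)) > 0.5).astype(np.uint8)
        record = PreprocessRecord((8, 8, 4), (0, 4), was_flipped=False)
        assert np.array_equal(flip_back(mask, record), mask)

    def test_involution_with_preprocess_flip(self, rng):
        vol = rng.normal(size=(8, 8, 4)).astype(np.float32)
        mask = (rng.random((8, 8, 4)) > 0.5).astype(np.uint8)
        record = PreprocessRecord((8, 8, 4), (0, 4))
        _, flipped, _ = flip_if_left(vol, mask, "left", record)
        assert np.array_equal(flip_back(flipped, record), mask)


class TestFillHoles:
    @pytest.mark.parametrize("macwe_iters", [0, 20])
    def test_interior_hole_filled_matches_flood_oracle(self, macwe_iters):
        plane = disk_with_hole()
        out = fill_holes(plane[:, :, None].astype(np.uint8),
                         macwe_iters=macwe_iters)
        oracle = border_flood_fill_oracle(plane)
        if macwe_iters == 0:
            assert np.array_equal(out[:, :, 0].astype(bool), oracle)
        else:  # smoothing may add voxels within the 1-voxel band
            assert (out[:, :, 0].astype(bool) | oracle == out[:, :, 0] | oracle).all()
            assert oracle[~out[:, :, 0].astype(bool)].sum() == 0

    @pytest.mark.parametrize("macwe_iters", [0, 20])
    def test_border_connected_notch_stays_open(self, macwe_iters):
        plane = disk_with_hole(hole=0)
        plane[18:24, 0:21] = False  # notch from the border into the interior
        out = fill_holes(plane[:, :, None].astype(np.uint8),
                         macwe_iters=macwe_iters)
        assert out[20, 5, 0] == 0 and out[20, 15, 0] == 0

    def test_solid_mask_unchanged(self):
        plane = disk_with_hole(hole=0)
        out = fill_holes(plane[:, :, None].astype(np.uint8))
        assert np.array_equal(out[:, :, 0].astype(bool), plane)

    def test_idempotent_and_monotone(self, rng):
        mask = (rng.random((24, 24, 3)) > 0.6).astype(np.uint8)
        once = fill_holes(mask)
        twice = fill_holes(once)
        assert np.array_equal(once, twice)
        assert ((once - mask) >= 0).all()

    def test_macwe_boundary_moves_at_most_tol(self):
        plane = disk_with_hole()
        mask = plane[:, :, None].astype(np.uint8)
        out = fill_holes(mask, macwe_iters=20, tol=1)
        filled = fill_holes(mask, macwe_iters=0)
        allowed = ndimage.binary_dilation(filled[:, :, 0], iterations=1)
        assert not (out[:, :, 0].astype(bool) & ~allowed).any()
        assert ((out - filled) >= 0).all()


class TestRestore:
    def test_full_mask_restores_to_full(self):
        record = PreprocessRecord((64, 64, 40), (10, 30),
                                  resize_factors=(0.5, 0.5, 0.8))
        up = restore_full_resolution(np.ones((32, 32, 16), np.uint8), record)
        assert up.shape == (64, 64, 20)
        assert up.all()

    def test_disk_downscale_then_restore_high_dice(self):
        rr, cc = np.meshgrid(np.arange(128), np.arange(128), indexing="ij")
        disk = ((rr - 64) ** 2 + (cc - 64) ** 2 <= 40**2)
        mask = np.repeat(disk[:, :, None], 8, axis=2).astype(np.uint8)
        record = PreprocessRecord((128, 128, 8), (0, 8))
        _, small = resize_case(mask.astype(np.float32), mask, (64, 64, 8), record)
        up = restore_full_resolution(small, record)
        assert dsc_binary(up, mask) >= 0.98

    def test_missing_record_fields_raise(self):
        record = PreprocessRecord((64, 64, 40), (10, 30))
        with pytest.raises(VOIRangeError):
            restore_full_resolution(np.ones((32, 32, 16), np.uint8), record)

    def test_dropped_slices_bookkeeping(self):
        record = PreprocessRecord((16, 16, 250), (60, 140))
        mask = np.ones((16, 16, 80), np.uint8)
        out = restore_dropped_slices(mask, record)
        assert out.shape == (16, 16, 250)
        assert out[:, :, 60:140].all()
        assert out[:, :, :60].sum() == 0 and out[:, :, 140:].sum() == 0

    def test_full_annotation_is_identity(self, rng):
        mask = (rng.random((8, 8, 10)) > 0.5).astype(np.uint8)
        record = PreprocessRecord((8, 8, 10), (0, 10))
        assert np.array_equal(restore_dropped_slices(mask, record), mask)

    def test_inconsistent_range_raises(self):
        record = PreprocessRecord((8, 8, 10), (5, 12))
        with pytest.raises(VOIRangeError):
            restore_dropped_slices(np.ones((8, 8, 7), np.uint8), record)

    def test_crop_then_restore_reproduces_ground_truth(self, small_case):
        volume, mask = small_case
        ann = mask_to_contour(mask)
        _, cropped, record = extract_annotated_region(volume, ann)
        restored = restore_dropped_slices(cropped, record)
        lo, hi = mask.annotated_range
        assert np.array_equal(restored[:, :, lo:hi], mask.values[:, :, lo:hi])
        assert restored[:, :, :lo].sum() == 0


class TestFullChainShapeContract:
    @pytest.mark.parametrize("laterality", ["left", "right"])
    def test_preprocess_postprocess_restores_grid(self, small_spec, laterality):
        spec = dataclasses.replace(small_spec, laterality=laterality, seed=9)
        volume, mask = generate_phantom(spec)
        ann = mask_to_contour(mask)
        ann.laterality = laterality
        vol, msk, record = preprocess_case(volume, ann, None, (64, 64, 16))
        fake_prob = msk.astype(np.float32)  # a perfect "prediction"
        restored = postprocess_prediction(fake_prob, record,
                                          voxel_size_mm=volume.voxel_size_mm)
        assert restored.shape == volume.shape
        lo, hi = mask.annotated_range
        assert restored.values[:, :, :lo].sum() == 0
        assert dsc_binary(restored.values[:, :, lo:hi],
                          mask.values[:, :, lo:hi]) > 0.97
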