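"""Pre-processing chain: VOI cropping, resizing, laterality flip, normalization.

The chain mirrors the clinical training setup: slices outside the expert's
annotated range are dropped, every case is resampled to a common network
grid (512x512 in-plane, 80 slices at full scale), left hands are mirrored
to a canonical right-hand orientation, and intensities are standardised
with the mean and variance of the *training* split only.  A
:class:`PreprocessRecord` captures everything needed to map a prediction
back onto the original grid.

Order of operations is fixed and documented: crop -> resize -> flip ->
normalize, with normalization statistics computed on resized training
volumes so they match the network-input distribution.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from skimage.transform import resize as _sk_resize

from .core import FLIP_AXIS, BinaryMask, CalibratedVolume, ContourAnnotation
from .errors import DegenerateDataError, MetadataError, VOIRangeError
from .io import contour_to_mask

__all__ = [
    "PreprocessRecord", "NormalizationStats", "extract_annotated_region",
    "resize_case", "flip_if_left", "compute_norm_stats", "normalize",
    "preprocess_case", "TARGET_SHAPE",
]

TARGET_SHAPE = (512, 512, 80)  # full-scale network grid


@dataclass
class PreprocessRecord:
    """Bookkeeping sufficient to restore a prediction to the original grid."""

    original_shape: tuple[int, int, int]
    annotated_range: tuple[int, int]
    was_flipped: bool = False
    resize_factors: tuple[float, float, float] | None = None
    normalization_stats_id: str | None = None


@dataclass(frozen=True)
class NormalizationStats:
    """Global intensity mean/variance of the training split."""

    mean: float
    variance: float
    provenance: str = ""
    case_ids: tuple[str, ...] = field(default_factory=tuple)

    def __post_init__(self):
        if self.variance <= 0:
            raise DegenerateDataError("normalization variance must be positive")


def extract_annotated_region(
    volume: CalibratedVolume, annotation: ContourAnnotation
) -> tuple[np.ndarray, np.ndarray, PreprocessRecord]:
    """Drop all slices outside the annotated VOI.

    Returns the cropped intensity array, the cropped binary mask rasterized
    from the annotation, and the record holding the original slice range.
    """
    lo, hi = annotation.voi
    n_slices = volume.shape[2]
    if not (0 <= lo < hi <= n_slices):
        raise VOIRangeError(
            f"VOI [{lo}, {hi}) outside volume slice range [0, {n_slices})")
    mask = contour_to_mask(annotation, volume.shape, volume.voxel_size_mm)
    record = PreprocessRecord(original_shape=volume.shape,
                              annotated_range=(lo, hi))
    return (volume.intensities[:, :, lo:hi].copy(),
            mask.values[:, :, lo:hi].copy(), record)


def resize_case(
    volume: np.ndarray,
    mask: np.ndarray,
    target_shape: tuple[int, int, int] = TARGET_SHAPE,
    record: PreprocessRecord | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Trilinear resample to the network grid.

    The mask is resampled with the same trilinear kernel and re-binarized at
    0.5, which yields smoother boundaries than nearest-neighbour at the 3x
    in-plane downscale used at full resolution.
    """
    if min(target_shape) < 1:
        raise ValueError("target shape must be positive")
    vol_out = _sk_resize(volume.astype(np.float32), target_shape, order=1,
                         mode="edge", anti_aliasing=False, preserve_range=True)
    mask_out = _sk_resize(mask.astype(np.float32), target_shape, order=1,
                          mode="edge", anti_aliasing=False, preserve_range=True)
    if record is not None:
        record.resize_factors = tuple(
            t / s for t, s in zip(target_shape, volume.shape))
    return vol_out.astype(np.float32), (mask_out > 0.5).astype(np.uint8)


def flip_if_left(
    volume: np.ndarray, mask: np.ndarray, laterality: str,
    record: PreprocessRecord | None = None,
) -> tuple[np.ndarray, np.ndarray, bool]:
    """Mirror left hands along the column axis to canonical right orientation."""
    if laterality not in ("left", "right"):
        raise MetadataError(f"unknown laterality {laterality!r}")
    was_flipped = laterality == "left"
    if was_flipped:
        volume = np.flip(volume, axis=FLIP_AXIS).copy()
        mask = np.flip(mask, axis=FLIP_AXIS).copy()
    if record is not None:
        record.was_flipped = was_flipped
    return volume, mask, was_flipped


def compute_norm_stats(
    training_volumes: list[np.ndarray],
    provenance: str = "train",
    case_ids: tuple[str, ...] = (),
) -> NormalizationStats:
    """Global zero-mean/unit-variance statistics over all training voxels.

    Must only ever see the training split; ``provenance`` and ``case_ids``
    record which split the stats came from so that training can verify no
    validation/test case contributed (leakage guard).
    """
    total = 0
    s1 = 0.0
    s2 = 0.0
    for v in training_volumes:
        v = np.asarray(v, dtype=np.float64)
        total += v.size
        s1 += v.sum()
        s2 += (v * v).sum()
    if total == 0:
        raise DegenerateDataError("no voxels provided")
    mean = s1 / total
    variance = s2 / total - mean * mean
    if variance <= 0:
        raise DegenerateDataError("training intensities have zero variance")
    return NormalizationStats(mean=float(mean), variance=float(variance),
                              provenance=provenance, case_ids=tuple(case_ids))


def normalize(volume: np.ndarray, stats: NormalizationStats) -> np.ndarray:
    """Apply (x - mean) / sqrt(variance) voxelwise."""
    return ((np.asarray(volume, dtype=np.float32) - stats.mean)
            / np.sqrt(stats.variance)).astype(np.float32)


def preprocess_case(
    volume: CalibratedVolume,
    annotation: ContourAnnotation,
    stats: NormalizationStats | None,
    target_shape: tuple[int, int, int] = TARGET_SHAPE,
) -> tuple[np.ndarray, np.ndarray, PreprocessRecord]:
    """Full chain crop -> resize -> flip -> normalize for one case."""
    vol, mask, record = extract_annotated_region(volume, annotation)
    vol, mask = resize_case(vol, mask, target_shape, record)
    vol, mask, _ = flip_if_left(vol, mask, volume.laterality, record)
    if stats is not None:
        vol = normalize(vol, stats)
        record.normalization_stats_id = stats.provenance
    return vol, mask, record
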