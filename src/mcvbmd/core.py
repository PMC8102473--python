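"""Core data containers shared across the pipeline.

Conventions fixed repo-wide:

* volumes and masks are numpy arrays indexed ``(row, col, slice)``;
* voxel indices are 0-based, slice ranges are half-open;
* polygon vertices live in continuous voxel coordinates where integer
  coordinates are voxel centers;
* "flipping along the y-axis" (left-to-right hand mirroring) flips the
  column axis (axis 1).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["Calibration", "CalibratedVolume", "BinaryMask", "ContourAnnotation"]

FLIP_AXIS = 1  # column axis; the in-plane mirror used for left hands


@dataclass(frozen=True)
class Calibration:
    """Linear map from stored intensity units to density in mg HA/cm^3."""

    slope: float = 0.25
    intercept: float = -100.0

    def __post_init__(self):
        if self.slope <= 0:
            raise ValueError("calibration slope must be positive")

    def density(self, intensities: np.ndarray) -> np.ndarray:
        return self.slope * np.asarray(intensities, dtype=np.float64) + self.intercept

    def intensity(self, densities: np.ndarray) -> np.ndarray:
        return (np.asarray(densities, dtype=np.float64) - self.intercept) / self.slope


@dataclass
class CalibratedVolume:
    """A 3D intensity grid with voxel size and density calibration."""

    intensities: np.ndarray  # (rows, cols, slices) float32
    voxel_size_mm: float
    calibration: Calibration
    laterality: str = "right"
    case_id: str = ""

    def __post_init__(self):
        self.intensities = np.asarray(self.intensities, dtype=np.float32)
        if self.intensities.ndim != 3 or min(self.intensities.shape) < 1:
            raise ValueError("volume must be a non-empty 3D grid")
        if self.voxel_size_mm <= 0:
            raise ValueError("voxel size must be positive")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.intensities.shape

    def densities(self) -> np.ndarray:
        """Calibrated densities in mg HA/cm^3, same shape as the grid."""
        return self.calibration.density(self.intensities)


@dataclass
class BinaryMask:
    """A {0,1} grid on the same lattice as its companion volume."""

    values: np.ndarray  # (rows, cols, slices) uint8
    voxel_size_mm: float
    annotated_range: tuple[int, int] | None = None

    def __post_init__(self):
        values = np.asarray(self.values)
        if not np.isin(values, (0, 1)).all():
            raise ValueError("mask values must be strictly binary")
        self.values = values.astype(np.uint8)
        if self.values.ndim != 3:
            raise ValueError("mask must be a 3D grid")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape

    def count(self) -> int:
        return int(self.values.sum())


@dataclass
class ContourAnnotation:
    """Per-slice closed polygons plus the annotated (VOI) slice range.

    ``polygons`` maps slice index -> list of (k, 2) float arrays of
    (row, col) vertices; polygons are implicitly closed (last vertex joins
    the first).
    """

    polygons: dict[int, list[np.ndarray]] = field(default_factory=dict)
    voi_start_slice: int = 0
    voi_end_slice: int = 0
    laterality: str = "right"
    case_id: str = ""

    def __post_init__(self):
        if self.voi_start_slice >= self.voi_end_slice and self.polygons:
            raise ValueError("VOI must be a non-empty half-open slice range")
        for z in self.polygons:
            if not (self.voi_start_slice <= z < self.voi_end_slice):
                raise ValueError(f"polygon slice {z} outside the VOI")

    @property
    def voi(self) -> tuple[int, int]:
        return (self.voi_start_slice, self.voi_end_slice)

    def n_polygons(self) -> int:
        return sum(len(p) for p in self.polygons.values())
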