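"""Synthetic calibrated metacarpal phantoms with ground-truth masks.

Real HR-pQCT scans of the second metacarpal cannot be redistributed, so this
module emulates the relevant imaging conditions: a tapering tubular bone with
a dense cortical shell around a lower-density trabecular interior, embedded
in soft tissue, optionally with cortical erosions (notches breaching the
shell), nearby distractor bones, left/right laterality, additive Gaussian
noise in density units and a linear intensity-density calibration.

Geometry model: the bone is a disk swept along a gently curved axis; the
cortical shell is the swept disk minus its inward-eroded copy.  A voxel
belongs to a region iff its center lies inside the continuous region
(closed disks), which makes every mask testable against a brute-force
point-in-region count.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .core import FLIP_AXIS, BinaryMask, CalibratedVolume, Calibration
from .errors import ConfigurationError, GeometryError

__all__ = ["PhantomSpec", "generate_phantom", "generate_cohort", "radius_profile"]


@dataclass(frozen=True)
class PhantomSpec:
    """Parameters of one synthetic metacarpal volume.

    Defaults approximate a clinical second-metacarpal acquisition at 82 um
    isotropic voxels: cortical bone around 900 mg HA/cm^3, trabecular bone
    around 250 mg HA/cm^3, soft-tissue background around 30 mg HA/cm^3,
    and moderate density noise.
    """

    grid_shape: tuple[int, int, int] = (128, 128, 220)  # rows, cols, slices
    voxel_size_mm: float = 0.082
    cortical_density: float = 900.0
    trabecular_density: float = 250.0
    background_density: float = 30.0
    shell_thickness_mm: float = 0.6
    bone_radius_mm: float | tuple[float, float] | tuple[float, ...] = (2.6, 2.0)
    distal_delta_frac: float = 0.12  # distal fraction with delta-shape narrowing
    axis_curvature: float = 0.4  # lateral bow amplitude of the bone axis, mm
    n_erosions: int = 0
    erosion_radius_mm: float = 0.6
    n_distractors: int = 1
    noise_sigma: float = 25.0  # additive Gaussian SD, mg HA/cm^3
    laterality: str = "right"
    annotated_range: tuple[int, int] | None = None
    calibration: Calibration = field(default_factory=Calibration)
    seed: int = 0

    def resolved_annotated_range(self) -> tuple[int, int]:
        if self.annotated_range is not None:
            return tuple(self.annotated_range)
        n = self.grid_shape[2]
        return (int(round(0.1 * n)), int(round(0.9 * n)))

    def validate(self) -> None:
        if not (self.cortical_density > self.trabecular_density
                > self.background_density >= 0):
            raise ConfigurationError(
                "densities must satisfy cortical > trabecular > background >= 0")
        radii = radius_profile(self, self.grid_shape[2])
        if self.shell_thickness_mm >= radii.min():
            raise ConfigurationError("shell thickness must be below the minimum radius")
        lo, hi = self.resolved_annotated_range()
        if not (0 <= lo < hi <= self.grid_shape[2]):
            raise ConfigurationError("annotated_range must lie within [0, slices)")
        if self.laterality not in ("left", "right"):
            raise ConfigurationError(f"unknown laterality {self.laterality!r}")


def radius_profile(spec: PhantomSpec, n_slices: int) -> np.ndarray:
    """Per-slice bone radius in mm: linear taper plus distal delta narrowing."""
    r = spec.bone_radius_mm
    if np.isscalar(r):
        prof = np.full(n_slices, float(r))
    elif len(r) == 2:
        prof = np.linspace(r[0], r[1], n_slices)
    else:
        prof = np.asarray(r, dtype=float)
        if prof.shape != (n_slices,):
            raise ConfigurationError("per-slice radius profile length mismatch")
    if spec.distal_delta_frac > 0:
        # smooth narrowing over the distal end, emulating the epiphyseal
        # "delta" region where the expert annotator stops
        k = max(int(round(spec.distal_delta_frac * n_slices)), 1)
        t = np.linspace(0.0, 1.0, k)
        prof = prof.copy()
        prof[n_slices - k:] *= 1.0 - 0.45 * (1 - np.cos(np.pi * t)) / 2.0
    return prof


def _bone_axis(spec: PhantomSpec, n_slices: int) -> tuple[np.ndarray, np.ndarray]:
    """Per-slice (row, col) axis centers in voxel units; a gentle lateral bow."""
    rows, cols, _ = spec.grid_shape
    z = np.linspace(0.0, 1.0, n_slices)
    bow_vox = spec.axis_curvature / spec.voxel_size_mm
    center_r = np.full(n_slices, (rows - 1) / 2.0)
    center_c = (cols - 1) / 2.0 + bow_vox * np.sin(np.pi * z)
    return center_r, center_c


def generate_phantom(spec: PhantomSpec) -> tuple[CalibratedVolume, BinaryMask]:
    """Generate one calibrated phantom volume with its ground-truth mask.

    The mask marks exactly the target bone (shell plus interior, minus any
    eroded voxels); distractor bones are imaged but never part of the mask.
    Identical specs (including seed) produce bit-identical output, and a
    left phantom is the exact column-axis mirror of its right twin.
    """
    spec.validate()
    rows, cols, n_slices = spec.grid_shape
    vox = spec.voxel_size_mm
    rng = np.random.default_rng(spec.seed)

    radii_vox = radius_profile(spec, n_slices) / vox
    center_r, center_c = _bone_axis(spec, n_slices)
    if (center_c + radii_vox).max() > cols - 1 or (center_c - radii_vox).min() < 0 \
            or (center_r + radii_vox).max() > rows - 1 or (center_r - radii_vox).min() < 0:
        raise GeometryError("bone radius plus axis curvature exceeds the field of view")

    rr = np.arange(rows, dtype=np.float32)[:, None, None]
    cc = np.arange(cols, dtype=np.float32)[None, :, None]
    cr = center_r.astype(np.float32)[None, None, :]
    ccen = center_c.astype(np.float32)[None, None, :]
    rad = radii_vox.astype(np.float32)[None, None, :]

    density = np.full((rows, cols, n_slices), spec.background_density,
                      dtype=np.float32)

    # distractor bones: straight, narrower tubes beside the target
    shell_vox = spec.shell_thickness_mm / vox
    for k in range(spec.n_distractors):
        off = (2.6 + 2.2 * k) * radii_vox.max()
        d_c = ccen - off
        d_rad = 0.75 * rad
        d2 = (rr - cr) ** 2 + (cc - d_c) ** 2
        inside = d2 <= d_rad**2
        interior = d2 <= np.maximum(d_rad - shell_vox, 0.0) ** 2
        density[inside] = spec.cortical_density
        density[interior] = spec.trabecular_density

    # target bone
    d2 = (rr - cr) ** 2 + (cc - ccen) ** 2
    bone = d2 <= rad**2
    interior = d2 <= (rad - shell_vox) ** 2
    density[bone] = spec.cortical_density
    density[interior] = spec.trabecular_density
    mask = bone

    # cortical erosions: spherical notches centred on the shell surface,
    # breaching it so the interior connects to the exterior
    if spec.n_erosions > 0:
        lo, hi = spec.resolved_annotated_range()
        er_vox = spec.erosion_radius_mm / vox
        zz = np.arange(n_slices, dtype=np.float32)[None, None, :]
        for _ in range(spec.n_erosions):
            z0 = int(rng.integers(lo + 2, hi - 2))
            theta = rng.uniform(0.0, 2.0 * np.pi)
            er_r = center_r[z0] + radii_vox[z0] * np.sin(theta)
            er_c = center_c[z0] + radii_vox[z0] * np.cos(theta)
            sphere = ((rr - er_r) ** 2 + (cc - er_c) ** 2
                      + (zz - z0) ** 2) <= er_vox**2
            density[sphere] = spec.background_density
            mask = mask & ~sphere

    if spec.noise_sigma > 0:
        density += rng.normal(0.0, spec.noise_sigma,
                              density.shape).astype(np.float32)

    if spec.laterality == "left":
        density = np.flip(density, axis=FLIP_AXIS).copy()
        mask = np.flip(mask, axis=FLIP_AXIS).copy()

    intensities = spec.calibration.intensity(density).astype(np.float32)
    volume = CalibratedVolume(intensities, vox, spec.calibration,
                              laterality=spec.laterality, case_id=f"seed{spec.seed}")
    return volume, BinaryMask(mask.astype(np.uint8), vox,
                              annotated_range=spec.resolved_annotated_range())


# fields that generate_cohort may vary; int-valued ones are rounded
_INT_FIELDS = {"n_erosions", "n_distractors"}
_FLOAT_FIELDS = {
    "cortical_density", "trabecular_density", "background_density",
    "shell_thickness_mm", "axis_curvature", "noise_sigma", "erosion_radius_mm",
}

#: fraction of left hands observed in the clinical cohort (130 of 541 scans)
LEFT_FRACTION = 130.0 / 541.0


def generate_cohort(
    n: int,
    base_spec: PhantomSpec,
    variation: dict | None = None,
    seed: int = 0,
    with_contours: bool = True,
):
    """Sample ``n`` phantom cases around ``base_spec``.

    ``variation`` maps spec field names to ``(low, high)`` ranges; the
    special keys ``"laterality"`` (probability of a left hand, default the
    clinical fraction 130/541) and ``"n_slices"`` (slice-count range) are
    also understood.  Returns ``(cases, metadata)`` where each case is
    ``(CalibratedVolume, BinaryMask, ContourAnnotation)`` and metadata is a
    per-case DataFrame.  Sampling is reproducible from ``seed``.
    """
    from .io import mask_to_contour  # local import: io depends on core only

    if n < 1:
        raise ConfigurationError("cohort size must be >= 1")
    variation = dict(variation or {})
    p_left = variation.pop("laterality", LEFT_FRACTION)
    slice_range = variation.pop("n_slices", None)
    for name, rng_ in variation.items():
        if name not in _INT_FIELDS | _FLOAT_FIELDS:
            raise ConfigurationError(f"cannot vary unknown field {name!r}")
        lo, hi = rng_
        if hi < lo:
            raise ConfigurationError(f"empty variation range for {name!r}")
    if slice_range is not None and slice_range[1] < slice_range[0]:
        raise ConfigurationError("empty variation range for 'n_slices'")

    master = np.random.default_rng(seed)
    cases, rows = [], []
    for i in range(n):
        overrides: dict = {"seed": int(master.integers(2**31))}
        for name, (lo, hi) in variation.items():
            value = master.uniform(lo, hi)
            overrides[name] = int(round(value)) if name in _INT_FIELDS else value
        if slice_range is not None:
            n_slices = int(master.integers(slice_range[0], slice_range[1] + 1))
            overrides["grid_shape"] = base_spec.grid_shape[:2] + (n_slices,)
            overrides["annotated_range"] = None
        overrides["laterality"] = "left" if master.random() < p_left else "right"
        spec = replace(base_spec, **overrides)
        volume, mask = generate_phantom(spec)
        case_id = f"case_{i:03d}"
        volume.case_id = case_id
        annotation = None
        if with_contours:
            annotation = mask_to_contour(mask)
            annotation.case_id = case_id
            annotation.laterality = spec.laterality
        cases.append((volume, mask, annotation))
        lo_a, hi_a = spec.resolved_annotated_range()
        rows.append({
            "case_id": case_id,
            "laterality": spec.laterality,
            "n_slices": spec.grid_shape[2],
            "annotated_start": lo_a,
            "annotated_end": hi_a,
            "cortical_density": spec.cortical_density,
            "trabecular_density": spec.trabecular_density,
            "background_density": spec.background_density,
            "noise_sigma": spec.noise_sigma,
            "n_erosions": spec.n_erosions,
            "n_distractors": spec.n_distractors,
            "seed": spec.seed,
        })
    return cases, pd.DataFrame(rows)
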