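"""Reading, writing and converting volumes, masks and contour annotations.

Volumes and masks are stored as NIfTI (``.nii.gz``/``.nii``) or MetaImage
(``.mha``/``.mhd``) through SimpleITK; calibration and case metadata travel
in a JSON sidecar next to the image file (same stem, ``.json`` extension).
Contour annotations use a documented JSON format: one record per slice with
the slice index and a list of (row, col) vertex arrays, plus the VOI range.

Rasterization follows the repo-wide voxel-center rule: a pixel belongs to a
polygon iff its center lies strictly inside the polygon interior.
"""

from __future__ import annotations

import json
import os
from pathlib import Path

import numpy as np
import shapely
import SimpleITK as sitk
from scipy import ndimage
from skimage import measure

from .core import BinaryMask, CalibratedVolume, Calibration, ContourAnnotation
from .errors import FormatError, GeometryError, MissingSidecarError

__all__ = [
    "read_volume", "write_volume", "read_mask", "write_mask",
    "read_contours", "write_contours", "contour_to_mask", "mask_to_contour",
]

_VOLUME_EXTS = (".nii.gz", ".nii", ".mha", ".mhd")


def _split_ext(path: Path) -> tuple[str, str]:
    name = path.name
    for ext in _VOLUME_EXTS:
        if name.endswith(ext):
            return name[: -len(ext)], ext
    raise FormatError(
        f"unknown volume extension on {path.name!r}; expected one of {_VOLUME_EXTS}")


def _sidecar_path(path: Path) -> Path:
    stem, _ = _split_ext(path)
    return path.parent / (stem + ".json")


def _to_sitk(array: np.ndarray, voxel_size_mm: float) -> sitk.Image:
    # our convention is (row, col, slice); SimpleITK arrays are (slice, row, col)
    img = sitk.GetImageFromArray(np.ascontiguousarray(array.transpose(2, 0, 1)))
    img.SetSpacing((voxel_size_mm,) * 3)
    return img


def _from_sitk(img: sitk.Image) -> tuple[np.ndarray, float]:
    array = sitk.GetArrayFromImage(img).transpose(1, 2, 0)
    return array, float(img.GetSpacing()[0])


def _atomic_write(img: sitk.Image, path: Path) -> None:
    stem, ext = _split_ext(path)
    tmp = path.parent / (stem + ".tmp" + ext)
    try:
        sitk.WriteImage(img, os.fspath(tmp), useCompression=ext.endswith(".gz"))
        os.replace(tmp, path)
    except BaseException:
        tmp.unlink(missing_ok=True)
        raise


def write_volume(volume: CalibratedVolume, path) -> None:
    """Write a calibrated volume plus its metadata sidecar; atomic per file."""
    path = Path(path)
    _atomic_write(_to_sitk(volume.intensities, volume.voxel_size_mm), path)
    sidecar = {
        "calibration": {"slope": volume.calibration.slope,
                        "intercept": volume.calibration.intercept},
        "laterality": volume.laterality,
        "case_id": volume.case_id,
    }
    _sidecar_path(path).write_text(json.dumps(sidecar, indent=1))


def read_volume(path) -> CalibratedVolume:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    sidecar = _sidecar_path(path)
    if not sidecar.exists():
        raise MissingSidecarError(
            f"calibration sidecar {sidecar.name!r} not found next to {path.name!r}")
    try:
        img = sitk.ReadImage(os.fspath(path))
    except RuntimeError as exc:
        raise FormatError(f"cannot read {path}: {exc}") from exc
    array, spacing = _from_sitk(img)
    meta = json.loads(sidecar.read_text())
    calib = Calibration(**meta["calibration"])
    return CalibratedVolume(array.astype(np.float32), spacing, calib,
                            laterality=meta.get("laterality", "right"),
                            case_id=meta.get("case_id", ""))


def write_mask(mask: BinaryMask, path) -> None:
    path = Path(path)
    _atomic_write(_to_sitk(mask.values.astype(np.uint8), mask.voxel_size_mm), path)
    sidecar = {"annotated_range": list(mask.annotated_range)
               if mask.annotated_range is not None else None}
    _sidecar_path(path).write_text(json.dumps(sidecar, indent=1))


def read_mask(path) -> BinaryMask:
    path = Path(path)
    try:
        img = sitk.ReadImage(os.fspath(path))
    except RuntimeError as exc:
        raise FormatError(f"cannot read {path}: {exc}") from exc
    array, spacing = _from_sitk(img)
    annotated_range = None
    sidecar = _sidecar_path(path)
    if sidecar.exists():
        rng = json.loads(sidecar.read_text()).get("annotated_range")
        annotated_range = tuple(rng) if rng is not None else None
    return BinaryMask((array > 0).astype(np.uint8), spacing, annotated_range)


# -- contour JSON ----------------------------------------------------------

def write_contours(annotation: ContourAnnotation, path) -> None:
    payload = {
        "case_id": annotation.case_id,
        "laterality": annotation.laterality,
        "voi": [annotation.voi_start_slice, annotation.voi_end_slice],
        "slices": [
            {"slice": int(z),
             "polygons": [np.asarray(p, dtype=float).tolist() for p in polys]}
            for z, polys in sorted(annotation.polygons.items())
        ],
    }
    Path(path).write_text(json.dumps(payload))


def read_contours(path) -> ContourAnnotation:
    payload = json.loads(Path(path).read_text())
    polygons = {
        int(rec["slice"]): [np.asarray(p, dtype=float) for p in rec["polygons"]]
        for rec in payload["slices"]
    }
    return ContourAnnotation(polygons=polygons,
                             voi_start_slice=int(payload["voi"][0]),
                             voi_end_slice=int(payload["voi"][1]),
                             laterality=payload.get("laterality", "right"),
                             case_id=payload.get("case_id", ""))


# -- contour <-> mask ------------------------------------------------------

def _rasterize_polygon(poly: np.ndarray, shape: tuple[int, int]) -> np.ndarray:
    """Pixels of an in-plane grid whose centers lie strictly inside ``poly``."""
    poly = np.asarray(poly, dtype=float)
    if len(poly) >= 2 and np.allclose(poly[0], poly[-1]):
        poly = poly[:-1]
    if len(poly) < 3:
        return np.zeros(shape, dtype=bool)
    region = shapely.Polygon(poly)
    if not region.is_valid:
        raise GeometryError("self-intersecting or otherwise invalid polygon")
    rmin = max(int(np.floor(poly[:, 0].min())), 0)
    rmax = min(int(np.ceil(poly[:, 0].max())), shape[0] - 1)
    cmin = max(int(np.floor(poly[:, 1].min())), 0)
    cmax = min(int(np.ceil(poly[:, 1].max())), shape[1] - 1)
    out = np.zeros(shape, dtype=bool)
    if rmax < rmin or cmax < cmin:
        return out
    rr, cc = np.meshgrid(np.arange(rmin, rmax + 1), np.arange(cmin, cmax + 1),
                         indexing="ij")
    inside = shapely.contains_xy(region, rr.ravel(), cc.ravel())
    out[rmin:rmax + 1, cmin:cmax + 1] = inside.reshape(rr.shape)
    return out


def contour_to_mask(annotation: ContourAnnotation,
                    grid_shape: tuple[int, int, int],
                    voxel_size_mm: float = 0.082) -> BinaryMask:
    """Rasterize per-slice polygons onto a voxel grid (voxel-center rule).

    Slices outside the VOI are all-zero; the mask's ``annotated_range`` is
    the annotation's VOI.
    """
    rows, cols, n_slices = grid_shape
    for z, polys in annotation.polygons.items():
        for poly in polys:
            p = np.asarray(poly, dtype=float)
            if (p < -0.5).any() or (p[:, 0] > rows - 0.5).any() \
                    or (p[:, 1] > cols - 0.5).any():
                raise GeometryError(
                    f"polygon on slice {z} does not fit grid {grid_shape}")
    values = np.zeros(grid_shape, dtype=np.uint8)
    for z, polys in annotation.polygons.items():
        for poly in polys:
            values[:, :, z] |= _rasterize_polygon(poly, (rows, cols))
    return BinaryMask(values, voxel_size_mm=voxel_size_mm,
                      annotated_range=annotation.voi)


def mask_to_contour(mask: BinaryMask) -> ContourAnnotation:
    """Trace closed outer-boundary polygons of every component per slice.

    Interior holes are not contoured (downstream post-processing solidifies
    masks anyway), so ``contour_to_mask(mask_to_contour(m))`` reproduces
    ``m`` exactly whenever each slice component is simply connected.  Only
    slices inside the mask's ``annotated_range`` (all slices when unset)
    are traced; the VOI of the result is that range.
    """
    values = mask.values
    n_slices = values.shape[2]
    lo, hi = mask.annotated_range if mask.annotated_range is not None \
        else (0, n_slices)
    polygons: dict[int, list[np.ndarray]] = {}
    for z in range(lo, hi):
        plane = values[:, :, z]
        if not plane.any():
            continue
        labels, n = ndimage.label(plane)
        polys = []
        for lab in range(1, n + 1):
            comp = ndimage.binary_fill_holes(labels == lab)
            padded = np.pad(comp.astype(float), 1)
            contours = measure.find_contours(padded, 0.5)
            outer = max(contours, key=len) - 1.0  # undo padding offset
            polys.append(outer)
        polygons[z] = polys
    return ContourAnnotation(polygons=polygons, voi_start_slice=lo,
                             voi_end_slice=hi)
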