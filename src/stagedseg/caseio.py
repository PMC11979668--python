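"""Volumes, label maps and on-disk cases.

All grids are stored as plain :class:`numpy.ndarray` objects indexed
``(x, y, z)``, matching the first-to-third axes of the NIfTI affine.  The
pipeline assumes axis-aligned grids: the affine must be a positive diagonal
scaling (the voxel spacing in mm) plus a translation (the origin); anything
with rotations or shears is rejected with an explicit error rather than
silently resampled.

A *case* is a directory holding the image to segment, its reference labels
and, for mid-treatment data, a registered prior image and prior mask::

    <case_id>/image.nii.gz
    <case_id>/ref.nii.gz
    <case_id>/prior_image.nii.gz   (optional)
    <case_id>/prior_mask.nii.gz    (optional)

Labels are ``0`` background, ``1`` primary gross tumor volume (GTVp),
``2`` metastatic lymph nodes (GTVn).
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import nibabel as nib
import numpy as np

VALID_LABELS = (0, 1, 2)

IMAGE_FILE = "image.nii.gz"
REF_FILE = "ref.nii.gz"
PRIOR_IMAGE_FILE = "prior_image.nii.gz"
PRIOR_MASK_FILE = "prior_mask.nii.gz"


class GeometryError(ValueError):
    """Grids that should share a geometry do not."""


class ValidationError(ValueError):
    """A volume or label map violates an invariant."""


@dataclass
class Volume3D:
    """A scalar 3D image with voxel spacing and origin in mm."""

    data: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValidationError(f"expected a 3D array, got ndim={self.data.ndim}")
        self.spacing = tuple(float(s) for s in self.spacing)
        self.origin = tuple(float(o) for o in self.origin)
        if len(self.spacing) != 3 or any(not np.isfinite(s) or s <= 0 for s in self.spacing):
            raise ValidationError(f"spacing must be three finite positive values, got {self.spacing}")
        if not np.all(np.isfinite(self.data)):
            raise ValidationError("volume contains NaN or Inf voxels")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    def same_geometry(self, other: "Volume3D | LabelMap", atol: float = 1e-5) -> bool:
        return (
            self.shape == other.shape
            and np.allclose(self.spacing, other.spacing, atol=atol)
            and np.allclose(self.origin, other.origin, atol=atol)
        )


@dataclass
class LabelMap:
    """Integer segmentation sharing a Volume3D's geometry; labels in {0, 1, 2}."""

    labels: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 3:
            raise ValidationError(f"expected a 3D label array, got ndim={self.labels.ndim}")
        if not np.issubdtype(self.labels.dtype, np.integer):
            if np.any(self.labels != np.round(self.labels)):
                raise ValidationError("label map contains non-integer values")
            self.labels = self.labels.astype(np.int16)
        bad = np.setdiff1d(np.unique(self.labels), VALID_LABELS)
        if bad.size:
            raise ValidationError(f"label map contains values outside {VALID_LABELS}: {bad.tolist()}")
        self.spacing = tuple(float(s) for s in self.spacing)
        self.origin = tuple(float(o) for o in self.origin)
        if len(self.spacing) != 3 or any(not np.isfinite(s) or s <= 0 for s in self.spacing):
            raise ValidationError(f"spacing must be three finite positive values, got {self.spacing}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.labels.shape

    def binarized(self) -> np.ndarray:
        """Foreground mask merging GTVp and GTVn."""
        return self.labels > 0

    def same_geometry(self, other: "Volume3D | LabelMap", atol: float = 1e-5) -> bool:
        return (
            self.shape == other.shape
            and np.allclose(self.spacing, other.spacing, atol=atol)
            and np.allclose(self.origin, other.origin, atol=atol)
        )


@dataclass
class CaseRecord:
    """One patient at one timepoint, plus optional registered prior data."""

    case_id: str
    image: Volume3D
    reference: LabelMap
    prior_image: Optional[Volume3D] = None
    prior_mask: Optional[LabelMap] = None

    def __post_init__(self) -> None:
        grids: list[Volume3D | LabelMap] = [self.image, self.reference]
        if self.prior_image is not None:
            grids.append(self.prior_image)
        if self.prior_mask is not None:
            grids.append(self.prior_mask)
        for g in grids[1:]:
            if not self.image.same_geometry(g):
                raise GeometryError(
                    f"case {self.case_id!r}: grid with shape {g.shape} does not match "
                    f"image geometry {self.image.shape}"
                )

    @property
    def has_prior(self) -> bool:
        return self.prior_image is not None and self.prior_mask is not None


def _affine_from(spacing, origin) -> np.ndarray:
    aff = np.eye(4)
    aff[0, 0], aff[1, 1], aff[2, 2] = spacing
    aff[:3, 3] = origin
    return aff


def _spacing_origin_from(affine: np.ndarray, path) -> tuple[tuple, tuple]:
    rot = affine[:3, :3]
    diag = np.diag(rot)
    if np.any(np.abs(rot - np.diag(diag)) > 1e-6 * max(1.0, np.abs(diag).max())):
        raise ValidationError(
            f"{path}: affine has rotation/shear terms; only axis-aligned grids are supported"
        )
    if np.any(diag <= 0):
        raise ValidationError(f"{path}: affine diagonal must be positive (no axis flips), got {diag}")
    return tuple(diag), tuple(affine[:3, 3])


def read_volume(path: str | os.PathLike) -> Volume3D:
    """Read a NIfTI scalar volume.

    Spacing and origin come from the affine; voxel order in the returned
    array is the file's (i, j, k) order, never reordered.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such volume: {path}")
    img = nib.load(str(path))
    spacing, origin = _spacing_origin_from(img.affine, path)
    data = np.asarray(img.dataobj).astype(np.float32)
    if not np.all(np.isfinite(data)):
        raise ValidationError(f"{path}: volume contains NaN/Inf voxels")
    return Volume3D(data=data, spacing=spacing, origin=origin)


def read_labelmap(path: str | os.PathLike) -> LabelMap:
    """Read a NIfTI label map; values must be integers in {0, 1, 2}."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such label map: {path}")
    img = nib.load(str(path))
    spacing, origin = _spacing_origin_from(img.affine, path)
    raw = np.asarray(img.dataobj)
    if not np.all(np.isfinite(raw)):
        raise ValidationError(f"{path}: label map contains NaN/Inf voxels")
    try:
        return LabelMap(labels=raw, spacing=spacing, origin=origin)
    except ValidationError as e:
        raise ValidationError(f"{path}: {e}") from e


def write_volume(vol: Volume3D, path: str | os.PathLike) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    img = nib.Nifti1Image(np.asarray(vol.data, dtype=np.float32), _affine_from(vol.spacing, vol.origin))
    nib.save(img, str(path))


def write_labelmap(lmap: LabelMap, path: str | os.PathLike) -> None:
    """Write a label map as integer NIfTI; round-trips bit-exactly."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    img = nib.Nifti1Image(
        np.asarray(lmap.labels, dtype=np.int16), _affine_from(lmap.spacing, lmap.origin)
    )
    nib.save(img, str(path))


def save_case(case: CaseRecord, root: str | os.PathLike) -> Path:
    """Write a case to ``root/<case_id>/`` in the documented layout."""
    case_dir = Path(root) / case.case_id
    write_volume(case.image, case_dir / IMAGE_FILE)
    write_labelmap(case.reference, case_dir / REF_FILE)
    if case.prior_image is not None:
        write_volume(case.prior_image, case_dir / PRIOR_IMAGE_FILE)
    if case.prior_mask is not None:
        write_labelmap(case.prior_mask, case_dir / PRIOR_MASK_FILE)
    return case_dir


def load_case(case_dir: str | os.PathLike, needs_prior: bool = False) -> CaseRecord:
    """Assemble a CaseRecord from a case directory, verifying geometry.

    Prior fields are populated iff the prior files are present.  With
    ``needs_prior=True``, missing prior files raise a configuration error.
    """
    case_dir = Path(case_dir)
    if not case_dir.is_dir():
        raise FileNotFoundError(f"case directory does not exist: {case_dir}")
    image = read_volume(case_dir / IMAGE_FILE)
    reference = read_labelmap(case_dir / REF_FILE)
    prior_image = prior_mask = None
    if (case_dir / PRIOR_IMAGE_FILE).exists():
        prior_image = read_volume(case_dir / PRIOR_IMAGE_FILE)
    if (case_dir / PRIOR_MASK_FILE).exists():
        prior_mask = read_labelmap(case_dir / PRIOR_MASK_FILE)
    if needs_prior and (prior_image is None or prior_mask is None):
        raise ValueError(
            f"case {case_dir.name!r} requires a registered prior image and mask "
            f"({PRIOR_IMAGE_FILE}, {PRIOR_MASK_FILE}) but they are absent"
        )
    return CaseRecord(
        case_id=case_dir.name,
        image=image,
        reference=reference,
        prior_image=prior_image,
        prior_mask=prior_mask,
    )


def load_cohort(root: str | os.PathLike, needs_prior: bool = False) -> list[CaseRecord]:
    """Load every case directory under ``root``, sorted by case id."""
    root = Path(root)
    dirs = sorted(p for p in root.iterdir() if p.is_dir() and (p / IMAGE_FILE).exists())
    if not dirs:
        raise FileNotFoundError(f"no case directories under {root}")
    return [load_case(d, needs_prior=needs_prior) for d in dirs]
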