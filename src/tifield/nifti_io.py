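"""NIfTI export/import of vector fields and masks on the sampling lattice.

Vector fields are written as 4-D NIfTI-1 volumes (x, y, z, 3 components,
float32, V/m per mA); masks as uint8 volumes. The affine is RAS+ with mm
units, diagonal spacing, and the lattice origin in the translation column.
The import path accepts per-pair field volumes exported by an external FEM
toolchain together with ROI and gray-matter masks, provided all volumes share
one lattice.
"""
from __future__ import annotations

from pathlib import Path

import nibabel as nib
import numpy as np

from .fields import VectorFieldSample
from .grid import EmptyMaskError, SphereGrid

__all__ = [
    "RegistrationError",
    "FormatError",
    "ImportedFields",
    "save_vector_field",
    "save_mask",
    "import_fields",
]

_AFFINE_TOL = 1e-4


class RegistrationError(ValueError):
    """Volumes do not share a lattice (shape or affine mismatch)."""


class FormatError(ValueError):
    """A volume does not have the expected dimensionality/components."""


def _affine(grid: SphereGrid) -> np.ndarray:
    aff = np.eye(4)
    aff[0, 0] = aff[1, 1] = aff[2, 2] = grid.spacing_mm
    aff[:3, 3] = grid.origin_mm
    return aff


def save_vector_field(
    field: VectorFieldSample, grid: SphereGrid, path: str | Path
) -> Path:
    """Write a per-pair vector field as a 4-D float32 NIfTI volume."""
    vol = grid.embed(field.vectors).astype(np.float32)
    img = nib.Nifti1Image(vol, _affine(grid))
    img.header.set_xyzt_units("mm")
    path = Path(path)
    nib.save(img, str(path))
    return path


def save_mask(mask: np.ndarray, grid: SphereGrid, path: str | Path) -> Path:
    """Write a point mask as a uint8 NIfTI volume."""
    vol = grid.embed(np.asarray(mask, dtype=float)).astype(np.uint8)
    img = nib.Nifti1Image(vol, _affine(grid))
    img.header.set_xyzt_units("mm")
    path = Path(path)
    nib.save(img, str(path))
    return path


class ImportedFields:
    """Pipeline-ready representation of externally computed pair fields.

    Attributes
    ----------
    points : (n, 3) world coordinates (mm) of in-brain voxels.
    field1, field2 : VectorFieldSample on those points (V/m per mA).
    roi_mask, gm_mask : boolean masks over the points.
    affine : the shared 4x4 voxel-to-world affine.
    """

    def __init__(self, points, vec1, vec2, roi_mask, gm_mask, affine):
        self.points = points
        self.field1 = VectorFieldSample(points, vec1, "imported")
        self.field2 = VectorFieldSample(points, vec2, "imported")
        self.roi_mask = roi_mask
        self.gm_mask = gm_mask
        self.affine = affine


def _load_checked(path, ref_shape3, ref_affine):
    img = nib.load(str(path))
    data = np.asarray(img.dataobj, dtype=float)
    if ref_affine is not None:
        if data.shape[:3] != ref_shape3 or not np.allclose(
            img.affine, ref_affine, atol=_AFFINE_TOL, rtol=0.0
        ):
            raise RegistrationError(
                f"{path}: lattice mismatch (shape {data.shape[:3]} vs "
                f"{ref_shape3}, or affine differs beyond {_AFFINE_TOL})"
            )
    return data, img.affine


def import_fields(
    field1_path: str | Path,
    field2_path: str | Path,
    roi_mask_path: str | Path,
    gm_mask_path: str | Path,
) -> ImportedFields:
    """Load two pair-field volumes plus ROI/gray-matter masks from NIfTI.

    All four volumes must share shape and affine (within 1e-4); field volumes
    must be 4-D with 3 components per voxel. Voxels where either field is
    defined (any nonzero component) or either mask is set constitute the
    imported point set.
    """
    d1, affine = _load_checked(field1_path, None, None)
    d2, _ = _load_checked(field2_path, d1.shape[:3], affine)
    roi, _ = _load_checked(roi_mask_path, d1.shape[:3], affine)
    gm, _ = _load_checked(gm_mask_path, d1.shape[:3], affine)
    for name, d in (("field1", d1), ("field2", d2)):
        if d.ndim != 4 or d.shape[3] != 3:
            raise FormatError(
                f"{name} must be 4-D with 3 components per voxel, got {d.shape}"
            )
    for name, m in (("roi", roi), ("gm", gm)):
        if m.ndim != 3:
            raise FormatError(f"{name} mask must be 3-D, got shape {m.shape}")
    roi_b = roi > 0.5
    gm_b = gm > 0.5
    if not roi_b.any():
        raise EmptyMaskError("roi mask volume contains no voxels")
    if not gm_b.any():
        raise EmptyMaskError("gm mask volume contains no voxels")
    support = (np.any(d1 != 0, axis=3) | np.any(d2 != 0, axis=3)
               | roi_b | gm_b)
    idx = np.argwhere(support)
    homog = np.column_stack([idx, np.ones(len(idx))])
    points = (affine @ homog.T).T[:, :3]
    return ImportedFields(
        points=points,
        vec1=d1[support],
        vec2=d2[support],
        roi_mask=roi_b[support],
        gm_mask=gm_b[support],
        affine=affine,
    )
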