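"""Regular sampling lattice inside the sphere, with gray-matter and ROI masks.

The lattice is node-centered with a configurable spacing in mm, clipped to the
sphere interior. The gray-matter mask is a radial shell; regions of interest
are balls whose default geometry mimics the depth ordering of the three
targets analysed in the pipeline: a hippocampus-like left-lateral deep ball,
a thalamus-like central ball, and a motor-like ball just under the
gray-matter shell.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .sphere import SURFACE_BAND, SphereModel

__all__ = ["RoiSpec", "SphereGrid", "sample_grid", "default_rois"]


class DegenerateGridError(ValueError):
    """Grid spacing too coarse to yield a usable interior point set."""


class EmptyMaskError(ValueError):
    """A mask selects no points of the lattice."""


@dataclass(frozen=True)
class RoiSpec:
    """Spherical region of interest: ball(center, radius) in template mm."""

    name: str
    center_mm: tuple[float, float, float]
    radius_mm: float


def default_rois(model: SphereModel) -> tuple[RoiSpec, ...]:
    """ROI balls mimicking the targets' depth ordering (left = -x).

    * ``hippocampus``: 15 mm ball at depth 0.45 a, left-lateral.
    * ``thalamus``: 12 mm ball at the center.
    * ``motor``: 12 mm ball just under the gray-matter shell, left-superior.
    """
    a = model.radius_mm
    motor_dir = np.array([-0.45, -0.05, 0.89])
    motor_dir = motor_dir / np.linalg.norm(motor_dir)
    r_in, _ = model.gm_shell
    motor_center = tuple((r_in - 0.03) * a * motor_dir)
    return (
        RoiSpec("hippocampus", (-0.45 * a, 0.0, 0.0), 15.0),
        RoiSpec("thalamus", (0.0, 0.0, 0.0), 12.0),
        RoiSpec("motor", motor_center, 12.0),
    )


@dataclass(frozen=True)
class SphereGrid:
    """Interior lattice points plus mask index sets and volume bookkeeping."""

    points: np.ndarray          # (n, 3) mm, interior lattice nodes
    gm_mask: np.ndarray         # (n,) bool
    roi_masks: dict             # name -> (n,) bool
    spacing_mm: float
    shape: tuple[int, int, int]  # full lattice shape before clipping
    origin_mm: np.ndarray        # world coordinate of voxel (0, 0, 0)
    flat_index: np.ndarray       # (n,) index of each point in the full lattice

    def __len__(self) -> int:
        return self.points.shape[0]

    def mask_for(self, name: str) -> np.ndarray:
        if name == "gm":
            return self.gm_mask
        if name == "interior":
            return np.ones(len(self), dtype=bool)
        try:
            return self.roi_masks[name]
        except KeyError:
            raise KeyError(
                f"unknown mask {name!r}; have gm, interior, "
                f"{', '.join(self.roi_masks)}"
            ) from None

    def embed(self, values: np.ndarray, fill: float = 0.0) -> np.ndarray:
        """Scatter per-point values back into the full 3-D lattice."""
        values = np.asarray(values)
        out_shape = self.shape + values.shape[1:]
        flat = np.full((int(np.prod(self.shape)),) + values.shape[1:], fill,
                       dtype=float)
        flat[self.flat_index] = values
        return flat.reshape(out_shape)


def sample_grid(
    model: SphereModel,
    spacing_mm: float,
    rois: tuple[RoiSpec, ...] | None = None,
    min_points: int = 1000,
) -> SphereGrid:
    """Node-centered lattice clipped to the sphere interior, with masks.

    Raises :class:`DegenerateGridError` if fewer than ``min_points`` interior
    points result.
    """
    if spacing_mm <= 0:
        raise ValueError(f"spacing must be positive, got {spacing_mm}")
    a = model.radius_mm
    half = int(np.floor(a / spacing_mm))
    axis = np.arange(-half, half + 1) * spacing_mm
    shape = (axis.size,) * 3
    gx, gy, gz = np.meshgrid(axis, axis, axis, indexing="ij")
    pts = np.column_stack([gx.ravel(), gy.ravel(), gz.ravel()])
    r = np.linalg.norm(pts, axis=1)
    interior = r < a * (1.0 - SURFACE_BAND)
    if interior.sum() < min_points:
        raise DegenerateGridError(
            f"spacing {spacing_mm} mm yields only {int(interior.sum())} "
            f"interior points (need >= {min_points})"
        )
    flat_index = np.flatnonzero(interior)
    pts = pts[interior]
    r = r[interior]

    r_in, r_out = model.gm_shell
    gm = (r >= r_in * a) & (r <= r_out * a)

    if rois is None:
        rois = default_rois(model)
    roi_masks = {}
    for roi in rois:
        c = np.asarray(roi.center_mm, dtype=float)
        roi_masks[roi.name] = np.linalg.norm(pts - c, axis=1) <= roi.radius_mm
        if not roi_masks[roi.name].any():
            raise EmptyMaskError(
                f"ROI {roi.name!r} contains no lattice points at spacing "
                f"{spacing_mm} mm"
            )

    return SphereGrid(
        points=pts,
        gm_mask=gm,
        roi_masks=roi_masks,
        spacing_mm=float(spacing_mm),
        shape=shape,
        origin_mm=np.array([axis[0]] * 3, dtype=float),
        flat_index=flat_index,
    )
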