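"""Shared containers for sampled vector fields and scalar amplitude fields.

All positions are in millimetres, all field values in V/m. Fields are stored
as flat point lists (one row per sample point); the lattice bookkeeping needed
for volume export lives in :mod:`tifield.grid`.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

TTIS_ENVELOPE = "ttis_envelope"
TACS_AMPLITUDE = "tacs_amplitude"
_MODES = (TTIS_ENVELOPE, TACS_AMPLITUDE)


class FieldAlignmentError(ValueError):
    """Two fields that must share a point set do not."""


@dataclass(frozen=True)
class VectorFieldSample:
    """Vector electric field of one electrode pair sampled at a point set.

    Parameters
    ----------
    points
        ``(n, 3)`` positions in mm.
    vectors
        ``(n, 3)`` electric-field vectors in V/m per mA of pair current.
    space_tag
        Coordinate-space label, e.g. ``"template"`` or ``"subject_3"``.
    """

    points: np.ndarray
    vectors: np.ndarray
    space_tag: str = "template"

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=float)
        vec = np.asarray(self.vectors, dtype=float)
        if pts.ndim != 2 or pts.shape[1] != 3:
            raise ValueError(f"points must be (n, 3), got {pts.shape}")
        if vec.shape != pts.shape:
            raise ValueError(
                f"vectors shape {vec.shape} does not match points {pts.shape}"
            )
        if not np.all(np.isfinite(vec)):
            raise ValueError("field vectors contain non-finite values")
        object.__setattr__(self, "points", pts)
        object.__setattr__(self, "vectors", vec)

    def __len__(self) -> int:
        return self.points.shape[0]

    def magnitude(self) -> np.ndarray:
        return np.linalg.norm(self.vectors, axis=-1)

    def scaled(self, factor: float) -> "VectorFieldSample":
        return VectorFieldSample(self.points, self.vectors * factor, self.space_tag)


@dataclass(frozen=True)
class EnvelopeField:
    """Scalar stimulation amplitude (tTIS envelope or tACS magnitude) per point."""

    points: np.ndarray
    amplitude: np.ndarray
    mode: str = TTIS_ENVELOPE

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=float)
        amp = np.asarray(self.amplitude, dtype=float)
        if pts.ndim != 2 or pts.shape[1] != 3:
            raise ValueError(f"points must be (n, 3), got {pts.shape}")
        if amp.shape != (pts.shape[0],):
            raise ValueError("amplitude must have one value per point")
        if self.mode not in _MODES:
            raise ValueError(f"mode must be one of {_MODES}, got {self.mode!r}")
        if np.any(amp < 0):
            raise ValueError("amplitude must be non-negative")
        object.__setattr__(self, "points", pts)
        object.__setattr__(self, "amplitude", amp)

    def __len__(self) -> int:
        return self.points.shape[0]


def require_same_points(a, b, tol: float = 1e-9) -> None:
    """Raise :class:`FieldAlignmentError` unless two fields share a point set."""
    pa, pb = np.asarray(a.points), np.asarray(b.points)
    if pa.shape != pb.shape or not np.allclose(pa, pb, atol=tol, rtol=0.0):
        raise FieldAlignmentError("fields are not sampled on the same point set")
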