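"""Analytic forward solver: point current sources on a homogeneous sphere.

The head is modelled as a homogeneous conducting sphere of radius ``a`` with
insulating exterior. For a point electrode injecting current ``I`` at surface
direction ``s``, the interior potential admits the Legendre series

    V(r, gamma) = I / (4 pi sigma a) * sum_{l>=1} (2l+1)/l * (r/a)^l P_l(cos gamma),

with ``gamma`` the angle between the field point and the electrode. An
electrode pair superposes the +I (anode) and -I (cathode) terms; the electric
field E = -grad V is obtained by term-wise analytic differentiation of the
series. The series is exactly harmonic in the interior and converges
geometrically for r < a, so a modest truncation order suffices away from the
surface; evaluation is restricted to strictly interior points.

This is a deliberately simple stand-in for subject-specific finite-element
head models: it reproduces the qualitative structure tTIS analysis depends on
(fields strongest under the electrodes, decaying with depth, pattern set by
montage geometry) while remaining exactly verifiable.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .electrodes import electrode_position
from .fields import VectorFieldSample

__all__ = [
    "SphereModel",
    "ElectrodePair",
    "OutOfDomainError",
    "sphere_potential",
    "pair_potential",
    "point_source_field",
    "pair_field",
]

#: relative width of the excluded band under the surface
SURFACE_BAND = 1e-6


class OutOfDomainError(ValueError):
    """Evaluation requested on or outside the sphere surface."""


@dataclass(frozen=True)
class SphereModel:
    """Homogeneous spherical head model.

    Parameters
    ----------
    radius_mm
        Sphere (scalp) radius in mm. Default 87 mm, a typical adult head.
    sigma
        Bulk conductivity in S/m. Default 0.275 S/m (gray matter).
    gm_shell
        Radial band ``(r_in, r_out)`` as fractions of the radius, taken as the
        gray-matter compartment for masking.
    series_order
        Legendre truncation order L.
    """

    radius_mm: float = 87.0
    sigma: float = 0.275
    gm_shell: tuple[float, float] = (0.75, 0.85)
    series_order: int = 48

    def __post_init__(self) -> None:
        r_in, r_out = self.gm_shell
        if not (0.0 < r_in < r_out <= 1.0):
            raise ValueError(f"gm_shell must satisfy 0 < r_in < r_out <= 1, got {self.gm_shell}")
        if self.sigma <= 0:
            raise ValueError(f"sigma must be positive, got {self.sigma}")
        if self.radius_mm <= 0:
            raise ValueError(f"radius must be positive, got {self.radius_mm}")
        if self.series_order < 8:
            raise ValueError(f"series_order must be >= 8, got {self.series_order}")


@dataclass(frozen=True)
class ElectrodePair:
    """Anode/cathode pair at named 10-20 sites (or explicit directions)."""

    anode_label: str
    cathode_label: str
    current_mA: float = 1.0
    anode_dir: np.ndarray | None = None
    cathode_dir: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.current_mA <= 0:
            raise ValueError(f"current must be positive, got {self.current_mA}")
        a = (electrode_position(self.anode_label)
             if self.anode_dir is None else np.asarray(self.anode_dir, float))
        c = (electrode_position(self.cathode_label)
             if self.cathode_dir is None else np.asarray(self.cathode_dir, float))
        for name, v in (("anode", a), ("cathode", c)):
            if abs(np.linalg.norm(v) - 1.0) > 1e-9:
                raise ValueError(f"{name} direction must be unit length")
        object.__setattr__(self, "anode_dir", a)
        object.__setattr__(self, "cathode_dir", c)

    def rotated(self, rotation: np.ndarray) -> "ElectrodePair":
        """Pair with both electrode directions rotated by a 3x3 matrix."""
        return replace(
            self,
            anode_dir=rotation @ self.anode_dir,
            cathode_dir=rotation @ self.cathode_dir,
        )


def _check_interior(model: SphereModel, points_mm: np.ndarray) -> np.ndarray:
    pts = np.asarray(points_mm, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 3:
        raise ValueError(f"points must be (n, 3), got {pts.shape}")
    r = np.linalg.norm(pts, axis=1)
    limit = model.radius_mm * (1.0 - SURFACE_BAND)
    if np.any(r >= limit):
        raise OutOfDomainError(
            "points must lie strictly inside the sphere (the surface series "
            f"converges too slowly); max |p| = {r.max():.6g} mm, "
            f"limit {limit:.6g} mm"
        )
    return pts


def _legendre_sums(u: np.ndarray, x: np.ndarray, L: int):
    """Accumulate the three series sums needed for V and grad V.

    Returns (sum_V, sum_dr, sum_du) where, with c_l = (2l+1)/l,
      sum_V  = sum c_l x^l P_l(u)
      sum_dr = sum c_l l x^(l-1) P_l(u)        (d/dx of sum_V)
      sum_du = sum c_l x^l P_l'(u)
    P_l' uses the singularity-free recurrence P_l' = (2l-1) P_{l-1} + P_{l-2}'.
    """
    p_prev = np.ones_like(u)   # P_0
    p_cur = u.copy()           # P_1
    dp_prev = np.zeros_like(u)  # P_0'
    dp_cur = np.ones_like(u)   # P_1'
    xl = x.copy()              # x^l at l = 1
    c = 3.0                    # (2l+1)/l at l = 1
    s_v = c * xl * p_cur
    s_dr = c * np.ones_like(x) * p_cur  # l = 1: x^(l-1) = 1 exactly
    s_du = c * xl * dp_cur
    for l in range(2, L + 1):
        p_next = ((2 * l - 1) * u * p_cur - (l - 1) * p_prev) / l
        dp_next = (2 * l - 1) * p_cur + dp_prev
        xl_prev = xl
        xl = xl * x
        c = (2 * l + 1) / l
        s_v = s_v + c * xl * p_next
        s_dr = s_dr + c * l * xl_prev * p_next
        s_du = s_du + c * xl * dp_next
        p_prev, p_cur = p_cur, p_next
        dp_prev, dp_cur = dp_cur, dp_next
    return s_v, s_dr, s_du


def sphere_potential(
    model: SphereModel, source_dir, points_mm, current_A: float = 1.0
) -> np.ndarray:
    """Interior potential of a single surface point source, volts.

    ``source_dir`` is the unit direction of the electrode; ``current_A`` the
    injected current in amperes (negative for a sink).
    """
    pts = _check_interior(model, points_mm)
    s = np.asarray(source_dir, dtype=float).reshape(3)
    s = s / np.linalg.norm(s)
    a = model.radius_mm * 1e-3  # m
    p = pts * 1e-3
    r = np.linalg.norm(p, axis=1)
    safe_r = np.where(r > 0, r, 1.0)
    u = (p @ s) / safe_r
    u = np.where(r > 0, u, 1.0)
    x = r / a
    s_v, _, _ = _legendre_sums(u, x, model.series_order)
    return current_A / (4.0 * np.pi * model.sigma * a) * s_v


def pair_potential(
    model: SphereModel, pair: ElectrodePair, points_mm
) -> np.ndarray:
    """Potential of an anode/cathode pair at the pair's current, volts."""
    i_amp = pair.current_mA * 1e-3
    return (sphere_potential(model, pair.anode_dir, points_mm, i_amp)
            - sphere_potential(model, pair.cathode_dir, points_mm, i_amp))


def point_source_field(
    model: SphereModel, source_dir, points_mm, current_A: float = 1.0
) -> np.ndarray:
    """E = -grad V of a single surface point source, V/m, shape (n, 3)."""
    pts = _check_interior(model, points_mm)
    s = np.asarray(source_dir, dtype=float).reshape(3)
    s = s / np.linalg.norm(s)
    a = model.radius_mm * 1e-3
    p = pts * 1e-3
    r = np.linalg.norm(p, axis=1)
    central = r < 1e-12 * a
    safe_r = np.where(central, 1.0, r)
    rhat = p / safe_r[:, None]
    u = np.clip((p @ s) / safe_r, -1.0, 1.0)
    x = r / a
    _, s_dr, s_du = _legendre_sums(u, x, model.series_order)
    coeff = current_A / (4.0 * np.pi * model.sigma * a)
    # grad V = (dV/dr) rhat + (dV/du) (s - u rhat) / r ; dV/dr = coeff * s_dr / a
    dv_dr = coeff * s_dr / a
    tang = (s[None, :] - u[:, None] * rhat) / safe_r[:, None]
    grad = dv_dr[:, None] * rhat + (coeff * s_du)[:, None] * tang
    if np.any(central):
        # r -> 0 limit: only the l=1 term contributes, grad V = 3 coeff / a * s
        grad[central] = 3.0 * coeff / a * s[None, :]
    return -grad


def pair_field(
    model: SphereModel,
    pair: ElectrodePair,
    points_mm,
    space_tag: str = "template",
    per_mA: bool = True,
) -> VectorFieldSample:
    """Vector field of an electrode pair sampled at interior points.

    By default the returned vectors are normalised to 1 mA of pair current
    (V/m per mA); set ``per_mA=False`` to scale by ``pair.current_mA``.
    """
    i_amp = 1e-3 if per_mA else pair.current_mA * 1e-3
    vec = (point_source_field(model, pair.anode_dir, points_mm, i_amp)
           - point_source_field(model, pair.cathode_dir, points_mm, i_amp))
    return VectorFieldSample(np.asarray(points_mm, float), vec, space_tag)


def center_field_antipodal(model: SphereModel, current_A: float) -> float:
    """Closed-form |E| at the sphere center for antipodal electrodes.

    For anode at +s and cathode at -s, only the l=1 term survives at the
    center and |E| = 3 I / (2 pi sigma a^2).
    """
    a = model.radius_mm * 1e-3
    return 3.0 * current_A / (2.0 * np.pi * model.sigma * a * a)
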