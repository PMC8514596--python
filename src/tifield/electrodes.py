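"""Idealized 10-20 / 10-10 electrode positions on a unit sphere.

Positions are generated from the geodesic construction of the extended 10-20
system on an ideal sphere, in RAS-like coordinates (x right, y anterior,
z superior), with Cz at the vertex:

* the midline sagittal arc runs from Nz (nasion) through Cz to Iz (inion),
  with labels at 10% steps of the arc (AFz at 20%, Fz at 30%, ...);
* the outer 10% ring (through Fpz, T7/T8 and Oz) sits at 72 deg inclination
  from the vertex, with ring labels every 18 deg of azimuth; the "9" labels
  (e.g. P9) lie on the ring 10% further down, at 90 deg inclination;
* intermediate labels (F1, FC1, CP3, AF3, ...) are placed by spherical linear
  interpolation along the great-circle arc from the ring electrode of their
  row to the midline electrode (e.g. F1 is 75% of the way from F7 to Fz).

These are idealized fixture coordinates for the spherical head model, not
digitized positions on a real scalp.
"""
from __future__ import annotations

import numpy as np

__all__ = ["electrode_position", "electrode_table", "ELECTRODE_NAMES"]

_RING_INCL = np.deg2rad(72.0)  # outer 10% ring, inclination from vertex
_LOWER_INCL = np.deg2rad(90.0)  # "9" ring (P9 etc.)

# azimuth (deg) of ring labels measured from the anterior midline,
# negative = left hemisphere
_RING_AZ = {
    "Fpz": 0.0, "Fp1": -18.0, "Fp2": 18.0,
    "AF7": -36.0, "AF8": 36.0,
    "F7": -54.0, "F8": 54.0,
    "FT7": -72.0, "FT8": 72.0,
    "T7": -90.0, "T8": 90.0,
    "TP7": -108.0, "TP8": 108.0,
    "P7": -126.0, "P8": 126.0,
    "PO7": -144.0, "PO8": 144.0,
    "O1": -162.0, "O2": 162.0,
    "Oz": 180.0,
}

_LOWER_AZ = {"F9": -54.0, "F10": 54.0, "P9": -126.0, "P10": 126.0,
             "TP9": -108.0, "TP10": 108.0}

# midline labels: fraction of the Nz -> Iz sagittal arc
_MIDLINE_FRAC = {
    "Nz": 0.0, "Fpz_mid": 0.1, "AFz": 0.2, "Fz": 0.3, "FCz": 0.4,
    "Cz": 0.5, "CPz": 0.6, "Pz": 0.7, "POz": 0.8, "Oz_mid": 0.9, "Iz": 1.0,
}

# intermediate labels: (ring endpoint, midline endpoint, arc fraction from ring)
_INTERMEDIATE = {
    "AF3": ("AF7", "AFz", 0.5), "AF4": ("AF8", "AFz", 0.5),
    "F5": ("F7", "Fz", 0.25), "F3": ("F7", "Fz", 0.5), "F1": ("F7", "Fz", 0.75),
    "F6": ("F8", "Fz", 0.25), "F4": ("F8", "Fz", 0.5), "F2": ("F8", "Fz", 0.75),
    "FC5": ("FT7", "FCz", 0.25), "FC3": ("FT7", "FCz", 0.5),
    "FC1": ("FT7", "FCz", 0.75),
    "FC6": ("FT8", "FCz", 0.25), "FC4": ("FT8", "FCz", 0.5),
    "FC2": ("FT8", "FCz", 0.75),
    "C5": ("T7", "Cz", 0.25), "C3": ("T7", "Cz", 0.5), "C1": ("T7", "Cz", 0.75),
    "C6": ("T8", "Cz", 0.25), "C4": ("T8", "Cz", 0.5), "C2": ("T8", "Cz", 0.75),
    "CP5": ("TP7", "CPz", 0.25), "CP3": ("TP7", "CPz", 0.5),
    "CP1": ("TP7", "CPz", 0.75),
    "CP6": ("TP8", "CPz", 0.25), "CP4": ("TP8", "CPz", 0.5),
    "CP2": ("TP8", "CPz", 0.75),
    "P5": ("P7", "Pz", 0.25), "P3": ("P7", "Pz", 0.5), "P1": ("P7", "Pz", 0.75),
    "P6": ("P8", "Pz", 0.25), "P4": ("P8", "Pz", 0.5), "P2": ("P8", "Pz", 0.75),
    "PO3": ("PO7", "POz", 0.5), "PO4": ("PO8", "POz", 0.5),
}


def _sph(incl: float, az_deg: float) -> np.ndarray:
    az = np.deg2rad(az_deg)
    return np.array([np.sin(incl) * np.sin(az),
                     np.sin(incl) * np.cos(az),
                     np.cos(incl)])


def _midline(frac: float) -> np.ndarray:
    # great-circle arc Nz (0, 1, 0) -> Cz (0, 0, 1) -> Iz (0, -1, 0)
    ang = np.pi * frac
    return np.array([0.0, np.cos(ang), np.sin(ang)])


def _slerp(a: np.ndarray, b: np.ndarray, t: float) -> np.ndarray:
    omega = np.arccos(np.clip(a @ b, -1.0, 1.0))
    if omega < 1e-12:
        return a.copy()
    return (np.sin((1 - t) * omega) * a + np.sin(t * omega) * b) / np.sin(omega)


def _build_table() -> dict[str, np.ndarray]:
    table: dict[str, np.ndarray] = {}
    for name, az in _RING_AZ.items():
        table[name] = _sph(_RING_INCL, az)
    for name, az in _LOWER_AZ.items():
        table[name] = _sph(_LOWER_INCL, az)
    for name, frac in _MIDLINE_FRAC.items():
        if name.endswith("_mid"):  # Fpz/Oz already defined on the ring
            continue
        table[name] = _midline(frac)
    for name, (ring, mid, t) in _INTERMEDIATE.items():
        table[name] = _slerp(table[ring], table[mid], t)
    return {k: v / np.linalg.norm(v) for k, v in table.items()}


_TABLE = _build_table()
ELECTRODE_NAMES = tuple(sorted(_TABLE))


class UnknownElectrodeError(KeyError):
    """Electrode label not present in the built-in 10-20/10-10 table."""


def electrode_position(label: str) -> np.ndarray:
    """Unit direction of a 10-20/10-10 electrode site (RAS, Cz at +z)."""
    try:
        return _TABLE[label].copy()
    except KeyError:
        raise UnknownElectrodeError(
            f"unknown electrode label {label!r}; known labels: "
            f"{', '.join(ELECTRODE_NAMES)}"
        ) from None


def electrode_table() -> dict[str, np.ndarray]:
    """Copy of the full label -> unit-vector table."""
    return {k: v.copy() for k, v in _TABLE.items()}
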