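"""Montage definitions and the built-in presets targeting the three ROIs.

A montage is two electrode pairs plus the stimulation mode. In tTIS mode the
pairs carry distinct carrier frequencies (f1 < f2) and the effective
stimulation frequency is the beat f_diff = f2 - f1; in tACS mode both pairs
are driven in phase at one frequency and only the current split between the
pairs (``current_ratio`` under the total budget) matters.

Preset electrode choices follow published optimized montages: hippocampus
tTIS AFz/P7 + AF4/P9 at 1 mA per pair, motor tTIS F1/CP1 + FC1/CP3, thalamus
tTIS F7/PO7 + F8/PO8; hippocampus tACS AF3/P7 + AFz/TP7 with current ratio
0.1 under a 2 mA budget, motor tACS ratio 10, thalamus tACS the same
electrodes as thalamus tTIS with ratio 1 (a documented convention; no
published ratio exists for that montage).
"""
from __future__ import annotations

from dataclasses import dataclass, field

from .sphere import ElectrodePair

__all__ = ["Montage", "PRESETS", "get_preset", "preset_names"]

TTIS = "ttis"
TACS = "tacs"


@dataclass(frozen=True)
class Montage:
    """Two electrode pairs with frequencies, mode and current policy."""

    pair1: ElectrodePair
    pair2: ElectrodePair
    mode: str = TTIS
    f1_hz: float = 1000.0
    f2_hz: float = 1010.0
    current_ratio: float = 1.0
    total_current_cap_mA: float = 2.0

    def __post_init__(self) -> None:
        if self.mode not in (TTIS, TACS):
            raise ValueError(f"mode must be '{TTIS}' or '{TACS}', got {self.mode!r}")
        if self.mode == TTIS:
            if not self.f1_hz < self.f2_hz:
                raise ValueError(
                    f"ttis mode needs f1 < f2, got {self.f1_hz}, {self.f2_hz}"
                )
            total = self.pair1.current_mA + self.pair2.current_mA
            if total > self.total_current_cap_mA + 1e-9:
                raise ValueError(
                    f"pair currents sum to {total} mA, above the "
                    f"{self.total_current_cap_mA} mA budget"
                )
        else:
            if self.current_ratio <= 0:
                raise ValueError(
                    f"tacs current ratio must be positive, got {self.current_ratio}"
                )

    @property
    def f_diff_hz(self) -> float:
        return self.f2_hz - self.f1_hz


def _pair(anode: str, cathode: str, current: float = 1.0) -> ElectrodePair:
    return ElectrodePair(anode, cathode, current_mA=current)


def _build_presets() -> dict[str, tuple[str, Montage]]:
    presets: dict[str, tuple[str, Montage]] = {}
    presets["hippocampus_ttis"] = (
        "hippocampus",
        Montage(_pair("AFz", "P7"), _pair("AF4", "P9"), mode=TTIS),
    )
    presets["hippocampus_tacs"] = (
        "hippocampus",
        Montage(_pair("AF3", "P7"), _pair("AFz", "TP7"), mode=TACS,
                current_ratio=0.1),
    )
    presets["motor_ttis"] = (
        "motor",
        Montage(_pair("F1", "CP1"), _pair("FC1", "CP3"), mode=TTIS),
    )
    presets["motor_tacs"] = (
        "motor",
        Montage(_pair("F1", "CP1"), _pair("FC1", "CP3"), mode=TACS,
                current_ratio=10.0),
    )
    presets["thalamus_ttis"] = (
        "thalamus",
        Montage(_pair("F7", "PO7"), _pair("F8", "PO8"), mode=TTIS),
    )
    presets["thalamus_tacs"] = (
        "thalamus",
        Montage(_pair("F7", "PO7"), _pair("F8", "PO8"), mode=TACS,
                current_ratio=1.0),
    )
    return presets


PRESETS = _build_presets()


def preset_names() -> tuple[str, ...]:
    return tuple(PRESETS)


def get_preset(name: str) -> tuple[str, Montage]:
    """Return ``(roi_name, montage)`` for a preset name."""
    try:
        roi, montage = PRESETS[name]
    except KeyError:
        raise KeyError(
            f"unknown preset {name!r}; available: {', '.join(PRESETS)}"
        ) from None
    return roi, montage
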