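"""Field-characterization metrics: ROI strength and gray-matter focality.

A stimulation field is summarized by the statistics commonly tabulated for
transcranial electric stimulation: mean and maximum amplitude inside the ROI,
the gray-matter maximum (how strong the field gets anywhere physiological
effects are expected), and the percentage of ROI / gray-matter points whose
amplitude strictly exceeds each threshold (defaults 0.1 and 0.2 V/m, the
range where physiological effects are typically reported at 1 mA). The
gray-matter threshold percentages are the focality index: a focal montage
exceeds threshold in few gray-matter voxels outside its target.

Points are unweighted (the sampling lattice is uniform, so each point stands
for an equal volume); exceedance is strict (> threshold). ``max_e_gm`` is
taken over the entire gray-matter mask, ROI included; ``max_e_gm_excl_roi``
over gray matter with ROI points removed is also reported since both readings
of "maximum outside the ROI" are defensible.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .fields import EnvelopeField
from .grid import EmptyMaskError

__all__ = [
    "FieldSummary",
    "ModeComparison",
    "summarize_field",
    "compare_modes",
    "cohort_summaries",
]

DEFAULT_THRESHOLDS = (0.1, 0.2)


class ThresholdError(ValueError):
    """A threshold is negative or the list is not sorted ascending."""


class ComparisonError(ValueError):
    """Summaries being compared do not describe the same ROI/thresholds."""


@dataclass(frozen=True)
class FieldSummary:
    """One table row characterizing a field for one ROI and mode."""

    roi_name: str
    mode: str
    mean_e_roi: float
    max_e_roi: float
    max_e_gm: float
    max_e_gm_excl_roi: float
    pct_roi_gt: dict
    pct_gm_gt: dict
    n_roi: int = 0
    n_gm: int = 0

    def as_series(self) -> pd.Series:
        data = {
            "roi_name": self.roi_name,
            "mode": self.mode,
            "mean_e_roi": self.mean_e_roi,
            "max_e_roi": self.max_e_roi,
            "max_e_gm": self.max_e_gm,
            "max_e_gm_excl_roi": self.max_e_gm_excl_roi,
        }
        for thr, pct in self.pct_roi_gt.items():
            data[f"roi_gt_{thr:g}"] = pct
        for thr, pct in self.pct_gm_gt.items():
            data[f"gm_gt_{thr:g}"] = pct
        return pd.Series(data)


def _check_thresholds(thresholds) -> tuple[float, ...]:
    thr = tuple(float(t) for t in thresholds)
    if any(t < 0 for t in thr):
        raise ThresholdError(f"thresholds must be >= 0, got {thr}")
    if list(thr) != sorted(thr):
        raise ThresholdError(f"thresholds must be sorted ascending, got {thr}")
    return thr


def _pct_exceeding(values: np.ndarray, thr: float) -> float:
    return 100.0 * float(np.count_nonzero(values > thr)) / values.size


def summarize_field(
    field: EnvelopeField,
    roi_mask: np.ndarray,
    gm_mask: np.ndarray,
    thresholds=DEFAULT_THRESHOLDS,
    roi_name: str = "roi",
) -> FieldSummary:
    """Summarize an amplitude field over ROI and gray-matter masks."""
    thr = _check_thresholds(thresholds)
    amp = field.amplitude
    roi_mask = np.asarray(roi_mask, dtype=bool)
    gm_mask = np.asarray(gm_mask, dtype=bool)
    for name, mask in (("roi", roi_mask), ("gm", gm_mask)):
        if mask.shape != amp.shape:
            raise ValueError(f"{name} mask shape {mask.shape} != field {amp.shape}")
        if not mask.any():
            raise EmptyMaskError(f"{name} mask selects no points")
    roi_vals = amp[roi_mask]
    gm_vals = amp[gm_mask]
    gm_excl = amp[gm_mask & ~roi_mask]
    return FieldSummary(
        roi_name=roi_name,
        mode=field.mode,
        mean_e_roi=float(roi_vals.mean()),
        max_e_roi=float(roi_vals.max()),
        max_e_gm=float(gm_vals.max()),
        max_e_gm_excl_roi=float(gm_excl.max()) if gm_excl.size else float("nan"),
        pct_roi_gt={t: _pct_exceeding(roi_vals, t) for t in thr},
        pct_gm_gt={t: _pct_exceeding(gm_vals, t) for t in thr},
        n_roi=int(roi_vals.size),
        n_gm=int(gm_vals.size),
    )


@dataclass(frozen=True)
class ModeComparison:
    """Signed differences (tacs - ttis) plus the focality verdict."""

    roi_name: str
    d_mean_e_roi: float
    d_max_e_roi: float
    d_max_e_gm: float
    d_pct_roi_gt: dict
    d_pct_gm_gt: dict
    tacs_less_focal: bool


def compare_modes(ttis: FieldSummary, tacs: FieldSummary) -> ModeComparison:
    """Contrast a tTIS-envelope summary with an in-phase tACS summary.

    ``tacs_less_focal`` is true when tACS drives a larger share of gray
    matter above the lowest threshold than tTIS does.
    """
    if ttis.roi_name != tacs.roi_name:
        raise ComparisonError(
            f"summaries describe different ROIs: {ttis.roi_name!r} vs "
            f"{tacs.roi_name!r}"
        )
    if set(ttis.pct_roi_gt) != set(tacs.pct_roi_gt):
        raise ComparisonError("summaries use different threshold sets")
    lowest = min(ttis.pct_gm_gt)
    return ModeComparison(
        roi_name=ttis.roi_name,
        d_mean_e_roi=tacs.mean_e_roi - ttis.mean_e_roi,
        d_max_e_roi=tacs.max_e_roi - ttis.max_e_roi,
        d_max_e_gm=tacs.max_e_gm - ttis.max_e_gm,
        d_pct_roi_gt={t: tacs.pct_roi_gt[t] - ttis.pct_roi_gt[t]
                      for t in ttis.pct_roi_gt},
        d_pct_gm_gt={t: tacs.pct_gm_gt[t] - ttis.pct_gm_gt[t]
                     for t in ttis.pct_gm_gt},
        tacs_less_focal=tacs.pct_gm_gt[lowest] > ttis.pct_gm_gt[lowest],
    )


def cohort_summaries(
    fields: list[EnvelopeField],
    roi_mask: np.ndarray,
    gm_mask: np.ndarray,
    thresholds=DEFAULT_THRESHOLDS,
    roi_name: str = "roi",
) -> pd.DataFrame:
    """Per-subject summary rows plus ``mean`` / ``sd`` aggregation rows.

    The SD rows use the sample standard deviation (ddof=1); with a single
    subject the SD is reported as 0 and flagged in the ``sd_defined`` column.
    """
    if len(fields) < 1:
        raise ValueError("need at least one subject field")
    rows = []
    for i, f in enumerate(fields):
        s = summarize_field(f, roi_mask, gm_mask, thresholds, roi_name)
        row = s.as_series()
        row["subject"] = i
        rows.append(row)
    table = pd.DataFrame(rows).set_index("subject")
    numeric = table.select_dtypes("number")
    mean_row = numeric.mean()
    n = len(fields)
    sd_row = numeric.std(ddof=1) if n > 1 else mean_row * 0.0
    agg = pd.DataFrame([mean_row, sd_row], index=["mean", "sd"])
    agg["roi_name"] = roi_name
    agg["mode"] = table["mode"].iloc[0]
    out = pd.concat([table, agg])
    out["sd_defined"] = n > 1
    return out
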