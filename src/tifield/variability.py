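"""Cross-subject spatial-correlation analysis of stimulation fields.

Subjects' amplitude fields, resampled to the common template lattice, are
compared by Pearson correlation over a mask (gray matter by default, or the
whole interior). Two comparisons are reported: each subject against the
template prediction, and all unordered subject pairs. Distributions of r are
summarized boxplot-style: mean, sample SD, median, quartiles, extremes and
the Tukey outlier count (points beyond 1.5*IQR from the quartiles, the
adjacent-value convention). Quartiles use linear interpolation between order
statistics; correlations are averaged arithmetically on r by default, with a
Fisher-z mean available.
"""
from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np

from .fields import EnvelopeField

__all__ = [
    "DegenerateFieldError",
    "CorrelationStats",
    "spatial_correlation",
    "correlation_stats",
    "subject_vs_template",
    "pairwise_correlations",
]


class DegenerateFieldError(ValueError):
    """A field has zero variance over the mask; correlation is undefined."""


@dataclass(frozen=True)
class CorrelationStats:
    """Boxplot-style distribution summary of a set of correlations."""

    values: np.ndarray
    mean: float
    sd: float
    median: float
    q25: float
    q75: float
    min: float
    max: float
    n_outliers: int
    fisher_mean: float

    @property
    def n(self) -> int:
        return self.values.size


def _masked(field: EnvelopeField, mask) -> np.ndarray:
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != field.amplitude.shape:
        raise ValueError(
            f"mask shape {mask.shape} != field shape {field.amplitude.shape}"
        )
    if not mask.any():
        raise ValueError("mask selects no points")
    return field.amplitude[mask]


def spatial_correlation(
    field_a: EnvelopeField, field_b: EnvelopeField, mask
) -> float:
    """Pearson correlation of two amplitude fields over masked points."""
    a = _masked(field_a, mask)
    b = _masked(field_b, mask)
    # tolerance-based: a constant array's std is roundoff-level, not exactly 0
    tol_a = 1e-12 * max(np.abs(a).max(), 1e-300)
    tol_b = 1e-12 * max(np.abs(b).max(), 1e-300)
    if a.std() <= tol_a or b.std() <= tol_b:
        raise DegenerateFieldError(
            "field has zero variance over the mask; correlation undefined"
        )
    return float(np.corrcoef(a, b)[0, 1])


def correlation_stats(values) -> CorrelationStats:
    """Summarize correlation values (mean, SD, quartiles, Tukey outliers)."""
    vals = np.asarray(values, dtype=float)
    if vals.size < 1:
        raise ValueError("need at least one correlation value")
    q25, med, q75 = np.percentile(vals, [25, 50, 75])
    iqr = q75 - q25
    lo, hi = q25 - 1.5 * iqr, q75 + 1.5 * iqr
    n_out = int(np.count_nonzero((vals < lo) | (vals > hi)))
    z = np.arctanh(np.clip(vals, -1 + 1e-15, 1 - 1e-15))
    return CorrelationStats(
        values=vals,
        mean=float(vals.mean()),
        sd=float(vals.std(ddof=1)) if vals.size > 1 else 0.0,
        median=float(med),
        q25=float(q25),
        q75=float(q75),
        min=float(vals.min()),
        max=float(vals.max()),
        n_outliers=n_out,
        fisher_mean=float(np.tanh(z.mean())),
    )


def subject_vs_template(
    subject_fields: list[EnvelopeField],
    template_field: EnvelopeField,
    mask,
) -> CorrelationStats:
    """Correlation of each subject's template-space field with the template."""
    if len(subject_fields) < 2:
        raise ValueError("need at least two subjects")
    rs = [spatial_correlation(f, template_field, mask) for f in subject_fields]
    return correlation_stats(rs)


def pairwise_correlations(
    subject_fields: list[EnvelopeField], mask
) -> tuple[CorrelationStats, np.ndarray]:
    """All unordered pairwise correlations plus the full symmetric matrix."""
    n = len(subject_fields)
    if n < 2:
        raise ValueError("need at least two subjects")
    matrix = np.eye(n)
    rs = []
    for i, j in combinations(range(n), 2):
        r = spatial_correlation(subject_fields[i], subject_fields[j], mask)
        matrix[i, j] = matrix[j, i] = r
        rs.append(r)
    return correlation_stats(rs), matrix
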