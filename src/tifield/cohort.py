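"""Synthetic subject cohort: jittered sphere models emulating anatomy.

Cross-subject variability of simulated stimulation fields stems from
anatomical differences (head size and shape, tissue conductivity) and from
electrode placement relative to anatomy. The cohort generator perturbs the
template sphere per subject:

* head radius scaled by ``1 + N(0, radius_jitter_sd)``,
* each electrode direction rotated by an angle drawn from
  ``N(0, electrode_jitter_sd)`` degrees about a random axis,
* conductivity scaled by ``1 + N(0, sigma_jitter_sd)``.

Multiplicative factors are clipped below at 0.05 so jitter can never produce
a non-physical (non-positive) radius or conductivity. Each subject's fields
are sampled on its own lattice, obtained by radially scaling the template
lattice (r -> r * a_subject / a_template); because that map is a bijection
between the lattices, the same arrays read in template order ARE the
template-space resampled fields used for cross-subject comparison.

Generation is a pure function of (spec, template, montage, grid): the same
seed yields a bit-identical cohort.
"""
from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .fields import VectorFieldSample
from .grid import SphereGrid
from .montage import Montage
from .sphere import ElectrodePair, SphereModel, pair_field

__all__ = ["CohortSpec", "Subject", "make_cohort"]

_MIN_FACTOR = 0.05


class CohortGenerationError(ValueError):
    """Jitter produced a non-physical subject model."""


@dataclass(frozen=True)
class CohortSpec:
    """Cohort size and jitter magnitudes.

    Defaults describe a realistic adult cohort: 25 subjects, ~3% head-radius
    spread, 5 deg electrode placement scatter, ~10% conductivity spread.
    """

    n_subjects: int = 25
    radius_jitter_sd: float = 0.03
    electrode_jitter_sd_deg: float = 5.0
    sigma_jitter_sd: float = 0.10
    seed: int = 0
    subject0_is_template: bool = False

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise ValueError(f"need n_subjects >= 1, got {self.n_subjects}")
        for name in ("radius_jitter_sd", "electrode_jitter_sd_deg",
                     "sigma_jitter_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


@dataclass(frozen=True)
class Subject:
    """One synthetic subject: jittered model, electrode pairs, pair fields.

    ``fields`` holds the per-mA vector field of each montage pair sampled on
    the subject lattice; point i corresponds to template lattice point i under
    the radial normalization, so the arrays double as template-space fields.
    """

    index: int
    model: SphereModel
    pairs: tuple[ElectrodePair, ElectrodePair]
    points_mm: np.ndarray
    fields: tuple[VectorFieldSample, VectorFieldSample]


def _random_rotation(rng: np.random.Generator, angle_sd_deg: float) -> np.ndarray:
    """Small random rotation: angle ~ N(0, sd) degrees about a random axis."""
    angle = np.deg2rad(rng.normal(0.0, angle_sd_deg))
    axis = rng.normal(size=3)
    axis = axis / np.linalg.norm(axis)
    k = np.array([
        [0.0, -axis[2], axis[1]],
        [axis[2], 0.0, -axis[0]],
        [-axis[1], axis[0], 0.0],
    ])
    return np.eye(3) + np.sin(angle) * k + (1.0 - np.cos(angle)) * (k @ k)


def _jitter_subject(
    rng: np.random.Generator,
    spec: CohortSpec,
    template: SphereModel,
    pairs: tuple[ElectrodePair, ElectrodePair],
) -> tuple[SphereModel, tuple[ElectrodePair, ElectrodePair]]:
    radius_factor = max(_MIN_FACTOR, 1.0 + rng.normal(0.0, spec.radius_jitter_sd))
    sigma_factor = max(_MIN_FACTOR, 1.0 + rng.normal(0.0, spec.sigma_jitter_sd))
    model = replace(
        template,
        radius_mm=template.radius_mm * radius_factor,
        sigma=template.sigma * sigma_factor,
    )
    if model.radius_mm <= 0 or model.sigma <= 0:
        raise CohortGenerationError("jitter produced a non-physical model")
    new_pairs = []
    for pair in pairs:
        rot_a = _random_rotation(rng, spec.electrode_jitter_sd_deg)
        rot_c = _random_rotation(rng, spec.electrode_jitter_sd_deg)
        new_pairs.append(replace(
            pair,
            anode_dir=rot_a @ pair.anode_dir,
            cathode_dir=rot_c @ pair.cathode_dir,
        ))
    return model, (new_pairs[0], new_pairs[1])


def make_cohort(
    spec: CohortSpec,
    template: SphereModel,
    montage: Montage,
    grid: SphereGrid,
) -> list[Subject]:
    """Generate the jittered cohort and its per-pair fields.

    Fields are evaluated on each subject's radially-scaled copy of the
    template lattice, in V/m per mA of pair current.
    """
    rng = np.random.default_rng(spec.seed)
    pairs = (montage.pair1, montage.pair2)
    subjects: list[Subject] = []
    for i in range(spec.n_subjects):
        if i == 0 and spec.subject0_is_template:
            model, subj_pairs = template, pairs
            # burn the same number of draws so later subjects are unchanged
            _jitter_subject(rng, spec, template, pairs)
        else:
            model, subj_pairs = _jitter_subject(rng, spec, template, pairs)
        scale = model.radius_mm / template.radius_mm
        points = grid.points * scale
        tag = f"subject_{i}"
        f1 = pair_field(model, subj_pairs[0], points, space_tag=tag)
        f2 = pair_field(model, subj_pairs[1], points, space_tag=tag)
        subjects.append(Subject(i, model, subj_pairs, points, (f1, f2)))
    return subjects
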