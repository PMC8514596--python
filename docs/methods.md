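# Methods

## Problem

Temporal interference stimulation (tTIS) drives two electrode pairs with
sinusoidal currents at nearby kHz carrier frequencies f1 < f2. The summed
field at any point is a kHz carrier whose amplitude beats at the difference
frequency f_diff = f2 − f1; neural modulation is attributed to that
low-frequency envelope, which is largest where the two pair fields overlap
with comparable strength and orientation — typically at depth — rather than
under the electrodes. `tifield` computes the envelope amplitude from the two
pair fields, characterizes target strength and focality against an in-phase
two-pair tACS reference, and quantifies how much the resulting field maps
vary across subjects.

## Envelope model

Let E1 and E2 be the field phasors of the two pairs at a point. The envelope
amplitude projected on a unit direction n is

    |E_AM(n)| = | |(E1 + E2)·n| − |(E1 − E2)·n| |,

which is algebraically identical to 2·min(|E1·n|, |E2·n|); the maximal
envelope over all directions is

    |E_AM_max| = 2|E2|                          if |E2| ≤ |E1| cos α,
                 2|E2 × (E1 − E2)| / |E1 − E2|  otherwise,

with α the angle between the fields. The closed forms presume a labelling;
we canonicalize losslessly (relabel so |E1| ≥ |E2|, flip E2's sign if
E1·E2 < 0 — the envelope is invariant under both operations), which makes
cos α ≥ 0 and the branch test well defined. The boundary |E2| = |E1| cos α
is assigned to the first branch; when |E1 − E2| falls below 1e−12 of the
field scale the continuous limit 2|E2| is returned, avoiding 0/0. Unit
directions are accepted within 1e−9 of unit length; fields below 1e−15 V/m
are treated as zero. One wording note: the directional quantity is the
projection of the modulation amplitude **onto** n (the formula contracts
both fields with n); descriptions of it as "tangential to" the direction are
at odds with the algebra, and we implement the formula as printed.

Two independent oracles verify the closed forms: (a) a brute-force search of
the directional formula over a deterministic Fibonacci-lattice direction
grid (a lower bound converging from below as the grid is refined; 20,000
directions agree with the closed form to better than 1% on random pairs);
(b) a time-domain simulation of the two-tone signal at 1,000/1,010 Hz whose
analytic-signal (Hilbert) envelope peak-to-trough reproduces the directional
formula to better than 1e−3 relative.

For in-phase tACS with per-mA pair solutions e1, e2, the amplitude is
|I1·e1 + I2·e2| with the pair currents derived from the current ratio
I1/I2 under a 2 mA total budget (ratio 0.1 yields ≈ 0.18/1.8 mA).

## Forward model and what it stands in for

Pair fields come from an analytic solver: a point current source I on the
surface of an insulated homogeneous sphere (radius a = 87 mm, conductivity
σ = 0.275 S/m, the standard gray-matter value) has interior potential

    V(r, γ) = I/(4πσa) · Σ_{l≥1} ((2l+1)/l) (r/a)^l P_l(cos γ),

and E = −∇V is obtained by term-wise differentiation, with the Legendre
derivative computed by the singularity-free recurrence
P'_l = (2l−1)P_{l−1} + P'_{l−2}. Anode and cathode superpose with ±I; the
default truncation is L = 48 and evaluation is restricted to strictly
interior points (the series converges slowly at the surface). Truncation is
geometric in r/a: doubling L from 32 to 64 changes potentials by < 1e−6 of
the field scale for r ≤ 0.6a, by ~2e−4 at 0.8a and ~4e−3 at 0.9a; the
near-surface field is therefore a smoothed version of the exact
point-electrode field, which is acceptable because the truncated series is
itself exactly harmonic (each term is a solid harmonic) and is *the* model.
Verification: finite-difference Laplacian residuals shrink with stencil
refinement, analytic gradients match central differences to 1e−4, and the
antipodal-pair center field matches the closed form 3I/(2πσa²) to 1e−6.

Electrode positions come from an idealized geodesic construction of the
extended 10–20 system on the unit sphere (midline arc at 10% steps, the
outer ring at 72° inclination with 18° azimuth steps, intermediate sites by
spherical interpolation along their row arcs). These are fixture
coordinates, not digitized scalp positions.

Deliberate simplifications relative to subject-specific finite-element
modelling: one homogeneous compartment (no skull, CSF or white matter),
point electrodes (no pad/paste geometry), spherical anatomy. Consequences a
user must keep in mind: absolute amplitudes are **higher** than
realistic-head simulations at the same current (no low-conductivity skull
attenuating the injected current), so shallow-target montages can saturate
the 0.1 V/m exceedance metric across the whole gray-matter shell — the
hippocampus-like presets do. Relative statements (tTIS envelope vs tACS
focality ordering on the deep thalamus-like target, depth ordering of ROI
means, variability trends under jitter) are the quantities the synthetic
model is designed to exercise; absolute V/m values are model-specific and
not comparable to tissue-resolved simulations.

A note on depth decay: the *shell-averaged* field magnitude of a pair
decreases monotonically with depth (each spherical-harmonic component of E
scales as r^(l−1)), but the pointwise profile along the axis through the
mid-scalp point between two widely separated electrodes is not monotone —
it can peak at mid-depth, since the mid-scalp point is far from both
electrodes. Tests assert the shell-average property.

## Geometry, grids, masks

Fields are sampled on a node-centered cubic lattice (default spacing 6 mm,
~13,000 interior points; coarse analyses use 8–12 mm) clipped to the sphere
interior. Gray matter is the radial shell [0.75, 0.85]·a. ROIs are balls
mimicking the depth ordering of the three analysis targets: a 15 mm
"hippocampus" ball at 0.45·a left-lateral, a 12 mm "thalamus" ball at the
center, and a 12 mm "motor" ball just under the shell, left-superior. The
deep ROI balls are disjoint from the shell by construction; ROI statistics
are computed over the ROI ball regardless.

## Montage presets

Six presets pair the three targets with the two modes, using published
optimized electrode montages: hippocampus tTIS AFz/P7 + AF4/P9 (1 mA per
pair), hippocampus tACS AF3/P7 + AFz/TP7 (ratio 0.1), motor tTIS F1/CP1 +
FC1/CP3, motor tACS same electrodes (ratio 10), thalamus tTIS F7/PO7 +
F8/PO8, thalamus tACS same electrodes. The hippocampus tACS electrodes
deliberately differ from the hippocampus tTIS electrodes — both are kept as
published, not "harmonized". No published current ratio exists for thalamus
tACS; ratio 1 under the 2 mA budget (1 mA per pair, mirroring the tTIS
currents) is this package's convention. Default carriers are 1,000 and
1,010 Hz (f_diff = 10 Hz); carriers do not enter the quasi-static field
computation and are carried for bookkeeping and the time-domain oracle.

## Metrics

Per field and ROI: mean and max amplitude in the ROI; max over the whole
gray-matter mask (and, separately, over gray matter excluding the ROI,
since "maximum outside the target" admits both readings — the whole-mask
value is the default); percent of ROI and of gray-matter points strictly
exceeding each threshold (defaults 0.1 and 0.2 V/m). Points are unweighted
(uniform lattice = equal volumes); imported mesh-based fields must be
resampled to a lattice before these metrics apply. Linearity of the field
in the injected current makes threshold exceedance exactly rescalable:
doubling the field maps the 0.1 V/m percentage onto the 0.2 V/m one, which
the tests assert as an identity. Cohort tables aggregate per-subject rows
with mean and sample SD (ddof = 1; a single-subject cohort reports SD 0 and
a flag). Report CSVs round to 2 decimals; a full-precision companion file
is always written.

## Synthetic cohort

Interindividual variability is emulated by perturbing the template sphere
per subject: head radius × (1 + N(0, 0.03)), conductivity × (1 + N(0,
0.10)), and each electrode direction rotated by N(0, 5°) about a random
axis. The defaults (25 subjects) represent a plausible adult cohort:
a few percent head-size spread, cap-placement scatter of a few degrees,
and a broad conductivity uncertainty; multiplicative factors are clipped at
0.05 so no jitter can produce a non-physical model. Subject lattices are
the template lattice scaled radially by a_subject/a_template, so index i of
a subject field corresponds to index i of the template lattice — that
radial affine map *is* the package's declared template-normalization
convention (real studies register individual anatomy to a template in ways
this model cannot reproduce). Generation is a pure function of the spec and
seed.

What the cohort does **not** emulate: focal anatomical features (CSF
thickness, skull inhomogeneity, gyrification) that drive much of the
real-world variability; correlations induced here are accordingly high
(pairwise r ≈ 0.96 at default jitter) and should be read as an upper bound
regime in which the analysis machinery — not human variability — is being
tested. The designed, test-asserted behaviour is monotone: mean pairwise
correlation decreases as electrode jitter grows (1.0 at 0°, ≈ 0.90 at 10°).

## Correlation statistics

Subject fields (template space, amplitude scalars) are compared by Pearson
correlation over the gray-matter mask by default (a whole-interior mask is
available). Two comparisons: each subject vs the template prediction, and
all n(n−1)/2 unordered pairs. Distributions are summarized with mean,
sample SD, median, quartiles (linear interpolation between order
statistics), extremes, and the Tukey outlier count (values beyond 1.5·IQR
from the quartiles — the boxplot adjacent-value convention). Means are
arithmetic on r, matching common reporting practice; a Fisher-z mean is
also emitted.

## Problem sizes and determinism

Default analyses use the 6 mm template lattice and an 8 mm lattice for the
25-subject cohort runs; verification suites use 1,000 random field pairs ×
20,000 directions, 10,000 identity triples, 100 time-domain simulations,
and 10-seed × 10-subject jitter grids on a 12 mm lattice. All randomness
flows from a single integer seed through `numpy.random.default_rng`; the
same configuration and seed reproduce every CSV byte-for-byte.

## Known limitations

- Homogeneous single-shell head: absolute amplitudes exceed tissue-resolved
  simulations; threshold metrics saturate for shallow, strongly-driven
  targets.
- Point electrodes: no current-density spreading under pads.
- Radial-affine template normalization is a convention, not a registration.
- Envelope analysis is quasi-static and amplitude-only: carrier waveform
  shape, non-sinusoidal envelope structure, and any neural transduction
  model are out of scope.
- The 10–20 table is an idealized spherical construction; do not use it for
  real-head targeting.
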