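# Methods

This note records the models, conventions and numerical choices behind
`spinealign`, in the spirit of a model-description appendix: what is
assumed, what is configurable, and what the synthetic experiments do and
do not demonstrate.

## Frontal spinal geometry

A spinal curve is the ordered set of frontal-plane coordinates of the 12
marker vertebrae (C7, T1–T4, T6, T8, T10, T12, L1, L2, L5). Validity
requires strict monotonicity of the markers **along the L5–C7 chord**
rather than along the raw x axis: the two are identical for axis-aligned
recordings, but chord-projection monotonicity survives the arbitrary
rotations under which the P8 statistic must be invariant. A zero-length
chord (L5 and C7 coincident) is therefore impossible for a valid curve and
is rejected at construction.

**Line fit.** Each spine segment is fitted by orthogonal regression
(total least squares), computed from the SVD of the centered coordinates.
TLS is used rather than ordinary regression because the deviations of
interest are perpendicular to the spine axis and the axis orientation in
the image is arbitrary; ordinary regression would make the fitted angle
depend on the camera frame. Fitted directions are oriented caudal →
cephalad (positive projection onto the L5→C7 chord) before the angle
between the thoracic and lumbar directions is taken, so `dev_deg` is an
unsigned kink angle in [0°, 180°] and `p8_deg = 180° − dev_deg`.

**Segment membership.** The thoracolumbar transition is near T11, which
carries no marker; the split is therefore placed strictly between T10 and
T12: thoracic = {C7 … T10} (8 markers), lumbar = {T12 … L5} (4 markers).

**Normalization.** Curves are matched to a common scale by the similarity
transform (translation, rotation, uniform scaling — no reflection) that
maps L5 to (0, 0) and C7 to (1000, 0). The chord length 1000 mm is an
arbitrary fixed choice; P8 is similarity-invariant, so any fixed chord
yields identical statistics.

**Chord deviations.** Alongside P8 the per-vertebra signed orthogonal
distances from the L5–C7 chord are reported as a descriptive shape
profile. They are plumbing for downstream inspection, not part of the P8
definition.

Missing markers are an error, never interpolated: the measurement protocol
always provides all 12, and silent interpolation would bias the segment
fits.

## Marker detection

Images are grayscale with bright circular markers. Pixels above a
configurable intensity threshold (default 0.5) are grouped into
8-connected components; components of at least `min_area_px` (default 4)
pixels contribute one **intensity-weighted** centroid — the weighting
honors the idea of locating the marker's center rather than its brightest
pixel, and makes the estimate sub-pixel accurate for symmetric blobs.

Labeling centroids as vertebrae uses a caudal→cephalad axis hint. With
exactly 12 centroids they are sorted by axial position and assigned
L5 … C7. With more, the surplus must be explainable as reference markers
(the capture protocol places four: a pair 5 cm from L5 and a pair 10 cm
from C7, flanking the subject). Candidate 12-marker windows (contiguous in
axial order) are enumerated; a window is admissible when every excluded
point lies beyond the window's axial extremes or farther off the window's
TLS line than a margin (default 30 mm), and among admissible windows the
one whose internal spacing best matches the anatomical inter-marker
pattern (3,1,1,2,2,2,2,1,1,1,1 vertebral levels from L5 up, at most 0.5
levels RMS mismatch) is selected. Anything else raises a counting error —
ambiguity is surfaced, not guessed away. Image distortion and depth
correction from a second camera are out of scope; no usable model for them
exists.

## LGA metrics

`E` integrates the loading curve by the trapezoid rule, with the 450 N
endpoint located by linear interpolation so the integral stops exactly at
the force limit. `C` averages tangent slopes at the 210/275/340 N force
levels; each tangent is a central finite difference across the sample
nearest the crossing (a parametric fit is deliberately avoided because the
functional form of real foam/spring curves is unknown). Force plateaus at
a required level make the tangent location ambiguous and are an error.
The "points of 210, 275 and 340 N" are interpreted as force levels, not
deflections.

Softness classes are bands on E/C, closed on the lower edge, with a value
exactly on an edge assigned to the softer band. No official band
boundaries are public; the defaults (soft ≥ 2000 mm², medium ≥ 1000 mm²,
firm below) are anchored to the one published example of a soft surface
(E/C ≈ 2476 mm²) and fully configurable under `lga.bands`.

Zone stiffness tables are normalized to percent of the stiffest zone,
rounded to one decimal for reporting, raw values retained.

## The body-on-mattress surrogate

The reference analysis used a commercial multibody engine whose equations,
joint parameters and contact models are not reproducible from published
information. The package replaces it with a declared quasi-static
energy model with the same qualitative physics:

* **Body**: six longitudinal segments — head, shoulder/thorax, waist,
  pelvis, thigh, leg — each with mass `m_i` (fractions of body weight:
  0.08/0.32/0.12/0.26/0.14/0.08), extent (fractions of height:
  0.15/0.20/0.10/0.10/0.25/0.20) and lateral contour half-width `w_i`
  (spine midline to mattress contact in side lying). The shoulder
  half-width default is 210 mm; the pelvis half-width is
  `shoulder / shoulder_pelvis_ratio`, so each preset's published width
  ratio is realized exactly; the waist is 0.95 × pelvis (the inward-curved
  waist contour); head/thigh/leg defaults are 90/130/85 mm. These are
  modeling assumptions, configurable per subject. The narrow waist and
  pelvis extents concentrate the trunk load, which is what lets a soft
  uniform surface distort the spine more than a firm one — the behavior
  the model is required to reproduce.
* **Mattress**: a row of independent elastic blocks (default
  200 × 1000 × 100 mm, height × width × length) on a rigid base, grouped
  into 6 equal-extent zones. A zone of per-block stiffness `k` acts as a
  stiffness line density `k / block_length`; the support stiffness under a
  segment, `K_i`, integrates that density over the segment (fractional
  block attribution keeps the model continuous in zone boundaries).
* **Equilibrium**: segment sags `s` minimize
  `Σ (K_i s_i²/2 − m_i g s_i) + λ ‖D(w − s)‖²` subject to
  `0 ≤ s_i ≤ 0.8 × block height`, where `D` is the second-difference
  operator on segment spine heights `h_i = w_i − s_i` and `λ ≥ 0`
  (N/mm) is the spinal bending coupling (default 2). With `λ = 0` each
  segment settles independently at `m g / K`. The saturation bound stands
  in for foam densification. The box-constrained quadratic program is
  solved by a primal active-set iteration on the 6×6 system — exact,
  deterministic, no tolerance knobs. Interior solutions satisfy global
  force balance `Σ K_i s_i = W g` identically; when a contact (s = 0) or
  saturation bound is active the bending term transfers the load, and the
  identity intentionally no longer holds segment-wise.
* **Vertebra mapping**: C7 sits at the cranial shoulder boundary and L5 a
  configurable 30 % into the pelvis; intermediate markers are placed
  linearly in anatomical vertebral level. Each vertebra inherits the spine
  height of the segment beneath it. The trunk-angle (135°) and
  knee-flexion (90°) posture constants of the lateral-lying protocol are
  carried as metadata; they do not enter the frontal-plane equilibrium.

**Zone optimization** minimizes the model's `dev_deg` by cyclic coordinate
descent: zones in fixed order 1…6, each zone minimized over the stiffness
bounds by golden-section search (resolved to 0.1 % of the range), sweeps
repeated until the per-sweep improvement falls below `tol` (default
10⁻⁴ degrees) or 25 sweeps. Initialization is the geometric mean of the
bounds; there is no randomness anywhere in the optimizer. A run that
cannot improve on its starting deviation returns the start flagged
`no_improvement`. The default stiffness bounds, 2–20 N/mm per block,
represent a realistic manufacturable spring range; they matter because the
zero-deviation optimum is typically a manifold (any straight, tilted spine
is "straight"), and very loose bounds let the search wander along it,
producing arbitrary-looking stiffness tables. Near-zero deviations around
10⁻⁴–10⁻¹ degrees in the optimizer output are converged results at `tol`,
not exact zeros.

## Statistics

Welch's heteroscedastic one-way ANOVA is implemented in its standard
weighted-means form (weights `n_i/s_i²`, denominator
`1 + 2(k−2)/(k²−1) · A`, denominator df `(k²−1)/(3A)`); note that even
with equal group variances and sizes the Welch statistic equals the
classical F only up to this finite-sample denominator, so the two agree
asymptotically, not identically. Levene's test is the classical ANOVA on
absolute deviations from the group mean (mean centering being the
long-standing default of the statistical software tradition this follows;
median centering — Brown-Forsythe — is available by flag). The
heteroscedastic post hoc is Tamhane's T2: pairwise Welch t tests with
Welch–Satterthwaite degrees of freedom, each pair tested at the
Šidák-adjusted level `1 − (1−α)^(1/m)` with adjusted p values
`1 − (1−p)^m`. Significance levels α = 0.05 and 0.001 are exposed in
configuration. Implementations are the package's own (a few lines each,
needed in exactly this combination); scipy and pingouin serve as
independent cross-checks in the test suite, never as the implementation.

Repeated trials of one subject on one surface are averaged before any
test — the group unit is the subject, not the trial.

## Synthetic data

The cohort generator emulates the three-surface lateral-lying protocol:
25 subjects by default, drawn from an equal mix of the four presets, two
trials per subject and surface, soft (2 N/mm) and firm (100 N/mm) uniform
regimes plus a per-subject customized arrangement. Subject variability is
multiplicative log-normal jitter (sd 0.05) on segment masses and contour
half-widths — keeping both positive — and measurement error is isotropic
Gaussian marker noise (sd 2 mm). All randomness flows through one
`numpy` generator seeded explicitly; equal seeds give byte-identical
cohorts.

What the generator does **not** emulate: skin-motion artifacts (corrected
manually in the measurement protocol), soft-tissue deformation, mattress
creep, sagittal-plane shape, or any correlation structure between trials
beyond the shared body. Passing tests on synthetic cohorts therefore
demonstrate the pipeline's internal consistency — that the analysis
recovers what the model put in — not the fidelity of the surrogate body
model to any particular human. Because the measured deviation is a
non-negative angle, marker noise inflates small deviations upward on
average (visible as custom-surface group means sitting above their
noiseless ground truth); this is a property of the statistic, not a bias
in the generator.

Marker images are rendered as Gaussian-profile spots (peak 1, sd =
radius/2) with optional reference markers placed 50 mm from L5 and 100 mm
from C7, angled 30° off the chord so each pair straddles the subject.
Load-deflection curves come from linear, cubic or foam (linear + cubic)
force models, sampled to 500 N and validated against the loading-branch
invariants.

## Known limitations

* The surrogate equilibrium model is one-dimensional in each segment and
  piecewise-constant in spine height; it reproduces orderings and
  signatures (soft > firm > custom deviation; C7 above the pelvis on soft
  beds; lumbar lowest on rigid surfaces; soft shoulder zones after
  customization), not subject-level angles, and published group means or
  F statistics from human cohorts are outside what it can or should
  reproduce.
* The published normalized stiffness tables for the four presets derive
  from an unreproducible commercial simulation; only their qualitative
  structure (shoulder zones softer than waist zones for triangular bodies,
  heavier bodies needing at least as much zone differentiation) is claimed
  and tested here.
* The P-parameter family beyond P8 is not defined in the source
  literature; chord deviations are provided as a descriptive stand-in.
* Reference-marker exclusion assumes the markers follow the stated
  placement geometry; a reference marker lying inside the marker chain's
  span and near its line would be misattributed, and an extra spurious
  blob inside the chain raises an error rather than being resolved.
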