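"""Quasi-static model of a segmented body lying laterally on a zoned mattress.

The body is reduced to six longitudinal segments (head, shoulder/thorax,
waist, pelvis, thigh, leg), each with a mass and a lateral contour
half-width: the distance from the spine midline to the mattress-contact
surface when lying on the side. The mattress is a row of independent
elastic blocks on a rigid base, grouped into stiffness zones. Each segment
compresses the blocks beneath it; at equilibrium the spine height above the
base under a segment is ``half_width - sag``.

With zero bending coupling every segment settles independently at
``sag = m * g / K`` (K = summed stiffness of the blocks under it),
saturating at 80 % block compression, a stand-in for foam densification.
A positive coupling adds a smoothness penalty on the spine (sum of squared
second differences of segment spine heights), making the equilibrium a
small box-constrained quadratic program.

This transparent surrogate reproduces the qualitative mechanics of lateral
lying: on a firm bed only the wide shoulder and pelvis are supported and
the lumbar spine drops toward the narrow waist contour; on a soft bed the
heavy pelvis sags deepest so C7 ends up above the pelvis. Customizing the
zone stiffnesses (cyclic golden-section coordinate descent on the frontal
deviation angle) straightens the simulated spine.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np

from .config import DEFAULTS, ConfigError
from .mattress_metrics import StiffnessTable, normalize_stiffness
from .spine_geometry import (VERTEBRAE, VERTEBRAL_LEVEL, SpinalCurve,
                             compute_p8)

__all__ = [
    "GRAVITY_M_PER_S2", "SEGMENT_NAMES", "PRESETS",
    "AnthropometricPreset", "BodySegmentProfile", "MattressArrangement",
    "EquilibriumResult", "OptimizationResult", "BodyBedError",
    "UncoveredSegmentError", "ConvergenceError",
    "classify_body_shape", "build_body", "solve_equilibrium", "optimize_zones",
]

GRAVITY_M_PER_S2 = 9.81

SEGMENT_NAMES: tuple[str, ...] = (
    "head", "shoulder", "waist", "pelvis", "thigh", "leg")


class BodyBedError(ValueError):
    """Invalid body or mattress specification."""


class UncoveredSegmentError(BodyBedError):
    """A body segment has no mattress blocks beneath it."""


class ConvergenceError(BodyBedError):
    """The coupled equilibrium minimization failed to converge."""


@dataclass(frozen=True)
class AnthropometricPreset:
    """Height, weight and shoulder/pelvis width ratio of a modeled subject."""

    name: str
    height_cm: float
    weight_kg: float
    shoulder_pelvis_ratio: float

    @property
    def shape(self) -> str:
        return classify_body_shape(self.shoulder_pelvis_ratio)


#: The four modeled subjects: heavy/light x triangular/square men.
PRESETS: dict[str, AnthropometricPreset] = {
    "HTM": AnthropometricPreset("HTM", 181.0, 103.0, 1.59),
    "HSM": AnthropometricPreset("HSM", 183.0, 93.0, 1.33),
    "LTM": AnthropometricPreset("LTM", 182.0, 74.0, 1.52),
    "LSM": AnthropometricPreset("LSM", 184.0, 76.0, 1.28),
}


def classify_body_shape(shoulder_pelvis_ratio: float) -> str:
    """Triangular if the shoulder-to-pelvis width ratio exceeds 1.45, else square."""
    if not shoulder_pelvis_ratio > 0:
        raise BodyBedError("shoulder/pelvis ratio must be positive")
    return "triangular" if shoulder_pelvis_ratio > 1.45 else "square"


@dataclass(frozen=True)
class BodySegmentProfile:
    """Segment masses, extents and contour half-widths of a lying body.

    Arrays are ordered as :data:`SEGMENT_NAMES`, head first. ``vertebra_x_mm``
    maps each vertebra label to its longitudinal position (mm from the top of
    the head). ``posture`` records the lying-protocol constants (trunk angle
    135 deg, knee flexion 90 deg) as metadata.
    """

    masses_kg: np.ndarray
    extents_mm: np.ndarray
    half_widths_mm: np.ndarray
    vertebra_x_mm: dict[str, float]
    posture: dict[str, float] = field(default_factory=dict)

    def __post_init__(self):
        for name in ("masses_kg", "extents_mm", "half_widths_mm"):
            arr = np.asarray(getattr(self, name), dtype=float)
            object.__setattr__(self, name, arr)
            if arr.shape != (len(SEGMENT_NAMES),):
                raise BodyBedError(f"{name} must have {len(SEGMENT_NAMES)} entries")
            if (arr <= 0).any() or not np.isfinite(arr).all():
                raise BodyBedError(f"{name} must be positive and finite")
        missing = [v for v in VERTEBRAE if v not in self.vertebra_x_mm]
        if missing:
            raise BodyBedError(f"vertebra_x_mm missing {missing}")

    @property
    def total_mass_kg(self) -> float:
        return float(self.masses_kg.sum())

    @property
    def length_mm(self) -> float:
        return float(self.extents_mm.sum())

    @property
    def boundaries_mm(self) -> np.ndarray:
        """Segment boundaries: length 7, from 0 (head top) to body length."""
        return np.concatenate([[0.0], np.cumsum(self.extents_mm)])

    def segment_of(self, x_mm: float) -> int:
        """Index of the segment containing longitudinal position ``x_mm``."""
        b = self.boundaries_mm
        if not (b[0] <= x_mm <= b[-1]):
            raise BodyBedError(f"position {x_mm} mm outside body [0, {b[-1]}]")
        return int(np.clip(np.searchsorted(b, x_mm, side="right") - 1,
                           0, len(SEGMENT_NAMES) - 1))


def build_body(preset: AnthropometricPreset | str,
               contour_config: Mapping | None = None) -> BodySegmentProfile:
    """Instantiate a six-segment body from a preset and contour configuration.

    Segment masses are ``mass_fractions * weight`` and extents
    ``extent_fractions * height``. The shoulder half-width comes from config
    and the pelvis half-width is ``shoulder / ratio``, so the preset's
    shoulder-to-pelvis ratio is realized exactly; the waist is a configurable
    fraction of the pelvis (narrower, reflecting the inward-curved waist
    contour). Vertebra positions C7..L5 are distributed over the shoulder,
    waist and cranial pelvis extents, linearly in anatomical vertebral level.
    """
    if isinstance(preset, str):
        try:
            preset = PRESETS[preset]
        except KeyError:
            raise BodyBedError(f"unknown preset {preset!r}; "
                               f"choose from {sorted(PRESETS)}") from None
    cfg = dict(DEFAULTS["body"])
    if contour_config:
        cfg.update(contour_config)

    mass_fr = np.array([cfg["mass_fractions"][s] for s in SEGMENT_NAMES])
    ext_fr = np.array([cfg["extent_fractions"][s] for s in SEGMENT_NAMES])
    for name, fr in (("mass_fractions", mass_fr), ("extent_fractions", ext_fr)):
        if abs(fr.sum() - 1.0) > 1e-9:
            raise ConfigError(f"body.{name} must sum to 1, got {fr.sum()!r}")

    masses = mass_fr * preset.weight_kg
    extents = ext_fr * preset.height_cm * 10.0  # cm -> mm

    hw_cfg = cfg["half_widths_mm"]
    shoulder_hw = float(hw_cfg["shoulder"])
    pelvis_hw = shoulder_hw / preset.shoulder_pelvis_ratio
    waist_hw = float(cfg["waist_to_pelvis"]) * pelvis_hw
    half_widths = np.array([
        float(hw_cfg["head"]), shoulder_hw, waist_hw, pelvis_hw,
        float(hw_cfg["thigh"]), float(hw_cfg["leg"]),
    ])

    # C7 sits at the cranial shoulder boundary; L5 a configurable fraction
    # into the pelvis. Intermediate markers follow their vertebral level.
    b = np.concatenate([[0.0], np.cumsum(extents)])
    x_c7 = b[1]                                   # head/shoulder boundary
    x_l5 = b[3] + float(cfg["l5_pelvis_fraction"]) * extents[3]
    span = x_l5 - x_c7
    max_level = VERTEBRAL_LEVEL["L5"]
    vertebra_x = {v: float(x_c7 + VERTEBRAL_LEVEL[v] / max_level * span)
                  for v in VERTEBRAE}

    posture = {"trunk_angle_deg": float(cfg["trunk_angle_deg"]),
               "knee_flexion_deg": float(cfg["knee_flexion_deg"])}
    return BodySegmentProfile(masses, extents, half_widths, vertebra_x, posture)


@dataclass(frozen=True)
class MattressArrangement:
    """Zoned row of elastic blocks on a rigid base.

    ``stiffness_n_per_mm`` is the stiffness of one block in each zone;
    blocks are ``block_length_mm`` long, and a zone of extent ``e`` therefore
    contributes a stiffness line density ``k / block_length`` over ``e``.
    Default block dimensions are 200 x 1000 x 100 mm (height x width x length).
    """

    zone_ids: tuple[int, ...]
    extents_mm: np.ndarray
    stiffness_n_per_mm: np.ndarray
    block_length_mm: float = 100.0
    block_height_mm: float = 200.0
    max_compression_frac: float = 0.8

    def __post_init__(self):
        ext = np.asarray(self.extents_mm, dtype=float)
        k = np.asarray(self.stiffness_n_per_mm, dtype=float)
        object.__setattr__(self, "extents_mm", ext)
        object.__setattr__(self, "stiffness_n_per_mm", k)
        if not (len(self.zone_ids) == len(ext) == len(k)):
            raise BodyBedError("zone arrays must have equal length")
        if (ext <= 0).any() or (k <= 0).any():
            raise BodyBedError("zone extents and stiffness must be positive")
        if self.block_length_mm <= 0 or self.block_height_mm <= 0:
            raise BodyBedError("block dimensions must be positive")
        if not 0 < self.max_compression_frac <= 1:
            raise BodyBedError("max_compression_frac must lie in (0, 1]")

    @classmethod
    def uniform(cls, stiffness_n_per_mm: float, length_mm: float,
                n_zones: int = 6, **kwargs) -> "MattressArrangement":
        """Equal zones of identical stiffness tiling ``length_mm``."""
        ext = np.full(n_zones, length_mm / n_zones)
        return cls(tuple(range(1, n_zones + 1)), ext,
                   np.full(n_zones, float(stiffness_n_per_mm)), **kwargs)

    @classmethod
    def tiling(cls, body: BodySegmentProfile, stiffness: Sequence[float],
               **kwargs) -> "MattressArrangement":
        """Equal zones tiling the body length with given per-zone stiffness."""
        n = len(stiffness)
        ext = np.full(n, body.length_mm / n)
        return cls(tuple(range(1, n + 1)), ext, np.asarray(stiffness, float),
                   **kwargs)

    @property
    def max_sag_mm(self) -> float:
        return self.max_compression_frac * self.block_height_mm

    @property
    def boundaries_mm(self) -> np.ndarray:
        return np.concatenate([[0.0], np.cumsum(self.extents_mm)])

    def stiffness_table(self) -> StiffnessTable:
        return normalize_stiffness(
            StiffnessTable(self.zone_ids, self.stiffness_n_per_mm.copy()))


@dataclass(frozen=True)
class EquilibriumResult:
    """Equilibrium sag per segment and the resulting frontal spinal curve."""

    sag_mm: np.ndarray
    spine_heights_mm: dict[str, float]
    curve: SpinalCurve

    @property
    def dev_deg(self) -> float:
        return compute_p8(self.curve).dev_deg


def _segment_stiffness(body: BodySegmentProfile,
                       bed: MattressArrangement) -> np.ndarray:
    """Summed block stiffness under each segment (N/mm).

    Blocks are attributed fractionally by overlap length, i.e. the zone
    stiffness acts as a line density ``k_zone / block_length`` integrated
    over the segment extent.
    """
    sb = body.boundaries_mm
    zb = bed.boundaries_mm
    if zb[-1] < sb[-1] - 1e-6:
        raise UncoveredSegmentError(
            f"mattress covers {zb[-1]:.0f} mm of a {sb[-1]:.0f} mm body")
    K = np.zeros(len(SEGMENT_NAMES))
    for i in range(len(SEGMENT_NAMES)):
        lo, hi = sb[i], sb[i + 1]
        for z in range(len(bed.zone_ids)):
            overlap = max(0.0, min(hi, zb[z + 1]) - max(lo, zb[z]))
            K[i] += bed.stiffness_n_per_mm[z] * overlap / bed.block_length_mm
    if (K <= 0).any():
        bad = [SEGMENT_NAMES[i] for i in np.flatnonzero(K <= 0)]
        raise UncoveredSegmentError(f"no mattress stiffness under {bad}")
    return K


def _second_difference_matrix(n: int) -> np.ndarray:
    D = np.zeros((n - 2, n))
    for i in range(n - 2):
        D[i, i:i + 3] = (1.0, -2.0, 1.0)
    return D


def _solve_box_qp(H: np.ndarray, rhs: np.ndarray, lo: float, hi: float,
                  max_iter: int = 100) -> np.ndarray:
    """Minimize ``s' H s / 2 - rhs' s`` subject to ``lo <= s <= hi``.

    Primal active-set iteration: solve the equality-reduced system, clamp
    violated bounds, release clamped variables whose KKT multiplier points
    inward, repeat. H must be symmetric positive definite (it is: a positive
    diagonal plus a PSD bending term), so the loop terminates at the unique
    minimizer.
    """
    n = len(rhs)
    clamped = np.full(n, np.nan)  # nan = free, else clamped value
    for _ in range(max_iter):
        free = np.isnan(clamped)
        s = clamped.copy()
        if free.any():
            fixed_contrib = H[np.ix_(free, ~free)] @ clamped[~free] if (~free).any() else 0.0
            s[free] = np.linalg.solve(H[np.ix_(free, free)],
                                      rhs[free] - fixed_contrib)
        changed = False
        for i in range(n):
            if free[i]:
                if s[i] < lo - 1e-12:
                    clamped[i] = lo
                    changed = True
                elif s[i] > hi + 1e-12:
                    clamped[i] = hi
                    changed = True
        if not changed:
            grad = H @ s - rhs
            for i in range(n):
                if not free[i]:
                    # Release a clamp whose multiplier has the wrong sign.
                    if (clamped[i] == lo and grad[i] < -1e-12) or \
                       (clamped[i] == hi and grad[i] > 1e-12):
                        clamped[i] = np.nan
                        changed = True
        if not changed:
            return np.clip(s, lo, hi)
    raise ConvergenceError(
        f"active-set equilibrium solve did not settle in {max_iter} iterations "
        f"(residual {np.linalg.norm(np.clip(s, lo, hi) - s):.3g})")


def solve_equilibrium(body: BodySegmentProfile, bed: MattressArrangement,
                      coupling: float = 0.0) -> EquilibriumResult:
    """Quasi-static equilibrium of the segmented body on the zoned mattress.

    Minimizes elastic + gravitational energy
    ``sum(K_i s_i^2 / 2 - m_i g s_i) + coupling * |D (w - s)|^2``
    over segment sags ``s`` in ``[0, max_sag]``, where ``w`` are contour
    half-widths and ``D`` the second-difference operator on segment spine
    heights (``coupling`` in N/mm weights spinal bending). With
    ``coupling = 0`` the solution is the per-segment force balance
    ``s_i = m_i g / K_i``, clipped at 80 % block compression.
    """
    if coupling < 0:
        raise BodyBedError("coupling must be >= 0")
    K = _segment_stiffness(body, bed)
    w = body.half_widths_mm
    load = body.masses_kg * GRAVITY_M_PER_S2
    smax = bed.max_sag_mm

    if coupling == 0:
        sag = np.clip(load / K, 0.0, smax)
    else:
        D = _second_difference_matrix(len(SEGMENT_NAMES))
        H = np.diag(K) + 2.0 * coupling * (D.T @ D)
        rhs = load + 2.0 * coupling * (D.T @ D) @ w
        sag = _solve_box_qp(H, rhs, 0.0, smax)

    heights = w - sag
    spine_heights = {v: float(heights[body.segment_of(x)])
                     for v, x in body.vertebra_x_mm.items()}
    xs = np.array([body.vertebra_x_mm[v] for v in VERTEBRAE])
    ys = np.array([spine_heights[v] for v in VERTEBRAE])
    curve = SpinalCurve(xs, ys, frame="raw")
    return EquilibriumResult(sag_mm=sag, spine_heights_mm=spine_heights,
                             curve=curve)


@dataclass(frozen=True)
class OptimizationResult:
    """Outcome of zonal stiffness customization."""

    arrangement: MattressArrangement
    dev_deg: float
    table: StiffnessTable
    initial_dev_deg: float
    no_improvement: bool


_GOLDEN = (np.sqrt(5.0) - 1.0) / 2.0


def _golden_section(f, lo: float, hi: float, tol: float) -> tuple[float, float]:
    """Deterministic golden-section minimization of ``f`` on [lo, hi]."""
    a, b = lo, hi
    c = b - _GOLDEN * (b - a)
    d = a + _GOLDEN * (b - a)
    fc, fd = f(c), f(d)
    while (b - a) > tol:
        if fc <= fd:
            b, d, fd = d, c, fc
            c = b - _GOLDEN * (b - a)
            fc = f(c)
        else:
            a, c, fc = c, d, fd
            d = a + _GOLDEN * (b - a)
            fd = f(d)
    return (c, fc) if fc <= fd else (d, fd)


def optimize_zones(body: BodySegmentProfile,
                   bounds: tuple[float, float] = (2.0, 20.0),
                   coupling: float = 0.0,
                   tol: float = 1e-4,
                   n_zones: int = 6,
                   max_sweeps: int = 25,
                   bed: MattressArrangement | None = None,
                   ) -> OptimizationResult:
    """Customize zone stiffnesses to straighten the simulated spine.

    Cyclic coordinate descent: zones are visited in fixed order and each
    zone's stiffness is minimized over ``bounds`` by golden-section search
    on the frontal deviation angle; sweeps repeat until the improvement in
    ``dev_deg`` falls below ``tol`` (degrees). Initialization is the
    geometric mean of the bounds, so the procedure is fully deterministic.
    """
    kmin, kmax = float(bounds[0]), float(bounds[1])
    if not (0 < kmin < kmax):
        raise BodyBedError("bounds must satisfy 0 < min < max")
    if bed is None:
        k0 = float(np.sqrt(kmin * kmax))
        bed = MattressArrangement.tiling(body, [k0] * n_zones)
    stiffness = bed.stiffness_n_per_mm.copy()

    def dev_for(k: np.ndarray) -> float:
        return solve_equilibrium(body, replace(bed, stiffness_n_per_mm=k),
                                 coupling=coupling).dev_deg

    current = dev_for(stiffness)
    initial = current
    # Resolve each zone to ~0.1% of the stiffness range per golden search.
    k_tol = 1e-3 * (kmax - kmin)
    for _ in range(max_sweeps):
        before = current
        for z in range(len(stiffness)):
            def f(kz, z=z):
                trial = stiffness.copy()
                trial[z] = kz
                return dev_for(trial)
            k_best, f_best = _golden_section(f, kmin, kmax, k_tol)
            if f_best < current:
                stiffness[z] = k_best
                current = f_best
        if before - current < tol:
            break

    final_bed = replace(bed, stiffness_n_per_mm=stiffness)
    return OptimizationResult(
        arrangement=final_bed,
        dev_deg=current,
        table=final_bed.stiffness_table(),
        initial_dev_deg=initial,
        no_improvement=not (current < initial),
    )
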