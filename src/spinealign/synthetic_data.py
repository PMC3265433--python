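"""Synthetic study inputs with known ground truth.

Generates everything the analysis pipeline consumes:

* cohorts of frontal spinal curves per surface regime, produced by jittering
  an anthropometric preset, solving the body-on-mattress equilibrium on a
  soft uniform bed, a firm uniform bed and a per-subject customized zone
  arrangement, then adding Gaussian marker noise;
* rendered grayscale marker images (Gaussian-profile bright spots, optional
  reference markers flanking the chain) for the detection round trip;
* load-deflection curves from linear, cubic and foam-plateau force models.

The generator's defaults emulate the lateral-lying study protocol:
25 subjects, two trials per subject and surface, ~2 mm marker noise, and
soft/firm uniform regimes of 2 and 100 N/mm per block. All randomness flows
from an explicit seed; identical seeds give identical artifacts.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .body_bed_model import (PRESETS, BodySegmentProfile, MattressArrangement,
                             build_body, optimize_zones, solve_equilibrium)
from .config import DEFAULTS, ConfigError
from .imaging_io import MarkerImage
from .mattress_metrics import LoadDeflectionCurve, MattressMetricsError
from .spine_geometry import (VERTEBRAE, SpinalCurve, compute_p8,
                             write_marker_csv)

__all__ = [
    "CohortConfig", "Cohort", "SubjectRecord",
    "generate_cohort", "write_cohort", "render_marker_image",
    "generate_load_curve", "make_kinked_curve",
]

SURFACES = ("soft", "firm", "custom")


@dataclass(frozen=True)
class CohortConfig:
    """Study conditions for a synthetic cohort.

    ``n_subjects`` subjects are drawn from the preset mix; each is measured
    ``repeats`` times per surface with independent marker noise. ``jitter_sd``
    is the log-normal sd of multiplicative subject variability applied to
    segment masses and contour half-widths.
    """

    n_subjects: int = 25
    preset_mix: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULTS["cohort"]["preset_mix"]))
    soft_stiffness: float = 2.0
    firm_stiffness: float = 100.0
    marker_noise_sd_mm: float = 2.0
    jitter_sd: float = 0.05
    repeats: int = 2
    coupling: float = 2.0
    bounds: tuple[float, float] = (2.0, 20.0)
    seed: int = 0

    def __post_init__(self):
        if self.n_subjects < 1:
            raise ConfigError("n_subjects must be >= 1")
        if self.marker_noise_sd_mm < 0 or self.jitter_sd < 0:
            raise ConfigError("noise and jitter sds must be >= 0")
        if self.repeats < 1:
            raise ConfigError("repeats must be >= 1")
        mix = dict(self.preset_mix)
        unknown = set(mix) - set(PRESETS)
        if unknown:
            raise ConfigError(f"unknown presets in mix: {sorted(unknown)}")
        if abs(sum(mix.values()) - 1.0) > 1e-9:
            raise ConfigError("preset_mix proportions must sum to 1")


@dataclass(frozen=True)
class SubjectRecord:
    """One subject x surface x repeat observation plus its ground truth."""

    subject: int
    preset: str
    surface: str
    repeat: int
    curve: SpinalCurve
    true_dev_deg: float


@dataclass(frozen=True)
class Cohort:
    records: tuple[SubjectRecord, ...]
    config: CohortConfig

    def ground_truth(self) -> pd.DataFrame:
        rows = [{"subject": r.subject, "preset": r.preset, "surface": r.surface,
                 "repeat": r.repeat, "true_dev_deg": r.true_dev_deg}
                for r in self.records]
        return pd.DataFrame(rows)


def _jittered_body(preset_name: str, jitter_sd: float,
                   rng: np.random.Generator) -> BodySegmentProfile:
    body = build_body(PRESETS[preset_name])
    if jitter_sd == 0:
        return body
    n = len(body.masses_kg)
    masses = body.masses_kg * rng.lognormal(0.0, jitter_sd, n)
    widths = body.half_widths_mm * rng.lognormal(0.0, jitter_sd, n)
    return BodySegmentProfile(masses, body.extents_mm.copy(), widths,
                              dict(body.vertebra_x_mm), dict(body.posture))


def _noisy_curve(curve: SpinalCurve, sd: float,
                 rng: np.random.Generator) -> SpinalCurve:
    if sd == 0:
        return curve
    x = curve.x + rng.normal(0.0, sd, len(curve.x))
    y = curve.y + rng.normal(0.0, sd, len(curve.y))
    return SpinalCurve(x, y, frame="raw")


def generate_cohort(config: CohortConfig) -> Cohort:
    """Simulate the three-surface protocol for a synthetic cohort.

    For every subject: draw a preset from the mix, jitter the body, solve the
    equilibrium on the soft and firm uniform beds and on the zone arrangement
    customized to that subject, then emit ``repeats`` noisy marker curves per
    surface. The noiseless model deviation is recorded as ground truth.
    """
    rng = np.random.default_rng(config.seed)
    names = sorted(config.preset_mix)
    probs = np.array([config.preset_mix[n] for n in names])
    records: list[SubjectRecord] = []
    for subject in range(1, config.n_subjects + 1):
        preset = str(rng.choice(names, p=probs))
        body = _jittered_body(preset, config.jitter_sd, rng)
        beds = {
            "soft": MattressArrangement.tiling(
                body, [config.soft_stiffness] * 6),
            "firm": MattressArrangement.tiling(
                body, [config.firm_stiffness] * 6),
            "custom": optimize_zones(body, bounds=config.bounds,
                                     coupling=config.coupling).arrangement,
        }
        for surface in SURFACES:
            eq = solve_equilibrium(body, beds[surface],
                                   coupling=config.coupling)
            true_dev = compute_p8(eq.curve).dev_deg
            for repeat in range(1, config.repeats + 1):
                noisy = _noisy_curve(eq.curve, config.marker_noise_sd_mm, rng)
                records.append(SubjectRecord(
                    subject=subject, preset=preset, surface=surface,
                    repeat=repeat, curve=noisy, true_dev_deg=true_dev))
    return Cohort(tuple(records), config)


def write_cohort(cohort: Cohort, out_dir: str | Path) -> Path:
    """Write a cohort as marker CSVs plus index and ground-truth tables."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rows = []
    for r in cohort.records:
        name = f"s{r.subject:03d}_{r.surface}_r{r.repeat}.csv"
        write_marker_csv(r.curve, out / name)
        rows.append({"subject": r.subject, "preset": r.preset,
                     "surface": r.surface, "repeat": r.repeat, "path": name})
    pd.DataFrame(rows).to_csv(out / "index.csv", index=False)
    cohort.ground_truth().to_csv(out / "ground_truth.csv", index=False)
    return out


def make_kinked_curve(kink_deg: float, spine_length_mm: float = 500.0,
                      noise_sd: float = 0.0, seed: int = 0) -> SpinalCurve:
    """A spinal curve with an exactly known thoracolumbar kink angle.

    The lumbar markers (T12..L5) lie on the longitudinal axis; the thoracic
    markers (C7..T10) lie on a straight line tilted ``kink_deg`` degrees,
    hinged midway between T10 and T12 (where the marker-less T11 would sit).
    With ``noise_sd = 0`` the pi-P8 deviation of the curve equals
    ``kink_deg`` exactly. Markers are spaced by anatomical vertebral level.
    """
    if not 0 <= kink_deg < 90:
        raise ValueError("kink_deg must lie in [0, 90)")
    from .spine_geometry import VERTEBRAL_LEVEL
    max_level = VERTEBRAL_LEVEL["L5"]
    # caudal -> cephalad x, L5 at 0.
    x = np.array([(max_level - VERTEBRAL_LEVEL[v]) / max_level * spine_length_mm
                  for v in VERTEBRAE])
    hinge = 0.5 * (x[VERTEBRAE.index("T10")] + x[VERTEBRAE.index("T12")])
    y = np.where(x > hinge,
                 np.tan(np.radians(kink_deg)) * (x - hinge), 0.0)
    curve = SpinalCurve(x, y, frame="raw")
    if noise_sd > 0:
        curve = _noisy_curve(curve, noise_sd, np.random.default_rng(seed))
    return curve


# ---------------------------------------------------------------------------
# Marker image rendering.

def render_marker_image(curve: SpinalCurve,
                        marker_radius_px: int = 4,
                        scale_mm_per_px: float = 2.0,
                        noise_sd: float = 0.0,
                        seed: int = 0,
                        include_reference: bool = False,
                        pad_mm: float = 30.0,
                        canvas_shape: tuple[int, int] | None = None,
                        ) -> MarkerImage:
    """Render bright Gaussian-profile markers on a dark canvas.

    Markers are stamped at the curve's coordinates (x -> columns,
    y -> rows) with peak intensity 1 and profile sd ``radius / 2``. With
    ``include_reference``, four reference markers are added per the capture
    protocol: two 50 mm lateral of L5 and two 100 mm beyond C7 (also placed
    laterally, flanking the subject). Additive Gaussian pixel noise is
    applied and intensities clipped to [0, 1]. If an explicit
    ``canvas_shape`` (rows, cols) is too small to contain every marker, an
    error is raised.
    """
    if marker_radius_px < 2:
        raise ValueError("marker_radius_px must be >= 2")
    pts = np.column_stack([curve.x, curve.y]).astype(float)
    if include_reference:
        # Reference pairs flank the subject: 50 mm from L5 and 100 mm from
        # C7, angled 30 deg off the chord so each pair straddles the spine
        # while clearly overshooting the marker chain longitudinally.
        l5 = np.array(curve.point("L5"))
        c7 = np.array(curve.point("C7"))
        chord = c7 - l5
        u = chord / np.hypot(*chord)
        nvec = np.array([-u[1], u[0]])
        cos30, sin30 = np.cos(np.pi / 6), np.sin(np.pi / 6)
        refs = np.array([
            l5 - 50.0 * (cos30 * u - sin30 * nvec),
            l5 - 50.0 * (cos30 * u + sin30 * nvec),
            c7 + 100.0 * (cos30 * u + sin30 * nvec),
            c7 + 100.0 * (cos30 * u - sin30 * nvec),
        ])
        pts = np.vstack([pts, refs])

    origin = pts.min(axis=0) - pad_mm
    px = (pts - origin) / scale_mm_per_px
    if canvas_shape is None:
        extent = (pts.max(axis=0) - origin + pad_mm) / scale_mm_per_px
        canvas_shape = (int(np.ceil(extent[1])) + 1, int(np.ceil(extent[0])) + 1)
    rows, cols = canvas_shape
    margin = float(marker_radius_px)
    if ((px[:, 0] < margin) | (px[:, 0] > cols - 1 - margin)
            | (px[:, 1] < margin) | (px[:, 1] > rows - 1 - margin)).any():
        raise ValueError("marker falls outside the canvas")

    img = np.zeros((rows, cols))
    sigma = marker_radius_px / 2.0
    half = int(np.ceil(4 * sigma))
    for cx, cy in px:
        r0, r1 = int(np.floor(cy)) - half, int(np.floor(cy)) + half + 1
        c0, c1 = int(np.floor(cx)) - half, int(np.floor(cx)) + half + 1
        r0, c0 = max(r0, 0), max(c0, 0)
        r1, c1 = min(r1, rows), min(c1, cols)
        rr, cc = np.meshgrid(np.arange(r0, r1), np.arange(c0, c1),
                             indexing="ij")
        img[r0:r1, c0:c1] += np.exp(
            -((rr - cy) ** 2 + (cc - cx) ** 2) / (2.0 * sigma ** 2))
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        img = img + rng.normal(0.0, noise_sd, img.shape)
    return MarkerImage(np.clip(img, 0.0, 1.0), scale_mm_per_px)


# ---------------------------------------------------------------------------
# Load-deflection curve models.

def generate_load_curve(model: str, params: Mapping[str, float],
                        n_samples: int = 200,
                        max_force_n: float = 500.0) -> LoadDeflectionCurve:
    """Sample a monotone loading curve from a parametric force model.

    Models:
      * ``linear``: F = k * d, ``params = {"k": N/mm}``;
      * ``cubic``:  F = a * d**3, ``params = {"a": N/mm^3}``;
      * ``foam``:   F = k1 * d + a * d**3, an initial slope with cubic
        densification, ``params = {"k1", "a"}``.

    The curve is sampled on a uniform deflection grid from 0 to the
    deflection where the force reaches ``max_force_n`` (default 500 N, past
    the 450 N work limit). Parameter sets that violate monotonicity or never
    reach the force level are rejected.
    """
    models = {
        "linear": lambda d, p: p["k"] * d,
        "cubic": lambda d, p: p["a"] * d ** 3,
        "foam": lambda d, p: p["k1"] * d + p["a"] * d ** 3,
    }
    if model not in models:
        raise MattressMetricsError(
            f"unknown load-curve model {model!r}; choose from {sorted(models)}")
    f = models[model]
    p = dict(params)
    # Find the deflection reaching max_force_n by bisection on a huge bracket.
    d_hi = 1.0
    for _ in range(80):
        if f(d_hi, p) >= max_force_n:
            break
        d_hi *= 2.0
    else:
        raise MattressMetricsError(
            f"model never reaches {max_force_n} N; parameters too soft")
    lo, hi = 0.0, d_hi
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if f(mid, p) < max_force_n:
            lo = mid
        else:
            hi = mid
    d = np.linspace(0.0, hi, n_samples)
    force = np.asarray(f(d, p), dtype=float)
    if (np.diff(force) < 0).any():
        raise MattressMetricsError(
            f"{model} model with {p} is non-monotone on the loading branch")
    return LoadDeflectionCurve(d, force)
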