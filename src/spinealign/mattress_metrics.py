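"""LGA mattress stiffness metrics from quasi-static load-deflection curves.

Following the LGA convention for rating sleep-surface firmness, a loading
curve F(d) measured on a mattress core yields two summaries:

* ``E`` (N.mm): the work needed to compress the core up to a force of
  450 N, i.e. the area under the loading curve between 0 and 450 N;
* ``C`` (N/mm): the average differential stiffness, the mean slope of
  tangents to the loading curve at the 210, 275 and 340 N force levels.

Their ratio ``E/C`` (mm^2) increases with softness and classifies the
surface into soft / medium / firm bands. The official band boundaries are
not public; they are configurable here, with defaults placing the classic
soft-surface example (E/C ~ 2476 mm^2) in the soft class.
"""
from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .config import ConfigError

__all__ = [
    "E_FORCE_LIMIT_N", "C_FORCE_LEVELS_N",
    "LoadDeflectionCurve", "LgaMetrics", "StiffnessTable",
    "MattressMetricsError", "InsufficientLoadError",
    "compute_E", "compute_C", "compute_lga", "classify_surface",
    "normalize_stiffness",
    "read_load_curve_csv", "write_load_curve_csv",
    "read_stiffness_csv", "write_stiffness_csv",
]

#: Upper force bound of the compression-work integral (N).
E_FORCE_LIMIT_N = 450.0
#: Force levels at which tangent slopes are averaged for C (N).
C_FORCE_LEVELS_N = (210.0, 275.0, 340.0)


class MattressMetricsError(ValueError):
    """Invalid load-deflection input."""


class InsufficientLoadError(MattressMetricsError):
    """The loading curve does not reach the required force level."""


@dataclass(frozen=True)
class LoadDeflectionCurve:
    """Loading branch of a quasi-static compression test.

    Deflection (mm) must be strictly increasing and start at 0; force (N)
    must be non-decreasing and start at 0.
    """

    deflection_mm: np.ndarray
    force_n: np.ndarray

    def __post_init__(self):
        d = np.asarray(self.deflection_mm, dtype=float)
        f = np.asarray(self.force_n, dtype=float)
        object.__setattr__(self, "deflection_mm", d)
        object.__setattr__(self, "force_n", f)
        if d.ndim != 1 or d.shape != f.shape or len(d) < 2:
            raise MattressMetricsError("need matching 1-D arrays of >= 2 samples")
        if not (np.isfinite(d).all() and np.isfinite(f).all()):
            raise MattressMetricsError("non-finite samples")
        if d[0] != 0 or f[0] != 0:
            raise MattressMetricsError("loading curve must start at (0, 0)")
        if not (np.diff(d) > 0).all():
            raise MattressMetricsError("deflection must be strictly increasing")
        if (np.diff(f) < 0).any():
            raise MattressMetricsError("force must be non-decreasing (loading branch)")

    @property
    def max_force_n(self) -> float:
        return float(self.force_n[-1])


@dataclass(frozen=True)
class LgaMetrics:
    """LGA summary of a loading curve: work E, stiffness C, softness E/C."""

    E_nmm: float
    C_n_per_mm: float
    ratio_mm2: float
    surface_class: str


@dataclass(frozen=True)
class StiffnessTable:
    """Per-zone mattress stiffness, optionally normalized to % of maximum."""

    zone_ids: tuple[int, ...]
    stiffness_n_per_mm: np.ndarray
    normalized_pct: np.ndarray | None = None

    def __post_init__(self):
        k = np.asarray(self.stiffness_n_per_mm, dtype=float)
        object.__setattr__(self, "stiffness_n_per_mm", k)
        if len(self.zone_ids) != len(k):
            raise MattressMetricsError("zone_ids and stiffness lengths differ")
        if (k <= 0).any() or not np.isfinite(k).all():
            raise MattressMetricsError("zone stiffness must be positive and finite")
        if self.normalized_pct is not None:
            object.__setattr__(self, "normalized_pct",
                               np.asarray(self.normalized_pct, dtype=float))


def _deflection_at_force(curve: LoadDeflectionCurve, level: float) -> float:
    """Deflection at which force first reaches ``level`` (linear interpolation)."""
    f, d = curve.force_n, curve.deflection_mm
    if curve.max_force_n < level:
        raise InsufficientLoadError(
            f"curve reaches only {curve.max_force_n:.1f} N, "
            f"needs {level:.0f} N ({level - curve.max_force_n:.1f} N short)")
    i = int(np.searchsorted(f, level, side="left"))
    if f[i] == level:
        return float(d[i])
    # level lies strictly inside (f[i-1], f[i]); f[i] > f[i-1] here.
    if i == 0:
        return float(d[0])
    frac = (level - f[i - 1]) / (f[i] - f[i - 1])
    return float(d[i - 1] + frac * (d[i] - d[i - 1]))


def compute_E(curve: LoadDeflectionCurve) -> float:
    """Compression work (N.mm): area under the loading curve up to 450 N.

    Trapezoidal integration over the samples, with the endpoint where the
    force crosses 450 N located by linear interpolation so the integral
    stops exactly at the force limit.
    """
    d450 = _deflection_at_force(curve, E_FORCE_LIMIT_N)
    d, f = curve.deflection_mm, curve.force_n
    inside = d <= d450
    d_in = np.append(d[inside], d450)
    f_in = np.append(f[inside], np.interp(d450, d, f))
    return float(np.trapezoid(f_in, d_in))


def compute_C(curve: LoadDeflectionCurve, levels: Sequence[float] = C_FORCE_LEVELS_N,
              ) -> float:
    """Average differential stiffness (N/mm).

    Mean tangent slope dF/dd at the deflections where the force reaches each
    of the configured levels (default 210, 275, 340 N). Each tangent is a
    central finite difference across the sample nearest the crossing.
    """
    d, f = curve.deflection_mm, curve.force_n
    slopes = []
    for level in levels:
        if np.count_nonzero(f == level) > 1:
            raise MattressMetricsError(
                f"force plateau at {level:.0f} N; tangent location ambiguous")
        d_star = _deflection_at_force(curve, level)
        j = int(np.clip(np.argmin(np.abs(d - d_star)), 1, len(d) - 2))
        slope = (f[j + 1] - f[j - 1]) / (d[j + 1] - d[j - 1])
        if slope <= 0:
            raise MattressMetricsError(
                f"flat curve around {level:.0f} N; tangent slope undefined")
        slopes.append(slope)
    return float(np.mean(slopes))


def _validate_bands(bands: Sequence[Sequence]) -> list[tuple[str, float]]:
    out = [(str(label), float(edge)) for label, edge in bands]
    if not out:
        raise ConfigError("lga.bands must list at least one band")
    edges = [e for _, e in out]
    if any(b >= a for a, b in zip(edges, edges[1:])):
        raise ConfigError("lga.bands edges must be strictly decreasing")
    if edges[-1] != 0.0:
        raise ConfigError("lowest lga.bands edge must be 0 so every ratio maps")
    if any(e < 0 for e in edges):
        raise ConfigError("lga.bands edges must be non-negative")
    return out


def classify_surface(ratio_mm2: float, bands: Sequence[Sequence]) -> str:
    """Band lookup of the E/C softness ratio.

    ``bands`` is a sequence of ``(label, lower_edge)`` with strictly
    decreasing edges; bands are closed on the lower edge, so a ratio exactly
    on an edge falls in the softer (higher-ratio) band.
    """
    if not ratio_mm2 > 0:
        raise MattressMetricsError("E/C ratio must be positive")
    for label, edge in _validate_bands(bands):
        if ratio_mm2 >= edge:
            return label
    raise AssertionError("unreachable: lowest band edge is 0")


def compute_lga(curve: LoadDeflectionCurve, bands: Sequence[Sequence]) -> LgaMetrics:
    """Full LGA summary: E, C, E/C and the softness class."""
    E = compute_E(curve)
    C = compute_C(curve)
    ratio = E / C
    return LgaMetrics(E_nmm=E, C_n_per_mm=C, ratio_mm2=ratio,
                      surface_class=classify_surface(ratio, bands))


def normalize_stiffness(table: StiffnessTable) -> StiffnessTable:
    """Express zone stiffness as percent of the stiffest zone.

    Each value becomes ``100 * k / max(k)``, rounded to one decimal for
    reporting; raw values are retained. The maximum normalized value is 100
    exactly and the result is invariant to scaling all raw values.
    """
    k = table.stiffness_n_per_mm
    normalized = np.round(100.0 * k / k.max(), 1)
    return StiffnessTable(table.zone_ids, k.copy(), normalized)


# ---------------------------------------------------------------------------
# CSV I/O.

def read_load_curve_csv(path: str | Path) -> LoadDeflectionCurve:
    df = pd.read_csv(path, comment="#")
    if not {"deflection_mm", "force_N"}.issubset(df.columns):
        raise MattressMetricsError(
            f"{path}: expected columns deflection_mm,force_N")
    return LoadDeflectionCurve(df["deflection_mm"].to_numpy(),
                               df["force_N"].to_numpy())


def write_load_curve_csv(curve: LoadDeflectionCurve, path: str | Path) -> None:
    pd.DataFrame({"deflection_mm": curve.deflection_mm,
                  "force_N": curve.force_n}).to_csv(path, index=False)


def read_stiffness_csv(path: str | Path) -> StiffnessTable:
    df = pd.read_csv(path, comment="#")
    normalized = (df["normalized_pct"].to_numpy()
                  if "normalized_pct" in df.columns else None)
    return StiffnessTable(tuple(int(z) for z in df["zone"]),
                          df["stiffness_N_per_mm"].to_numpy(), normalized)


def write_stiffness_csv(table: StiffnessTable, path: str | Path) -> None:
    data = {"zone": table.zone_ids,
            "stiffness_N_per_mm": table.stiffness_n_per_mm}
    if table.normalized_pct is not None:
        data["normalized_pct"] = table.normalized_pct
    pd.DataFrame(data).to_csv(path, index=False)
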