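"""Frontal-plane spinal geometry: the P8 kink angle and its deviation statistic.

A lateral-lying subject's spine is observed in the frontal plane as an
ordered chain of 12 surface markers over the spinous processes of
C7, T1, T2, T3, T4, T6, T8, T10, T12, L1, L2 and L5. The spinal slope
typically shows a discontinuity near T11, at the transition from the
flexible lumbar region to the stiffer thoracic region, so the chain is
split there into a thoracic part (C7..T10) and a lumbar part (T12..L5).
An orthogonal-regression (total least squares) line is fitted to each
part; the angle between the two lines is the frontal parameter P8, equal
to 180 deg for a perfectly straight spine. The deviation from straightness,
``dev_deg = 180 - P8``, is the quantity compared across sleep surfaces and
minimized when customizing a zoned mattress.

P8 is invariant under similarity transforms of the marker coordinates
(translation, rotation, reflection, uniform scaling), which is what makes
curves from different subjects and camera setups comparable once matched
to a common chord.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "VERTEBRAE", "THORACIC", "LUMBAR", "VERTEBRAL_LEVEL",
    "SpinalCurve", "FrontalParameters",
    "SpineGeometryError", "DegenerateSpineError", "MissingVertebraError",
    "fit_segment_line", "compute_p8", "normalize_curve",
    "read_marker_csv", "write_marker_csv",
]

#: Marker set in cephalad -> caudal order. Exactly these 12, always.
VERTEBRAE: tuple[str, ...] = (
    "C7", "T1", "T2", "T3", "T4", "T6", "T8", "T10", "T12", "L1", "L2", "L5",
)
#: Thoracic segment: everything cephalad of the (marker-less) T11 transition.
THORACIC: tuple[str, ...] = VERTEBRAE[:8]
#: Lumbar segment: T12 and below.
LUMBAR: tuple[str, ...] = VERTEBRAE[8:]

#: Anatomical level index of each marker (C7 = 0, one unit per vertebra),
#: used to space markers proportionally along the spine.
VERTEBRAL_LEVEL: dict[str, int] = {
    "C7": 0, "T1": 1, "T2": 2, "T3": 3, "T4": 4, "T6": 6, "T8": 8,
    "T10": 10, "T12": 12, "L1": 13, "L2": 14, "L5": 17,
}

#: Chord length of a normalized curve: L5 -> (0, 0), C7 -> (chord, 0).
NORMALIZED_CHORD_MM = 1000.0


class SpineGeometryError(ValueError):
    """Invalid spinal-curve input."""


class DegenerateSpineError(SpineGeometryError):
    """L5 and C7 coincide: the spine chord has zero length."""


class MissingVertebraError(SpineGeometryError):
    """A required vertebra marker is absent."""


@dataclass(frozen=True)
class SpinalCurve:
    """Ordered frontal-plane marker coordinates of the 12 named vertebrae.

    ``x`` is the longitudinal position (mm) and ``y`` the lateral deviation
    (mm) of each marker, stored in the fixed cephalad->caudal order of
    :data:`VERTEBRAE`. ``x`` must be strictly monotone along the chain.
    """

    x: np.ndarray
    y: np.ndarray
    frame: str = "raw"

    def __post_init__(self):
        x = np.asarray(self.x, dtype=float)
        y = np.asarray(self.y, dtype=float)
        object.__setattr__(self, "x", x)
        object.__setattr__(self, "y", y)
        if x.shape != (len(VERTEBRAE),) or y.shape != (len(VERTEBRAE),):
            raise SpineGeometryError(
                f"curve needs exactly {len(VERTEBRAE)} points, "
                f"got x{x.shape}, y{y.shape}")
        if not (np.isfinite(x).all() and np.isfinite(y).all()):
            raise SpineGeometryError("non-finite marker coordinates")
        # Markers must be strictly ordered along the spine axis. To keep the
        # check meaningful in any camera orientation it is applied to the
        # projection onto the L5-C7 chord (equals plain x-monotonicity when
        # the chord is axis-aligned); a zero-length chord is degenerate.
        chord = np.array([x[-1] - x[0], y[-1] - y[0]])
        if not np.hypot(*chord) > 0:
            raise DegenerateSpineError("L5 and C7 coincide: zero-length spine")
        proj = np.column_stack([x, y]) @ chord
        if not (np.diff(proj) > 0).all():
            raise SpineGeometryError(
                "markers must be strictly monotone along the spine from L5 to C7")
        if self.frame not in ("raw", "normalized"):
            raise SpineGeometryError(f"unknown frame {self.frame!r}")

    @classmethod
    def from_points(cls, points: Mapping[str, tuple[float, float]],
                    frame: str = "raw") -> "SpinalCurve":
        """Build a curve from a ``{vertebra: (x, y)}`` mapping.

        Raises :class:`MissingVertebraError` naming any absent marker.
        """
        missing = [v for v in VERTEBRAE if v not in points]
        if missing:
            raise MissingVertebraError(
                f"missing vertebra marker(s): {', '.join(missing)}")
        xs = np.array([points[v][0] for v in VERTEBRAE], dtype=float)
        ys = np.array([points[v][1] for v in VERTEBRAE], dtype=float)
        return cls(xs, ys, frame=frame)

    def point(self, vertebra: str) -> tuple[float, float]:
        i = VERTEBRAE.index(vertebra)
        return float(self.x[i]), float(self.y[i])

    def coords(self, vertebrae: Sequence[str]) -> np.ndarray:
        """(n, 2) coordinate array for a subset of vertebrae, in given order."""
        idx = [VERTEBRAE.index(v) for v in vertebrae]
        return np.column_stack([self.x[idx], self.y[idx]])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"vertebra": VERTEBRAE, "x_mm": self.x, "y_mm": self.y})


@dataclass(frozen=True)
class FrontalParameters:
    """P8 angle, the pi-P8 deviation, and per-vertebra chord deviations.

    ``p8_deg`` is 180 for a straight spine; ``dev_deg = 180 - p8_deg`` is the
    deviation-from-straightness statistic. ``chord_dev_mm`` holds the signed
    orthogonal deviation of every marker from the L5-C7 chord, in the order
    of :data:`VERTEBRAE` (a descriptive companion, not part of P8).
    """

    p8_deg: float
    dev_deg: float
    chord_dev_mm: np.ndarray = field(repr=False)

    def chord_dev(self, vertebra: str) -> float:
        return float(self.chord_dev_mm[VERTEBRAE.index(vertebra)])


def fit_segment_line(points: Iterable[tuple[float, float]] | np.ndarray,
                     orient: np.ndarray | None = None,
                     ) -> tuple[np.ndarray, np.ndarray]:
    """Total-least-squares (orthogonal regression) line through 2-D points.

    Returns ``(direction, centroid)`` where ``direction`` is a unit vector
    minimizing the sum of squared orthogonal distances. The sign of the
    direction follows ``orient`` if given; otherwise it follows the order of
    the input (positive projection on last point - first point).

    Raises :class:`SpineGeometryError` for fewer than 2 distinct points.
    """
    pts = np.asarray(list(points) if not isinstance(points, np.ndarray) else points,
                     dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2 or pts.shape[0] < 2:
        raise SpineGeometryError("need at least 2 points of shape (n, 2)")
    centroid = pts.mean(axis=0)
    centered = pts - centroid
    if not np.any(np.abs(centered) > 0):
        raise SpineGeometryError("all points coincide; line is undefined")
    # Principal axis of the centered cloud = TLS direction.
    _, _, vt = np.linalg.svd(centered, full_matrices=False)
    direction = vt[0]
    if orient is None:
        orient = pts[-1] - pts[0]
    s = float(np.dot(direction, orient))
    if s < 0:
        direction = -direction
    elif s == 0 and (direction[0] < 0 or (direction[0] == 0 and direction[1] < 0)):
        direction = -direction
    return direction, centroid


def _chord(curve: SpinalCurve) -> np.ndarray:
    """Caudal->cephalad chord vector, L5 -> C7."""
    l5 = np.array(curve.point("L5"))
    c7 = np.array(curve.point("C7"))
    return c7 - l5


def compute_p8(curve: SpinalCurve) -> FrontalParameters:
    """Compute the frontal P8 angle and pi-P8 deviation of a spinal curve.

    The thoracic line is fitted to C7..T10 and the lumbar line to T12..L5
    (the split falls strictly between T10 and T12, since T11 carries no
    marker). Both directions are oriented caudal->cephalad along the L5-C7
    chord before taking the angle between them, so ``dev_deg`` is the
    unsigned kink angle in [0, 180] and ``p8_deg = 180 - dev_deg``.
    """
    chord = _chord(curve)
    chord_len = float(np.hypot(*chord))
    if chord_len <= 0:
        raise DegenerateSpineError("L5 and C7 coincide")
    d_th, _ = fit_segment_line(curve.coords(THORACIC), orient=chord)
    d_lu, _ = fit_segment_line(curve.coords(LUMBAR), orient=chord)
    cosang = float(np.clip(np.dot(d_th, d_lu), -1.0, 1.0))
    dev = float(np.degrees(np.arccos(cosang)))
    # Signed orthogonal deviation of each marker from the L5-C7 chord.
    l5 = np.array(curve.point("L5"))
    n = np.array([-chord[1], chord[0]]) / chord_len
    rel = np.column_stack([curve.x, curve.y]) - l5
    chord_dev = rel @ n
    return FrontalParameters(p8_deg=180.0 - dev, dev_deg=dev,
                             chord_dev_mm=chord_dev)


def normalize_curve(curve: SpinalCurve) -> SpinalCurve:
    """Similarity-map a raw curve onto the common chord frame.

    Translation + rotation + uniform scaling (no reflection) maps L5 to
    (0, 0) and C7 to (:data:`NORMALIZED_CHORD_MM`, 0); relative geometry,
    and hence P8, is preserved exactly.
    """
    if curve.frame != "raw":
        raise SpineGeometryError("curve is already normalized")
    l5 = curve.point("L5")
    chord = _chord(curve)
    chord_c = complex(chord[0], chord[1])
    if abs(chord_c) <= 0:
        raise DegenerateSpineError("L5 and C7 coincide: zero-length spine")
    z = (curve.x - l5[0]) + 1j * (curve.y - l5[1])
    w = NORMALIZED_CHORD_MM * z / chord_c
    return SpinalCurve(w.real.copy(), w.imag.copy(), frame="normalized")


# ---------------------------------------------------------------------------
# Marker CSV I/O: header `vertebra,x_mm,y_mm`, `#` comments; the writer adds
# a `# frame: <raw|normalized>` comment line.

def read_marker_csv(path: str | Path) -> SpinalCurve:
    path = Path(path)
    frame = "raw"
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line.startswith("#"):
                body = line.lstrip("#").strip()
                if body.lower().startswith("frame:"):
                    frame = body.split(":", 1)[1].strip()
            elif line:
                break
    df = pd.read_csv(path, comment="#")
    required = {"vertebra", "x_mm", "y_mm"}
    if not required.issubset(df.columns):
        raise SpineGeometryError(
            f"{path}: expected columns {sorted(required)}, got {list(df.columns)}")
    points = {str(r.vertebra): (float(r.x_mm), float(r.y_mm))
              for r in df.itertuples()}
    return SpinalCurve.from_points(points, frame=frame)


def write_marker_csv(curve: SpinalCurve, path: str | Path) -> None:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(f"# frame: {curve.frame}\n")
        curve.to_frame().to_csv(fh, index=False)
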