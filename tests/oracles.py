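"""Independent brute-force oracles used only by the tests.

These deliberately avoid the library's own code paths: the line fit is an
exhaustive angle scan and the kink angle an explicit arccos of a dot
product, so agreement with the package is a genuine cross-check.
"""
from __future__ import annotations

import numpy as np

THORACIC_ORACLE = ("C7", "T1", "T2", "T3", "T4", "T6", "T8", "T10")
LUMBAR_ORACLE = ("T12", "L1", "L2", "L5")
ORDER = THORACIC_ORACLE + LUMBAR_ORACLE


def scan_tls_angle(points: np.ndarray, coarse_deg: float = 0.01,
                   fine_deg: float = 1e-5) -> float:
    """Orientation (deg, in [0, 180)) of the orthogonal-regression line,
    found by exhaustive angle scan: coarse grid then a refined window."""
    pts = np.asarray(points, dtype=float)
    centered = pts - pts.mean(axis=0)

    def residual(angles_deg):
        ang = np.radians(angles_deg)
        normals = np.stack([-np.sin(ang), np.cos(ang)], axis=1)  # (m, 2)
        proj = centered @ normals.T                               # (n, m)
        return (proj ** 2).sum(axis=0)

    grid = np.arange(0.0, 180.0, coarse_deg)
    best = grid[np.argmin(residual(grid))]
    window = np.arange(best - 2 * coarse_deg, best + 2 * coarse_deg, fine_deg)
    return float(window[np.argmin(residual(window))] % 180.0)


def brute_force_dev_deg(curve) -> float:
    """pi-P8 deviation via the angle-scan TLS oracle on both segments."""
    pts = {v: np.array(curve.point(v)) for v in ORDER}
    chord = pts["C7"] - pts["L5"]

    def segment_dir(labels):
        arr = np.array([pts[v] for v in labels])
        ang = np.radians(scan_tls_angle(arr))
        d = np.array([np.cos(ang), np.sin(ang)])
        return d if np.dot(d, chord) >= 0 else -d

    d_th = segment_dir(THORACIC_ORACLE)
    d_lu = segment_dir(LUMBAR_ORACLE)
    return float(np.degrees(np.arccos(np.clip(np.dot(d_th, d_lu), -1, 1))))


def random_curve(rng: np.random.Generator, lateral_sd: float = 15.0):
    """A random valid spinal curve (strictly monotone x, bounded lateral y)."""
    from spinealign.spine_geometry import VERTEBRAE, SpinalCurve
    n = len(VERTEBRAE)
    steps = rng.uniform(20.0, 60.0, n - 1)
    x = np.concatenate([[0.0], np.cumsum(steps)])[::-1]  # C7 high, L5 at 0
    y = rng.normal(0.0, lateral_sd, n)
    return SpinalCurve(x, y, frame="raw")
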