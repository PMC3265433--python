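"""Marker localization in frontal-plane grayscale images.

Bright circular markers on a dark background are segmented by intensity
thresholding, grouped into 8-connected components, and summarized by their
intensity-weighted centroids ("locus of the marker center"), which reduces
the bias of picking a single bright pixel. Detected centroids are then
ordered along the body axis and assigned to the 12 vertebra labels; the
four reference markers of the capture protocol (placed 5 cm lateral of L5
and 10 cm beyond C7) are recognized and excluded because they sit outside
the marker chain, either laterally or longitudinally.
"""
from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import imageio.v3 as iio
import numpy as np
from skimage import measure

from .spine_geometry import (VERTEBRAE, VERTEBRAL_LEVEL, SpinalCurve,
                             fit_segment_line)

__all__ = [
    "MarkerImage", "MarkerDetection", "ImagingError", "MarkerCountError",
    "detect_marker_centroids", "centroids_to_curve",
    "read_image", "write_image",
]


class ImagingError(ValueError):
    """Invalid imaging input."""


class MarkerCountError(ImagingError):
    """Number of candidate marker centroids differs from the required 12."""


@dataclass(frozen=True)
class MarkerImage:
    """Grayscale image with intensities in [0, 1] and a mm-per-pixel scale."""

    pixels: np.ndarray
    scale_mm_per_px: float

    def __post_init__(self):
        px = np.asarray(self.pixels, dtype=float)
        object.__setattr__(self, "pixels", px)
        if px.ndim != 2:
            raise ImagingError("image must be a 2-D intensity grid")
        if px.size and (px.min() < 0 or px.max() > 1):
            raise ImagingError("intensities must lie in [0, 1]")
        if not self.scale_mm_per_px > 0:
            raise ImagingError("scale must be positive")


@dataclass(frozen=True)
class MarkerDetection:
    """Centroids (mm, image frame: x = column, y = row) and component areas."""

    centroids_mm: np.ndarray  # (n, 2)
    areas_px: np.ndarray      # (n,)

    def __len__(self) -> int:
        return len(self.areas_px)


def detect_marker_centroids(image: MarkerImage,
                            intensity_threshold: float = 0.5,
                            min_area_px: int = 4) -> MarkerDetection:
    """Find bright-marker centroids by thresholding and connected components.

    Pixels strictly above ``intensity_threshold`` are grouped into
    8-connected components; components with at least ``min_area_px`` pixels
    contribute one intensity-weighted centroid each, converted to mm via the
    image scale. An empty image or no component above threshold yields an
    empty detection.
    """
    if not (0.0 < intensity_threshold < 1.0):
        raise ImagingError("intensity_threshold must lie in (0, 1)")
    if min_area_px < 1:
        raise ImagingError("min_area_px must be >= 1")
    px = image.pixels
    if px.size == 0:
        return MarkerDetection(np.empty((0, 2)), np.empty(0, dtype=int))
    labels = measure.label(px > intensity_threshold, connectivity=2)
    centroids, areas = [], []
    for region in measure.regionprops(labels, intensity_image=px):
        if region.area < min_area_px:
            continue
        row, col = region.centroid_weighted
        centroids.append((col * image.scale_mm_per_px,
                          row * image.scale_mm_per_px))
        areas.append(int(region.area))
    if not centroids:
        return MarkerDetection(np.empty((0, 2)), np.empty(0, dtype=int))
    return MarkerDetection(np.asarray(centroids, dtype=float),
                           np.asarray(areas, dtype=int))


#: Caudal -> cephalad inter-marker spacing pattern, in vertebral levels.
_LEVEL_GAPS = np.diff([VERTEBRAL_LEVEL[v] for v in reversed(VERTEBRAE)]) * -1.0


def _window_spacing_score(t_window: np.ndarray) -> float:
    """Mismatch (RMS, in vertebral-level units) between a candidate window's
    axial gaps and the anatomical marker spacing pattern."""
    gaps = np.diff(t_window)
    level_mm = (t_window[-1] - t_window[0]) / _LEVEL_GAPS.sum()
    if level_mm <= 0:
        return np.inf
    return float(np.sqrt(np.mean((gaps / level_mm - _LEVEL_GAPS) ** 2)))


def _excluded_explained(pts: np.ndarray, window: np.ndarray,
                        excluded: np.ndarray, t: np.ndarray,
                        ref_margin_mm: float) -> bool:
    """True if every excluded point looks like a reference marker: beyond
    the window's axial extremes, or off the window's TLS line, by more than
    the margin."""
    if len(excluded) == 0:
        return True
    t_lo, t_hi = t[window].min(), t[window].max()
    direction, centroid = fit_segment_line(pts[window])
    normal = np.array([-direction[1], direction[0]])
    for i in excluded:
        beyond = max(t_lo - t[i], t[i] - t_hi, 0.0)
        off_line = abs(float((pts[i] - centroid) @ normal))
        if max(beyond, off_line) <= ref_margin_mm:
            return False
    return True


def centroids_to_curve(detection: MarkerDetection,
                       axis_hint: tuple[float, float] = (1.0, 0.0),
                       ref_margin_mm: float = 30.0) -> SpinalCurve:
    """Order centroids along the body axis and label them L5..C7.

    ``axis_hint`` points caudal -> cephalad. If more than 12 centroids are
    present, the extras must be identifiable as reference markers: sorting
    the candidates by axial position, some contiguous window of 12 must
    explain every excluded centroid as lying beyond the window's
    longitudinal extremes, or more than ``ref_margin_mm`` off the window's
    TLS line (reference markers flank the subject laterally and beyond L5 /
    C7 longitudinally). If no window validates, a :class:`MarkerCountError`
    reports the candidate count; among several valid windows the one whose
    excluded points clear the margin most decisively wins. The returned
    curve uses chain coordinates: x = position along ``axis_hint``,
    y = lateral offset.
    """
    pts = np.asarray(detection.centroids_mm, dtype=float)
    axis = np.asarray(axis_hint, dtype=float)
    norm = np.hypot(*axis)
    if norm <= 0:
        raise ImagingError("axis_hint must be a non-zero vector")
    axis = axis / norm
    lateral = np.array([-axis[1], axis[0]])

    n_required = len(VERTEBRAE)
    if len(pts) < n_required:
        raise MarkerCountError(
            f"found {len(pts)} candidate centroids, need {n_required}")
    t_all = pts @ axis
    if len(pts) == n_required:
        chain_idx = np.arange(n_required)
    else:
        # Among contiguous 12-marker windows in axial order, keep those whose
        # excluded points all look like reference markers and whose internal
        # spacing matches the anatomical vertebral pattern; prefer the best
        # spacing match (at most half a vertebral level RMS).
        order = np.argsort(t_all, kind="stable")
        best_start, best_score = None, 0.5
        for start in range(len(pts) - n_required + 1):
            window = order[start:start + n_required]
            excluded = np.concatenate(
                [order[:start], order[start + n_required:]])
            if not _excluded_explained(pts, window, excluded, t_all,
                                       ref_margin_mm):
                continue
            score = _window_spacing_score(t_all[window])
            if score < best_score:
                best_start, best_score = start, score
        if best_start is None:
            raise MarkerCountError(
                f"found {len(pts)} candidate centroids and could not "
                f"attribute the surplus to reference markers; need "
                f"{n_required}")
        chain_idx = order[best_start:best_start + n_required]

    chain = pts[chain_idx]
    t = chain @ axis          # caudal -> cephalad position
    s = chain @ lateral
    order = np.argsort(t)     # most caudal (L5) first
    # SpinalCurve stores C7 first, so reverse to cephalad -> caudal.
    x = t[order][::-1].copy()
    y = s[order][::-1].copy()
    return SpinalCurve(x, y, frame="raw")


# ---------------------------------------------------------------------------
# Grayscale image I/O (PGM or PNG).

def read_image(path: str | Path, scale_mm_per_px: float) -> MarkerImage:
    arr = np.asarray(iio.imread(path))
    if arr.ndim == 3:  # collapse any color channels
        arr = arr.mean(axis=2)
    if np.issubdtype(arr.dtype, np.integer):
        arr = arr.astype(float) / np.iinfo(arr.dtype).max
    else:
        arr = arr.astype(float)
    return MarkerImage(np.clip(arr, 0.0, 1.0), scale_mm_per_px)


def write_image(image: MarkerImage, path: str | Path) -> None:
    arr = np.clip(image.pixels * 255.0, 0, 255).round().astype(np.uint8)
    iio.imwrite(Path(path), arr)
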