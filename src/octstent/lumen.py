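"""Lumen border detection in polar coordinates.

Each OCT frame is binarized, cleaned morphologically, resampled onto an
(r, θ) grid centred on the catheter axis, and the lumen border is taken
per A-scan as the first edge of the wall signal (Sobel along r).  Border
tracking across the pullback uses a validity band around the previous
frame's border to reject artefacts, fills angular gaps by circular linear
interpolation — or, for wide gaps characteristic of a bifurcation ostium,
by copying the previous border — and smooths the closed contour with a
circular moving average.

Angle convention: θ in degrees in [0, 360), θ=0 along +x (image columns),
increasing counter-clockwise with y pointing up (decreasing image row).
Radii are handled in pixels internally and reported in μm.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage import filters, morphology

logger = logging.getLogger(__name__)


@dataclass
class PolarFrame:
    """One frame resampled onto an (r, θ) grid about the catheter axis.

    ``image[r, t]`` is the intensity at pixel radius ``r`` along the
    A-scan with angle ``theta_deg[t]``.
    """

    image: np.ndarray  # (r_max, n_theta)
    origin: tuple[float, float]  # (row, col) of the polar origin
    pixel_size: float  # μm / pixel

    @property
    def n_theta(self) -> int:
        return self.image.shape[1]

    @property
    def r_max(self) -> int:
        return self.image.shape[0]

    @property
    def theta_deg(self) -> np.ndarray:
        return np.arange(self.n_theta) * 360.0 / self.n_theta


@dataclass
class LumenContour:
    """Closed lumen border of one frame.

    ``radius`` holds one value per angular bin, in μm from the polar
    origin.  ``gaps`` lists the angular intervals (degrees) that had to be
    filled; ``bifurcation_flag`` is set when a gap wider than the
    bifurcation threshold was encountered.  ``centroid`` is the polygon
    centroid in μm relative to the polar origin; ``area`` is in mm².
    """

    radius: np.ndarray
    frame_index: int
    gaps: list[tuple[float, float]]
    bifurcation_flag: bool
    centroid: tuple[float, float]
    area: float
    origin: tuple[float, float] = (0.0, 0.0)

    @property
    def n_theta(self) -> int:
        return self.radius.size

    @property
    def theta_deg(self) -> np.ndarray:
        return np.arange(self.n_theta) * 360.0 / self.n_theta

    def radius_px(self, pixel_size: float) -> np.ndarray:
        return self.radius / pixel_size


def binarize_and_clean(
    frame: np.ndarray,
    opening_radius: int = 3,
    min_area: int = 30,
    threshold: float | None = None,
) -> np.ndarray:
    """Binarize a preprocessed frame and remove salt-and-pepper noise.

    Otsu thresholding highlights the high-intensity wall; a morphological
    opening with a disk structuring element removes specks, and connected
    components below ``min_area`` pixels are dropped.
    """
    frame = np.asarray(frame, dtype=float)
    if threshold is None:
        if not np.any(frame > 0):
            return np.zeros(frame.shape, dtype=bool)
        threshold = filters.threshold_otsu(frame)
    binary = frame > threshold
    if opening_radius > 0:
        binary = morphology.opening(binary, morphology.disk(opening_radius))
    if min_area > 0:
        # drop connected components of fewer than min_area pixels
        binary = morphology.remove_small_objects(binary, max_size=min_area - 1)
    return binary


def to_polar(
    frame: np.ndarray,
    origin: tuple[float, float],
    n_theta: int = 360,
    r_max: int | None = None,
    pixel_size: float = 1.0,
) -> PolarFrame:
    """Resample a frame onto an (r, θ) grid by bilinear interpolation.

    ``origin`` is the (row, col) of the catheter axis.  Row r of the
    output samples radius r pixels from the origin; column t samples the
    angle ``t·360/n_theta`` degrees counter-clockwise from +x.
    """
    frame = np.asarray(frame, dtype=float)
    orow, ocol = origin
    h, w = frame.shape
    if not (0 <= orow < h and 0 <= ocol < w):
        raise ValueError(f"origin {origin} lies outside the {h}x{w} frame")
    if r_max is None:
        r_max = int(min(orow, h - 1 - orow, ocol, w - 1 - ocol))
    theta = np.deg2rad(np.arange(n_theta) * 360.0 / n_theta)
    r = np.arange(r_max)
    rr, tt = np.meshgrid(r, theta, indexing="ij")
    rows = orow - rr * np.sin(tt)  # y up == row down-negative
    cols = ocol + rr * np.cos(tt)
    polar = ndimage.map_coordinates(frame, [rows, cols], order=1, mode="constant")
    return PolarFrame(image=polar, origin=(orow, ocol), pixel_size=pixel_size)


def detect_raw_border(polar: PolarFrame) -> np.ndarray:
    """Per-A-scan raw lumen border from a binarized polar frame.

    A Sobel filter along r turns the lumen→wall transition into a band of
    non-zero response; the border candidate for each θ is the smallest r
    with non-zero response.  For a crisp 0→1 step between rows b−1 and b
    the Sobel response starts at row b−1 while the edge itself sits at
    b−0.5, so half a pixel is added to centre the estimate on the edge.
    A-scans with no edge are returned as NaN.
    """
    img = np.asarray(polar.image, dtype=float)
    edges = ndimage.sobel(img, axis=0, mode="nearest")
    nonzero = np.abs(edges) > 1e-9
    candidates = np.full(polar.n_theta, np.nan)
    any_edge = nonzero.any(axis=0)
    first = nonzero.argmax(axis=0)
    candidates[any_edge] = first[any_edge] + 0.5
    return candidates


def apply_validity_region(
    candidates: np.ndarray, previous_radius_px: np.ndarray, width: float = 10.0
) -> np.ndarray:
    """Reject border candidates outside a band about the previous border.

    The band is centred on the previous frame's border and is ``width``
    pixels wide in total (±width/2).  Rejected bins become NaN; the first
    frame of a stack bypasses this step (no previous border exists).
    """
    if width <= 0:
        raise ValueError("validity-region width must be positive")
    candidates = np.asarray(candidates, dtype=float)
    previous = np.asarray(previous_radius_px, dtype=float)
    if candidates.shape != previous.shape:
        raise ValueError("candidate and previous-border arrays differ in length")
    out = candidates.copy()
    with np.errstate(invalid="ignore"):
        out[np.abs(candidates - previous) > width / 2.0] = np.nan
    return out


def _circular_gaps(missing: np.ndarray) -> list[tuple[int, int]]:
    """Runs of True in a circular boolean array as (start, length) pairs."""
    n = missing.size
    if missing.all():
        return [(0, n)]
    if not missing.any():
        return []
    # rotate so position 0 is valid, then find plain runs
    start0 = int(np.argmin(missing))
    rolled = np.roll(missing, -start0)
    runs = []
    starts = np.flatnonzero(np.diff(np.r_[0, rolled.astype(int)]) == 1)
    ends = np.flatnonzero(np.diff(np.r_[rolled.astype(int), 0]) == -1)
    for s, e in zip(starts, ends):
        runs.append(((s + start0) % n, e - s + 1))
    return runs


def _circular_interp(values: np.ndarray) -> np.ndarray:
    """Fill NaNs by linear interpolation on the circle."""
    n = values.size
    missing = np.isnan(values)
    if not missing.any():
        return values
    idx = np.arange(n)
    valid = idx[~missing]
    # extend the valid support periodically so every gap has both endpoints
    xp = np.r_[valid - n, valid, valid + n]
    fp = np.tile(values[~missing], 3)
    out = values.copy()
    out[missing] = np.interp(idx[missing], xp, fp)
    return out


def _circular_moving_average(values: np.ndarray, window: int) -> np.ndarray:
    window = max(1, int(window))
    if window % 2 == 0:
        window += 1
    if window == 1:
        return values
    return ndimage.uniform_filter1d(values, size=window, mode="wrap")


def fill_and_smooth(
    candidates_px: np.ndarray,
    previous_contour: LumenContour | None,
    gap_threshold: float = 50.0,
    smooth_span: float = 0.10,
    small_smooth_span: float = 0.05,
    pixel_size: float = 1.0,
    frame_index: int = 0,
    origin: tuple[float, float] = (0.0, 0.0),
) -> LumenContour:
    """Close the lumen border: fill gaps, smooth, compute centroid and area.

    Angular gaps no wider than ``gap_threshold`` degrees are filled by
    circular linear interpolation of radius over θ and the contour is
    smoothed with a circular moving average spanning ``small_smooth_span``
    of the angular samples.  Wider gaps — the signature of a bifurcation
    ostium — are filled with the previous frame's border and the heavier
    ``smooth_span`` filter is applied to blend the seam;
    ``bifurcation_flag`` records that event.
    """
    radii = np.asarray(candidates_px, dtype=float).copy()
    n = radii.size
    missing = np.isnan(radii)
    if missing.all() and previous_contour is None:
        raise ValueError(
            "no border candidates and no previous contour: cannot seed tracking"
        )
    deg_per_bin = 360.0 / n
    gaps: list[tuple[float, float]] = []
    bifurcation = False
    for start, length in _circular_gaps(missing):
        width_deg = length * deg_per_bin
        gaps.append((start * deg_per_bin, ((start + length) % n) * deg_per_bin))
        if width_deg > gap_threshold:
            bifurcation = True
            bins = (start + np.arange(length)) % n
            if previous_contour is not None:
                radii[bins] = previous_contour.radius_px(pixel_size)[bins]
            else:
                logger.warning(
                    "frame %d: gap of %.0f° with no previous border; "
                    "falling back to circular interpolation",
                    frame_index,
                    width_deg,
                )
    radii = _circular_interp(radii)
    span = smooth_span if bifurcation else small_smooth_span
    radii = _circular_moving_average(radii, round(span * n))
    radius_um = radii * pixel_size
    area_mm2, centroid_um = _polygon_area_centroid(radius_um)
    return LumenContour(
        radius=radius_um,
        frame_index=frame_index,
        gaps=gaps,
        bifurcation_flag=bifurcation,
        centroid=centroid_um,
        area=area_mm2,
        origin=origin,
    )


def _polygon_area_centroid(radius_um: np.ndarray) -> tuple[float, tuple[float, float]]:
    """Shoelace area (mm²) and centroid (μm) of a per-θ radius contour."""
    n = radius_um.size
    theta = np.deg2rad(np.arange(n) * 360.0 / n)
    x = radius_um * np.cos(theta)
    y = radius_um * np.sin(theta)
    x1, y1 = np.roll(x, -1), np.roll(y, -1)
    cross = x * y1 - x1 * y
    area_um2 = cross.sum() / 2.0
    if area_um2 == 0:
        return 0.0, (float(x.mean()), float(y.mean()))
    cx = ((x + x1) * cross).sum() / (6.0 * area_um2)
    cy = ((y + y1) * cross).sum() / (6.0 * area_um2)
    return abs(area_um2) / 1e6, (float(cx), float(cy))


def lumen_area(contour: LumenContour) -> float:
    """Polygon (shoelace) area of the closed contour, in mm²."""
    area, _ = _polygon_area_centroid(contour.radius)
    return area


def lumen_volume(contours: list[LumenContour], frame_spacing: float) -> float:
    """Lumen volume as Σ area × slice spacing, in mm³.

    ``frame_spacing`` is in μm; areas are per-frame shoelace areas in mm².
    """
    if not contours:
        raise ValueError("need at least one contour")
    areas = np.array([lumen_area(c) for c in contours])
    return float(areas.sum() * frame_spacing / 1000.0)
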