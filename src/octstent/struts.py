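"""Metallic stent-strut detection from the bloom-plus-shadow signature.

A metallic strut reflects strongly and shields the tissue behind it, so
in polar coordinates its A-scan shows a saturated peak followed by a dark
trail.  Detection tests, per A-scan, the slope of the line from a high
peak (above the frame's 90th intensity percentile) down to the 30th
following pixel that falls below the frame median; slopes steeper than a
threshold mark strut pixels.  A triangular radial window centred on the
expected strut position (the lumen border) suppresses far-field false
positives, and candidates are confirmed against the neighbouring ±5
frames before centres of mass are computed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .lumen import LumenContour, PolarFrame

logger = logging.getLogger(__name__)


@dataclass
class StrutCandidate:
    """A merged high-slope region on one frame's polar grid."""

    frame_index: int
    theta_bin: int  # angular bin of the peak pixel
    peak_r: int  # radial row of the peak pixel
    pixels: np.ndarray  # (k, 2) array of (r, θ) indices
    confirmed: bool = False


@dataclass
class Strut:
    """A confirmed strut: centre of mass and apposition distance.

    ``loa`` (length of apposition) is the signed radial distance from the
    strut centroid to the lumen border at the same θ; positive values lie
    outside the border (embedded/malapposed outward).
    """

    frame_index: int
    centroid_polar: tuple[float, float]  # (r μm, θ deg)
    centroid_cartesian: tuple[float, float]  # (x μm, y μm) about polar origin
    loa: float  # μm


def apply_triangular_window(
    polar: PolarFrame, expected_r: np.ndarray, half_width: float = 40.0
) -> PolarFrame:
    """Weight each A-scan by a triangular window about the expected strut radius.

    The window has apex weight 1 at ``expected_r(θ)`` (pixels), falls
    linearly to 0 at ±``half_width``, and is 0 outside — penalising bright
    structures far from the lumen border such as the outer vessel wall.
    """
    if half_width <= 0:
        raise ValueError("half_width must be positive")
    expected_r = np.asarray(expected_r, dtype=float)
    if expected_r.size != polar.n_theta:
        raise ValueError("expected_r must provide one radius per angular bin")
    r = np.arange(polar.r_max)[:, None]
    weight = 1.0 - np.abs(r - expected_r[None, :]) / half_width
    weight = np.clip(weight, 0.0, None)
    return PolarFrame(
        image=polar.image * weight, origin=polar.origin, pixel_size=polar.pixel_size
    )


def detect_candidates(
    polar: PolarFrame,
    slope_threshold: float = -1.5,
    low_offset: int = 30,
    peak_percentile: float = 90.0,
    frame_index: int = 0,
    expected_r: np.ndarray | None = None,
    half_width: float = 40.0,
    bloom_fraction: float = 0.8,
    order: str = "detect-then-window",
    count_low_pixels: bool = True,
) -> list[StrutCandidate]:
    """Per-A-scan slope test for strut blooms, with far-field suppression.

    For every run of pixels strictly above the frame's ``peak_percentile``
    intensity, the run maximum is the peak; the algorithm then walks down
    the A-scan to the ``low_offset``-th pixel whose intensity is below the
    frame median (zero-padding the scan if it ends first) and accepts the
    run when the connecting line's slope is strictly below
    ``slope_threshold`` (intensity/pixel).

    When ``expected_r`` (the lumen border, pixels per θ) is given, the
    triangular window of ``half_width`` pixels then culls accepted pixels
    whose *windowed* intensity does not exceed the percentile threshold,
    suppressing bright structures far from the border.  An additional
    relative trim keeps only pixels above ``bloom_fraction`` of each
    run's peak, isolating the saturated bloom from the adjoining wall
    signal.  Surviving pixels are merged 8-connectivity-wise (with θ
    wrap-around) into candidates.

    ``order="window-then-detect"`` instead runs the slope test on the
    windowed image (percentile/median statistics still come from the
    unweighted frame).  ``count_low_pixels=False`` switches to the simpler
    reading in which the low point is the pixel ``low_offset`` rows beyond
    the peak, whatever its intensity.
    """
    if order not in ("detect-then-window", "window-then-detect"):
        raise ValueError(f"unknown detection order {order!r}")
    raw = np.asarray(polar.image, dtype=float)
    windowed = None
    if expected_r is not None:
        windowed = apply_triangular_window(polar, expected_r, half_width).image
    img = windowed if (order == "window-then-detect" and windowed is not None) else raw
    p_hi = float(np.percentile(raw, peak_percentile))
    med = float(np.median(raw))
    r_max, n_theta = img.shape

    strut_mask = np.zeros_like(img, dtype=bool)
    for t in range(n_theta):
        col = img[:, t]
        above = col > p_hi
        if not above.any():
            continue
        # contiguous above-percentile runs; one peak per run
        starts = np.flatnonzero(np.diff(np.r_[0, above.astype(int)]) == 1)
        ends = np.flatnonzero(np.diff(np.r_[above.astype(int), 0]) == -1)
        for s, e in zip(starts, ends):
            peak_r = s + int(np.argmax(col[s : e + 1]))
            i_peak = col[peak_r]
            r_low = _nth_low_pixel(col, peak_r, med, low_offset, count_low_pixels)
            i_low = col[r_low] if r_low < r_max else 0.0  # zero padding
            if r_low == peak_r:
                continue
            slope = (i_low - i_peak) / (r_low - peak_r)
            if slope < slope_threshold:
                run = np.arange(s, e + 1)
                keep = col[run] >= bloom_fraction * i_peak
                strut_mask[run[keep], t] = True

    if windowed is not None and order == "detect-then-window":
        strut_mask &= windowed > p_hi

    return _merge_candidates(strut_mask, raw, frame_index)


def _nth_low_pixel(
    col: np.ndarray, peak_r: int, median: float, n_low: int, count_low: bool
) -> int:
    """Row index of the n-th low-intensity pixel beyond the peak.

    Rows past the end of the A-scan are treated as zero-padded (and count
    as low whenever 0 < median).
    """
    if not count_low:
        return peak_r + n_low
    rest = col[peak_r + 1 :]
    low = np.flatnonzero(rest < median)
    if low.size >= n_low:
        return peak_r + 1 + int(low[n_low - 1])
    remaining = n_low - low.size
    if 0.0 < median:
        # virtual zero-padded rows below the image are all "low"
        return col.size - 1 + remaining
    # median == 0: no padding pixel can be below it; fall back to scan end
    return col.size - 1 + n_low


def _merge_candidates(
    mask: np.ndarray, img: np.ndarray, frame_index: int
) -> list[StrutCandidate]:
    """Label strut pixels 8-connectively with θ wrap-around."""
    structure = np.ones((3, 3), dtype=int)
    labels, n = ndimage.label(mask, structure=structure)
    if n == 0:
        return []
    # merge labels touching across the θ seam
    parent = {i: i for i in range(1, n + 1)}

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    left, right = labels[:, 0], labels[:, -1]
    for dr in (-1, 0, 1):
        l = left
        r = np.roll(right, dr)
        both = (l > 0) & (r > 0)
        for a, b in zip(l[both], r[both]):
            ra, rb = find(int(a)), find(int(b))
            if ra != rb:
                parent[ra] = rb

    groups: dict[int, list[int]] = {}
    for i in range(1, n + 1):
        groups.setdefault(find(i), []).append(i)

    out = []
    for members in groups.values():
        region = np.isin(labels, members)
        rr, tt = np.nonzero(region)
        pixels = np.column_stack([rr, tt])
        peak_flat = np.argmax(np.where(region, img, -np.inf))
        pr, pt = np.unravel_index(peak_flat, img.shape)
        out.append(
            StrutCandidate(
                frame_index=frame_index,
                theta_bin=int(pt),
                peak_r=int(pr),
                pixels=pixels,
            )
        )
    out.sort(key=lambda c: c.theta_bin)
    return out


def _circular_mean_bins(
    bins: np.ndarray, weights: np.ndarray | None, n: int | None
) -> float:
    """Weighted circular mean of angular bin indices, returned in bins."""
    if n is None:
        n = 360
    ang = np.asarray(bins, dtype=float) * 2 * np.pi / n
    w = np.ones_like(ang) if weights is None else np.asarray(weights, dtype=float)
    s = (w * np.sin(ang)).sum()
    c = (w * np.cos(ang)).sum()
    mean = np.arctan2(s, c) % (2 * np.pi)
    return float(mean * n / (2 * np.pi))


def confirm_across_frames(
    candidates: list[list[StrutCandidate]],
    window_frames: int = 5,
    theta_tol: float = 10.0,
    r_tol: float = 15.0,
    n_theta: int = 360,
) -> list[list[StrutCandidate]]:
    """Keep only candidates supported by a neighbour within ±``window_frames``.

    A candidate on frame n is confirmed iff some candidate on another
    frame in [n−window, n+window] lies within ``theta_tol`` degrees and
    ``r_tol`` pixels of it; isolated single-frame blobs (guide-wire
    reflections, saturation artefacts) are discarded.  Frames near the
    stack ends use whatever neighbours exist.
    """
    if window_frames < 1:
        raise ValueError("window_frames must be ≥ 1")
    deg_per_bin = 360.0 / n_theta
    centroids = [
        [
            (c.pixels[:, 0].mean(), _circular_mean_bins(c.pixels[:, 1], None, n_theta))
            for c in frame
        ]
        for frame in candidates
    ]
    n_frames = len(candidates)
    confirmed: list[list[StrutCandidate]] = []
    for i, frame in enumerate(candidates):
        kept = []
        lo = max(0, i - window_frames)
        hi = min(n_frames - 1, i + window_frames)
        for c, (r0, t0) in zip(frame, centroids[i]):
            ok = False
            for j in range(lo, hi + 1):
                if j == i:
                    continue
                for r1, t1 in centroids[j]:
                    dt = abs(t1 - t0) % n_theta
                    dt = min(dt, n_theta - dt) * deg_per_bin
                    if dt <= theta_tol and abs(r1 - r0) <= r_tol:
                        ok = True
                        break
                if ok:
                    break
            c.confirmed = ok
            if ok:
                kept.append(c)
        confirmed.append(kept)
    return confirmed


def strut_centroids(
    candidates: list[StrutCandidate],
    polar: PolarFrame,
    contour: LumenContour,
) -> list[Strut]:
    """Intensity-weighted centres of mass of confirmed strut regions.

    Centroids are reported both in polar (r μm, θ deg) and Cartesian
    (x, y μm about the polar origin) form; ``loa`` is the signed radial
    distance to the lumen border interpolated at the centroid's θ.
    """
    img = np.asarray(polar.image, dtype=float)
    n_theta = polar.n_theta
    out = []
    for cand in candidates:
        rr, tt = cand.pixels[:, 0], cand.pixels[:, 1]
        w = img[rr, tt]
        if w.sum() <= 0:
            logger.warning(
                "frame %d: skipping strut region with zero total intensity",
                cand.frame_index,
            )
            continue
        r_bin = float((w * rr).sum() / w.sum())
        t_bin = _circular_mean_bins(tt, w, n_theta)
        r_um = r_bin * polar.pixel_size
        theta_deg = t_bin * 360.0 / n_theta
        theta_rad = np.deg2rad(theta_deg)
        x_um = r_um * np.cos(theta_rad)
        y_um = r_um * np.sin(theta_rad)
        border = _interp_radius(contour.radius, theta_deg)
        out.append(
            Strut(
                frame_index=cand.frame_index,
                centroid_polar=(r_um, theta_deg),
                centroid_cartesian=(float(x_um), float(y_um)),
                loa=float(r_um - border),
            )
        )
    return out


def _interp_radius(radius_um: np.ndarray, theta_deg: float) -> float:
    """Circular linear interpolation of a per-θ radius table."""
    n = radius_um.size
    pos = (theta_deg % 360.0) / (360.0 / n)
    i0 = int(np.floor(pos)) % n
    i1 = (i0 + 1) % n
    frac = pos - np.floor(pos)
    return float((1 - frac) * radius_um[i0] + frac * radius_um[i1])
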