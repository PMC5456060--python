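"""Validation metrics for lumen and strut segmentations.

Implements the agreement measures used to validate automatic OCT
segmentation against a reference (manual) one: pixel-level confusion
counts and similarity indexes (sensitivity, specificity, Jaccard, Dice,
all in percent), the strut-count specificity variant
(1 − FP/n_strut)·100, per-A-scan contour distances, nearest-neighbour
strut matching with total and radial distances, Bland–Altman limits of
agreement, and repeatability summaries (lumen volume and mean struts per
frame across repeated pullbacks).

Percentile summaries use the Hazen (midpoint) plotting-position
convention — the convention under which the repeatability table's
printed percentiles reproduce exactly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .lumen import LumenContour, lumen_volume
from .struts import Strut


@dataclass
class ConfusionCounts:
    TP: int
    FP: int
    FN: int
    TN: int = 0

    def __post_init__(self) -> None:
        if min(self.TP, self.FP, self.FN, self.TN) < 0:
            raise ValueError("confusion counts must be non-negative")


@dataclass
class SimilarityReport:
    """The four similarity indexes, in percent; NaN marks an undefined index."""

    sensitivity: float
    specificity: float
    jaccard: float
    dice: float


@dataclass
class StrutMatchResult:
    pairs: list[tuple[object, object, float, float]]  # (auto, ref, total μm, radial μm)
    counts: ConfusionCounts
    n_strut_ref: int

    @property
    def total_distances(self) -> np.ndarray:
        return np.array([p[2] for p in self.pairs])

    @property
    def radial_distances(self) -> np.ndarray:
        return np.array([p[3] for p in self.pairs])


@dataclass
class BlandAltmanResult:
    mean_difference: float
    lower_loa: float
    upper_loa: float
    pairs_n: int


def confusion_counts(auto_mask: np.ndarray, ref_mask: np.ndarray) -> ConfusionCounts:
    """Pixel-wise confusion counts with ``ref_mask`` as the truth."""
    auto = np.asarray(auto_mask, dtype=bool)
    ref = np.asarray(ref_mask, dtype=bool)
    if auto.shape != ref.shape:
        raise ValueError(f"mask shapes differ: {auto.shape} vs {ref.shape}")
    return ConfusionCounts(
        TP=int(np.sum(auto & ref)),
        FP=int(np.sum(auto & ~ref)),
        FN=int(np.sum(~auto & ref)),
        TN=int(np.sum(~auto & ~ref)),
    )


def _ratio(num: float, den: float) -> float:
    return math.nan if den == 0 else 100.0 * num / den


def similarity_indexes(c: ConfusionCounts) -> SimilarityReport:
    """Sensitivity, specificity, Jaccard and Dice indexes in percent.

    An index whose denominator is zero is reported as NaN, never as 0.
    """
    return SimilarityReport(
        sensitivity=_ratio(c.TP, c.TP + c.FN),
        specificity=_ratio(c.TN, c.FP + c.TN),
        jaccard=_ratio(c.TP, c.TP + c.FP + c.FN),
        dice=_ratio(2 * c.TP, 2 * c.TP + c.FP + c.FN),
    )


def strut_specificity(FP: int, n_strut: int) -> float:
    """Strut-count specificity (1 − FP/n_strut)·100.

    ``n_strut`` is the reference (manual) strut count.  The formula is
    unbounded below: more false positives than reference struts yields a
    negative value, reported as-is.
    """
    if n_strut == 0:
        return math.nan
    return (1.0 - FP / n_strut) * 100.0


def contour_distance(auto: LumenContour, ref: LumenContour) -> np.ndarray:
    """Per-A-scan absolute radius differences |r_auto(θ) − r_ref(θ)| in μm."""
    if auto.n_theta != ref.n_theta:
        raise ValueError(
            f"contours have different angular sampling ({auto.n_theta} vs "
            f"{ref.n_theta}); resample before comparing"
        )
    return np.abs(auto.radius - ref.radius)


def _strut_xyr(s) -> tuple[float, float, float]:
    if isinstance(s, Strut):
        x, y = s.centroid_cartesian
        return x, y, s.centroid_polar[0]
    x, y = float(s[0]), float(s[1])
    return x, y, math.hypot(x, y)


def match_struts(
    auto: Sequence, ref: Sequence, max_distance: float = 150.0
) -> StrutMatchResult:
    """Greedy nearest-neighbour pairing of detected and reference struts.

    Struts may be :class:`~octstent.struts.Strut` objects or plain (x, y)
    μm pairs about the polar origin.  Pairs are formed in order of
    increasing in-plane Euclidean (total) distance, each strut used at
    most once, and rejected beyond ``max_distance``.  Unmatched detected
    struts count as FP, unmatched reference struts as FN; the radial
    distance is |r_auto − r_ref| about the polar origin.
    """
    a = [_strut_xyr(s) for s in auto]
    r = [_strut_xyr(s) for s in ref]
    dist = [
        (math.hypot(ax - rx, ay - ry), i, j)
        for i, (ax, ay, _) in enumerate(a)
        for j, (rx, ry, _) in enumerate(r)
    ]
    dist.sort(key=lambda t: t[0])
    used_a: set[int] = set()
    used_r: set[int] = set()
    pairs = []
    for d, i, j in dist:
        if d > max_distance:
            break
        if i in used_a or j in used_r:
            continue
        used_a.add(i)
        used_r.add(j)
        pairs.append((auto[i], ref[j], d, abs(a[i][2] - r[j][2])))
    counts = ConfusionCounts(
        TP=len(pairs), FP=len(a) - len(used_a), FN=len(r) - len(used_r)
    )
    return StrutMatchResult(pairs=pairs, counts=counts, n_strut_ref=len(r))


def bland_altman(
    pairs: Sequence[tuple[float, float]], percent: bool = False
) -> BlandAltmanResult:
    """Bland–Altman mean difference and 95% limits of agreement.

    Differences are a−b (or, with ``percent``, (a−b)/mean(a,b)·100, the
    form used for paired area measurements); limits of agreement are
    mean ± 1.96 · SD of the differences.
    """
    arr = np.asarray(pairs, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2 or arr.shape[0] < 2:
        raise ValueError("bland_altman needs at least 2 (a, b) pairs")
    d = arr[:, 0] - arr[:, 1]
    if percent:
        d = d / arr.mean(axis=1) * 100.0
    mean = float(d.mean())
    sd = float(d.std(ddof=1))
    return BlandAltmanResult(
        mean_difference=mean,
        lower_loa=mean - 1.96 * sd,
        upper_loa=mean + 1.96 * sd,
        pairs_n=arr.shape[0],
    )


def percentiles(values: Sequence[float], q=(25, 50, 75)) -> tuple[float, ...]:
    """Percentiles under the Hazen (midpoint) convention."""
    return tuple(float(v) for v in np.percentile(np.asarray(values, float), q, method="hazen"))


def repeatability_summary(
    scans: Sequence | None = None,
    *,
    volumes: Sequence[float] | None = None,
    struts_per_frame: Sequence[float] | None = None,
) -> dict:
    """Repeatability of repeated pullbacks of the same object.

    Either pass segmented ``scans`` (objects exposing ``contours``,
    ``struts`` and ``frame_spacing``, e.g. pipeline results), or the
    per-scan ``volumes`` (mm³) and mean ``struts_per_frame`` directly.
    Returns the per-scan values plus their 25/50/75th percentiles.
    """
    if scans is not None:
        volumes = [lumen_volume(s.contours, s.frame_spacing) for s in scans]
        struts_per_frame = [
            len(s.struts) / max(1, len(s.contours)) for s in scans
        ]
    if volumes is None or struts_per_frame is None:
        raise ValueError("provide scans, or volumes and struts_per_frame")
    return {
        "volumes_mm3": [float(v) for v in volumes],
        "struts_per_frame": [float(s) for s in struts_per_frame],
        "volume_percentiles": percentiles(volumes),
        "struts_per_frame_percentiles": percentiles(struts_per_frame),
    }


def contour_to_mask(
    contour: LumenContour,
    shape: tuple[int, int],
    origin: tuple[float, float],
    pixel_size: float,
    border_band: int = 0,
) -> np.ndarray:
    """Rasterize a contour as a filled lumen mask (or a border band).

    With ``border_band`` 0 the region enclosed by the contour is filled —
    the representation used for the pixel-level similarity indexes.  A
    positive ``border_band`` instead returns only pixels within that many
    pixels of the contour curve.
    """
    from skimage.draw import polygon

    orow, ocol = origin
    theta = np.deg2rad(contour.theta_deg)
    r_px = contour.radius / pixel_size
    rows = orow - r_px * np.sin(theta)
    cols = ocol + r_px * np.cos(theta)
    rr, cc = polygon(rows, cols, shape=shape)
    filled = np.zeros(shape, dtype=bool)
    filled[rr, cc] = True
    if border_band <= 0:
        return filled
    from scipy import ndimage as ndi

    eroded = ndi.binary_erosion(filled, iterations=border_band)
    dilated = ndi.binary_dilation(filled, iterations=border_band)
    return dilated & ~eroded
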