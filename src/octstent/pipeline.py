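"""End-to-end orchestration: preprocess → lumen → struts → point cloud.

The pipeline is fully deterministic: given the same stack and
configuration it produces byte-identical outputs (all randomness lives
in the synthetic phantom generator, behind one seed).

Conventions, fixed project-wide: pixel indices are 0-based; θ is in
degrees in [0, 360), counter-clockwise from +x; z runs along the
pullback with frame 0 at z = 0; lengths are μm internally, with areas in
mm² and volumes in mm³ at reporting time.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import lumen as lm
from . import metrics as mx
from . import preprocess as pp
from . import struts as st
from .pointcloud import LabeledPointCloud, build_point_cloud, export_cloud
from .struts import Strut

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """All pipeline tunables.

    Defaults follow the method's stated constants: morphological opening
    disk radius 3 px, 10-px validity region, 50° bifurcation gap
    threshold, 10% smoothing span, slope threshold −1.5 intensity/px with
    the 30th low pixel, 90th-percentile peaks, ±5-frame confirmation.
    """

    # preprocessing
    crop_rows: int = 0
    catheter_quantile: float = 0.99
    # lumen detection
    opening_radius: int = 3
    min_area: int = 30
    n_theta: int = 360
    validity_width: float = 10.0  # px, total width of the band
    gap_threshold: float = 50.0  # degrees
    smooth_span: float = 0.10  # fraction of angular samples (wide-gap case)
    small_smooth_span: float = 0.05
    # strut detection
    slope_threshold: float = -1.5  # intensity / pixel
    low_offset: int = 30  # the n-th low-intensity pixel
    peak_percentile: float = 90.0
    triangular_half_width: float = 40.0  # px
    bloom_fraction: float = 0.8
    window_order: str = "detect-then-window"
    count_low_pixels: bool = True
    window_frames: int = 5
    theta_tol: float = 10.0  # degrees
    r_tol: float = 15.0  # px
    # validation / registration
    match_max_distance: float = 150.0  # μm
    icp_angle_step: float = 1.0  # degrees
    icp_max_iter: int = 100
    icp_tol: float = 1e-3  # μm
    # geometry overrides (None = take from the stack metadata)
    pixel_size: float | None = None
    frame_spacing: float | None = None
    recenter_cloud: bool = True

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self)))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)


@dataclass
class SegmentationResult:
    """Everything the pipeline derives from one pullback."""

    contours: list[lm.LumenContour]
    struts: list[Strut]
    cloud: LabeledPointCloud
    catheter_mask: np.ndarray
    origin: tuple[float, float]
    pixel_size: float
    frame_spacing: float

    def struts_on_frame(self, frame: int) -> list[Strut]:
        return [s for s in self.struts if s.frame_index == frame]

    @property
    def lumen_areas(self) -> np.ndarray:
        return np.array([c.area for c in self.contours])

    @property
    def lumen_volume(self) -> float:
        return lm.lumen_volume(self.contours, self.frame_spacing)

    @property
    def struts_per_frame(self) -> float:
        return len(self.struts) / max(1, len(self.contours))

    @property
    def bifurcation_frames(self) -> list[int]:
        return [c.frame_index for c in self.contours if c.bifurcation_flag]


def segment_stack(
    stack: pp.FrameStack,
    config: PipelineConfig | None = None,
    overlay_mask: np.ndarray | None = None,
) -> SegmentationResult:
    """Run the full segmentation pipeline on a frame stack.

    ``overlay_mask`` should give the console's overlay pixels when known
    (device-dialect specific); otherwise the zero-variance heuristic of
    :func:`octstent.preprocess.build_overlay_mask` is used.
    """
    cfg = config or PipelineConfig()
    pixel_size = cfg.pixel_size or stack.pixel_size
    frame_spacing = cfg.frame_spacing or stack.frame_spacing

    overlay = None
    if overlay_mask is not None:
        overlay = pp.StaticMask(mask=overlay_mask, kind="overlay")
    else:
        auto = pp.build_overlay_mask(stack)
        if auto.mask.mean() > 0.05:
            logger.warning(
                "auto-detected overlay mask covers %.0f%% of the frame "
                "(static scene?); ignoring it — supply an explicit mask",
                100 * auto.mask.mean(),
            )
            auto = pp.StaticMask(mask=np.zeros(stack.frame_shape, bool), kind="overlay")
        overlay = auto
    clean, catheter = pp.preprocess_stack(
        stack, crop_rows=cfg.crop_rows, overlay=overlay,
        threshold_quantile=cfg.catheter_quantile,
    )
    try:
        origin = pp.catheter_centroid(catheter)
    except ValueError:
        h, w = clean.frame_shape
        origin = (h / 2.0, w / 2.0)
        logger.warning("no catheter found; using the image centre as polar origin")

    contours: list[lm.LumenContour] = []
    candidates_per_frame: list[list[st.StrutCandidate]] = []
    polar_frames: list[lm.PolarFrame] = []
    previous: lm.LumenContour | None = None
    for i, frame in enumerate(clean.frames):
        binary = lm.binarize_and_clean(
            frame, opening_radius=cfg.opening_radius, min_area=cfg.min_area
        )
        polar_bin = lm.to_polar(
            binary.astype(float), origin, cfg.n_theta, pixel_size=pixel_size
        )
        polar_bin.image = (polar_bin.image > 0.5).astype(float)
        cand = lm.detect_raw_border(polar_bin)
        if previous is not None:
            cand = lm.apply_validity_region(
                cand, previous.radius_px(pixel_size), cfg.validity_width
            )
        contour = lm.fill_and_smooth(
            cand,
            previous,
            gap_threshold=cfg.gap_threshold,
            smooth_span=cfg.smooth_span,
            small_smooth_span=cfg.small_smooth_span,
            pixel_size=pixel_size,
            frame_index=i,
            origin=origin,
        )
        contours.append(contour)
        previous = contour

        polar = lm.to_polar(frame, origin, cfg.n_theta, pixel_size=pixel_size)
        polar_frames.append(polar)
        candidates_per_frame.append(
            st.detect_candidates(
                polar,
                slope_threshold=cfg.slope_threshold,
                low_offset=cfg.low_offset,
                peak_percentile=cfg.peak_percentile,
                frame_index=i,
                expected_r=contour.radius_px(pixel_size),
                half_width=cfg.triangular_half_width,
                bloom_fraction=cfg.bloom_fraction,
                order=cfg.window_order,
                count_low_pixels=cfg.count_low_pixels,
            )
        )

    if len(candidates_per_frame) > 1:
        confirmed = st.confirm_across_frames(
            candidates_per_frame,
            window_frames=cfg.window_frames,
            theta_tol=cfg.theta_tol,
            r_tol=cfg.r_tol,
            n_theta=cfg.n_theta,
        )
    else:
        confirmed = candidates_per_frame

    struts: list[Strut] = []
    for cands, polar, contour in zip(confirmed, polar_frames, contours):
        struts.extend(st.strut_centroids(cands, polar, contour))

    cloud = build_point_cloud(
        contours, struts, frame_spacing, recenter=cfg.recenter_cloud
    )
    return SegmentationResult(
        contours=contours,
        struts=struts,
        cloud=cloud,
        catheter_mask=catheter.mask,
        origin=origin,
        pixel_size=pixel_size,
        frame_spacing=frame_spacing,
    )


# ---------------------------------------------------------------------------
# File-level orchestration (the CLI's backend)


def contours_table(contours: list[lm.LumenContour]) -> pd.DataFrame:
    rows = []
    for c in contours:
        for t, r in zip(c.theta_deg, c.radius):
            rows.append({"frame": c.frame_index, "theta_deg": t, "radius_um": r})
    return pd.DataFrame(rows)


def struts_table(struts: list[Strut]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "frame": s.frame_index,
                "x_um": s.centroid_cartesian[0],
                "y_um": s.centroid_cartesian[1],
                "r_um": s.centroid_polar[0],
                "theta_deg": s.centroid_polar[1],
                "loa_um": s.loa,
            }
            for s in struts
        ],
        columns=["frame", "x_um", "y_um", "r_um", "theta_deg", "loa_um"],
    )


def run_segment(
    input_path: str | Path,
    out_dir: str | Path,
    config: PipelineConfig | None = None,
    pixel_size: float | None = None,
    frame_spacing: float | None = None,
) -> SegmentationResult:
    """Segment a stack read from disk and write contours, struts, cloud, summary."""
    cfg = config or PipelineConfig()
    stack = pp.read_stack(
        input_path,
        pixel_size=pixel_size or cfg.pixel_size,
        frame_spacing=frame_spacing or cfg.frame_spacing,
    )
    result = segment_stack(stack, cfg)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    contours_table(result.contours).to_csv(out / "contours.csv", index=False)
    struts_table(result.struts).to_csv(out / "struts.csv", index=False)
    if len(result.cloud):
        export_cloud(result.cloud, out / "cloud.ply")
        export_cloud(result.cloud, out / "cloud.csv")
    summary = {
        "n_frames": len(result.contours),
        "pixel_size_um": result.pixel_size,
        "frame_spacing_um": result.frame_spacing,
        "polar_origin_rowcol": list(result.origin),
        "lumen_areas_mm2": [round(a, 6) for a in result.lumen_areas],
        "lumen_volume_mm3": round(result.lumen_volume, 6),
        "n_struts": len(result.struts),
        "struts_per_frame": round(result.struts_per_frame, 4),
        "bifurcation_frames": result.bifurcation_frames,
    }
    (out / "summary.json").write_text(json.dumps(summary, indent=2))
    cfg.to_yaml(out / "config.yaml")
    return result


def _load_results_dir(path: Path) -> tuple[dict[int, np.ndarray], dict[int, list]]:
    """Read contours.csv / struts.csv as per-frame radius tables and strut lists."""
    contours: dict[int, np.ndarray] = {}
    cpath = path / "contours.csv"
    if cpath.exists():
        df = pd.read_csv(cpath)
        for f, grp in df.groupby("frame"):
            contours[int(f)] = grp.sort_values("theta_deg")["radius_um"].to_numpy()
    struts: dict[int, list] = {}
    spath = path / "struts.csv"
    if spath.exists():
        df = pd.read_csv(spath)
        for f, grp in df.groupby("frame"):
            struts[int(f)] = list(zip(grp["x_um"], grp["y_um"]))
    return contours, struts


def run_validate(
    auto_dir: str | Path,
    ref_dir: str | Path,
    out_dir: str | Path,
    config: PipelineConfig | None = None,
) -> dict:
    """Compare two segmentation result directories frame by frame.

    Emits contour-distance percentiles, strut-match confusion counts and
    similarity indexes, and total/radial strut distance percentiles as a
    JSON report (plus the per-frame distance table as CSV).
    """
    cfg = config or PipelineConfig()
    auto_contours, auto_struts = _load_results_dir(Path(auto_dir))
    ref_contours, ref_struts = _load_results_dir(Path(ref_dir))
    frames = sorted(set(auto_contours) & set(ref_contours))
    strut_frames = sorted(
        (set(auto_struts) | set(ref_struts))
        & set(auto_contours)
        & set(ref_contours)
    )
    if not frames and not strut_frames:
        raise ValueError("no overlapping frames between the two result sets")

    all_dist = []
    for f in frames:
        a, r = auto_contours[f], ref_contours[f]
        if a.size != r.size:
            raise ValueError(f"frame {f}: angular sampling differs between sets")
        all_dist.append(np.abs(a - r))
    dist = np.concatenate(all_dist) if all_dist else np.array([])

    tp = fp = fn = 0
    totals, radials = [], []
    for f in strut_frames:
        match = mx.match_struts(
            auto_struts.get(f, []), ref_struts.get(f, []), cfg.match_max_distance
        )
        tp += match.counts.TP
        fp += match.counts.FP
        fn += match.counts.FN
        totals.extend(match.total_distances)
        radials.extend(match.radial_distances)
    counts = mx.ConfusionCounts(TP=tp, FP=fp, FN=fn)
    sim = mx.similarity_indexes(counts)
    n_ref = tp + fn
    report = {
        "frames_compared": len(frames),
        "contour_distance_um_percentiles": (
            list(mx.percentiles(dist)) if dist.size else None
        ),
        "strut_counts": {"TP": tp, "FP": fp, "FN": fn},
        "strut_sensitivity_pct": sim.sensitivity,
        "strut_jaccard_pct": sim.jaccard,
        "strut_dice_pct": sim.dice,
        "strut_specificity_pct": mx.strut_specificity(fp, n_ref) if n_ref else None,
        "strut_total_distance_um_percentiles": (
            list(mx.percentiles(totals)) if totals else None
        ),
        "strut_radial_distance_um_percentiles": (
            list(mx.percentiles(radials)) if radials else None
        ),
    }
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "validation.json").write_text(json.dumps(report, indent=2))
    if dist.size:
        pd.DataFrame({"distance_um": dist}).to_csv(
            out / "contour_distances.csv", index=False
        )
    return report
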