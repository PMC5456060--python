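"""3D point clouds of lumen contours and stent struts.

Per-frame contours and strut centroids are stacked orthogonally to a
straight pullback axis: each frame is translated so its lumen centroid
lies on the z-axis and placed at z = frame index × inter-frame spacing.
Recentring removes catheter wobble (and any true vessel curvature — a
fair assumption for straight-tube phantoms; disable it for in vivo
pullbacks).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .lumen import LumenContour
from .struts import Strut

LABELS = ("lumen", "strut")


@dataclass
class LabeledPointCloud:
    """3D points in μm, each tagged lumen|strut with its frame of origin."""

    points: np.ndarray  # (n, 3) μm
    labels: np.ndarray  # (n,) str, "lumen" or "strut"
    frame_of_origin: np.ndarray  # (n,) int

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float).reshape(-1, 3)
        self.labels = np.asarray(self.labels)
        self.frame_of_origin = np.asarray(self.frame_of_origin, dtype=int)
        if not (len(self.points) == len(self.labels) == len(self.frame_of_origin)):
            raise ValueError("points, labels and frame_of_origin must align")

    def __len__(self) -> int:
        return len(self.points)

    def select(self, label: str) -> np.ndarray:
        return self.points[self.labels == label]


def build_point_cloud(
    contours: list[LumenContour],
    struts: list[Strut],
    frame_spacing: float,
    recenter: bool = True,
) -> LabeledPointCloud:
    """Stack contours and struts along the straight pullback axis.

    With ``recenter`` (the default) every frame is shifted so its lumen
    centroid sits at x = y = 0; z is frame index × ``frame_spacing`` μm.
    """
    frames = {c.frame_index for c in contours}
    for s in struts:
        if s.frame_index not in frames:
            raise ValueError(
                f"strut on frame {s.frame_index} has no matching lumen contour"
            )
    centroids = {c.frame_index: c.centroid for c in contours}

    pts, labels, origin = [], [], []
    for c in contours:
        theta = np.deg2rad(c.theta_deg)
        x = c.radius * np.cos(theta)
        y = c.radius * np.sin(theta)
        if recenter:
            x = x - c.centroid[0]
            y = y - c.centroid[1]
        z = np.full_like(x, c.frame_index * frame_spacing)
        pts.append(np.column_stack([x, y, z]))
        labels.extend(["lumen"] * len(x))
        origin.extend([c.frame_index] * len(x))
    for s in struts:
        x, y = s.centroid_cartesian
        if recenter:
            cx, cy = centroids[s.frame_index]
            x, y = x - cx, y - cy
        pts.append(np.array([[x, y, s.frame_index * frame_spacing]]))
        labels.append("strut")
        origin.append(s.frame_index)
    points = np.vstack(pts) if pts else np.empty((0, 3))
    return LabeledPointCloud(
        points=points, labels=np.array(labels), frame_of_origin=np.array(origin)
    )


def export_cloud(cloud: LabeledPointCloud, path: str | Path, fmt: str | None = None) -> Path:
    """Write the cloud as ascii PLY (with label/frame vertex properties) or CSV."""
    if len(cloud) == 0:
        raise ValueError("refusing to write an empty point cloud")
    path = Path(path)
    fmt = fmt or path.suffix.lstrip(".").lower()
    path.parent.mkdir(parents=True, exist_ok=True)
    if fmt == "csv":
        df = pd.DataFrame(cloud.points, columns=["x_um", "y_um", "z_um"])
        df["label"] = cloud.labels
        df["frame"] = cloud.frame_of_origin
        # 17 significant digits: exact float64 round trip
        df.to_csv(path, index=False, float_format="%.17g")
        return path
    if fmt == "ply":
        lines = [
            "ply",
            "format ascii 1.0",
            f"element vertex {len(cloud)}",
            "property double x",
            "property double y",
            "property double z",
            "property uchar label",
            "property int frame",
            "end_header",
        ]
        for (x, y, z), lab, fr in zip(cloud.points, cloud.labels, cloud.frame_of_origin):
            code = LABELS.index(lab)
            lines.append(f"{float(x)!r} {float(y)!r} {float(z)!r} {code} {fr}")
        path.write_text("\n".join(lines) + "\n")
        return path
    raise ValueError(f"unknown point-cloud format {fmt!r}")


def read_cloud(path: str | Path) -> LabeledPointCloud:
    """Read a cloud written by :func:`export_cloud` (or any xyz CSV/PLY)."""
    path = Path(path)
    if path.suffix.lower() == ".csv":
        df = pd.read_csv(path, float_precision="round_trip")
        points = df[["x_um", "y_um", "z_um"]].to_numpy()
        labels = (
            df["label"].to_numpy() if "label" in df else np.full(len(df), "lumen")
        )
        frames = df["frame"].to_numpy() if "frame" in df else np.zeros(len(df), int)
        return LabeledPointCloud(points=points, labels=labels, frame_of_origin=frames)
    if path.suffix.lower() == ".ply":
        text = path.read_text().splitlines()
        try:
            header_end = text.index("end_header")
        except ValueError:
            raise ValueError(f"{path}: not an ascii PLY file (no end_header)")
        props = [ln.split()[-1] for ln in text[:header_end] if ln.startswith("property")]
        points, labels, frames = [], [], []
        for ln in text[header_end + 1 :]:
            if not ln.strip():
                continue
            vals = ln.split()
            rec = dict(zip(props, vals))
            points.append([float(rec["x"]), float(rec["y"]), float(rec["z"])])
            labels.append(LABELS[int(rec.get("label", 0))])
            frames.append(int(rec.get("frame", 0)))
        return LabeledPointCloud(
            points=np.array(points),
            labels=np.array(labels),
            frame_of_origin=np.array(frames),
        )
    raise ValueError(f"unsupported point-cloud file {path}")
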