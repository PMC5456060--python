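"""Synthetic OCT phantom stacks with exact ground truth.

Generates pullback-like frame stacks that reproduce the image features
the segmentation pipeline relies on: a bright annular vessel wall around
a dark lumen, metallic struts rendered as saturated blooms each casting a
radial trail shadow, a catheter cross-section fixed in position across
frames, console overlay graphics at fixed pixel positions, additive
speckle-like noise, and optional bifurcation ostia appearing as wide
angular gaps in the wall signal.  Every rendered feature is recorded in a
:class:`GroundTruth` so that detection and validation stages can be
tested without acquired data.

Frames are rendered in Cartesian coordinates, as acquired; polar
conversion is the pipeline's job.  Geometry defaults mirror a typical
Fourier-domain pullback: 540 frames at 100 μm spacing, ~13 μm/pixel.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Sequence

import numpy as np

from .preprocess import FrameStack

# (frame index, θ degrees, radial offset from lumen border in μm, bloom radius px)
StrutPlacement = tuple[int, float, float, int]


def circular_profile(radius_um: float) -> Callable[[int, np.ndarray], np.ndarray]:
    """Lumen radius profile of a straight circular tube."""

    def profile(frame: int, theta_deg: np.ndarray) -> np.ndarray:
        return np.full_like(np.asarray(theta_deg, dtype=float), radius_um)

    return profile


def elliptic_profile(a_um: float, b_um: float) -> Callable[[int, np.ndarray], np.ndarray]:
    """Lumen radius profile of an elliptical cross-section (semi-axes in μm)."""

    def profile(frame: int, theta_deg: np.ndarray) -> np.ndarray:
        t = np.deg2rad(np.asarray(theta_deg, dtype=float))
        return (a_um * b_um) / np.sqrt(
            (b_um * np.cos(t)) ** 2 + (a_um * np.sin(t)) ** 2
        )

    return profile


def helical_stent_layout(
    n_frames: int,
    struts_per_frame: int = 10,
    twist_deg_per_frame: float = 3.0,
    radial_offset_um: float = 0.0,
    bloom_px: int = 2,
    first_frame: int = 0,
    last_frame: int | None = None,
) -> list[StrutPlacement]:
    """Strut placements along a helix, as in a real tubular stent.

    ``struts_per_frame`` struts are spread evenly over θ on every frame,
    the whole ring advancing ``twist_deg_per_frame`` degrees per frame so
    each strut traces a helical track through the stack.
    """
    last = n_frames - 1 if last_frame is None else last_frame
    layout = []
    for f in range(first_frame, last + 1):
        base = (f * twist_deg_per_frame) % 360.0
        for k in range(struts_per_frame):
            theta = (base + k * 360.0 / struts_per_frame) % 360.0
            layout.append((f, theta, radial_offset_um, bloom_px))
    return layout


@dataclass
class PhantomSpec:
    """Full description of a synthetic pullback. All lengths in μm unless noted."""

    n_frames: int = 540
    image_size: int = 512  # square frames, pixels
    pixel_size: float = 13.0  # μm / pixel
    frame_spacing: float = 100.0  # μm
    lumen_radius_profile: Callable[[int, np.ndarray], np.ndarray] = field(
        default_factory=lambda: circular_profile(1500.0)
    )
    wall_thickness: float = 400.0  # μm, nominal bright-band depth (fit checks)
    attenuation_length: float = 500.0  # μm, depth decay constant of wall signal
    wall_intensity: float = 180.0
    lumen_intensity: float = 5.0
    background_intensity: float = 5.0
    strut_layout: list[StrutPlacement] = field(default_factory=list)
    strut_intensity: float = 255.0
    shadow_attenuation: float = 0.1
    catheter_center: tuple[float, float] | None = None  # (row, col); default centre
    catheter_radius: int = 16  # px
    catheter_intensity: float = 230.0
    overlay_mask: np.ndarray | None = None  # bool image; default scale-bar strip
    overlay_intensity: float = 251.0
    bifurcation: tuple[tuple[int, int], tuple[float, float]] | None = None
    noise_sigma: float = 8.0
    seed: int = 0

    def resolved_catheter_center(self) -> tuple[float, float]:
        if self.catheter_center is not None:
            return self.catheter_center
        c = self.image_size // 2
        return (float(c), float(c))

    def resolved_overlay_mask(self) -> np.ndarray:
        if self.overlay_mask is not None:
            return np.asarray(self.overlay_mask, dtype=bool)
        mask = np.zeros((self.image_size, self.image_size), dtype=bool)
        mask[4:6, 8 : min(72, self.image_size)] = True  # scale bar
        mask[10:14, 8:24] = True  # info block
        return mask

    def validate(self) -> None:
        if self.n_frames < 1:
            raise ValueError("n_frames must be ≥ 1")
        if not 0.0 <= self.shadow_attenuation <= 1.0:
            raise ValueError("shadow_attenuation must lie in [0, 1]")
        theta = np.arange(360.0)
        cath_r_um = self.catheter_radius * self.pixel_size
        half = self.image_size / 2.0
        for f in range(self.n_frames):
            r = np.asarray(self.lumen_radius_profile(f, theta), dtype=float)
            if np.any(r <= cath_r_um):
                raise ValueError(
                    "lumen_radius_profile: lumen must enclose the catheter "
                    f"(radius ≤ {cath_r_um:.0f} μm on frame {f})"
                )
            if np.any((r + self.wall_thickness) / self.pixel_size >= half - 1):
                raise ValueError(
                    f"lumen_radius_profile: wall leaves the image on frame {f}"
                )
        if self.bifurcation is not None:
            (f0, f1), (t0, t1) = self.bifurcation
            if not (0 <= f0 <= f1 < self.n_frames):
                raise ValueError("bifurcation: frame interval outside the stack")
            if not (0.0 <= t0 < 360.0 and 0.0 <= t1 < 360.0):
                raise ValueError("bifurcation: θ interval must lie in [0°, 360°)")
        for f, theta_s, _, bloom in self.strut_layout:
            if not 0 <= f < self.n_frames:
                raise ValueError(f"strut_layout: frame {f} outside the stack")
            if bloom < 1:
                raise ValueError("strut_layout: bloom size must be ≥ 1 px")


@dataclass
class GroundTruth:
    """Exact rendered geometry of a phantom stack.

    ``lumen_radius`` is a (n_frames, 360) table of border radii in μm
    about the catheter centre; ``strut_centroids`` holds one
    (frame, x μm, y μm) triple per rendered strut, in the same
    catheter-centred frame (θ counter-clockwise from +x, y up).
    """

    lumen_radius: np.ndarray
    strut_centroids: list[tuple[int, float, float]]
    bifurcation_frames: set[int]
    catheter_mask: np.ndarray
    overlay_mask: np.ndarray

    def struts_on_frame(self, frame: int) -> list[tuple[float, float]]:
        return [(x, y) for f, x, y in self.strut_centroids if f == frame]


def _angular_distance_deg(a: np.ndarray, b: float) -> np.ndarray:
    d = np.abs(a - b) % 360.0
    return np.minimum(d, 360.0 - d)


def _in_interval_deg(theta: np.ndarray, t0: float, t1: float) -> np.ndarray:
    """Membership of θ in the circular interval [t0, t1]."""
    if t0 <= t1:
        return (theta >= t0) & (theta <= t1)
    return (theta >= t0) | (theta <= t1)


def generate_stack(spec: PhantomSpec) -> tuple[FrameStack, GroundTruth]:
    """Render a phantom pullback and its exact ground truth.

    Same spec and seed produce a bit-identical stack.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    size = spec.image_size
    orow, ocol = spec.resolved_catheter_center()

    rows, cols = np.mgrid[0:size, 0:size]
    dx = cols - ocol
    dy = orow - rows  # y up
    r_px = np.hypot(dx, dy)
    theta_deg = np.degrees(np.arctan2(dy, dx)) % 360.0

    catheter_mask = r_px <= spec.catheter_radius
    overlay_mask = spec.resolved_overlay_mask()

    struts_by_frame: dict[int, list[tuple[float, float, int]]] = {}
    for f, t, off, bloom in spec.strut_layout:
        struts_by_frame.setdefault(f, []).append((t, off, bloom))

    gt_theta = np.arange(360.0)
    lumen_radius_gt = np.empty((spec.n_frames, 360))
    strut_centroids: list[tuple[int, float, float]] = []
    bifurcation_frames: set[int] = set()

    frames = np.empty((spec.n_frames, size, size), dtype=np.uint8)
    for f in range(spec.n_frames):
        radius_um = np.asarray(spec.lumen_radius_profile(f, theta_deg), dtype=float)
        lumen_radius_gt[f] = np.asarray(
            spec.lumen_radius_profile(f, gt_theta), dtype=float
        )
        border_px = radius_um / spec.pixel_size

        # wall signal: bright at the lumen border, decaying with depth as the
        # beam attenuates, over a dim diffuse floor
        img = np.full((size, size), spec.background_intensity)
        wall = r_px >= border_px
        depth_px = np.where(wall, r_px - border_px, 0.0)
        decay_px = spec.attenuation_length / spec.pixel_size
        img[wall] = spec.background_intensity + (
            spec.wall_intensity - spec.background_intensity
        ) * np.exp(-depth_px[wall] / decay_px)
        img[r_px < border_px] = spec.lumen_intensity

        if spec.bifurcation is not None:
            (f0, f1), (t0, t1) = spec.bifurcation
            if f0 <= f <= f1:
                bifurcation_frames.add(f)
                ostium = wall & _in_interval_deg(theta_deg, t0, t1)
                img[ostium] = spec.background_intensity

        for t_s, off_um, bloom in struts_by_frame.get(f, ()):
            r_center_um = float(
                np.asarray(spec.lumen_radius_profile(f, np.array([t_s])))[0] + off_um
            )
            r_center_px = r_center_um / spec.pixel_size
            t_rad = np.deg2rad(t_s)
            x_c = r_center_um * np.cos(t_rad)
            y_c = r_center_um * np.sin(t_rad)
            crow = orow - r_center_px * np.sin(t_rad)
            ccol = ocol + r_center_px * np.cos(t_rad)
            # shadow first so the bloom itself stays saturated
            half_angle = np.degrees(np.arctan2(bloom, r_center_px))
            shadow = (r_px > r_center_px + bloom) & (
                _angular_distance_deg(theta_deg, t_s) <= half_angle
            )
            img[shadow] = img[shadow] * spec.shadow_attenuation
            bloom_mask = (rows - crow) ** 2 + (cols - ccol) ** 2 <= bloom**2
            img[bloom_mask] = spec.strut_intensity
            strut_centroids.append((f, x_c, y_c))

        img[catheter_mask] = spec.catheter_intensity
        if spec.noise_sigma > 0:
            img = img + rng.normal(0.0, spec.noise_sigma, img.shape)
        img[overlay_mask] = spec.overlay_intensity
        frames[f] = np.clip(np.rint(img), 0, 255).astype(np.uint8)

    stack = FrameStack(
        frames=frames, pixel_size=spec.pixel_size, frame_spacing=spec.frame_spacing
    )
    truth = GroundTruth(
        lumen_radius=lumen_radius_gt,
        strut_centroids=strut_centroids,
        bifurcation_frames=bifurcation_frames,
        catheter_mask=catheter_mask,
        overlay_mask=overlay_mask,
    )
    return stack, truth


# ---------------------------------------------------------------------------
# Writers


def write_stack(stack: FrameStack, out: str | Path, fmt: str = "tiff") -> Path:
    """Write the stack as a multi-page TIFF or a directory of numbered PNGs."""
    out = Path(out)
    if fmt == "tiff":
        import tifffile

        out = out if out.suffix else out / "stack.tif"
        out.parent.mkdir(parents=True, exist_ok=True)
        tifffile.imwrite(out, stack.frames, photometric="minisblack")
        return out
    if fmt == "png":
        import imageio.v3 as iio

        out.mkdir(parents=True, exist_ok=True)
        for i, frame in enumerate(stack.frames):
            iio.imwrite(out / f"frame_{i:04d}.png", frame)
        return out
    raise ValueError(f"unknown stack format {fmt!r}")


def write_ground_truth(truth: GroundTruth, out_dir: str | Path) -> None:
    """Ground truth as JSON (summary) plus a CSV lumen-radius table."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    summary = {
        "strut_centroids": [
            {"frame": f, "x_um": x, "y_um": y} for f, x, y in truth.strut_centroids
        ],
        "bifurcation_frames": sorted(truth.bifurcation_frames),
    }
    (out_dir / "ground_truth.json").write_text(json.dumps(summary, indent=2))
    n_frames, n_theta = truth.lumen_radius.shape
    import pandas as pd

    table = pd.DataFrame(
        {
            "frame": np.repeat(np.arange(n_frames), n_theta),
            "theta_deg": np.tile(np.arange(n_theta), n_frames),
            "radius_um": truth.lumen_radius.ravel(),
        }
    )
    table.to_csv(out_dir / "lumen_radius.csv", index=False)
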