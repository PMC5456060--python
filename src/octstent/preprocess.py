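"""Pre-processing of raw OCT pullback frames.

Raw frames from a Fourier-domain OCT console carry, besides the
cross-sectional image itself, a longitudinal-view strip at the bottom,
overlay graphics (scale bar, section-plane line, acquisition text) at
fixed pixel positions, and the bright cross-section of the imaging
catheter, which sits at the same position in every frame of a pullback.
This module turns such frames into clean greyscale images suitable for
lumen and strut segmentation: RGB→greyscale conversion, bottom crop,
overlay blanking, and catheter removal via the cross-frame mean image.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
from scipy import ndimage


@dataclass
class FrameStack:
    """An ordered stack of greyscale OCT frames with acquisition metadata.

    Parameters
    ----------
    frames : ndarray, shape (n_frames, H, W)
        Pixel intensities, 0–255.
    pixel_size : float
        In-plane pixel size in micrometres per pixel.
    frame_spacing : float
        Pullback distance between consecutive frames in micrometres.
    """

    frames: np.ndarray
    pixel_size: float
    frame_spacing: float

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        if self.frames.ndim != 3:
            raise ValueError(
                f"frames must be a (n_frames, H, W) array, got shape {self.frames.shape}"
            )
        if self.pixel_size <= 0:
            raise ValueError(f"pixel_size must be > 0, got {self.pixel_size}")
        if self.frame_spacing <= 0:
            raise ValueError(f"frame_spacing must be > 0, got {self.frame_spacing}")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def frame_shape(self) -> tuple[int, int]:
        return self.frames.shape[1:]


@dataclass
class StaticMask:
    """A binary mask of pixels that are stationary across the pullback.

    ``kind`` distinguishes console overlay graphics from the catheter
    cross-section; both are blanked to background before segmentation.
    """

    mask: np.ndarray
    kind: Literal["overlay", "catheter"]

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.ndim != 2:
            raise ValueError("mask must be a 2D binary image")


# Rec. 601 luminance weights, the convention used by common image toolboxes
# for RGB→greyscale conversion.
_LUMA = np.array([0.2989, 0.5870, 0.1140])


def to_grayscale(frame: np.ndarray) -> np.ndarray:
    """Convert an RGB frame to greyscale; greyscale input passes through.

    Uses Rec. 601 luminance weighting and rounds back to the input's
    integer scale when the input is integer-valued.
    """
    frame = np.asarray(frame)
    if frame.ndim == 2:
        return frame
    if frame.ndim == 3 and frame.shape[2] == 3:
        grey = frame.astype(float) @ _LUMA
        if np.issubdtype(frame.dtype, np.integer):
            return np.clip(np.rint(grey), 0, 255).astype(frame.dtype)
        return grey
    raise ValueError(
        f"expected a single- or 3-channel image, got shape {frame.shape}"
    )


def crop_longitudinal(frame: np.ndarray, crop_rows: int) -> np.ndarray:
    """Remove the bottom ``crop_rows`` rows (the longitudinal-view strip)."""
    if crop_rows < 0:
        raise ValueError("crop_rows must be non-negative")
    if crop_rows >= frame.shape[0]:
        raise ValueError(
            f"crop_rows={crop_rows} must be smaller than the frame height {frame.shape[0]}"
        )
    return frame[: frame.shape[0] - crop_rows] if crop_rows else frame


def remove_overlays(stack: FrameStack, overlay: StaticMask) -> FrameStack:
    """Blank overlay pixels to the background value (0) in every frame."""
    if overlay.mask.shape != stack.frame_shape:
        raise ValueError(
            f"mask shape {overlay.mask.shape} does not match frame shape {stack.frame_shape}"
        )
    frames = stack.frames.copy()
    frames[:, overlay.mask] = 0
    return replace(stack, frames=frames)


def build_overlay_mask(stack: FrameStack) -> StaticMask:
    """Find overlay pixels as those constant and non-zero across all frames.

    Console graphics keep both position and intensity fixed over the
    pullback, so their across-frame intensity variance is exactly zero
    while tissue pixels fluctuate.  The catheter region also satisfies
    this on noise-free input; it is removed separately and its inclusion
    here is harmless.
    """
    if stack.n_frames < 2:
        raise ValueError("overlay detection requires at least 2 frames")
    frames = stack.frames.astype(float)
    constant = np.all(frames == frames[0], axis=0)
    mask = constant & (frames[0] > 0)
    return StaticMask(mask=mask, kind="overlay")


def detect_catheter(stack: FrameStack, threshold_quantile: float = 0.99) -> StaticMask:
    """Locate the catheter cross-section from the cross-frame mean image.

    Averaging across the pullback suppresses structures that move frame to
    frame (wall, struts) while the catheter, fixed in position, survives as
    the brightest region of the mean image.  The mask is the connected
    component of above-quantile pixels that contains the global maximum of
    the mean image.
    """
    if stack.n_frames < 2:
        raise ValueError(
            "catheter removal requires a multi-frame stack: the cross-frame "
            "average must suppress moving structures"
        )
    if not 0 < threshold_quantile < 1:
        raise ValueError("threshold_quantile must lie in (0, 1)")
    mean_img = stack.frames.mean(axis=0)
    if mean_img.max() == 0:
        return StaticMask(mask=np.zeros_like(mean_img, dtype=bool), kind="catheter")
    thresh = np.quantile(mean_img, threshold_quantile)
    bright = mean_img >= thresh
    labels, _ = ndimage.label(bright)
    peak = np.unravel_index(np.argmax(mean_img), mean_img.shape)
    mask = labels == labels[peak]
    return StaticMask(mask=mask, kind="catheter")


def catheter_centroid(mask: StaticMask) -> tuple[float, float]:
    """(row, col) centroid of the catheter mask — the polar origin."""
    rows, cols = np.nonzero(mask.mask)
    if rows.size == 0:
        raise ValueError("empty catheter mask has no centroid")
    return float(rows.mean()), float(cols.mean())


def preprocess_stack(
    stack: FrameStack,
    crop_rows: int = 0,
    overlay: StaticMask | None = None,
    threshold_quantile: float = 0.99,
) -> tuple[FrameStack, StaticMask]:
    """Full pre-processing chain: crop, overlay blanking, catheter removal.

    Returns the cleaned stack and the detected catheter mask (whose
    centroid serves as the polar origin downstream).
    """
    frames = np.stack([crop_longitudinal(f, crop_rows) for f in stack.frames])
    stack = replace(stack, frames=frames)
    if overlay is None:
        overlay = build_overlay_mask(stack)
    stack = remove_overlays(stack, overlay)
    catheter = detect_catheter(stack, threshold_quantile)
    cleaned = remove_overlays(stack, StaticMask(mask=catheter.mask, kind="overlay"))
    return cleaned, catheter


# ---------------------------------------------------------------------------
# Stack readers


def read_stack(
    path: str | Path,
    pixel_size: float | None = None,
    frame_spacing: float | None = None,
) -> FrameStack:
    """Read a pullback from a multi-frame DICOM, a multi-page TIFF, or a
    directory of ordered PNG/TIFF frames.

    ``pixel_size`` / ``frame_spacing`` (μm) are taken from DICOM metadata
    when present and must otherwise be supplied explicitly.
    """
    path = Path(path)
    if path.is_dir():
        files = sorted(
            p for p in path.iterdir() if p.suffix.lower() in {".png", ".tif", ".tiff"}
        )
        if not files:
            raise ValueError(f"no PNG/TIFF frames found in {path}")
        import imageio.v3 as iio

        frames = np.stack([to_grayscale(iio.imread(f)) for f in files])
    elif path.suffix.lower() in {".tif", ".tiff"}:
        import tifffile

        raw = tifffile.imread(path)
        frames = np.stack([to_grayscale(f) for f in raw])
    elif path.suffix.lower() in {".dcm", ".dicom"} or path.suffix == "":
        import pydicom

        ds = pydicom.dcmread(path)
        raw = ds.pixel_array
        if raw.ndim == 2:
            raw = raw[None]
        frames = np.stack([to_grayscale(f) for f in raw])
        if pixel_size is None and "PixelSpacing" in ds:
            pixel_size = float(ds.PixelSpacing[0]) * 1000.0  # mm → μm
        if frame_spacing is None and "SpacingBetweenSlices" in ds:
            frame_spacing = float(ds.SpacingBetweenSlices) * 1000.0
    else:
        raise ValueError(f"unsupported stack input: {path}")
    if pixel_size is None:
        raise ValueError(
            "pixel_size (μm/px) not available from metadata; pass --pixel-size"
        )
    if frame_spacing is None:
        raise ValueError(
            "frame_spacing (μm) not available from metadata; pass --frame-spacing"
        )
    return FrameStack(frames=frames, pixel_size=pixel_size, frame_spacing=frame_spacing)
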