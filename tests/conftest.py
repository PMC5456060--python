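"""Shared phantom fixtures.

Session-scoped because phantom generation and segmentation are the
expensive steps; every test treats the results as read-only.
"""

import numpy as np
import pytest

from octstent.phantom import (
    PhantomSpec,
    circular_profile,
    generate_stack,
    helical_stent_layout,
)
from octstent.pipeline import segment_stack


@pytest.fixture(scope="session")
def noisefree_cylinder():
    """Noise-free straight tube, circular lumen R = 1.5 mm, no struts."""
    spec = PhantomSpec(
        n_frames=8,
        image_size=512,
        lumen_radius_profile=circular_profile(1500.0),
        noise_sigma=0.0,
        seed=0,
    )
    return spec, *generate_stack(spec)


@pytest.fixture(scope="session")
def noisy_stent_stack():
    """Noisy pullback with a 10-strut/frame helical stent."""
    spec = PhantomSpec(
        n_frames=20,
        image_size=512,
        lumen_radius_profile=circular_profile(1200.0),
        strut_layout=helical_stent_layout(20, struts_per_frame=10, twist_deg_per_frame=3.0),
        noise_sigma=8.0,
        seed=1,
    )
    return spec, *generate_stack(spec)


@pytest.fixture(scope="session")
def segmented_noisy(noisy_stent_stack):
    spec, stack, truth = noisy_stent_stack
    return segment_stack(stack, overlay_mask=truth.overlay_mask), truth


def disk_image(size: int = 128, radius: float = 50.0, value: float = 1.0) -> np.ndarray:
    """Filled centred disk — the canonical polar-transform fixture."""
    c = size // 2
    rows, cols = np.mgrid[0:size, 0:size]
    return np.where(np.hypot(rows - c, cols - c) <= radius, value, 0.0)
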