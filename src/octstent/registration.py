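"""Rigid registration of stent point clouds by iterative closest point.

Registers the OCT-derived stent point cloud (moving) to a reference
cloud such as a micro-CT stent centerline (fixed).  Point-to-point ICP
alternates nearest-neighbour correspondence with the closed-form
least-squares rigid update (Kabsch/SVD).  Because a tubular stent is
nearly rotation-symmetric about the pullback axis, a single
initialization can converge to a local minimum; registration therefore
sweeps the initial rotation about z from 0 to 360° after aligning the
barycentres, keeping the transform with the smallest sum of squared
distances.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree


@dataclass
class RigidTransform:
    """x ↦ rotation·(x − center_of_rotation) + center_of_rotation + translation."""

    rotation: np.ndarray = field(default_factory=lambda: np.eye(3))
    translation: np.ndarray = field(default_factory=lambda: np.zeros(3))
    center_of_rotation: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self) -> None:
        self.rotation = np.asarray(self.rotation, dtype=float)
        self.translation = np.asarray(self.translation, dtype=float)
        self.center_of_rotation = np.asarray(self.center_of_rotation, dtype=float)
        if not np.allclose(self.rotation.T @ self.rotation, np.eye(3), atol=1e-9):
            raise ValueError("rotation must be orthonormal")
        if np.linalg.det(self.rotation) < 0:
            raise ValueError("rotation must be proper (det = +1)")

    def apply(self, points: np.ndarray) -> np.ndarray:
        p = np.asarray(points, dtype=float) - self.center_of_rotation
        return p @ self.rotation.T + self.center_of_rotation + self.translation

    def compose_with(self, first: "RigidTransform") -> "RigidTransform":
        """The transform equivalent to applying ``first`` then ``self``."""
        rot = self.rotation @ first.rotation
        # express both as x ↦ R x + t (center folded into translation)
        t_first = (
            first.translation
            + first.center_of_rotation
            - first.rotation @ first.center_of_rotation
        )
        t_self = (
            self.translation
            + self.center_of_rotation
            - self.rotation @ self.center_of_rotation
        )
        t = self.rotation @ t_first + t_self
        return RigidTransform(rotation=rot, translation=t)

    def matrix(self) -> np.ndarray:
        """Homogeneous 4×4 matrix of the transform."""
        m = np.eye(4)
        m[:3, :3] = self.rotation
        m[:3, 3] = (
            self.translation
            + self.center_of_rotation
            - self.rotation @ self.center_of_rotation
        )
        return m


@dataclass
class RegistrationResult:
    transform: RigidTransform
    rms_distance: float
    per_point_total: np.ndarray
    per_point_radial: np.ndarray
    best_init_angle: float = 0.0
    n_iterations: int = 0


def _kabsch(moving: np.ndarray, fixed: np.ndarray) -> RigidTransform:
    """Closed-form least-squares rigid transform mapping moving onto fixed."""
    mc = moving.mean(axis=0)
    fc = fixed.mean(axis=0)
    h = (moving - mc).T @ (fixed - fc)
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    rot = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    return RigidTransform(rotation=rot, translation=fc - rot @ mc)


def point_distances(
    registered_moving: np.ndarray, fixed: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Total and radial distances from each moving point to its nearest fixed point.

    Total is the 3D Euclidean distance; radial is the difference of the
    two points' distances from the z (pullback) axis, which isolates the
    strut-to-axis error from axial and angular misalignment.
    """
    moving = np.asarray(registered_moving, dtype=float)
    fixed = np.asarray(fixed, dtype=float)
    tree = cKDTree(fixed)
    total, idx = tree.query(moving)
    rho_m = np.hypot(moving[:, 0], moving[:, 1])
    rho_f = np.hypot(fixed[idx, 0], fixed[idx, 1])
    return total, np.abs(rho_m - rho_f)


def icp(
    moving: np.ndarray,
    fixed: np.ndarray,
    init: RigidTransform | None = None,
    max_iter: int = 100,
    tol: float = 1e-3,
) -> RegistrationResult:
    """Point-to-point ICP from a given initialization.

    Iterates nearest-neighbour correspondence and the closed-form rigid
    update until the RMS distance changes by less than ``tol`` μm or
    ``max_iter`` is reached.  The objective (sum of squared
    nearest-neighbour distances) is non-increasing across iterations.
    """
    moving = np.asarray(moving, dtype=float).reshape(-1, 3)
    fixed = np.asarray(fixed, dtype=float).reshape(-1, 3)
    if len(moving) == 0 or len(fixed) == 0:
        raise ValueError("both point clouds must be non-empty")
    transform = init if init is not None else RigidTransform()
    tree = cKDTree(fixed)
    current = transform.apply(moving)
    dist, idx = tree.query(current)
    rms = float(np.sqrt(np.mean(dist**2)))
    n_it = 0
    for n_it in range(1, max_iter + 1):
        step = _kabsch(current, fixed[idx])
        transform = step.compose_with(transform)
        current = transform.apply(moving)
        dist, idx = tree.query(current)
        new_rms = float(np.sqrt(np.mean(dist**2)))
        if abs(rms - new_rms) < tol:
            rms = new_rms
            break
        rms = new_rms
    total, radial = point_distances(current, fixed)
    return RegistrationResult(
        transform=transform,
        rms_distance=rms,
        per_point_total=total,
        per_point_radial=radial,
        n_iterations=n_it,
    )


def _z_rotation(angle_deg: float) -> np.ndarray:
    a = np.deg2rad(angle_deg)
    c, s = np.cos(a), np.sin(a)
    return np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])


def register_with_sweep(
    moving: np.ndarray,
    fixed: np.ndarray,
    angle_step: float = 1.0,
    max_iter: int = 100,
    tol: float = 1e-3,
) -> RegistrationResult:
    """ICP with barycentre alignment and a 0–360° z-axis initialization sweep.

    Each initialization translates the moving barycentre onto the fixed
    one and pre-rotates about the z axis through the fixed barycentre;
    the result with the smallest sum of squared distances wins.
    """
    if angle_step <= 0 or 360.0 % angle_step != 0:
        raise ValueError("angle_step must be positive and divide 360")
    moving = np.asarray(moving, dtype=float).reshape(-1, 3)
    fixed = np.asarray(fixed, dtype=float).reshape(-1, 3)
    if len(moving) == 0 or len(fixed) == 0:
        raise ValueError("both point clouds must be non-empty")
    bary_m = moving.mean(axis=0)
    bary_f = fixed.mean(axis=0)
    best: RegistrationResult | None = None
    for angle in np.arange(0.0, 360.0, angle_step):
        # x ↦ Rz·(x − bm) + bf: barycentres aligned, then rotated about the
        # (now common) barycentre, which is the chosen centre of rotation
        init = RigidTransform(
            rotation=_z_rotation(angle),
            translation=bary_f - bary_m,
            center_of_rotation=bary_m.copy(),
        )
        result = icp(moving, fixed, init=init, max_iter=max_iter, tol=tol)
        if best is None or result.rms_distance < best.rms_distance:
            best = result
            best.best_init_angle = float(angle)
    assert best is not None
    return best
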