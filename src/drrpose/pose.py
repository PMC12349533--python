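"""Rigid 6-DOF pose parametrisation and homogeneous transforms.

A pose is three translations (mm) and three rotations (degrees) about the
fixed world axes.  The rotation convention used throughout the package is
extrinsic ``R = Rz @ Ry @ Rx`` applied about a pivot point (by default the
volume centre), followed by the translation.  One fixed convention is used
everywhere; it is deliberately not configurable so that matrices, DRR
geometry and error reports can never silently disagree.

The lateral imaging view is related to the frontal one by a fixed
view-change transform (``default_view_change``): the lateral volume
transform is the matrix product ``view_change @ frontal`` with the view
change on the left.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "PoseParameters",
    "RigidTransform",
    "PoseError",
    "pose_to_matrix",
    "compose_lateral",
    "apply_transform",
    "pose_error",
    "default_view_change",
    "wrap_angle",
]

#: tolerance used when validating user-supplied matrices (config round trips
#: through text may carry a few ulps more error than freshly built products)
_RIGID_ATOL = 1e-6


def wrap_angle(angle_deg: float) -> float:
    """Wrap an angle in degrees onto the half-open interval (-180, 180]."""
    return ((float(angle_deg) - 180.0) % -360.0) + 180.0


@dataclass(frozen=True)
class PoseParameters:
    """Six rigid degrees of freedom: translations in mm, rotations in degrees.

    Angles are wrapped to (-180, 180] on construction; all fields must be
    finite.  The canonical vector order is (tx, ty, tz, theta_x, theta_y,
    theta_z).
    """

    tx: float = 0.0
    ty: float = 0.0
    tz: float = 0.0
    theta_x: float = 0.0
    theta_y: float = 0.0
    theta_z: float = 0.0

    def __post_init__(self) -> None:
        vals = [self.tx, self.ty, self.tz, self.theta_x, self.theta_y, self.theta_z]
        if not all(math.isfinite(float(v)) for v in vals):
            raise ValueError(f"pose parameters must be finite, got {vals}")
        object.__setattr__(self, "tx", float(self.tx))
        object.__setattr__(self, "ty", float(self.ty))
        object.__setattr__(self, "tz", float(self.tz))
        object.__setattr__(self, "theta_x", wrap_angle(self.theta_x))
        object.__setattr__(self, "theta_y", wrap_angle(self.theta_y))
        object.__setattr__(self, "theta_z", wrap_angle(self.theta_z))

    @property
    def translation(self) -> np.ndarray:
        return np.array([self.tx, self.ty, self.tz], dtype=float)

    @property
    def angles(self) -> np.ndarray:
        return np.array([self.theta_x, self.theta_y, self.theta_z], dtype=float)

    def as_vector(self) -> np.ndarray:
        """Serialise as (tx, ty, tz, theta_x, theta_y, theta_z)."""
        return np.concatenate([self.translation, self.angles])

    @classmethod
    def from_vector(cls, v) -> "PoseParameters":
        v = np.asarray(v, dtype=float).reshape(-1)
        if v.shape != (6,):
            raise ValueError(f"pose vector must have 6 entries, got shape {v.shape}")
        return cls(*v)


@dataclass(frozen=True)
class RigidTransform:
    """A 4x4 homogeneous rigid-body transform.

    The rotation block must be orthonormal with determinant +1 and the last
    row (0, 0, 0, 1).
    """

    matrix: np.ndarray = field(default_factory=lambda: np.eye(4))

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.shape != (4, 4):
            raise ValueError(f"transform matrix must be 4x4, got {m.shape}")
        if not np.all(np.isfinite(m)):
            raise ValueError("transform matrix must be finite")
        if not np.allclose(m[3], [0.0, 0.0, 0.0, 1.0], atol=_RIGID_ATOL):
            raise ValueError(f"last row must be (0,0,0,1), got {m[3]}")
        r = m[:3, :3]
        if not np.allclose(r.T @ r, np.eye(3), atol=_RIGID_ATOL):
            raise ValueError("rotation block is not orthonormal")
        if not np.isclose(np.linalg.det(r), 1.0, atol=_RIGID_ATOL):
            raise ValueError("rotation block must have determinant +1 (no reflections)")
        m = m.copy()
        m[3] = (0.0, 0.0, 0.0, 1.0)
        m.setflags(write=False)
        object.__setattr__(self, "matrix", m)

    @property
    def rotation(self) -> np.ndarray:
        return self.matrix[:3, :3]

    @property
    def translation(self) -> np.ndarray:
        return self.matrix[:3, 3]

    def inverse(self) -> "RigidTransform":
        r = self.rotation.T
        t = -r @ self.translation
        m = np.eye(4)
        m[:3, :3] = r
        m[:3, 3] = t
        return RigidTransform(m)

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """Return self @ other (``other`` acts first)."""
        return RigidTransform(self.matrix @ other.matrix)

    def __matmul__(self, other: "RigidTransform") -> "RigidTransform":
        return self.compose(other)

    def apply(self, points) -> np.ndarray:
        """Apply to one point (3,) or an array of points (..., 3)."""
        p = np.asarray(points, dtype=float)
        return p @ self.rotation.T + self.translation

    def to_list(self) -> list[float]:
        """Row-major 16-number serialisation for JSON/YAML configs."""
        return [float(v) for v in self.matrix.reshape(-1)]

    @classmethod
    def from_list(cls, values) -> "RigidTransform":
        v = np.asarray(values, dtype=float).reshape(-1)
        if v.shape != (16,):
            raise ValueError(f"transform list must have 16 entries, got {v.shape}")
        return cls(v.reshape(4, 4))

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(4))


@dataclass(frozen=True)
class PoseError:
    """Per-axis absolute pose errors: rotations in degrees, translations in mm.

    Rotation errors use the shorter arc, so each lies in [0, 180].
    """

    rotation_deg: np.ndarray
    translation_mm: np.ndarray

    def __post_init__(self) -> None:
        r = np.asarray(self.rotation_deg, dtype=float).reshape(3)
        t = np.asarray(self.translation_mm, dtype=float).reshape(3)
        if np.any(r < 0) or np.any(t < 0):
            raise ValueError("error components must be non-negative")
        if np.any(r > 180.0):
            raise ValueError("shorter-arc rotation errors cannot exceed 180 degrees")
        r.setflags(write=False)
        t.setflags(write=False)
        object.__setattr__(self, "rotation_deg", r)
        object.__setattr__(self, "translation_mm", t)

    def as_vector(self) -> np.ndarray:
        """(tx, ty, tz, rx, ry, rz) error vector matching the pose order."""
        return np.concatenate([self.translation_mm, self.rotation_deg])


def _rotation_zyx(theta_x: float, theta_y: float, theta_z: float) -> np.ndarray:
    """Extrinsic rotation about fixed world axes: Rz @ Ry @ Rx, angles in deg."""
    ax, ay, az = np.deg2rad([theta_x, theta_y, theta_z])
    cx, sx = np.cos(ax), np.sin(ax)
    cy, sy = np.cos(ay), np.sin(ay)
    cz, sz = np.cos(az), np.sin(az)
    rx = np.array([[1, 0, 0], [0, cx, -sx], [0, sx, cx]])
    ry = np.array([[cy, 0, sy], [0, 1, 0], [-sy, 0, cy]])
    rz = np.array([[cz, -sz, 0], [sz, cz, 0], [0, 0, 1]])
    return rz @ ry @ rx


def pose_to_matrix(pose: PoseParameters, center=(0.0, 0.0, 0.0)) -> RigidTransform:
    """Build the rigid transform for a 6-DOF pose.

    Rotates about ``center`` (the pivot, in world mm; the volume centre by
    default in the rendering pipeline) by (theta_x, theta_y, theta_z) applied
    as extrinsic Rz @ Ry @ Rx, then translates by (tx, ty, tz).
    """
    if not isinstance(pose, PoseParameters):
        pose = PoseParameters.from_vector(np.asarray(pose, dtype=float))
    c = np.asarray(center, dtype=float).reshape(3)
    if not np.all(np.isfinite(c)):
        raise ValueError("rotation pivot must be finite")
    r = _rotation_zyx(pose.theta_x, pose.theta_y, pose.theta_z)
    m = np.eye(4)
    m[:3, :3] = r
    # rotate about c then translate: x' = R (x - c) + c + t
    m[:3, 3] = pose.translation + c - r @ c
    return RigidTransform(m)


def compose_lateral(frontal: RigidTransform, view_change: RigidTransform) -> RigidTransform:
    """Volume transform for the lateral view: ``view_change @ frontal``.

    The frontal pose acts first; the fixed frontal-to-lateral view change is
    applied on the left.
    """
    if not isinstance(frontal, RigidTransform) or not isinstance(view_change, RigidTransform):
        raise TypeError("compose_lateral expects two RigidTransform inputs")
    return view_change.compose(frontal)


def apply_transform(t: RigidTransform, point) -> np.ndarray:
    """Homogeneous application of ``t`` to a 3-point (mm)."""
    p = np.asarray(point, dtype=float).reshape(3)
    if not np.all(np.isfinite(p)):
        raise ValueError("point must be finite")
    return t.apply(p)


def pose_error(estimated: PoseParameters, truth: PoseParameters) -> PoseError:
    """Component-wise absolute errors, with angles wrapped to the shorter arc."""
    dt = np.abs(estimated.translation - truth.translation)
    raw = estimated.angles - truth.angles
    dr = np.abs((raw + 180.0) % 360.0 - 180.0)
    return PoseError(rotation_deg=dr, translation_mm=dt)


def default_view_change(angle_deg: float = 90.0) -> RigidTransform:
    """Frontal-to-lateral view-change transform.

    A +90 degree rotation about the world Y axis (the patient longitudinal
    axis): applying it to the volume and projecting with the frontal camera
    is equivalent to leaving the volume in its frontal pose and viewing it
    with a camera swung onto the +X axis.  No detector offset is included.
    """
    return pose_to_matrix(PoseParameters(theta_y=angle_deg))
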