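"""Coordinate conventions, cameras, projections and Euclidean transforms.

The camera frame follows the convention used throughout the package: the
image plane is ``z = 0``, the principal point is the origin, and the center
of perspective projection is ``F = (0, 0, z_F)`` with ``z_F > 0``.  Scene
points conventionally sit at ``z < 0`` (in front of the image plane, away
from the eye), although projection itself is defined for any point not at
the depth of ``F``.  An orthographic camera is the limit ``z_F -> inf`` and
simply drops the ``z`` coordinate.

All point sets are ``(n, 3)`` or ``(n, 2)`` float arrays.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np

logger = logging.getLogger(__name__)

#: default absolute tolerance for geometric identities
GEOM_TOL = 1e-9


def _as_points(points, dim: int) -> np.ndarray:
    pts = np.asarray(points, dtype=float)
    if pts.size == 0:
        return pts.reshape(0, dim)
    pts = np.atleast_2d(pts)
    if pts.shape[1] != dim:
        raise ValueError(f"expected points of dimension {dim}, got shape {pts.shape}")
    if not np.all(np.isfinite(pts)):
        raise ValueError("points must have finite coordinates")
    return pts


@dataclass(frozen=True)
class Camera:
    """Perspective camera with projection center ``(0, 0, z_F)``.

    Parameters
    ----------
    z_F:
        Distance of the projection center from the image plane, in scene
        length units.  ``math.inf`` flags an orthographic camera.
    """

    z_F: float = 1.0

    def __post_init__(self):
        if not (self.z_F > 0):
            raise ValueError(f"z_F must be positive (or inf for orthographic), got {self.z_F}")

    @property
    def orthographic(self) -> bool:
        return math.isinf(self.z_F)

    @property
    def center(self) -> np.ndarray:
        return np.array([0.0, 0.0, self.z_F])


@dataclass(frozen=True)
class Plane3D:
    """Plane ``a x + b y + c z + d = 0`` with unit normal ``(a, b, c)``."""

    a: float
    b: float
    c: float
    d: float

    @classmethod
    def from_coefficients(cls, a, b, c, d, warn: bool = False) -> "Plane3D":
        """Build a plane, normalizing the coefficient vector.  ``warn`` logs
        when user-supplied coefficients were not normalized."""
        norm = math.sqrt(a * a + b * b + c * c)
        if norm == 0:
            raise ValueError("degenerate plane: zero normal")
        if warn and abs(norm - 1.0) > GEOM_TOL:
            logger.warning("plane normal not unit length (|n|=%g); normalizing", norm)
        return cls(a / norm, b / norm, c / norm, d / norm)

    @classmethod
    def from_normal_point(cls, normal, point) -> "Plane3D":
        n = np.asarray(normal, dtype=float)
        p = np.asarray(point, dtype=float)
        d = -float(n @ p)
        return cls.from_coefficients(n[0], n[1], n[2], d)

    @property
    def normal(self) -> np.ndarray:
        return np.array([self.a, self.b, self.c])

    def signed_distance(self, points) -> np.ndarray:
        pts = _as_points(points, 3)
        return pts @ self.normal + self.d


@dataclass(frozen=True)
class RigidMotion:
    """Proper rigid motion ``x -> R x + t`` (orthonormal R, det +1)."""

    rotation: np.ndarray
    translation: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self):
        R = np.asarray(self.rotation, dtype=float)
        t = np.asarray(self.translation, dtype=float)
        if R.shape != (3, 3):
            raise ValueError("rotation must be 3x3")
        if not np.allclose(R @ R.T, np.eye(3), atol=1e-8):
            raise ValueError("rotation matrix is not orthonormal")
        if np.linalg.det(R) < 0:
            raise ValueError("rotation matrix has negative determinant (improper)")
        object.__setattr__(self, "rotation", R)
        object.__setattr__(self, "translation", t)

    @property
    def scale(self) -> float:
        return 1.0

    @classmethod
    def identity(cls) -> "RigidMotion":
        return cls(np.eye(3), np.zeros(3))


@dataclass(frozen=True)
class SimilarityTransform(RigidMotion):
    """Similarity ``x -> s R x + t`` with uniform scale ``s > 0``."""

    s: float = 1.0

    def __post_init__(self):
        super().__post_init__()
        if not self.s > 0:
            raise ValueError("similarity scale must be positive")

    @property
    def scale(self) -> float:
        return self.s


def project_perspective(points, camera: Camera) -> np.ndarray:
    """Project 3D points through ``F = (0, 0, z_F)`` onto the plane ``z = 0``.

    The image of ``(X, Y, Z)`` is ``(X z_F/(z_F - Z), Y z_F/(z_F - Z))``
    (similar triangles along the projecting ray).  Points with ``Z = z_F``
    lie at the depth of the projection center and have no defined image.
    """
    if camera.orthographic:
        return project_orthographic(points)
    pts = _as_points(points, 3)
    denom = camera.z_F - pts[:, 2]
    if np.any(np.abs(denom) < 1e-15):
        raise ValueError("point at the depth of the projection center (Z = z_F): ray undefined")
    scale = camera.z_F / denom
    return pts[:, :2] * scale[:, None]


def project_orthographic(points) -> np.ndarray:
    """Orthographic projection: drop the ``z`` coordinate."""
    pts = _as_points(points, 3)
    return pts[:, :2].copy()


def mirror_reflect(points, plane: Plane3D) -> np.ndarray:
    """Reflect points about a plane; an involution (applying twice is identity)."""
    pts = _as_points(points, 3)
    dist = plane.signed_distance(pts)
    return pts - 2.0 * dist[:, None] * plane.normal


def apply_transform(points, transform: RigidMotion) -> np.ndarray:
    """Apply a rigid motion or similarity transform to a point set."""
    pts = _as_points(points, 3)
    return transform.scale * (pts @ transform.rotation.T) + transform.translation


def rotation_about_z(angle: float) -> np.ndarray:
    c, s = math.cos(angle), math.sin(angle)
    return np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])


def random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniform random rotation matrix (QR of a Gaussian matrix, sign-fixed)."""
    A = rng.standard_normal((3, 3))
    Q, R = np.linalg.qr(A)
    Q = Q * np.sign(np.diag(R))
    if np.linalg.det(Q) < 0:
        Q[:, 2] = -Q[:, 2]
    return Q


def similarity_procrustes_distance(A, B, allow_reflection: bool = True) -> float:
    """Normalized residual of the best similarity transform mapping B onto A.

    "Shape" throughout this package is the invariant of rigid motion plus
    uniform scaling, so two point sets have the same shape iff this
    distance is ~0.  Correspondence between rows is assumed.  The residual
    is normalized by the centered norm of A, making the measure
    scale-free;  reflections are allowed by default (a mirror-symmetric
    object and its reflection have the same shape).
    """
    A = _as_points(A, 3)
    B = _as_points(B, 3)
    if A.shape != B.shape:
        raise ValueError("point sets must have matching shapes")
    A0 = A - A.mean(axis=0)
    B0 = B - B.mean(axis=0)
    na = np.linalg.norm(A0)
    nb = np.linalg.norm(B0)
    if na < 1e-15 or nb < 1e-15:
        return 0.0 if na < 1e-15 and nb < 1e-15 else 1.0
    A0 /= na
    B0 /= nb
    U, s, Vt = np.linalg.svd(B0.T @ A0)
    R = U @ Vt
    if not allow_reflection and np.linalg.det(R) < 0:
        U = U.copy()
        U[:, -1] = -U[:, -1]
        s = s.copy()
        s[-1] = -s[-1]
        R = U @ Vt
    # optimal scale is the trace of the singular values; evaluate the
    # aligned residual directly (numerically exact near zero)
    return float(np.linalg.norm(A0 - s.sum() * (B0 @ R)))


def rotation_about_axis(axis, angle: float) -> np.ndarray:
    """Rotation by ``angle`` about an arbitrary unit axis (Rodrigues)."""
    u = np.asarray(axis, dtype=float)
    u = u / np.linalg.norm(u)
    K = np.array([[0, -u[2], u[1]], [u[2], 0, -u[0]], [-u[1], u[0], 0]])
    return np.eye(3) + math.sin(angle) * K + (1 - math.cos(angle)) * (K @ K)
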