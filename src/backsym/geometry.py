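"""Core geometric primitives: point clouds, rigid transforms, neighborhoods.

All coordinates are millimetres in the sensor frame: the sensor sits at the
origin looking along +z (depth increases into the scene); after pose
normalization +x is craniocaudal and +y mediolateral.  Surface normals are
oriented to face the sensor, i.e. their z component is negative.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.spatial import cKDTree

__all__ = [
    "PointCloud",
    "RigidTransform",
    "Neighborhood",
    "neighbors_within",
    "estimate_normals_and_curvature",
    "apply_transform",
    "PLANAR_RADIUS",
]

#: Sentinel curvature radius for locally planar neighborhoods.
PLANAR_RADIUS = np.inf

#: Radii above this are indistinguishable from a plane at sensor noise scale.
_PLANAR_RADIUS_LIMIT = 1.0e4  # mm


@dataclass
class PointCloud:
    """A 3D point cloud with optional per-point normals and curvature radii.

    Parameters
    ----------
    points
        ``(n, 3)`` float array of coordinates in mm.
    normals
        Optional ``(n, 3)`` unit vectors, oriented toward the sensor.
    curvature_radii
        Optional ``(n,)`` positive radii of curvature in mm; ``inf`` flags a
        locally planar point.
    curvature_signs
        Optional ``(n,)`` array of +/-1: the side of the surface, along the
        normal, on which the osculating sphere centre lies (+1 means
        ``centre = p + radius * n``).  0 for planar points.
    stage_tag
        Pipeline stage label (``P0`` ... ``P8r``).
    """

    points: np.ndarray
    normals: np.ndarray | None = None
    curvature_radii: np.ndarray | None = None
    curvature_signs: np.ndarray | None = None
    stage_tag: str = "P0"

    def __post_init__(self) -> None:
        self.points = np.ascontiguousarray(self.points, dtype=np.float64)
        if self.points.ndim != 2 or self.points.shape[1] != 3:
            raise ValueError("points must be an (n, 3) array")
        if not np.isfinite(self.points).all():
            raise ValueError("points must be finite")
        n = len(self.points)
        if self.normals is not None:
            self.normals = np.ascontiguousarray(self.normals, dtype=np.float64)
            if self.normals.shape != (n, 3):
                raise ValueError("normals must have one unit vector per point")
            norms = np.linalg.norm(self.normals, axis=1)
            if not np.allclose(norms, 1.0, atol=1e-6):
                raise ValueError("normals must be unit length within 1e-6")
        if self.curvature_radii is not None:
            self.curvature_radii = np.asarray(self.curvature_radii, dtype=np.float64)
            if self.curvature_radii.shape != (n,):
                raise ValueError("curvature_radii must have one entry per point")
            if np.any(self.curvature_radii <= 0):
                raise ValueError("curvature_radii must be positive (inf = planar)")
        if self.curvature_signs is not None:
            self.curvature_signs = np.asarray(self.curvature_signs, dtype=np.float64)
            if self.curvature_signs.shape != (n,):
                raise ValueError("curvature_signs must have one entry per point")

    def __len__(self) -> int:
        return len(self.points)

    @property
    def planar_mask(self) -> np.ndarray | None:
        """Boolean mask of points flagged locally planar, if curvature is set."""
        if self.curvature_radii is None:
            return None
        return ~np.isfinite(self.curvature_radii)

    def select(self, indices: np.ndarray, stage_tag: str | None = None) -> "PointCloud":
        """Sub-cloud at ``indices``, carrying attributes along."""
        return PointCloud(
            points=self.points[indices],
            normals=None if self.normals is None else self.normals[indices],
            curvature_radii=None
            if self.curvature_radii is None
            else self.curvature_radii[indices],
            curvature_signs=None
            if self.curvature_signs is None
            else self.curvature_signs[indices],
            stage_tag=stage_tag or self.stage_tag,
        )

    def with_stage(self, stage_tag: str) -> "PointCloud":
        return replace(self, stage_tag=stage_tag)


@dataclass(frozen=True)
class RigidTransform:
    """A proper rigid motion ``p -> R p + t`` (rotation then translation)."""

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self) -> None:
        R = np.asarray(self.rotation, dtype=np.float64)
        t = np.asarray(self.translation, dtype=np.float64).reshape(3)
        if R.shape != (3, 3):
            raise ValueError("rotation must be 3x3")
        if not np.allclose(R @ R.T, np.eye(3), atol=1e-9):
            raise ValueError("rotation must be orthonormal within 1e-9")
        if not np.isclose(np.linalg.det(R), 1.0, atol=1e-9):
            raise ValueError("rotation must be proper (det +1)")
        object.__setattr__(self, "rotation", R)
        object.__setattr__(self, "translation", t)

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3))

    @classmethod
    def from_rotvec(cls, rotvec_deg: np.ndarray, center: np.ndarray | None = None) -> "RigidTransform":
        """Rotation by ``rotvec_deg`` (axis * angle, degrees) about ``center``."""
        from scipy.spatial.transform import Rotation

        R = Rotation.from_rotvec(np.asarray(rotvec_deg, dtype=float), degrees=True).as_matrix()
        if center is None:
            t = np.zeros(3)
        else:
            c = np.asarray(center, dtype=float)
            t = c - R @ c
        return cls(R, t)

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """Return ``self ∘ other`` (apply ``other`` first)."""
        return RigidTransform(
            self.rotation @ other.rotation,
            self.rotation @ other.translation + self.translation,
        )

    def __matmul__(self, other: "RigidTransform") -> "RigidTransform":
        return self.compose(other)

    def inverse(self) -> "RigidTransform":
        Rt = self.rotation.T
        return RigidTransform(Rt, -Rt @ self.translation)

    def apply_points(self, points: np.ndarray) -> np.ndarray:
        return points @ self.rotation.T + self.translation

    def apply_vectors(self, vectors: np.ndarray) -> np.ndarray:
        return vectors @ self.rotation.T


@dataclass(frozen=True)
class Neighborhood:
    """Points of a cloud inside a sphere around ``center``."""

    center: np.ndarray
    radius: float
    member_indices: np.ndarray


def neighbors_within(cloud: PointCloud, center, radius: float) -> Neighborhood:
    """Exact radius query: indices of all points within ``radius`` of ``center``.

    Indices are returned in ascending order, so the result is deterministic
    and independent of any spatial-index internals.
    """
    if len(cloud) == 0:
        raise ValueError("empty cloud")
    if radius <= 0:
        raise ValueError("radius must be positive")
    center = np.asarray(center, dtype=np.float64).reshape(3)
    tree = cKDTree(cloud.points)
    idx = np.asarray(sorted(tree.query_ball_point(center, radius)), dtype=np.intp)
    return Neighborhood(center=center, radius=float(radius), member_indices=idx)


def _fit_sphere(points: np.ndarray) -> tuple[np.ndarray, float] | None:
    """Algebraic least-squares sphere fit; returns (centre, radius) or None."""
    A = np.column_stack([2.0 * points, np.ones(len(points))])
    b = np.einsum("ij,ij->i", points, points)
    try:
        sol, *_ = np.linalg.lstsq(A, b, rcond=None)
    except np.linalg.LinAlgError:  # pragma: no cover - defensive
        return None
    center = sol[:3]
    r2 = sol[3] + center @ center
    if r2 <= 0 or not np.isfinite(r2):
        return None
    return center, float(np.sqrt(r2))


def estimate_normals_and_curvature(cloud: PointCloud, radius: float = 25.0) -> PointCloud:
    """Estimate per-point normals and curvature radii from radius neighborhoods.

    The normal at each point is the eigenvector of the neighborhood covariance
    with the smallest eigenvalue, flipped so it faces the sensor
    (``n . (0,0,1) < 0``).  The curvature radius comes from a least-squares
    sphere fit to the same neighborhood; neighborhoods that a plane explains
    essentially as well as the sphere (residual improvement below 1%), or whose
    fitted radius exceeds 10^4 mm, are flagged planar (radius ``inf``).
    """
    if radius <= 0:
        raise ValueError("radius must be positive")
    if len(cloud) == 0:
        raise ValueError("empty cloud")
    pts = cloud.points
    tree = cKDTree(pts)
    neighbor_lists = tree.query_ball_point(pts, radius, workers=-1)

    n = len(pts)
    normals = np.tile([0.0, 0.0, -1.0], (n, 1))
    radii = np.full(n, PLANAR_RADIUS)
    signs = np.zeros(n)

    for i, idx in enumerate(neighbor_lists):
        nb = pts[idx]
        if len(nb) < 3:
            continue  # keep default sensor-facing normal, planar flag
        centered = nb - nb.mean(axis=0)
        cov = centered.T @ centered / len(nb)
        evals, evecs = np.linalg.eigh(cov)
        normal = evecs[:, 0]
        if normal[2] > 0 or (normal[2] == 0 and (normal[0] < 0 or (normal[0] == 0 and normal[1] < 0))):
            normal = -normal
        normals[i] = normal
        if len(nb) < 5:
            continue  # too few members for a stable sphere fit: planar
        plane_rms = float(np.sqrt(max(evals[0], 0.0)))
        fit = _fit_sphere(nb)
        if fit is None:
            continue
        center, r = fit
        if r > _PLANAR_RADIUS_LIMIT:
            continue
        sphere_rms = float(np.sqrt(np.mean((np.linalg.norm(nb - center, axis=1) - r) ** 2)))
        if plane_rms <= 0 or (plane_rms - sphere_rms) < 0.01 * plane_rms:
            continue
        radii[i] = r
        signs[i] = 1.0 if (center - pts[i]) @ normal >= 0 else -1.0

    return PointCloud(
        points=pts.copy(),
        normals=normals,
        curvature_radii=radii,
        curvature_signs=signs,
        stage_tag=cloud.stage_tag,
    )


def apply_transform(cloud: PointCloud, xf: RigidTransform, stage_tag: str | None = None) -> PointCloud:
    """Apply a rigid transform to a cloud (points and normals)."""
    return PointCloud(
        points=xf.apply_points(cloud.points),
        normals=None if cloud.normals is None else xf.apply_vectors(cloud.normals),
        curvature_radii=None if cloud.curvature_radii is None else cloud.curvature_radii.copy(),
        curvature_signs=None if cloud.curvature_signs is None else cloud.curvature_signs.copy(),
        stage_tag=stage_tag or cloud.stage_tag,
    )
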