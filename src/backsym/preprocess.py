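"""Scan preprocessing: smoothing, region segmentation, body selection, pose.

The raw scan contains the back plus surrounding anatomy and the floor.  Three
steps turn it into a pose-normalized body cloud: a 3D moving-average filter
knocks down sensor noise, smoothness-constrained region growing splits the
scene into connected smooth regions, and the body region (large enough and
closest to the sensor) is re-expressed in its principal-axis frame so the
approximate median sagittal plane coincides with the x-z plane.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .geometry import PointCloud, RigidTransform, estimate_normals_and_curvature

__all__ = [
    "SegmentationResult",
    "smooth_cloud",
    "segment_regions",
    "select_body_region",
    "pose_normalize",
    "BODY_BBOX_SIDE_SUM_MM",
]

#: A region qualifies as body-sized when its axis-aligned bounding-box side
#: lengths sum to more than this (sensor frame, mm).
BODY_BBOX_SIDE_SUM_MM = 650.0


def smooth_cloud(raw: PointCloud, window_radius: float = 5.0) -> PointCloud:
    """3D moving-average filter: each point becomes its neighborhood centroid.

    The neighborhood is the sphere of ``window_radius`` mm around the original
    point (always containing the point itself), so the point count never
    changes and isolated points are left in place.
    """
    if len(raw) == 0:
        raise ValueError("empty cloud")
    if window_radius <= 0:
        raise ValueError("window_radius must be positive")
    pts = raw.points
    tree = cKDTree(pts)
    neighbor_lists = tree.query_ball_point(pts, window_radius, workers=-1)
    out = np.empty_like(pts)
    for i, idx in enumerate(neighbor_lists):
        out[i] = pts[idx].mean(axis=0)
    return PointCloud(points=out, stage_tag="P1")


@dataclass
class SegmentationResult:
    """Partition of a cloud into smooth connected regions plus the body pick."""

    regions: list[PointCloud]
    selected_index: int
    bbox_side_sums: np.ndarray
    mean_depths: np.ndarray
    labels: np.ndarray

    def to_diagnostics(self) -> dict:
        return {
            "n_regions": len(self.regions),
            "region_sizes": [len(r) for r in self.regions],
            "bbox_side_sums_mm": self.bbox_side_sums.tolist(),
            "mean_depths_mm": self.mean_depths.tolist(),
            "selected_index": int(self.selected_index),
        }


def _bbox_side_sum(points: np.ndarray) -> float:
    return float((points.max(axis=0) - points.min(axis=0)).sum())


def segment_regions(
    cloud: PointCloud,
    angle_threshold: float = 10.0,
    n_neighbors: int = 10,
    normal_radius: float = 25.0,
) -> SegmentationResult:
    """Smoothness-constrained region growing over a k-nearest-neighbor graph.

    Seeds are visited flattest-first (largest curvature radius first); a
    neighbor joins the region of the point that reached it when the angle
    between their normals is below ``angle_threshold`` degrees, and then
    spreads the region further.  Every point ends up in exactly one region.
    """
    if len(cloud) == 0:
        raise ValueError("empty cloud")
    if cloud.normals is None or cloud.curvature_radii is None:
        cloud = estimate_normals_and_curvature(cloud, radius=normal_radius)
    pts = cloud.points
    normals = cloud.normals
    n = len(pts)
    k = min(n_neighbors + 1, n)
    tree = cKDTree(pts)
    _, knn = tree.query(pts, k=k, workers=-1)
    knn = knn[:, 1:] if k > 1 else np.empty((n, 0), dtype=np.intp)

    cos_thresh = np.cos(np.radians(angle_threshold))
    # flattest first: planar (inf radius) points seed before curved ones;
    # index breaks ties so the partition is order-deterministic
    finite = np.where(np.isfinite(cloud.curvature_radii), cloud.curvature_radii, np.inf)
    seed_order = np.lexsort((np.arange(n), -finite))

    labels = np.full(n, -1, dtype=np.intp)
    n_regions = 0
    for seed in seed_order:
        if labels[seed] != -1:
            continue
        labels[seed] = n_regions
        stack = [seed]
        while stack:
            cur = stack.pop()
            for nb in knn[cur]:
                if labels[nb] != -1:
                    continue
                if abs(normals[cur] @ normals[nb]) >= cos_thresh:
                    labels[nb] = n_regions
                    stack.append(nb)
        n_regions += 1

    regions = [cloud.select(np.flatnonzero(labels == r)) for r in range(n_regions)]
    bbox_sums = np.array([_bbox_side_sum(r.points) for r in regions])
    mean_depths = np.array([r.points[:, 2].mean() for r in regions])
    selected = _select_index(bbox_sums, mean_depths)
    return SegmentationResult(
        regions=regions,
        selected_index=selected,
        bbox_side_sums=bbox_sums,
        mean_depths=mean_depths,
        labels=labels,
    )


def _select_index(bbox_sums: np.ndarray, mean_depths: np.ndarray) -> int:
    qualifying = np.flatnonzero(bbox_sums > BODY_BBOX_SIDE_SUM_MM)
    if len(qualifying) == 0:
        return -1
    return int(qualifying[np.argmin(mean_depths[qualifying])])


def select_body_region(seg: SegmentationResult) -> PointCloud:
    """The body: closest-to-sensor region whose bbox side sum exceeds 650 mm."""
    if seg.selected_index < 0:
        raise ValueError("no body-sized region found")
    return seg.regions[seg.selected_index].with_stage("P2")


def pose_normalize(body: PointCloud) -> tuple[PointCloud, RigidTransform]:
    """Align the body's principal axes with the coordinate axes.

    Largest-variance axis maps to x (craniocaudal), second to y (mediolateral),
    smallest to z, with the centroid at the origin, so the approximate median
    sagittal plane becomes the x-z plane.  Sign conventions: the new +z keeps
    the sensor viewing sense (the third axis is chosen with positive component
    along the old +z); +x puts the wider, breech end of the width profile at
    lower x; y completes a right-handed frame.
    """
    pts = body.points
    centroid = pts.mean(axis=0)
    centered = pts - centroid
    cov = centered.T @ centered / len(pts)
    evals, evecs = np.linalg.eigh(cov)  # ascending
    rel = np.diff(np.sort(evals)) / max(evals.max(), 1e-30)
    if np.any(rel <= 1e-9):
        raise ValueError("degenerate covariance: principal axes not separable")
    e_x = evecs[:, 2]
    e_z = evecs[:, 0]
    if e_z[2] < 0:  # keep depth increasing into the scene
        e_z = -e_z
    x_proj = centered @ e_x
    # breech (wider) half goes to lower x
    y_tmp = centered @ np.cross(e_z, e_x)
    upper = x_proj > np.median(x_proj)
    if np.std(y_tmp[upper]) > np.std(y_tmp[~upper]):
        e_x = -e_x
    e_y = np.cross(e_z, e_x)
    R = np.vstack([e_x, e_y, e_z])  # rows = new axes -> proper rotation
    if np.linalg.det(R) < 0:  # pragma: no cover - construction guarantees +1
        raise AssertionError("improper axis frame")
    xf = RigidTransform(R, -R @ centroid)
    out = PointCloud(
        points=xf.apply_points(pts),
        normals=None if body.normals is None else xf.apply_vectors(body.normals),
        curvature_radii=None if body.curvature_radii is None else body.curvature_radii.copy(),
        curvature_signs=None if body.curvature_signs is None else body.curvature_signs.copy(),
        stage_tag="P3",
    )
    return out, xf
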