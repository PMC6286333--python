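"""Deviation extraction and the asymmetry index.

Given the back cloud P4 and its best-fitted reflection P6r, two deviation
layers are computed.  A display layer casts a ray from every back point along
its normal onto a triangle mesh of the reflection and records the hit
distance (the deviation colormap).  The measurement layer re-aligns both
clouds to the principal axes of their union, resamples each on a common
regular x-y grid through local spherical surface patches, and averages the
unsigned point-to-plane deviation over the valid grid points:

    I_asym = (1/|G_v|) * sum_{(l,m) in G_v} d_{l,m}      [mm]

A perfectly mirror-symmetric back yields I_asym = 0; the index grows with
the prominence of paraspinal asymmetry.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import Delaunay, cKDTree

from .boundary import (
    crop_back,
    find_back_boundaries,
    fit_width_polynomial,
    project_to_binary,
    width_function,
)
from .config import RunConfig
from .geometry import PointCloud, RigidTransform, estimate_normals_and_curvature
from .preprocess import pose_normalize, segment_regions, select_body_region, smooth_cloud
from .registration import (
    best_fit_with_perturbations,
    make_optimal_reflection,
    reflect_sagittal,
    restrict_width,
)

__all__ = [
    "ColormapResult",
    "ResampledCloud",
    "ResampledGrid",
    "AsymmetryResult",
    "colormap_deviations",
    "align_union_axes",
    "resample_on_grid",
    "effective_and_valid_sets",
    "grid_deviations",
    "asymmetry_index",
    "run_pipeline",
]

log = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Stage 7: deviation colormap
# ---------------------------------------------------------------------------

@dataclass
class ColormapResult:
    """Per-point ray-cast distances from P4 to the mesh of P6r.

    ``distances`` has one slot per P4 point; NaN marks rays that missed the
    mesh or exceeded the gate.
    """

    vertices: np.ndarray
    triangles: np.ndarray
    distances: np.ndarray
    gate: float

    @property
    def valid_mask(self) -> np.ndarray:
        return np.isfinite(self.distances)


def _delaunay_mesh(points: np.ndarray, max_edge_factor: float = 4.0) -> np.ndarray:
    """Triangulate the xy projection; drop long-edge triangles bridging holes."""
    if len(points) < 3:
        raise ValueError("need at least 3 points to mesh")
    tri = Delaunay(points[:, :2])
    simplices = tri.simplices
    edges = points[simplices[:, [0, 1, 2]]] - points[simplices[:, [1, 2, 0]]]
    edge_len = np.linalg.norm(edges[:, :, :2], axis=2)
    tree = cKDTree(points[:, :2])
    spacing = np.median(tree.query(points[:, :2], k=2, workers=-1)[0][:, 1])
    keep = edge_len.max(axis=1) <= max_edge_factor * max(spacing, 1e-9)
    simplices = simplices[keep]
    if len(simplices) == 0:
        raise ValueError("mesh construction left no triangles")
    return simplices


def _ray_mesh_distances(
    origins: np.ndarray,
    directions: np.ndarray,
    vertices: np.ndarray,
    triangles: np.ndarray,
    gate: float,
) -> np.ndarray:
    """Nearest |t| along each bidirectional ray to the mesh, NaN beyond gate.

    Moeller-Trumbore intersection against candidate triangles only: for each
    ray, the candidates are triangles whose centroid lies within
    ``gate + circumradius_max`` of the origin.
    """
    v0 = vertices[triangles[:, 0]]
    e1 = vertices[triangles[:, 1]] - v0
    e2 = vertices[triangles[:, 2]] - v0
    centroids = (v0 + vertices[triangles[:, 1]] + vertices[triangles[:, 2]]) / 3.0
    tri_radius = np.maximum(
        np.linalg.norm(vertices[triangles[:, 0]] - centroids, axis=1),
        np.maximum(
            np.linalg.norm(vertices[triangles[:, 1]] - centroids, axis=1),
            np.linalg.norm(vertices[triangles[:, 2]] - centroids, axis=1),
        ),
    ).max()
    tree = cKDTree(centroids)
    candidates = tree.query_ball_point(origins, gate + tri_radius, workers=-1)

    out = np.full(len(origins), np.nan)
    for i, cand in enumerate(candidates):
        if not cand:
            continue
        cand = np.asarray(cand, dtype=np.intp)
        d = directions[i]
        h = np.cross(d, e2[cand])
        a = np.einsum("ij,ij->i", e1[cand], h)
        ok = np.abs(a) > 1e-12
        if not ok.any():
            continue
        f = np.zeros_like(a)
        f[ok] = 1.0 / a[ok]
        s = origins[i] - v0[cand]
        u = f * np.einsum("ij,ij->i", s, h)
        q = np.cross(s, e1[cand])
        v = f * (q @ d)
        t = f * np.einsum("ij,ij->i", e2[cand], q)
        hit = ok & (u >= -1e-12) & (v >= -1e-12) & (u + v <= 1 + 1e-12)
        if hit.any():
            t_abs = np.abs(t[hit])
            best = t_abs.min()
            if best <= gate:
                out[i] = best
    return out


def colormap_deviations(P4: PointCloud, P6r: PointCloud, gate: float = 100.0) -> ColormapResult:
    """Ray-cast deviations from each back point to the reflected-surface mesh.

    For every point of P4 the ray along its (bidirectional) normal is
    intersected with a Delaunay mesh of P6r; the nearest intersection distance
    is the deviation, ignored when it exceeds ``gate`` mm.
    """
    if P4.normals is None:
        raise ValueError("P4 must carry normals")
    triangles = _delaunay_mesh(P6r.points)
    distances = _ray_mesh_distances(P4.points, P4.normals, P6r.points, triangles, gate)
    return ColormapResult(vertices=P6r.points, triangles=triangles, distances=distances, gate=gate)


# ---------------------------------------------------------------------------
# Stage 8: union alignment, grid resampling, index
# ---------------------------------------------------------------------------

def align_union_axes(P4: PointCloud, P6r: PointCloud) -> tuple[PointCloud, PointCloud, RigidTransform]:
    """One rigid motion aligning the union's principal axes with x, y, z.

    The same transform is applied to both clouds, so their relative pose (and
    hence every deviation) is untouched; only the grid frame changes.
    """
    union = np.vstack([P4.points, P6r.points])
    merged, xf = pose_normalize(PointCloud(points=union))
    del merged

    def _move(cloud: PointCloud, tag: str) -> PointCloud:
        return PointCloud(
            points=xf.apply_points(cloud.points),
            normals=None if cloud.normals is None else xf.apply_vectors(cloud.normals),
            curvature_radii=None if cloud.curvature_radii is None else cloud.curvature_radii.copy(),
            curvature_signs=None if cloud.curvature_signs is None else cloud.curvature_signs.copy(),
            stage_tag=tag,
        )

    return _move(P4, "P7"), _move(P6r, "P7r"), xf


@dataclass
class ResampledCloud:
    """A cloud resampled at regular x-y grid nodes through local patches.

    Node ``(l, m)`` sits at ``(l * dx, m * dy)`` on the x-y plane; arrays are
    indexed ``[l - l0, m - m0]``.
    """

    l0: int
    m0: int
    dx: float
    dy: float
    points: np.ndarray     # (L, M, 3); NaN where ineffective
    effective: np.ndarray  # (L, M) bool

    @property
    def shape(self) -> tuple[int, int]:
        return self.effective.shape


def _grid_indices(xy_min: np.ndarray, xy_max: np.ndarray, dx: float, dy: float):
    l_lo = int(np.ceil(xy_min[0] / dx))
    l_hi = int(np.floor(xy_max[0] / dx))
    m_lo = int(np.ceil(xy_min[1] / dy))
    m_hi = int(np.floor(xy_max[1] / dy))
    return l_lo, l_hi, m_lo, m_hi


def resample_on_grid(
    cloud: PointCloud,
    dx: float = 3.0,
    dy: float = 3.0,
    r8: float = 25.0,
    grid_bounds: tuple[int, int, int, int] | None = None,
) -> ResampledCloud:
    """Resample a cloud at regular grid nodes via local spherical patches.

    At each node the cloud point whose xy projection is nearest to the node
    supplies a surface patch: the sphere through that point with its stored
    normal and curvature radius (a plane when flagged planar).  The node's
    resampled point is the intersection of the vertical line through the node
    with the patch, taking the intersection nearer the through-point.  A node
    is effective only when the nearest projected point lies within
    ``sqrt(dx^2 + dy^2)`` of the node and the intersection exists.
    """
    if cloud.normals is None or cloud.curvature_radii is None:
        cloud = estimate_normals_and_curvature(cloud, radius=r8)
    pts = cloud.points
    if grid_bounds is None:
        grid_bounds = _grid_indices(pts[:, :2].min(axis=0), pts[:, :2].max(axis=0), dx, dy)
    l_lo, l_hi, m_lo, m_hi = grid_bounds
    L, M = l_hi - l_lo + 1, m_hi - m_lo + 1
    if L < 1 or M < 1:
        raise ValueError("empty resampling grid")

    nodes = np.stack(
        np.meshgrid(np.arange(l_lo, l_hi + 1) * dx, np.arange(m_lo, m_hi + 1) * dy, indexing="ij"),
        axis=-1,
    ).reshape(-1, 2)
    tree = cKDTree(pts[:, :2])
    dist, nearest = tree.query(nodes, workers=-1)
    in_range = dist <= np.hypot(dx, dy)

    out_pts = np.full((L * M, 3), np.nan)
    effective = np.zeros(L * M, dtype=bool)
    planar = cloud.planar_mask
    for k in np.flatnonzero(in_range):
        j = nearest[k]
        p, n = pts[j], cloud.normals[j]
        gx, gy = nodes[k]
        if planar[j] or cloud.curvature_signs is None or cloud.curvature_signs[j] == 0:
            if abs(n[2]) < 1e-9:
                continue  # vertical patch: no unique height at this node
            z = p[2] - (n[0] * (gx - p[0]) + n[1] * (gy - p[1])) / n[2]
        else:
            rho = cloud.curvature_radii[j]
            c = p + cloud.curvature_signs[j] * rho * n
            disc = rho**2 - (gx - c[0]) ** 2 - (gy - c[1]) ** 2
            if disc < 0:
                continue  # vertical line misses the sphere
            root = np.sqrt(disc)
            z = c[2] + root if abs(c[2] + root - p[2]) <= abs(c[2] - root - p[2]) else c[2] - root
        out_pts[k] = (gx, gy, z)
        effective[k] = True

    return ResampledCloud(
        l0=l_lo, m0=m_lo, dx=dx, dy=dy,
        points=out_pts.reshape(L, M, 3),
        effective=effective.reshape(L, M),
    )


def effective_and_valid_sets(
    P8: ResampledCloud, P8r: ResampledCloud, alpha: float
) -> tuple[np.ndarray, np.ndarray]:
    """Effective and valid grid masks.

    A node is effective when both clouds resampled it.  Within each column l,
    nodes are valid when their row index m lies in the central range
    ``M_min(l) + 0.5 (1-alpha) W(l) <= m <= M_max(l) - 0.5 (1-alpha) W(l)``
    where the bounds and width ``W`` are taken over the effective nodes of the
    column; ``alpha = 1`` keeps every effective node, smaller alpha trims the
    error-prone silhouette edges.
    """
    if (P8.l0, P8.m0, P8.dx, P8.dy, P8.shape) != (P8r.l0, P8r.m0, P8r.dx, P8r.dy, P8r.shape):
        raise ValueError("resampled grids must share spacing and origin")
    if not 0 <= alpha <= 1:
        raise ValueError("alpha must be in [0, 1]")
    G_E = P8.effective & P8r.effective
    G_v = np.zeros_like(G_E)
    m_index = np.arange(G_E.shape[1]) + P8.m0
    for l in range(G_E.shape[0]):
        rows = np.flatnonzero(G_E[l])
        if len(rows) == 0:
            continue
        m_min = m_index[rows[0]]
        m_max = m_index[rows[-1]]
        margin = 0.5 * (1.0 - alpha) * (m_max - m_min)
        G_v[l] = G_E[l] & (m_index >= m_min + margin) & (m_index <= m_max - margin)
    if not G_v.any():
        raise ValueError("no valid grid points")
    return G_E, G_v


def grid_deviations(
    P8: ResampledCloud, P8r: ResampledCloud, G_v: np.ndarray, r8: float = 25.0
) -> tuple[np.ndarray, np.ndarray]:
    """Unsigned point-to-plane deviations at valid nodes.

    The plane at each valid node passes through the resampled point with a
    normal re-estimated by PCA over the resampled neighborhood of radius
    ``r8``; the deviation is the absolute distance of the mirrored resampled
    point from that plane.  Nodes with fewer than 3 neighbors are dropped
    from the valid set.  Returns ``(D, G_v)`` where D is NaN off the valid
    set.
    """
    eff_pts = P8.points[P8.effective]
    tree = cKDTree(eff_pts)
    D = np.full(P8.shape, np.nan)
    G_v = G_v.copy()
    for l, m in np.argwhere(G_v):
        p = P8.points[l, m]
        idx = tree.query_ball_point(p, r8)
        if len(idx) < 3:
            log.warning("grid node (%d, %d): %d neighbors, dropped from valid set",
                        l + P8.l0, m + P8.m0, len(idx))
            G_v[l, m] = False
            continue
        nb = eff_pts[idx]
        centered = nb - nb.mean(axis=0)
        _, evecs = np.linalg.eigh(centered.T @ centered)
        n = evecs[:, 0]
        D[l, m] = abs(n @ (P8r.points[l, m] - p))
    if not G_v.any():
        raise ValueError("no valid grid points")
    return D, G_v


def asymmetry_index(D: np.ndarray, G_v: np.ndarray) -> float:
    """Mean deviation over the valid grid set (mm)."""
    if not np.any(G_v):
        raise ValueError("no valid grid points")
    vals = D[G_v]
    if np.isnan(vals).any():
        raise ValueError("deviations missing at valid grid points")
    return float(vals.mean())


@dataclass
class ResampledGrid:
    """Everything the grid stage produced, for diagnostics and export."""

    P8: ResampledCloud
    P8r: ResampledCloud
    G_E: np.ndarray
    G_v: np.ndarray
    D: np.ndarray
    alpha: float

    def deviations_table(self) -> np.ndarray:
        """(l, m, x, y, d) rows over the valid set, for CSV export."""
        rows = []
        for l, m in np.argwhere(self.G_v):
            x, y, _ = self.P8.points[l, m]
            rows.append((l + self.P8.l0, m + self.P8.m0, x, y, self.D[l, m]))
        return np.asarray(rows)


@dataclass
class AsymmetryResult:
    i_asym: float
    valid_count: int
    grid: ResampledGrid
    colormap: ColormapResult | None
    elapsed: float
    stages: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "i_asym_mm": self.i_asym,
            "valid_grid_points": self.valid_count,
            "effective_grid_points": int(self.grid.G_E.sum()),
            "alpha": self.grid.alpha,
            "elapsed_s": self.elapsed,
            "stage_point_counts": {k: len(v) for k, v in self.stages.items()},
        }


def run_pipeline(raw: PointCloud, config: RunConfig | None = None) -> AsymmetryResult:
    """Full scan-to-index pipeline on a raw sensor cloud.

    Smooth, segment, pose-normalize, crop to the back, reflect across the
    sagittal plane, register the reflection by perturbation-restarted
    point-to-plane ICP, then extract deviations and the asymmetry index.
    """
    config = config or RunConfig()
    t0 = time.perf_counter()
    stages: dict[str, PointCloud] = {"P0": raw}

    def _fail(stage: str, err: Exception):
        raise RuntimeError(f"pipeline failed at stage {stage}: {err}") from err

    try:
        P1 = smooth_cloud(raw, config.smoothing_radius)
    except ValueError as e:
        _fail("P1 smoothing", e)
    stages["P1"] = P1
    log.info("P1 smoothing: %d points", len(P1))

    try:
        P1n = estimate_normals_and_curvature(P1, radius=config.normal_radius)
        seg = segment_regions(
            P1n,
            angle_threshold=config.segmentation_angle_threshold,
            n_neighbors=config.segmentation_neighbors,
        )
        P2 = select_body_region(seg)
    except ValueError as e:
        _fail("P2 segmentation", e)
    stages["P2"] = P2
    log.info("P2 segmentation: %d regions, body %d points", len(seg.regions), len(P2))

    try:
        P3, _ = pose_normalize(P2)
    except ValueError as e:
        _fail("P3 pose normalization", e)
    stages["P3"] = P3

    try:
        img = project_to_binary(P3, config.image_dx, config.image_dy)
        profile = fit_width_polynomial(width_function(img), order=config.polynomial_order)
        x_neck, x_breech = find_back_boundaries(profile)
        P4 = crop_back(P3, x_neck, x_breech).cropped
    except ValueError as e:
        _fail("P4 boundary detection", e)
    stages["P4"] = P4
    log.info("P4 back crop: x in [%.1f, %.1f], %d points", x_breech, x_neck, len(P4))

    P4r = reflect_sagittal(P4)
    try:
        P5 = restrict_width(P4, config.icp.width_fraction, stage_tag="P5")
        P5r = restrict_width(P4r, config.icp.width_fraction, stage_tag="P5r")
        icp_result = best_fit_with_perturbations(P5, P5r, config.icp)
    except ValueError as e:
        _fail("P6 mirror registration", e)
    P6r = make_optimal_reflection(P4r, icp_result)
    stages["P5"] = P5
    stages["P6r"] = P6r
    log.info("P6 registration: objective %.4g mm^2 over %d pairs",
             icp_result.objective_value, icp_result.valid_pair_count)

    # normals/curvature for the deviation stages, estimated once on P4 and
    # carried to P6r through the rigid maps
    P4n = estimate_normals_and_curvature(P4, radius=config.normal_radius)
    P6rn = make_optimal_reflection(reflect_sagittal(P4n), icp_result)

    colormap = None
    if config.compute_colormap:
        P4_rays = P4n
        if config.colormap_max_points and len(P4n) > config.colormap_max_points:
            step = int(np.ceil(len(P4n) / config.colormap_max_points))
            P4_rays = P4n.select(np.arange(0, len(P4n), step))
        try:
            colormap = colormap_deviations(P4_rays, P6rn, gate=config.colormap_gate)
        except ValueError as e:
            _fail("P7 colormap", e)

    try:
        P7, P7r, _ = align_union_axes(P4n, P6rn)
        union_xy = np.vstack([P7.points[:, :2], P7r.points[:, :2]])
        bounds = _grid_indices(union_xy.min(axis=0), union_xy.max(axis=0),
                               config.grid_dx, config.grid_dy)
        P8 = resample_on_grid(P7, config.grid_dx, config.grid_dy,
                              config.resample_radius, grid_bounds=bounds)
        P8r = resample_on_grid(P7r, config.grid_dx, config.grid_dy,
                               config.resample_radius, grid_bounds=bounds)
        G_E, G_v = effective_and_valid_sets(P8, P8r, config.alpha)
        D, G_v = grid_deviations(P8, P8r, G_v, config.resample_radius)
        index = asymmetry_index(D, G_v)
    except ValueError as e:
        _fail("P8 grid deviations", e)
    stages["P7"] = P7

    grid = ResampledGrid(P8=P8, P8r=P8r, G_E=G_E, G_v=G_v, D=D, alpha=config.alpha)
    elapsed = time.perf_counter() - t0
    log.info("I_asym = %.3f mm over %d valid grid points (%.2f s)",
             index, int(G_v.sum()), elapsed)
    return AsymmetryResult(
        i_asym=index,
        valid_count=int(G_v.sum()),
        grid=grid,
        colormap=colormap,
        elapsed=elapsed,
        stages=stages,
    )
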