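"""Mirror registration: reflect the back across the sagittal plane and find
the rigid motion that best fits the reflection onto the original surface.

The registration objective is the mean squared point-to-plane distance

    (1/|pairs|) * sum_i | n_c(i) . (R p_i + t - p_c(i)) |^2

over closest-point pairs between the fixed cloud (which supplies the tangent
planes) and the moving reflected cloud, with pairs discarded when the angle
between the paired normals exceeds a gate (50 degrees by default).  Because
the converged fit depends slightly on the initial orientation, ICP is
restarted from a grid of small x/y pre-rotations and the best final objective
wins.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree
from scipy.spatial.transform import Rotation

from .geometry import PointCloud, RigidTransform, apply_transform, estimate_normals_and_curvature

__all__ = [
    "ICPConfig",
    "ICPResult",
    "reflect_sagittal",
    "restrict_width",
    "icp_point_to_plane",
    "best_fit_with_perturbations",
    "make_optimal_reflection",
]

log = logging.getLogger(__name__)


@dataclass
class ICPConfig:
    """Parameters of the perturbation-restarted point-to-plane ICP."""

    normal_angle_threshold: float = 50.0   # degrees; pair-validity gate
    perturbation_range: float = 5.0        # degrees, +/- about x and y
    perturbation_interval: float = 1.25    # degrees between restart angles
    iterations_per_start: int = 50
    neighborhood_radius: float = 25.0      # mm; r5 for normal estimation
    width_fraction: float = 0.90           # central y-fraction kept for fitting
    max_correspondence_distance: float | None = None  # mm; off by default
    convergence_tol: float | None = None   # mm^2; optional early stop, off by default

    def __post_init__(self) -> None:
        ratio = self.perturbation_range / self.perturbation_interval
        if abs(ratio - round(ratio)) > 1e-9:
            raise ValueError("perturbation_range must be divisible by perturbation_interval")
        if self.iterations_per_start < 1:
            raise ValueError("iterations_per_start must be >= 1")
        if not 0 < self.width_fraction <= 1:
            raise ValueError("width_fraction must be in (0, 1]")

    def perturbation_angles(self) -> np.ndarray:
        n = int(round(self.perturbation_range / self.perturbation_interval))
        return np.arange(-n, n + 1) * self.perturbation_interval


@dataclass
class ICPResult:
    """Outcome of one or many ICP runs."""

    best_transform: RigidTransform
    objective_value: float                  # mean squared point-to-plane distance, mm^2
    per_start_objectives: list[float] = field(default_factory=list)
    valid_pair_count: int = 0
    objective_history: list[float] = field(default_factory=list)


def reflect_sagittal(cloud: PointCloud) -> PointCloud:
    """Mirror a pose-normalized cloud across the x-z (sagittal) plane."""
    pts = cloud.points * np.array([1.0, -1.0, 1.0])
    normals = None if cloud.normals is None else cloud.normals * np.array([1.0, -1.0, 1.0])
    return PointCloud(
        points=pts,
        normals=normals,
        curvature_radii=None if cloud.curvature_radii is None else cloud.curvature_radii.copy(),
        curvature_signs=None if cloud.curvature_signs is None else cloud.curvature_signs.copy(),
        stage_tag="P4r",
    )


def restrict_width(cloud: PointCloud, width_fraction: float = 0.90, stage_tag: str | None = None) -> PointCloud:
    """Keep the central ``width_fraction`` of the cloud's y extent.

    Points near the silhouette boundary carry the largest sensor error, so a
    symmetric margin of ``(1 - f)/2`` of the y extent is trimmed per side
    before fitting.
    """
    if not 0 < width_fraction <= 1:
        raise ValueError("width_fraction must be in (0, 1]")
    y = cloud.points[:, 1]
    lo, hi = y.min(), y.max()
    margin = 0.5 * (1.0 - width_fraction) * (hi - lo)
    mask = (y >= lo + margin) & (y <= hi - margin)
    if not mask.any():
        raise ValueError("width restriction left no points")
    return cloud.select(np.flatnonzero(mask), stage_tag=stage_tag or cloud.stage_tag)


def _require_normals(cloud: PointCloud, radius: float) -> PointCloud:
    if cloud.normals is None:
        return estimate_normals_and_curvature(cloud, radius=radius)
    return cloud


def _pair_and_objective(
    tree: cKDTree,
    fixed_pts: np.ndarray,
    fixed_normals: np.ndarray,
    moved_pts: np.ndarray,
    moved_normals: np.ndarray,
    cos_gate: float,
    max_dist: float | None,
):
    dists, idx = tree.query(moved_pts, workers=-1)
    valid = np.einsum("ij,ij->i", fixed_normals[idx], moved_normals) >= cos_gate
    if max_dist is not None:
        valid &= dists <= max_dist
    sel = np.flatnonzero(valid)
    n = fixed_normals[idx[sel]]
    resid = np.einsum("ij,ij->i", n, moved_pts[sel] - fixed_pts[idx[sel]])
    return sel, idx[sel], n, resid


def icp_point_to_plane(
    fixed: PointCloud,
    moving: PointCloud,
    cfg: ICPConfig | None = None,
    initial: RigidTransform | None = None,
) -> ICPResult:
    """Point-to-plane ICP of ``moving`` onto ``fixed`` from one initial pose.

    Runs exactly ``cfg.iterations_per_start`` iterations (no early stop unless
    ``cfg.convergence_tol`` is set).  Each iteration pairs every moving point
    with its closest fixed point, discards pairs whose normals disagree by
    more than the gate angle, and solves the small-angle linearization of the
    point-to-plane objective for an incremental rigid motion.
    """
    cfg = cfg or ICPConfig()
    initial = initial or RigidTransform.identity()
    fixed = _require_normals(fixed, cfg.neighborhood_radius)
    moving = _require_normals(moving, cfg.neighborhood_radius)
    if len(moving) == 0:
        raise ValueError("empty moving cloud")

    tree = cKDTree(fixed.points)
    cos_gate = np.cos(np.radians(cfg.normal_angle_threshold))
    T = initial
    history: list[float] = []

    for _ in range(cfg.iterations_per_start):
        moved = T.apply_points(moving.points)
        moved_n = T.apply_vectors(moving.normals)
        sel, pair_idx, n, resid = _pair_and_objective(
            tree, fixed.points, fixed.normals, moved, moved_n,
            cos_gate, cfg.max_correspondence_distance,
        )
        if len(sel) == 0:
            raise ValueError("registration diverged: zero valid pairs")
        history.append(float(np.mean(resid**2)))
        if len(history) > 1 and history[-1] > history[-2] + 1e-9 * max(1.0, history[-2]):
            log.debug("ICP objective increased at iteration %d: %.3g -> %.3g",
                      len(history) - 1, history[-2], history[-1])
        A = np.hstack([np.cross(moved[sel], n), n])
        sol, *_ = np.linalg.lstsq(A, -resid, rcond=None)
        inc = RigidTransform(Rotation.from_rotvec(sol[:3]).as_matrix(), sol[3:])
        T = inc @ T
        if cfg.convergence_tol is not None and len(history) > 1:
            if abs(history[-2] - history[-1]) < cfg.convergence_tol:
                break

    moved = T.apply_points(moving.points)
    moved_n = T.apply_vectors(moving.normals)
    sel, _, n, resid = _pair_and_objective(
        tree, fixed.points, fixed.normals, moved, moved_n,
        cos_gate, cfg.max_correspondence_distance,
    )
    if len(sel) == 0:
        raise ValueError("registration diverged: zero valid pairs")
    objective = float(np.mean(resid**2))
    history.append(objective)
    return ICPResult(
        best_transform=T,
        objective_value=objective,
        per_start_objectives=[objective],
        valid_pair_count=int(len(sel)),
        objective_history=history,
    )


def best_fit_with_perturbations(
    fixed: PointCloud,
    moving: PointCloud,
    cfg: ICPConfig | None = None,
) -> ICPResult:
    """ICP restarted from a grid of small x/y pre-rotations; best fit wins.

    Each restart pre-rotates the moving cloud about its centroid by one
    (angle_x, angle_y) pair from the perturbation grid.  Restarts are
    independent; ties in the final objective break toward the lowest
    (x-index, y-index) pair, so the result does not depend on evaluation
    order.
    """
    cfg = cfg or ICPConfig()
    fixed = _require_normals(fixed, cfg.neighborhood_radius)
    moving = _require_normals(moving, cfg.neighborhood_radius)
    centroid = moving.points.mean(axis=0)
    angles = cfg.perturbation_angles()

    best: ICPResult | None = None
    objectives: list[float] = []
    for ax in angles:
        for ay in angles:
            Rx = RigidTransform.from_rotvec([ax, 0.0, 0.0], center=centroid)
            Ry = RigidTransform.from_rotvec([0.0, ay, 0.0], center=centroid)
            try:
                res = icp_point_to_plane(fixed, moving, cfg, initial=Rx @ Ry)
            except ValueError:
                objectives.append(np.inf)
                continue
            objectives.append(res.objective_value)
            if best is None or res.objective_value < best.objective_value:
                best = res
    if best is None:
        raise ValueError("registration diverged from every restart")
    best.per_start_objectives = objectives
    return best


def make_optimal_reflection(P4r: PointCloud, result: ICPResult) -> PointCloud:
    """Apply the optimal fit to the full reflected cloud, producing P6r."""
    return apply_transform(P4r, result.best_transform, stage_tag="P6r")
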