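"""Parametric synthetic scans of a forward-bending subject.

The generator emulates what a consumer depth sensor captures during the
Adams forward-bending test: the back plus breech, neck and occiput surfaces,
an optional floor plane behind the subject, a controllable scoliotic
deformity (a one-sided paraspinal hump, the surface expression of the rib
prominence), pose perturbations, and additive Gaussian depth noise.

The silhouette half-width along the craniocaudal axis is a degree-6
polynomial constructed from its planted extrema: maxima at the breech,
shoulders and occiput, minima at the breech-back and back-neck boundaries.
Those two minima are exactly the constrictions the boundary-detection stage
must find, so fixtures know their ground-truth crop planes.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from numpy.polynomial import Polynomial

from .geometry import PointCloud, RigidTransform

__all__ = ["TorsoSpec", "generate_scan", "generate_cohort"]


@dataclass(frozen=True)
class TorsoSpec:
    """Parameters of one synthetic forward-bend scan.

    Lengths in mm, angles in degrees.  Generation is a pure function of the
    spec (including its seed).
    """

    trunk_length: float = 450.0
    hump_amplitude: float = 0.0      # a: peak height of the paraspinal hump
    hump_center: tuple[float, float] | None = None  # (x, y) in the body frame
    hump_spread: float = 35.0        # Gaussian sigma across the hump
    curve_type: str = "single_thoracic"  # or "double", "thoracolumbar"
    include_floor: bool = True
    include_neck: bool = True
    include_breech: bool = True
    rot_x: float = 0.0               # pose perturbation about each axis
    rot_y: float = 0.0
    rot_z: float = 0.0
    noise_sigma: float = 0.0         # mm, depth noise
    pitch: float = 2.5               # mm, surface sampling
    body_depth: float = 900.0        # mm, distance sensor -> back
    floor_depth_offset: float = 500.0  # mm, floor behind the back surface
    seed: int = 0

    def __post_init__(self) -> None:
        if self.hump_amplitude < 0 or self.noise_sigma < 0 or self.pitch <= 0:
            raise ValueError("invalid spec: amplitude/noise must be >= 0, pitch > 0")
        if self.curve_type not in ("single_thoracic", "double", "thoracolumbar"):
            raise ValueError(f"unknown curve_type {self.curve_type!r}")

    # -- anatomy layout in the body frame (x = 0 at the caudal end) --------

    @property
    def x_breech_boundary(self) -> float:
        """Planted breech-back constriction (caudal width minimum)."""
        return 180.0

    @property
    def x_neck_boundary(self) -> float:
        """Planted back-neck constriction (cranial width minimum)."""
        return self.x_breech_boundary + self.trunk_length

    @property
    def total_length(self) -> float:
        occiput = 160.0 if self.include_neck else 0.0
        return self.x_neck_boundary + occiput

    def width_polynomial(self) -> Polynomial:
        """Degree-6 half-width polynomial with the planted extrema."""
        x2, x4 = self.x_breech_boundary, self.x_neck_boundary
        extrema = [70.0, x2, x2 + 0.57 * self.trunk_length, x4, x4 + 100.0]
        dw = Polynomial([-1.0])
        for r in extrema:
            dw = dw * Polynomial([-r, 1.0])
        w = dw.integ()
        xs = np.linspace(0.0, self.total_length, 400)
        vals = w(xs)
        lo, hi = vals.min(), vals.max()
        # affine map (preserves extrema locations) to half-widths 60..180 mm
        return (w - lo) * (120.0 / (hi - lo)) + 60.0

    def hump_centers(self) -> list[tuple[float, float, float]]:
        """(x, y, relative amplitude) of each hump for the curve type."""
        x2 = self.x_breech_boundary
        if self.hump_center is not None:
            main = (*self.hump_center, 1.0)
        elif self.curve_type == "thoracolumbar":
            main = (x2 + 0.35 * self.trunk_length, 45.0, 1.0)
        else:
            main = (x2 + 0.62 * self.trunk_length, 45.0, 1.0)
        humps = [main]
        if self.curve_type == "double":
            humps.append((x2 + 0.25 * self.trunk_length, -40.0, 0.8))
        return humps


def _body_surface(spec: TorsoSpec) -> np.ndarray:
    """Sample the noiseless body surface on a y-symmetric grid (body frame)."""
    wpoly = spec.width_polynomial()
    x_lo = 0.0 if spec.include_breech else spec.x_breech_boundary
    x_hi = spec.total_length if spec.include_neck else spec.x_neck_boundary
    xs = np.arange(x_lo, x_hi + 1e-9, spec.pitch)
    mid = 0.5 * (x_lo + x_hi)
    humps = spec.hump_centers()

    rows = []
    for x in xs:
        w = float(wpoly(x))
        m = int(np.floor(w / spec.pitch))
        ys = np.arange(-m, m + 1) * spec.pitch
        # rounded cross-section, apex toward the sensor, plus a gentle
        # longitudinal bow emulating the forward-bend kyphosis
        z = (
            spec.body_depth
            + 60.0 * ((x - mid) / max(x_hi - x_lo, 1.0)) ** 2 * 4.0
            - 70.0 * np.cos(0.5 * np.pi * ys / max(w, 1e-9))
        )
        for xc, yc, rel in humps:
            z -= (
                spec.hump_amplitude
                * rel
                * np.exp(
                    -((x - xc) ** 2) / (2 * (1.5 * spec.hump_spread) ** 2)
                    - ((ys - yc) ** 2) / (2 * spec.hump_spread**2)
                )
            )
        rows.append(np.column_stack([np.full_like(ys, x), ys, z]))
    return np.vstack(rows)


def generate_scan(spec: TorsoSpec) -> PointCloud:
    """Generate one raw scan (sensor frame, stage P0) from a spec."""
    rng = np.random.default_rng(spec.seed)
    body = _body_surface(spec)
    body[:, 0] -= 0.5 * spec.total_length  # centre the subject on the sensor axis

    if spec.noise_sigma > 0:
        body[:, 2] += rng.normal(0.0, spec.noise_sigma, size=len(body))

    if any((spec.rot_x, spec.rot_y, spec.rot_z)):
        centroid = body.mean(axis=0)
        xf = (
            RigidTransform.from_rotvec([0.0, 0.0, spec.rot_z], center=centroid)
            @ RigidTransform.from_rotvec([0.0, spec.rot_y, 0.0], center=centroid)
            @ RigidTransform.from_rotvec([spec.rot_x, 0.0, 0.0], center=centroid)
        )
        body = xf.apply_points(body)

    parts = [body]
    if spec.include_floor:
        pitch = 25.0
        fx = np.arange(-700.0, 700.0 + 1e-9, pitch)
        fy = np.arange(-750.0, 750.0 + 1e-9, pitch)
        gx, gy = np.meshgrid(fx, fy, indexing="ij")
        fz = np.full(gx.size, spec.body_depth + spec.floor_depth_offset)
        if spec.noise_sigma > 0:
            fz = fz + rng.normal(0.0, spec.noise_sigma, size=fz.size)
        parts.append(np.column_stack([gx.ravel(), gy.ravel(), fz]))

    return PointCloud(points=np.vstack(parts), stage_tag="P0")


def generate_cohort(
    n: int,
    cobb_to_amplitude=None,
    seed: int = 0,
    config=None,
    base_spec: TorsoSpec | None = None,
    cobb_range: tuple[float, float] = (0.0, 50.0),
    curve_types: tuple[str, ...] = ("single_thoracic", "double", "thoracolumbar"),
):
    """Generate a cohort of scans and run the pipeline on each.

    Cobb angles are drawn uniformly from ``cobb_range`` and mapped to hump
    amplitudes by ``cobb_to_amplitude`` (default 0.15 mm per degree, a
    monotone surrogate: no forward model from Cobb angle to surface shape is
    assumed).  Returns a ``ScreeningDataset`` of paired (Cobb, I_asym)
    records.
    """
    from .asymmetry import run_pipeline
    from .stats import ScreeningDataset, ScreeningRecord

    if n < 2:
        raise ValueError("cohort needs at least 2 subjects")
    if cobb_to_amplitude is None:
        cobb_to_amplitude = lambda cobb: 0.15 * cobb  # noqa: E731
    rng = np.random.default_rng(seed)
    base = base_spec or TorsoSpec()

    records = []
    for i in range(n):
        cobb = float(rng.uniform(*cobb_range))
        curve = curve_types[int(rng.integers(len(curve_types)))]
        scan_seed = int(rng.integers(2**31 - 1))
        spec = replace(
            base,
            hump_amplitude=float(cobb_to_amplitude(cobb)),
            curve_type=curve,
            seed=scan_seed,
        )
        result = run_pipeline(generate_scan(spec), config)
        records.append(
            ScreeningRecord(
                subject_id=f"synthetic-{i:03d}",
                i_asym=result.i_asym,
                cobb=cobb,
                curve_type=curve,
                seed=scan_seed,
            )
        )
    return ScreeningDataset(records=records)
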