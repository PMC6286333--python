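# Methods

This note records the model, the defaults that matter, the numerical
choices, and what the synthetic experiments do and do not demonstrate.

## Coordinate conventions

All coordinates are millimetres. The sensor sits at the origin looking along
+z (depth increases into the scene). After pose normalization, +x is
craniocaudal with the breech at lower x, +y mediolateral, and the
approximate median sagittal plane is the x–z plane. Surface normals are
oriented to face the sensor (n_z < 0); PCA normals are sign-ambiguous, so
this flip is applied explicitly.

## The asymmetry model

The back surface of a forward-bending subject is compared with its own
mirror image. Reflection across the estimated sagittal plane followed by a
*rigid* best fit absorbs the arbitrary pose of the subject, so the residual
deviation between the surface and its fitted reflection measures intrinsic
left–right asymmetry rather than positioning. The index is the mean
unsigned point-to-plane deviation over a valid grid region:

    I_asym = (1/|G_v|) Σ_{(l,m) ∈ G_v} d_{l,m}   [mm]

Deviations are averaged as magnitudes: the screening question is "how
asymmetric", not "which side". A signed variant exists only for colormap
display.

## Stage parameters (defaults and rationale)

| parameter | default | role |
|---|---|---|
| smoothing window | 5 mm | moving-average radius; 2–4× the sensor's point spacing, one pass |
| region-growing gate | 10° | normal-angle smoothness constraint; neighbor graph = 10-NN, seeds flattest-first |
| body size gate | 650 mm | min sum of bbox side lengths for a body-sized region |
| width polynomial | order 10 | silhouette width fit for neck/breech minima |
| width restriction | central 90 % | trims silhouette edges with the largest sensor error before ICP |
| ICP normal gate | 50° | drops miscorresponding closest-point pairs |
| ICP restarts | ±5° x/y grid, 1.25° steps | converged fit depends slightly on the initial orientation; best final objective wins |
| ICP iterations | 50 per start | fixed count, no early stop (a tolerance stop exists but is off) |
| estimation radii r5, r8 | 25 mm | PCA normal/curvature neighborhoods, original and resampled clouds |
| colormap gate | 100 mm | ray-cast distances above this are ignored |
| resampling grid Δx, Δy | 3 mm | matches the sensor's spatial sampling resolution |
| validity fraction α | 0.9 | central fraction of each grid column kept for the index |
| posture limits | 7.5° (x), 15° (y) | tilt gate on the detected body plane before analysis |

## Numerical and design choices

**Curvature estimation.** Normals come from the smallest-eigenvalue
eigenvector of the neighborhood covariance. The curvature radius comes from
an algebraic least-squares sphere fit to the same neighborhood; a
neighborhood is flagged planar when the sphere's orthogonal residual
improves on the tangent plane's by less than 1 %, when the fitted radius
exceeds 10⁴ mm, or when fewer than 5 neighbors exist. The side of the
surface on which the sphere centre lies is stored separately so the patch
can be reconstructed exactly during resampling.

**Region growing.** The neighbor-to-current-point normal angle is the
growth criterion (the classic smoothness constraint); every accepted point
spreads the region further. Seeds are visited flattest-first with index
tie-breaks, so the partition is deterministic and independent of point
order up to relabeling.

**Pose sign disambiguation.** PCA axes have arbitrary signs. The third axis
keeps the sensor's depth sense (positive component along old +z); +x puts
the wider (breech) half of the width profile at lower x; y completes a
right-handed frame. Any deterministic rule would do — the mirror
registration re-fits pose — but this one keeps "cranial/caudal" semantics
stable for the boundary stage.

**Width polynomial conditioning.** A raw 10th-order fit on a millimetre
abscissa is numerically hostile; the fit runs on the abscissa mapped to
[−1, 1] (`numpy.polynomial.Polynomial.fit`). Boundary minima are taken from
the exact roots of the fitted derivative: the neck is the deepest interior
minimum in the cranial 40 % of the domain, the breech the deepest in the
caudal 30 %, with domain-end fallbacks and a logged warning when a minimum
is missing. The crop is an x-range only; the y extent is kept.

**ICP solver.** Each iteration pairs every moving point with its closest
fixed point (k-d tree, exact), gates pairs on the angle between the fixed
normal and the *currently rotated* moving normal, and solves the standard
small-angle linearization of the point-to-plane objective (6-DOF linear
least squares), composing the increment via an exact rotation-vector
exponential. There is no distance gate by default (only the 50° normal
gate); an optional max-correspondence distance exists in the config.
Restarts are independent pure functions with a lexicographic tie-break, so
evaluation order cannot change the result.

**Colormap ray casting.** The reflected cloud is meshed by Delaunay
triangulation of its x–y projection, discarding triangles whose longest
edge exceeds 4× the median point spacing (prevents bridging holes). Rays
run bidirectionally along each back point's normal; intersection uses
Möller–Trumbore against candidate triangles preselected by a centroid
radius query. The brute-force all-triangle intersection is kept as a test
oracle. Display scale is linear, saturating at 10 mm.

**Resampling patches.** At each grid node the cloud point whose x–y
projection is nearest supplies the patch: the stored osculating sphere, or
the tangent plane when flagged planar. The vertical line through the node
intersects the patch at up to two points; the one nearer the through-point
is taken. A node is effective only when the nearest projected point lies
within √(Δx² + Δy²) of the node — one grid diagonal, the natural "there is
actually surface here" radius — and the intersection exists. The per-column
valid range
M_min(l) + 0.5(1−α)W(l) ≤ m ≤ M_max(l) − 0.5(1−α)W(l)
is applied verbatim per column, with the bounds taken over the nodes
effective in both clouds. Deviation normals are re-estimated by PCA on the
*resampled* cloud within r8; nodes with fewer than 3 neighbors are dropped
from the valid set with a warning.

**Screening statistics.** ROC cut-offs are midpoints between consecutive
distinct scores (positive prediction at score ≥ cut-off); AUC is
trapezoidal and equals the Mann–Whitney U formulation, which the tests
assert. Youden ties break toward the lower cut-off, favoring sensitivity in
a screening context. The AUC interval is DeLong by default with a seeded
percentile bootstrap as an option. CV uses the sample (n−1) SD. The ICC is
the two-way absolute-agreement single-measure form with the F-distribution
interval; this model choice shifts values relative to consistency or
averaged-measure forms and is stated wherever the ICC is reported.
Likelihood ratios follow the screening-table conventions: x/0 with x > 0 is
∞, 0/0 is flagged NaN.

## The synthetic torso

The generator emulates what the sensor captures: back + breech + neck +
occiput surfaces, an optional floor plane ≥ 400 mm behind the body, pose
perturbations about all three axes, and Gaussian depth noise on z.

The silhouette half-width along x is a degree-6 polynomial *constructed
from its planted extrema* (breech, shoulder and occiput maxima; breech-back
and back-neck minima), so every fixture knows its ground-truth crop planes
and the 10th-order width fit can represent the profile exactly. Cross
sections are cosine arcs (apex toward the sensor) over a gentle
longitudinal bow; sampling is on a y-symmetric grid so the zero-deformity
surface is *exactly* mirror symmetric. The deformity is an additive
anisotropic Gaussian hump on one paraspinal side (two humps on opposite
sides for double curves) — the simplest shape producing the rib-hump
asymmetry the forward bend exposes. Hump amplitude serves as a monotone
severity proxy when generating cohorts (default 0.15 mm per Cobb degree);
no biomechanical forward model from Cobb angle to surface shape is claimed,
so synthetic correlations must not be compared numerically with clinical
ones. Noise defaults: 1.0 mm emulates a consumer sensor, 0.2 mm a
high-definition digitizer.

What the phantom does *not* model: clothing and hair artifacts, soft-tissue
deformation between poses, sensor-specific systematic distortion, arms and
hands in the field of view, and realistic spine-to-surface mechanics.
Passing tests therefore demonstrate the correctness and stability of the
geometry and statistics, not clinical performance.

## Problem sizes and the desk-scale profile

Phantom experiments sample the surface at 5 mm pitch (≈ 12 000 points per
scan) and run the registration with a reduced 3×3 restart grid
(±2.5° at 2.5° steps) with the boundary-image pixel matched to the sampling
pitch; these are the package's desk-scale defaults for simulation studies,
chosen so a full experiment (a dozen pipeline runs) completes in minutes.
The full ±5°/1.25° grid (81 starts) remains the config default for real
scans. One caveat found while fixturing: the boundary-image pixel should
not be finer than the cloud's point spacing, otherwise silhouette columns
develop spurious gaps.

## Known limitations

- The index inflates with depth noise (unsigned deviations cannot average
  noise away), so indices are comparable only at matched noise levels —
  the motivation for the smoothing stage.
- Thoracolumbar humps sit near the breech crop boundary; part of such a
  deformity can fall outside P⁴, echoing the method's weaker performance on
  low curves.
- The sagittal-plane estimate assumes the dominant variance axes of the
  body are meaningful; extreme occlusion or truncated scans violate the
  650 mm gate before this becomes an issue.
- Reflection-and-rigid-fit is the only symmetry parameterization; no
  non-rigid registration is attempted.
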